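import pytest
from Bio.Seq import Seq

from snv2struct.consequence import (
    ConsequenceRecord,
    TranslationError,
    call_consequence,
    hgvs_p,
    translate,
)
from snv2struct.fixtures import VARIANT_POS_PLUS
from snv2struct.gene_models import cds_to_genomic, spliced_cds_sequence
from snv2struct.variant_io import GenomicVariant, parse_variant_table

from .oracles import retranslation_oracle


class TestTranslate:
    def test_trailing_stop_removed(self):
        assert translate("ATGGCCTAA") == "MA"
        assert translate("ATGTAA") == "M"

    def test_internal_stop_retained(self):
        assert translate("ATGTAAGCCTAA") == "M*A"

    def test_all_64_codons_against_independent_table(self):
        bases = "ACGT"
        for a in bases:
            for b in bases:
                for c in bases:
                    codon = a + b + c
                    # pad with a non-stop codon so the trailing-stop rule
                    # does not interfere with the codon under test
                    mine = translate(codon + "GGG")[0]
                    ref = str(Seq(codon).translate())
                    assert mine == ref, codon

    def test_non_acgt_names_offending_codon(self):
        with pytest.raises(TranslationError, match="ANG"):
            translate("ATGANGTAA")

    def test_length_must_be_multiple_of_three(self):
        with pytest.raises(TranslationError):
            translate("ATGA")


class TestHgvsP:
    def test_missense(self):
        rec = ConsequenceRecord("T", "missense", aa_pos=12, ref_aa="G", alt_aa="C")
        assert hgvs_p(rec) == "p.Gly12Cys"

    def test_synonymous(self):
        rec = ConsequenceRecord("T", "synonymous", aa_pos=3, ref_aa="L", alt_aa="L")
        assert hgvs_p(rec) == "p.(=)"

    def test_stop_written_ter(self):
        rec = ConsequenceRecord("T", "stop_gained", aa_pos=5, ref_aa="Y", alt_aa="*")
        assert hgvs_p(rec) == "p.Tyr5Ter"
        rec = ConsequenceRecord("T", "stop_lost", aa_pos=50, ref_aa="*", alt_aa="Q")
        assert hgvs_p(rec) == "p.Ter50Gln"

    def test_missing_fields_error(self):
        with pytest.raises(ValueError):
            hgvs_p(ConsequenceRecord("T", "missense"))


def fixture_variant(bundle):
    with open(bundle.variants) as fh:
        (v,), _ = parse_variant_table(fh)
    return v


class TestCallConsequence:
    def test_fixture_missense_gga_to_gca(self, bundle_plus, resources_plus):
        v = fixture_variant(bundle_plus)
        models = {t.transcript_id: t for t in resources_plus.transcripts}
        rec = call_consequence(models["TR1"], resources_plus.genome, v)
        assert rec.consequence == "missense"
        assert (rec.ref_codon, rec.alt_codon) == ("GGA", "GCA")
        assert (rec.ref_aa, rec.alt_aa) == ("G", "A")
        oracle = retranslation_oracle(models["TR1"], resources_plus.genome, rec.cds_pos, "C")
        assert rec.aa_pos == oracle["aa_pos"]

    def test_variant_absent_from_spliced_out_exon(self, bundle_plus, resources_plus):
        """The variant's exon is spliced out of TR2, so no protein position."""
        v = fixture_variant(bundle_plus)
        models = {t.transcript_id: t for t in resources_plus.transcripts}
        rec = call_consequence(models["TR2"], resources_plus.genome, v)
        assert rec.consequence == "intronic"
        assert rec.aa_pos is None

    def test_stop_gained(self, resources_plus):
        """TAC -> TAA via an offset-2 substitution is a gained stop."""
        models = {t.transcript_id: t for t in resources_plus.transcripts}
        tm = models["TR1"]
        genome = resources_plus.genome
        cds = spliced_cds_sequence(tm, genome)
        # find any codon whose third base can mutate into a stop
        for aa_pos in range(2, len(cds) // 3):
            codon = cds[(aa_pos - 1) * 3 : aa_pos * 3]
            for stop in ("TAA", "TAG", "TGA"):
                if codon[:2] == stop[:2] and codon[2] != stop[2]:
                    cds_pos = (aa_pos - 1) * 3 + 3
                    gpos = cds_to_genomic(tm, cds_pos)
                    alt = stop[2] if tm.strand == "+" else {"A": "T", "C": "G", "G": "C", "T": "A"}[stop[2]]
                    v = GenomicVariant(tm.chrom, gpos, genome[tm.chrom][gpos - 1], alt)
                    rec = call_consequence(tm, genome, v)
                    assert rec.consequence == "stop_gained"
                    assert rec.alt_aa == "*"
                    return
        pytest.skip("no codon one substitution away from a stop in this fixture seed")

    def test_utr_position_is_non_coding_exonic(self, resources_plus):
        models = {t.transcript_id: t for t in resources_plus.transcripts}
        tm = models["TR1"]
        # a position inside exon 1 but before the CDS (5' UTR)
        exon1, cds1 = sorted(tm.exons)[0], sorted(tm.cds)[0]
        utr_pos = exon1[0] if tm.strand == "+" else exon1[1]
        assert not any(s <= utr_pos <= e for s, e in tm.cds)
        v = GenomicVariant(tm.chrom, utr_pos, resources_plus.genome[tm.chrom][utr_pos - 1],
                           "A" if resources_plus.genome[tm.chrom][utr_pos - 1] != "A" else "C")
        assert call_consequence(tm, resources_plus.genome, v).consequence == "non_coding_exonic"

    def test_upstream_position(self, resources_plus):
        models = {t.transcript_id: t for t in resources_plus.transcripts}
        tm = models["TR1"]
        pos = min(tm.span) - 5
        base = resources_plus.genome[tm.chrom][pos - 1]
        v = GenomicVariant(tm.chrom, pos, base, "A" if base != "A" else "C")
        assert call_consequence(tm, resources_plus.genome, v).consequence == "upstream_downstream"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_codon_local_equals_full_retranslation_exhaustive(
        self, strand, resources_plus, resources_minus
    ):
        """Every coding position x 3 alt bases: local call == full-CDS diff."""
        res = resources_plus if strand == "+" else resources_minus
        for tm in res.transcripts:
            cds = spliced_cds_sequence(tm, res.genome)
            for cds_pos in range(1, len(cds) + 1):
                for alt in "ACGT":
                    if alt == cds[cds_pos - 1]:
                        continue
                    oracle = retranslation_oracle(tm, res.genome, cds_pos, alt)
                    rec = call_consequence(tm, res.genome, oracle["variant"])
                    assert rec.cds_pos == cds_pos
                    assert rec.consequence == oracle["consequence"]
                    assert (rec.aa_pos, rec.ref_aa, rec.alt_aa) == (
                        oracle["aa_pos"], oracle["ref_aa"], oracle["alt_aa"],
                    )

    def test_variant_pos_is_papers_worked_position(self, bundle_plus):
        assert fixture_variant(bundle_plus).pos == VARIANT_POS_PLUS == 123456
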
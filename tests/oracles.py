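"""Independent oracles used by unit and acceptance tests.

Each oracle recomputes an expected result by a different route than the
implementation: full-CDS retranslation instead of codon-local substitution,
Biopython's exact aligner instead of the in-package Smith-Waterman, and a
naive all-atom-pairs scan instead of the neighbour-search contact code.
"""

from __future__ import annotations

import math

from Bio import Align
from Bio.Align import substitution_matrices

from snv2struct.consequence import _COMP, _FORWARD, _STOPS  # codon table
from snv2struct.gene_models import cds_to_genomic, spliced_cds_sequence
from snv2struct.struct_annot import (
    CLASS_WATER,
    classify_entity,
    polymer_residue_indices,
    _reskey,
)
from snv2struct.variant_io import GenomicVariant


def codons_of(cds: str) -> list[str]:
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def aa_of(codon: str) -> str:
    return "*" if codon in _STOPS else _FORWARD[codon]


def retranslation_oracle(tm, genome, cds_pos: int, alt_base: str) -> dict:
    """Expected consequence by mutating the full CDS and diffing translations.

    ``alt_base`` is in CDS (sense-strand) space.  Returns the expected
    class, aa_pos, ref/alt amino acids and the genomic variant that realizes
    this substitution on ``tm``.
    """
    ref_cds = spliced_cds_sequence(tm, genome)
    assert ref_cds[cds_pos - 1] != alt_base
    alt_cds = ref_cds[: cds_pos - 1] + alt_base + ref_cds[cds_pos:]
    ref_aas = [aa_of(c) for c in codons_of(ref_cds)]
    alt_aas = [aa_of(c) for c in codons_of(alt_cds)]
    diffs = [i for i, (a, b) in enumerate(zip(ref_aas, alt_aas)) if a != b]
    aa_pos = (cds_pos + 2) // 3
    ref_aa, alt_aa = ref_aas[aa_pos - 1], alt_aas[aa_pos - 1]
    if not diffs:
        expected = "synonymous"
    else:
        assert diffs == [aa_pos - 1], "an SNV can change exactly one codon"
        if alt_aa == "*":
            expected = "stop_gained"
        elif ref_aa == "*":
            expected = "stop_lost"
        elif aa_pos == 1 and ref_cds[:3] == "ATG" and alt_aa != "M":
            expected = "start_lost"
        else:
            expected = "missense"
    gpos = cds_to_genomic(tm, cds_pos)
    genome_ref = genome[tm.chrom][gpos - 1]
    genomic_alt = alt_base if tm.strand == "+" else _COMP[alt_base]
    variant = GenomicVariant(tm.chrom, gpos, genome_ref, genomic_alt)
    return {
        "consequence": expected,
        "aa_pos": aa_pos,
        "ref_aa": ref_aa,
        "alt_aa": alt_aa,
        "variant": variant,
    }


def biopython_local_score(
    query: str, target: str, gap_open: float = 11.0, gap_extend: float = 1.0,
    matrix_name: str = "BLOSUM62",
) -> float:
    """Exact local affine-gap alignment score from an independent DP engine.

    Gap convention: a gap of length k costs gap_open + k * gap_extend.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return float(aligner.score(query, target))


def allpairs_contact_oracle(
    structure, chain_id: str, author_resid, cutoff: float = 4.0, min_sep: int = 5
) -> set[str]:
    """Contact flags by scanning every atom pair, no spatial index."""
    model = structure[0]
    indices = {ch.name: polymer_residue_indices(ch) for ch in model}
    target = None
    for ch in model:
        if ch.name != chain_id:
            continue
        for res in ch:
            if res.seqid.num == author_resid.num and res.seqid.icode.strip() == author_resid.icode:
                target = res
    if target is None:
        return set()
    t_index = indices[chain_id].get(_reskey(target))
    flags: set[str] = set()
    for ch in model:
        for res in ch:
            if ch.name == chain_id and _reskey(res) == _reskey(target):
                continue
            in_poly = _reskey(res) in indices.get(ch.name, {})
            cls = classify_entity(res.name, "polymer" if in_poly else "het")
            if cls == CLASS_WATER:
                continue
            if cls == "protein" and ch.name == chain_id and t_index is not None:
                o_index = indices[chain_id].get(_reskey(res))
                if o_index is not None and abs(o_index - t_index) < min_sep:
                    continue
            hit = False
            for a in target:
                if a.is_hydrogen():
                    continue
                for b in res:
                    if b.is_hydrogen():
                        continue
                    d = math.dist((a.pos.x, a.pos.y, a.pos.z), (b.pos.x, b.pos.y, b.pos.z))
                    if d <= cutoff:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                flags.add(cls)
    return flags
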
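import random

import pytest
from hypothesis import given, settings, strategies as st

from snv2struct.config import Config
from snv2struct.struct_map import (
    AuthorResId,
    StructureChain,
    UNOBSERVED,
    align_local,
    load_matrix,
    map_hit_position,
    map_residue,
    search_structures,
    seqres_to_author,
)

from .oracles import biopython_local_score

BLOSUM62 = load_matrix("BLOSUM62")
AA = "ACDEFGHIKLMNPQRSTVWY"


class TestAlignLocal:
    def test_identity_alignment(self):
        aln = align_local("MAVK", "MAVK", BLOSUM62)
        assert aln.score == sum(BLOSUM62[c, c] for c in "MAVK")
        assert aln.identity_fraction == 1.0
        assert aln.aligned_pairs == tuple((i, i) for i in range(1, 5))

    def test_against_independent_dp_engine(self):
        aln = align_local("MAVKW", "MAKW", BLOSUM62, gap_open=11, gap_extend=1)
        assert aln.score == biopython_local_score("MAVKW", "MAKW", 11, 1)

    def test_no_positive_pair_floors_at_zero(self):
        # glycine/proline against tryptophan-only: all substitution scores < 0
        aln = align_local("GPGPG", "WWWW", BLOSUM62)
        assert aln.score == 0.0
        assert aln.aligned_pairs == ()

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_local("", "MAVK", BLOSUM62)

    @given(
        st.text(alphabet=AA, min_size=1, max_size=12),
        st.text(alphabet=AA, min_size=1, max_size=12),
        st.sampled_from([(11.0, 1.0), (10.0, 0.5), (5.0, 2.0)]),
    )
    @settings(max_examples=200)
    def test_score_equals_oracle_on_random_pairs(self, q, t, gaps):
        go, ge = gaps
        aln = align_local(q, t, BLOSUM62, gap_open=go, gap_extend=ge)
        assert aln.score == biopython_local_score(q, t, go, ge)

    @given(st.text(alphabet=AA, min_size=1, max_size=12),
           st.text(alphabet=AA, min_size=1, max_size=12))
    @settings(max_examples=100)
    def test_aligned_pairs_strictly_increasing(self, q, t):
        aln = align_local(q, t, BLOSUM62)
        for (q1, t1), (q2, t2) in zip(aln.aligned_pairs, aln.aligned_pairs[1:]):
            assert q2 > q1 and t2 > t1
        assert aln.matches == sum(1 for qp, tp in aln.aligned_pairs if q[qp - 1] == t[tp - 1])


class TestMapResidue:
    def test_identity_maps_to_itself(self):
        aln = align_local("MAVKWWMA", "MAVKWWMA", BLOSUM62)
        assert map_residue(aln, 7) == 7

    def test_gap_column_is_absent(self):
        # target lacks the KK insert of the query: query positions in the
        # insert map to nothing
        q = "MAVKWCEDKKHMAVKWCED"
        t = "MAVKWCEDHMAVKWCED"
        aln = align_local(q, t, BLOSUM62)
        mapped = dict(aln.aligned_pairs)
        gap_positions = [p for p in range(1, len(q) + 1) if p not in mapped]
        assert gap_positions  # the alignment contains a real gap
        for p in gap_positions:
            assert map_residue(aln, p) is None

    def test_round_trip_over_aligned_pairs(self):
        aln = align_local("MAVKWCED", "MAVWCED", BLOSUM62)
        for q, t in aln.aligned_pairs:
            assert aln.map_target_position(aln.map_query_position(q)) == q
            assert aln.map_query_position(aln.map_target_position(t)) == t


class TestSeqresToAuthor:
    def test_offset_numbering_and_insertion_code(self, exact_chain, bundle_plus):
        expect = bundle_plus.manifest["structure"]
        assert str(seqres_to_author(exact_chain, 1)) == str(expect["first_author_number"])
        icode_idx = expect["insertion_code_seq_index"]
        author = seqres_to_author(exact_chain, icode_idx)
        assert isinstance(author, AuthorResId)
        assert str(author) == expect["insertion_code_author"]

    def test_unobserved_residue_marker(self, exact_chain, bundle_plus):
        idx = bundle_plus.manifest["structure"]["unobserved_seq_index"]
        assert seqres_to_author(exact_chain, idx) == UNOBSERVED

    def test_out_of_range(self, exact_chain):
        with pytest.raises(IndexError):
            seqres_to_author(exact_chain, 0)
        with pytest.raises(IndexError):
            seqres_to_author(exact_chain, len(exact_chain.sequence) + 1)


def canonical_sequence(bundle):
    return bundle.manifest["canonical_sequence"]


class TestSearchStructures:
    def test_exact_chain_outranks_homolog_and_decoy_is_dropped(
        self, bundle_plus, resources_plus
    ):
        hits = search_structures(canonical_sequence(bundle_plus), resources_plus.chains)
        ids = [h.target_id for h in hits]
        assert ids[:2] == bundle_plus.manifest["structure"]["ranked_chains"]
        for excluded in bundle_plus.manifest["structure"]["excluded_chains"]:
            assert excluded not in ids

    def test_ranking_invariant_under_input_permutation(self, bundle_plus, resources_plus):
        query = canonical_sequence(bundle_plus)
        baseline = [h.target_id for h in search_structures(query, resources_plus.chains)]
        rng = random.Random(0)
        for _ in range(5):
            shuffled = list(resources_plus.chains)
            rng.shuffle(shuffled)
            assert [h.target_id for h in search_structures(query, shuffled)] == baseline

    def test_resolution_breaks_ties_between_identical_chains(self):
        seq = "MAVKWCEDHMAVKWCEDH"
        def chain(pdb_id, resolution):
            return StructureChain(
                pdb_id=pdb_id, chain_id="A", sequence=seq,
                residue_names=tuple("UNK" for _ in seq),
                author_ids={i: AuthorResId(i) for i in range(1, len(seq) + 1)},
                resolution=resolution, sequence_source="seqres",
            )
        hits = search_structures(seq, [chain("XHIR", 2.8), chain("XLOW", 1.2)])
        assert [h.pdb_id for h in hits] == ["XLOW", "XHIR"]

    def test_no_chain_above_floor_gives_empty_ranking(self, bundle_plus):
        hits = search_structures(canonical_sequence(bundle_plus), [])
        assert hits == []

    def test_homolog_identity_near_seventy_percent(self, bundle_plus, resources_plus):
        hits = search_structures(canonical_sequence(bundle_plus), resources_plus.chains)
        hom = next(h for h in hits if h.pdb_id == "2BBB")
        m = bundle_plus.manifest["structure"]
        assert hom.alignment.matches <= m["homolog_identity_count"]
        assert hom.alignment.identity_fraction == pytest.approx(0.70, abs=0.05)

    def test_mapped_residue_name_matches_query_on_identity_column(
        self, bundle_plus, resources_plus
    ):
        query = canonical_sequence(bundle_plus)
        hits = search_structures(query, resources_plus.chains)
        top = hits[0]
        pos = bundle_plus.manifest["variant_aa_pos_canonical"]
        author, resname = map_hit_position(top, pos)
        expect = bundle_plus.manifest["structure"]["top_hit"]
        assert str(author) == expect["author_resid_of_variant"]
        assert resname == expect["residue_name_of_variant"]
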
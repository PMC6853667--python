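import random

import pytest
from hypothesis import given, settings, strategies as st

from snv2struct.struct_annot import (
    catalytic_flag,
    classify_entity,
    contacts,
    conservation_for_position,
    disulphide_partner_of,
    disulphides,
    load_position_table,
    msa_column_for_position,
    residue_context,
    scorecons,
)
from snv2struct.struct_map import AuthorResId, load_structure, search_structures

from .oracles import allpairs_contact_oracle

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestClassifyEntity:
    @pytest.mark.parametrize(
        "name,kind,expected",
        [
            ("ZN", "het", "metal"),
            ("HEM", "het", "ligand"),
            ("DA", "polymer", "nucleic"),
            ("U", "polymer", "nucleic"),
            ("GLY", "polymer", "protein"),
            ("HOH", "het", "water"),
            ("WAT", "polymer", "water"),
            ("MG", "het", "metal"),
            ("ACT", "het", "ligand"),
        ],
    )
    def test_classes(self, name, kind, expected):
        assert classify_entity(name, kind) == expected


def exact_structure(bundle):
    return load_structure(bundle.structures[0])


def author_of(chain, iso_pos):
    from snv2struct.struct_map import seqres_to_author

    return seqres_to_author(chain, iso_pos)


class TestContacts:
    def test_engineered_contact_classes(self, bundle_plus, exact_chain):
        """Each placed entity sets exactly its own class on its residue."""
        st_ = exact_chain.structure
        for pos_str, expected in bundle_plus.manifest["structure"]["contexts_1AAA"].items():
            author = author_of(exact_chain, int(pos_str))
            flags, _ = contacts(st_, "A", author)
            assert sorted(flags) == expected, f"canonical position {pos_str}"

    def test_water_never_sets_a_flag(self, bundle_plus, exact_chain):
        # the variant residue has only a water within the cutoff
        pos = bundle_plus.manifest["variant_aa_pos_canonical"]
        flags, partners = contacts(exact_chain.structure, "A", author_of(exact_chain, pos))
        assert flags == set()
        assert all(p.entity_class != "water" for p in partners)

    def test_matches_all_pairs_oracle_everywhere(self, bundle_plus, resources_plus):
        """Neighbour-search contacts equal a brute-force all-pairs scan."""
        for chain in resources_plus.chains:
            if chain.structure is None:
                continue
            for seq_index in sorted(chain.author_ids):
                author = chain.author_ids[seq_index]
                flags, _ = contacts(chain.structure, chain.chain_id, author)
                oracle = allpairs_contact_oracle(
                    chain.structure, chain.chain_id, author
                )
                assert flags == oracle, (chain.pdb_id, chain.chain_id, str(author))

    def test_missing_residue_has_no_contacts(self, exact_chain):
        flags, partners = contacts(exact_chain.structure, "A", AuthorResId(9999))
        assert flags == set() and partners == []


class TestDisulphides:
    def test_bonded_pair_detected_far_pair_not(self, bundle_plus):
        st_ = exact_structure(bundle_plus)
        found = sorted(
            sorted([str(r1), str(r2)]) for (c1, r1), (c2, r2) in disulphides(st_)
        )
        assert found == bundle_plus.manifest["structure"]["disulphides_1AAA"]
        neg = bundle_plus.manifest["structure"]["not_disulphide_1AAA"]
        assert neg not in found

    def test_partner_lookup_is_symmetric(self, bundle_plus):
        st_ = exact_structure(bundle_plus)
        ((c1, r1), (c2, r2)) = disulphides(st_)[0]
        assert disulphide_partner_of(st_, c1, r1) == r2
        assert disulphide_partner_of(st_, c2, r2) == r1

    def test_structure_without_cysteines_is_empty(self, bundle_plus):
        # the decoy sequence is drawn from a cysteine-free alphabet
        decoy = load_structure(bundle_plus.structures[2])
        assert disulphides(decoy) == []


class TestCatalyticFlag:
    def test_membership(self, bundle_plus):
        table = load_position_table(str(bundle_plus.catalytic))
        expect = bundle_plus.manifest["tables"]["catalytic"]
        assert catalytic_flag(table, expect["isoform"], expect["aa_pos"]) is True
        assert catalytic_flag(table, expect["isoform"], expect["aa_pos"] + 1) is False
        assert catalytic_flag({}, "ISO3", 1) is False


class TestScorecons:
    def test_identical_column_closed_form(self):
        from Bio.Align import substitution_matrices

        m = substitution_matrices.load("BLOSUM62")
        letters = [c for c in m.alphabet if c not in "BZX*"]
        smin = min(m[a, b] for a in letters for b in letters)
        smax = max(m[a, b] for a in letters for b in letters)
        expected = (m["A", "A"] - smin) / (smax - smin)
        assert scorecons(["A", "A", "A", "A"], 0) == pytest.approx(expected)

    def test_identical_beats_dissimilar(self):
        assert scorecons(["A", "A"], 0) > scorecons(["A", "W"], 0)

    def test_invariant_under_row_reordering(self):
        rows = ["AWV", "AGV", "CWV", "AWL"]
        for col in range(3):
            ref = scorecons(rows, col)
            assert scorecons(rows[::-1], col) == pytest.approx(ref)

    def test_gap_only_column_is_absent(self):
        assert scorecons(["A-", "C-"], 1) is None
        assert scorecons(["AW", "C-"], 1) is None  # a single residue is no column

    def test_perfect_score_requires_the_max_matrix_pair(self):
        assert scorecons(["W", "W"], 0) == pytest.approx(1.0)  # W-W is the BLOSUM62 max
        assert scorecons(["A", "A"], 0) < 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50)
    def test_bounded_on_random_columns(self, seed):
        rng = random.Random(seed)
        nrows = rng.randint(2, 8)
        col = [rng.choice(AA + "-") for _ in range(nrows)]  # one-column alignment
        score = scorecons(col, 0)
        if score is not None:
            assert 0.0 <= score <= 1.0


class TestConservationLookup:
    def test_column_location_skips_gaps(self):
        assert msa_column_for_position("M-AV", 2) == 2
        assert msa_column_for_position("MAV", 9) is None

    def test_fixture_variant_column(self, bundle_plus, resources_plus):
        pos = bundle_plus.manifest["variant_aa_pos_canonical"]
        expected_col = bundle_plus.manifest["msa"]["variant_column_residues"]
        rows = resources_plus.msa
        col_idx = msa_column_for_position(rows["ISO3"], pos)
        assert "".join(r[col_idx] for r in rows.values()) == expected_col
        value = conservation_for_position(rows, "ISO3", pos)
        assert value == pytest.approx(scorecons(list(rows.values()), col_idx))
        assert 0.0 <= value <= 1.0


class TestAggregation:
    def test_adding_a_structure_only_adds_flags(self, bundle_plus, resources_plus):
        """Context from homologous structures accumulates monotonically."""
        query = bundle_plus.manifest["canonical_sequence"]
        pos = bundle_plus.manifest["variant_aa_pos_canonical"]
        hits = search_structures(query, resources_plus.chains)
        assert len(hits) >= 2
        ctx_top = residue_context(hits[:1], pos)
        ctx_all = residue_context(hits, pos)
        for flag in ("contacts_protein", "contacts_nucleic", "contacts_ligand", "contacts_metal"):
            if getattr(ctx_top, flag):
                assert getattr(ctx_all, flag)
        # the metal contact exists only in the homologous structure
        expect = bundle_plus.manifest["structure"]["variant_context_aggregated"]
        assert ctx_top.contacts_metal is False
        assert ctx_all.contacts_metal is expect["contacts_metal"]
        assert ctx_all.supporting_structures["metal"] == expect["supporting"]["metal"]

    def test_every_true_flag_has_a_supporting_structure(self, bundle_plus, resources_plus):
        query = bundle_plus.manifest["canonical_sequence"]
        hits = search_structures(query, resources_plus.chains)
        for pos in range(1, len(query) + 1):
            ctx = residue_context(hits, pos)
            for cls in ("protein", "nucleic", "ligand", "metal"):
                if getattr(ctx, f"contacts_{cls}"):
                    assert ctx.supporting_structures.get(cls)
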
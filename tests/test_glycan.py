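"""Glycan data model: masses, canonical strings, enumeration, modified units."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycofirst.chem import (
    MONOSACCHARIDES,
    NH3,
    UnknownMonosaccharideError,
    elemental_mass,
)
from glycofirst.glycan import (
    EMPTY,
    GlycanComposition,
    GlycanDB,
    GlycanNode,
    GlycanStructure,
    MalformedGlycanError,
    oxonium_mz,
    parse_composition,
    parse_structure,
    subcompositions,
)


class TestMonosaccharideMasses:
    def test_residue_masses_follow_elemental_compositions(self):
        for mono in MONOSACCHARIDES.values():
            assert mono.residue_mass == pytest.approx(
                elemental_mass(mono.elemental_composition), abs=1e-9
            )

    @pytest.mark.parametrize(
        "symbol,expected",
        [
            ("H", 162.05282),
            ("N", 203.07937),
            ("F", 146.05791),
            ("A", 291.09542),
            ("G", 307.09033),
        ],
    )
    def test_standard_residue_masses(self, symbol, expected):
        assert MONOSACCHARIDES[symbol].residue_mass == pytest.approx(expected, abs=5e-5)

    def test_modified_units_are_base_plus_adduct(self):
        hex_mass = MONOSACCHARIDES["H"].residue_mass
        assert MONOSACCHARIDES["aH"].residue_mass == pytest.approx(hex_mass + NH3, abs=1e-9)
        assert MONOSACCHARIDES["pH"].residue_mass == pytest.approx(
            hex_mass + 79.96633, abs=5e-5
        )


class TestComposition:
    def test_empty_composition_has_zero_mass(self):
        assert parse_composition("").mass == 0.0
        assert parse_composition("H(0)N(0)").mass == 0.0

    def test_mass_is_additive_over_counts(self):
        assert parse_composition("H(2)").mass == pytest.approx(324.10564, abs=1e-4)

    def test_two_fuc_vs_one_neuac_is_one_dalton(self):
        # the near-isobar behind the chimera (isotope-shadow) filter
        delta = parse_composition("F(2)").mass - parse_composition("A(1)").mass
        assert delta == pytest.approx(1.02040, abs=1e-4)
        assert round(delta) == 1

    def test_partial_order(self):
        small, big = parse_composition("H(1)N(1)"), parse_composition("H(2)N(1)")
        assert small <= big and not big <= small
        assert EMPTY <= small

    def test_unknown_symbol_rejected(self):
        with pytest.raises(UnknownMonosaccharideError):
            GlycanComposition.from_dict({"X": 1})

    def test_bad_string_rejected(self):
        with pytest.raises(MalformedGlycanError):
            parse_composition("H(2)xN(1)")


@st.composite
def compositions(draw):
    counts = draw(st.lists(st.integers(0, 3), min_size=7, max_size=7))
    return GlycanComposition(tuple(counts))


class TestCompositionProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(compositions(), compositions())
    def test_mass_additivity(self, a, b):
        assert (a + b).mass == pytest.approx(a.mass + b.mass, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(compositions())
    def test_subcomposition_count_and_order(self, G):
        subs = subcompositions(G)
        expected = 1
        for c in G.counts:
            expected *= c + 1
        assert len(subs) == expected
        assert subs[0] == EMPTY and subs[-1] == G
        keys = [(g.total_units, g.counts) for g in subs]
        assert keys == sorted(keys)
        assert all(g <= G for g in subs)


class TestOxonium:
    @pytest.mark.parametrize(
        "comp,mz",
        [("N(1)", 204.087), ("H(1)", 163.060), ("H(1)N(1)", 366.139)],
    )
    def test_diagnostic_oxonium_masses(self, comp, mz):
        assert oxonium_mz(parse_composition(comp)) == pytest.approx(mz, abs=5e-4)

    def test_ammonia_adducted_hex_oxonium(self):
        assert oxonium_mz(parse_composition("aH(1)")) == pytest.approx(180.087, abs=5e-4)

    def test_empty_composition_rejected(self):
        with pytest.raises(ValueError):
            oxonium_mz(EMPTY)


class TestCanonicalString:
    def test_single_node(self):
        assert GlycanStructure(GlycanNode("H")).canonical_string() == "(H)"

    def test_sibling_order_invariance(self):
        a = GlycanStructure(GlycanNode("N", [GlycanNode("H"), GlycanNode("F")]))
        b = GlycanStructure(GlycanNode("N", [GlycanNode("F"), GlycanNode("H")]))
        assert a.canonical_string() == b.canonical_string()

    def test_round_trip_preserves_string_and_composition(self, trimannosyl):
        s = trimannosyl.canonical_string()
        again = parse_structure(s)
        assert again.canonical_string() == s
        assert again.composition == parse_composition("H(3)N(2)")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_canonicalization_idempotent_on_random_trees(self, seed):
        import random

        rng = random.Random(seed)
        symbols = list("HNFA")

        def random_tree(depth):
            children = []
            if depth < 3:
                for _ in range(rng.randint(0, 2)):
                    children.append(random_tree(depth + 1))
            return GlycanNode(rng.choice(symbols), children)

        s = GlycanStructure(random_tree(0)).canonical_string()
        assert parse_structure(s).canonical_string() == s

    def test_cycle_detected(self):
        a = GlycanNode("H")
        b = GlycanNode("N", [a])
        a.children.append(b)
        with pytest.raises(MalformedGlycanError):
            GlycanStructure(a).canonical_string()


class TestYEnumeration:
    def test_linear_chain_gives_root_prefixes(self):
        entry = GlycanDB.from_entries(["(N(N(H(H))))"]).entries[0]
        got = {str(y) for y in entry.y_compositions()}
        assert got == {"", "N(1)", "N(2)", "H(1)N(2)", "H(2)N(2)"}

    def test_trimannosyl_subtrees(self, trimannosyl):
        entry = GlycanDB.from_entries([trimannosyl.canonical_string()]).entries[0]
        got = {str(y) for y in entry.y_compositions()}
        assert got == {"", "N(1)", "N(2)", "H(1)N(2)", "H(2)N(2)", "H(3)N(2)"}

    def test_single_unit_glycan(self):
        entry = GlycanDB.from_entries(["(N)"]).entries[0]
        assert {str(y) for y in entry.y_compositions()} == {"", "N(1)"}

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_tree_ys_subset_of_subcompositions(self, seed):
        import random

        rng = random.Random(seed)

        def random_tree(depth):
            children = []
            if depth < 3:
                for _ in range(rng.randint(0, 2)):
                    children.append(random_tree(depth + 1))
            return GlycanNode(rng.choice("HNF"), children)

        structure = GlycanStructure(random_tree(0))
        entry = GlycanDB.from_entries([structure.canonical_string()]).entries[0]
        subs = {g.counts for g in subcompositions(entry.composition)}
        assert all(y.counts in subs for y in entry.y_compositions())


class TestSubcompositions:
    def test_f_is_product_of_counts_plus_one(self):
        assert len(subcompositions(parse_composition("H(2)N(2)"))) == 9
        assert subcompositions(EMPTY) == [EMPTY]

    def test_matches_exhaustive_triple_loop(self):
        G = parse_composition("H(1)N(1)F(1)")
        subs = subcompositions(G)
        brute = {
            (h, n, f, 0, 0, 0, 0)
            for h, n, f in itertools.product(range(2), range(2), range(2))
        }
        assert len(subs) == 8 and {g.counts for g in subs} == brute


class TestModifiedUnitExpansion:
    def test_composition_mode_substitution(self):
        db = GlycanDB.from_entries([parse_composition("H(2)")], glyco_type="O")
        out = db.expand_modified_units("H", "aH", 2)
        got = {str(e.composition) for e in out.entries}
        assert got == {"H(2)", "H(1)aH(1)", "aH(2)"}

    def test_no_base_symbol_is_noop(self):
        db = GlycanDB.from_entries([parse_composition("N(2)")], glyco_type="O")
        out = db.expand_modified_units("H", "aH", 2)
        assert len(out.entries) == 1

    def test_structure_mode_distinguishes_positions(self, trimannosyl):
        # one branching and two symmetric terminal Hex -> 2 distinct variants
        db = GlycanDB.from_entries([trimannosyl.canonical_string()])
        out = db.expand_modified_units("H", "aH", 1)
        added = [e for e in out.entries if e.composition["aH"] == 1]
        assert len(added) == 2
        assert len({e.structure.canonical_string() for e in added}) == 2

    def test_matches_brute_force_subset_substitution(self):
        structure = parse_structure("(N(H(H)(H(H))))")
        db = GlycanDB.from_entries([structure.canonical_string()])
        out = db.expand_modified_units("H", "aH", 2)
        added = {e.structure.canonical_string() for e in out.entries if "aH" in str(e.composition)}

        nodes = []

        def collect(node):
            nodes.append(node)
            for c in node.children:
                collect(c)

        collect(structure.root)
        hex_nodes = [n for n in nodes if n.symbol == "H"]
        expected = set()
        for k in (1, 2):
            for subset in itertools.combinations(hex_nodes, k):
                for n in subset:
                    n.symbol = "aH"
                expected.add(GlycanStructure(structure.root).canonical_string())
                for n in subset:
                    n.symbol = "H"
        assert added == expected

    def test_unknown_modified_symbol_rejected(self, linear_h2_db):
        with pytest.raises(UnknownMonosaccharideError):
            linear_h2_db.expand_modified_units("H", "zz", 1)


class TestGlycanDBIO:
    def test_round_trip(self, tmp_path, trimannosyl):
        db = GlycanDB.from_entries([trimannosyl.canonical_string(), "H(5)N(4)A(2)"])
        path = tmp_path / "glycans.txt"
        db.write(path)
        again = GlycanDB.read(path)
        assert [str(e.composition) for e in again.entries] == [
            str(e.composition) for e in db.entries
        ]
        assert again.entries[0].structure.canonical_string() == trimannosyl.canonical_string()

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("0\tH(2)\n1\t(H(H\n")
        with pytest.raises(MalformedGlycanError, match="2"):
            GlycanDB.read(path)

    def test_id_must_fit_31_bits(self):
        from glycofirst.glycan import GlycanEntry

        with pytest.raises(ValueError):
            GlycanEntry(2**31, parse_composition("H(1)"))
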
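"""Digestion with sequon marking, peptide search, chimera filter, FDR."""

import numpy as np
import pytest

from glycofirst.chem import ISOTOPE_SPACING, PROTON, WATER
from glycofirst.glycan import GlycanDB, GlycanEntry, parse_composition
from glycofirst.peptide import (
    GPSM,
    AA_MASS,
    Modification,
    PeptideEntry,
    apply_sequon,
    chimera_filter,
    digest,
    estimate_fdrs,
    peptide_mass,
    search_peptides,
)

from conftest import make_peptide, neutral_spectrum


class TestSequon:
    @pytest.mark.parametrize(
        "protein,expected",
        [
            ("AANVSKK", "AAJVSKK"),  # N-X-S
            ("AANPSKK", "AANPSKK"),  # X = P blocks
            ("AANVCKK", "AAJVCKK"),  # N-X-C counts
            ("AANVTKK", "AAJVTKK"),  # N-X-T
            ("AANVAKK", "AANVAKK"),  # no S/T/C
        ],
    )
    def test_sequon_marking(self, protein, expected):
        assert apply_sequon(protein) == expected

    def test_marking_happens_before_digestion(self):
        # sequon straddles the tryptic cut after K: N | K | S...
        store = digest(proteins={"P": "AAAGGKNKSAAAGGR"}, min_length=3,
                       with_decoys=False)
        assert any("JK" in e.sequence for e in store.entries)

    def test_j_keeps_asn_mass(self):
        assert AA_MASS["J"] == AA_MASS["N"]


class TestDigest:
    def test_tryptic_products_with_missed_cleavages(self):
        store = digest(
            proteins={"P": "AAAKBBBRCCCK".replace("B", "G").replace("C", "L")},
            min_length=3, missed_cleavages=1, with_decoys=False,
        )
        seqs = {e.sequence for e in store.entries}
        assert {"AAAK", "GGGR", "LLLK", "AAAKGGGR", "GGGRLLLK"} <= seqs

    def test_proline_blocks_cleavage(self):
        store = digest(proteins={"P": "AAAKPGGGGGR"}, min_length=3, with_decoys=False)
        seqs = {e.sequence for e in store.entries}
        assert "AAAKPGGGGGR" in seqs and "AAAK" not in seqs

    def test_decoys_are_reversed_proteins(self):
        store = digest(proteins={"P": "AAAGGGKCCCLLLR".replace("C", "M")}, min_length=3)
        assert any(e.is_decoy for e in store.entries)
        assert any(not e.is_decoy for e in store.entries)

    def test_fixed_and_variable_mods(self):
        fixed = [Modification.parse("C:57.02146:carbamidomethyl", True)]
        var = [Modification.parse("M:15.99491:oxidation", False)]
        store = digest(
            proteins={"P": "ACMGGGGK"}, min_length=3,
            fixed_mods=fixed, var_mods=var, with_decoys=False,
        )
        variants = [e for e in store.entries if e.sequence == "ACMGGGGK"]
        assert len(variants) == 2  # with and without the oxidation
        assert all(any(n == "carbamidomethyl" for _, _, n in e.mods) for e in variants)
        masses = sorted(e.mass for e in variants)
        assert masses[1] - masses[0] == pytest.approx(15.99491, abs=1e-5)

    def test_mass_window_query(self):
        store = digest(proteins={"P": "AAAGGGKLLLMMMR"}, min_length=3, with_decoys=False)
        target = peptide_mass("AAAGGGK")
        hits = store.query(target, 0.01)
        assert {e.sequence for e in hits} == {"AAAGGGK"}
        assert store.query(target + 5.0, 0.01) == []


def o_db():
    return GlycanDB.from_entries(["H(2)", "H(1)N(1)"], glyco_type="O")


class TestSearchPeptides:
    def _spectrum_for(self, pep, glycan_comp, extra=(), charge_peaks=None):
        from glycofirst.peptide import _prefix_suffix_masses

        prefix, suffix = _prefix_suffix_masses(pep)
        peaks = [pep.mass]  # Y0
        for i in range(1, len(pep.sequence)):
            peaks += [prefix[i - 1], suffix[i - 1] + WATER]
        peaks += list(extra)
        P = pep.mass + glycan_comp.mass
        return neutral_spectrum(sorted(peaks), precursor_neutral=P, activation="HCD")

    def test_true_peptide_outranks_mass_matched_competitors(self):
        db = o_db()
        true_pep = make_peptide("SAMPLETK")
        store_entries = [true_pep]
        rng = np.random.default_rng(0)
        # competitors within the precursor window but with wrong fragments
        for k in range(20):
            seq = "S" + "".join(rng.choice(list("ADEFGILQVW"), size=7))
            mass = true_pep.mass + float(rng.uniform(-0.004, 0.004))
            store_entries.append(PeptideEntry(seq, (), mass, (f"C{k}",)))
        from glycofirst.peptide import PeptideStore

        store = PeptideStore(store_entries)
        G = parse_composition("H(2)")
        spectrum = self._spectrum_for(true_pep, G)
        gpsms = search_peptides(
            spectrum, [(db.entries[0], False, None)], store,
            glyco_type="O", core_y_set=db.core_y_set,
        )
        assert gpsms[0].peptide.sequence == "SAMPLETK"

    def test_peptide_without_candidate_site_rejected(self):
        db = o_db()
        pep = make_peptide("GAMPLEGK")  # no S/T
        from glycofirst.peptide import PeptideStore

        store = PeptideStore([pep])
        spectrum = self._spectrum_for(pep, parse_composition("H(2)"))
        gpsms = search_peptides(
            spectrum, [(db.entries[0], False, None)], store,
            glyco_type="O", core_y_set=db.core_y_set,
        )
        assert gpsms == []

    def test_mass_window_contract(self):
        db = o_db()
        near = make_peptide("SAMPLETK")
        far = PeptideEntry("SGGGGGGK", (), near.mass + 3.0, ("FAR",))
        from glycofirst.peptide import PeptideStore

        store = PeptideStore([near, far])
        spectrum = self._spectrum_for(near, parse_composition("H(2)"))
        gpsms = search_peptides(
            spectrum, [(db.entries[0], False, None)], store,
            glyco_type="O", core_y_set=db.core_y_set, isotope_range=(0,),
        )
        assert {g.peptide.sequence for g in gpsms} == {"SAMPLETK"}


def gpsm(scan, total, precursor_neutral, pep_decoy=False, gly_decoy=False,
         pep_score=None, gly_score=None, units=5, k=0):
    pep = PeptideEntry("SAMPLEK", (), 700.0, ("P",), is_decoy=pep_decoy)
    comp = parse_composition(f"H({units})") if units else parse_composition("H(1)")
    z = 2
    return GPSM(
        scan_id=scan,
        precursor_mz=(precursor_neutral + z * PROTON) / z,
        precursor_charge=z,
        isotope_k=k,
        peptide=pep,
        glycan=GlycanEntry(0, comp),
        glycan_decoy=gly_decoy,
        glycan_mass=comp.mass,
        glycan_score=total / 2 if gly_score is None else gly_score,
        peptide_score=total / 2 if pep_score is None else pep_score,
        total_score=total,
    )


class TestChimeraFilter:
    def test_one_isotope_shadow_removed(self):
        # NeuAc(1) vs Fuc(2): precursors 1.0204 Da apart, within the window
        a = gpsm(9, total=10.0, precursor_neutral=2000.0)
        b = gpsm(9, total=6.0, precursor_neutral=2000.0 + 1.0204)
        kept = chimera_filter([a, b])
        assert kept == [a]

    def test_single_gpsm_unchanged(self):
        a = gpsm(9, total=10.0, precursor_neutral=2000.0)
        assert chimera_filter([a]) == [a]

    def test_distant_precursors_both_kept(self):
        a = gpsm(9, total=10.0, precursor_neutral=2000.0)
        b = gpsm(9, total=6.0, precursor_neutral=2005.0)
        assert len(chimera_filter([a, b])) == 2

    def test_different_scans_do_not_interact(self):
        a = gpsm(9, total=10.0, precursor_neutral=2000.0)
        b = gpsm(10, total=6.0, precursor_neutral=2000.0 + ISOTOPE_SPACING)
        assert len(chimera_filter([a, b])) == 2


class TestFDR:
    def test_ten_targets_one_decoy_gives_ten_percent(self):
        gpsms = [gpsm(i, total=10.0, precursor_neutral=2000.0) for i in range(10)]
        gpsms.append(gpsm(99, total=11.0, precursor_neutral=2000.0, pep_decoy=True))
        out = estimate_fdrs(gpsms)
        targets = [g for g in out if not g.peptide.is_decoy]
        assert all(g.peptide_fdr == pytest.approx(0.1) for g in targets)

    def test_combination_formula(self):
        g = gpsm(1, total=10.0, precursor_neutral=2000.0)
        g.glycan_fdr, g.peptide_fdr = 0.01, 0.01
        fg, fp = 0.01, 0.01
        assert fg + fp - fg * fp == pytest.approx(0.0199)
        out = estimate_fdrs([g])  # no decoys at all -> both levels 0
        assert out[0].glycopeptide_fdr == 0.0

    def test_small_glycan_skips_glycan_fdr(self):
        small = gpsm(1, total=10.0, precursor_neutral=2000.0, units=1, gly_score=0.1)
        decoy = gpsm(2, total=12.0, precursor_neutral=2000.0, gly_decoy=True,
                     gly_score=5.0)
        out = estimate_fdrs([small, decoy])
        target = next(g for g in out if not g.is_decoy)
        assert target.glycan_fdr == 0.0
        assert target.glycopeptide_fdr == pytest.approx(target.peptide_fdr)

    def test_q_values_monotone_in_score(self):
        rng = np.random.default_rng(3)
        gpsms = []
        for i in range(200):
            decoy = bool(rng.random() < 0.3)
            score = float(rng.normal(5.0 if not decoy else 3.0, 1.5))
            gpsms.append(
                gpsm(i, total=score, precursor_neutral=2000.0 + 7.0 * i,
                     pep_decoy=decoy, pep_score=score)
            )
        out = estimate_fdrs(gpsms)
        ranked = sorted(out, key=lambda g: -g.peptide_score)
        qs = [g.peptide_fdr for g in ranked]
        assert all(a <= b + 1e-12 for a, b in zip(qs, qs[1:]))

    def test_empty_input(self):
        assert estimate_fdrs([]) == []
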
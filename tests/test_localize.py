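"""Site localization: ScoreTable, DP best path, probabilities, SSGL-FDR."""

import numpy as np
import pytest

from glycofirst.chem import NH3, WATER, ELEMENT_MASS
from glycofirst.glycan import parse_composition, subcompositions
from glycofirst.localize import (
    LocalizationError,
    LocalizationResult,
    LocalizedUnit,
    best_path,
    build_score_table,
    estimate_probabilities,
    localize,
    ssgl_fdr,
    validation_fdr,
)
from glycofirst.peptide import _prefix_suffix_masses

from conftest import make_peptide, neutral_spectrum

H_MASS = ELEMENT_MASS["H"]


def sites_of(pep, letters="ST"):
    return [i for i, a in enumerate(pep.sequence, 1) if a in letters]


class TestScoreTable:
    def test_empty_spectrum_gives_all_zero_table(self):
        pep = make_peptide("TPSPTVAHESNWAK")
        G = parse_composition("H(2)N(2)")
        st = build_score_table(neutral_spectrum([]), pep, G, sites_of(pep))
        assert st.table.shape == (9, 15)  # F=9 rows, columns 0..L for L=14
        assert not st.table.any()

    def test_single_planted_c_ion_scores_one_cell(self):
        pep = make_peptide("TAAAGGGGVLK")
        G = parse_composition("H(1)N(1)")
        prefix, _ = _prefix_suffix_masses(pep)
        c5 = prefix[4] + NH3 + G.mass
        st = build_score_table(
            neutral_spectrum([c5], precursor_neutral=pep.mass + G.mass + 1000),
            pep, G, sites_of(pep),
        )
        hits = np.argwhere(st.table)
        assert hits.tolist() == [[st.row_of(G), 5]]
        assert st.table[st.row_of(G), 5] == 1

    def test_y_and_by_ions_removed_before_matching(self):
        pep = make_peptide("TAAAGGGGVLK")
        G = parse_composition("H(1)N(1)")
        # the Y0 peak equals no c/z hypothesis, but a b-ion could shadow one
        prefix, suffix = _prefix_suffix_masses(pep)
        peaks = [pep.mass, prefix[3], suffix[2] + WATER]
        st = build_score_table(
            neutral_spectrum(sorted(peaks), precursor_neutral=pep.mass + G.mass),
            pep, G, sites_of(pep),
        )
        assert not st.table.any()

    def test_ion_hypothesis_bound(self):
        pep = make_peptide("TPSPTVAHESNWAK")
        G = parse_composition("H(2)N(2)")
        st = build_score_table(neutral_spectrum([500.0]), pep, G, sites_of(pep))
        bound = st.F * (len(pep.sequence) - 1)
        assert st.n_c_hypotheses <= bound
        assert st.n_z_hypotheses <= bound


class TestBestPath:
    def test_single_candidate_site_carries_full_glycan(self):
        pep = make_peptide("ATAAGGGVLK")
        G = parse_composition("H(1)N(1)")
        st = build_score_table(neutral_spectrum([]), pep, G, [2])
        score, result, _ = best_path(st)
        assert score == 0
        assert len(result.units) == 1
        u = result.units[0]
        assert (u.site_start, u.site_end) == (2, 2)
        assert u.increment == G

    def test_all_zero_table_two_sites_gives_one_site_group(self):
        pep = make_peptide("ASAAGGTVLK")
        G = parse_composition("H(1)N(1)")
        st = build_score_table(neutral_spectrum([]), pep, G, [2, 7])
        _, result, _ = best_path(st)
        assert len(result.units) == 1
        u = result.units[0]
        assert u.is_group and (u.site_start, u.site_end) == (2, 7)
        assert u.increment == G

    def test_supported_site_is_uniquely_localized(self):
        pep = make_peptide("ASAAGGTVLK")
        G = parse_composition("H(1)N(1)")
        prefix, suffix = _prefix_suffix_masses(pep)
        # c ions for a glycan sitting on S2: carry G from position 2 onward
        peaks = sorted(
            [prefix[p - 1] + NH3 + G.mass for p in range(2, 10)]
            + [suffix[p - 1] + WATER - NH3 + H_MASS for p in range(2, 10)]
        )
        st = build_score_table(
            neutral_spectrum(peaks, precursor_neutral=pep.mass + G.mass),
            pep, G, [2, 7],
        )
        score, result, dp = best_path(st)
        assert score > 0
        (u,) = result.units
        assert not u.is_group and u.site_start == 2

    def test_no_candidate_site_raises(self):
        pep = make_peptide("AAAGGGVLK")
        G = parse_composition("H(1)")
        st = build_score_table(neutral_spectrum([]), pep, G, [])
        with pytest.raises(LocalizationError):
            best_path(st)

    def test_glycan_conservation(self):
        pep = make_peptide("ASTAGSGTVK")
        G = parse_composition("H(2)N(1)")
        rng = np.random.default_rng(0)
        for _ in range(10):
            peaks = np.sort(rng.uniform(100, 2500, size=40))
            st = build_score_table(
                neutral_spectrum(peaks, precursor_neutral=pep.mass + G.mass),
                pep, G, sites_of(pep),
            )
            _, result, _ = best_path(st)
            total = parse_composition("")
            for u in result.units:
                total = total + u.increment
            assert total == G

    def test_dp_update_bound(self):
        pep = make_peptide("ASTAGSGTVK")
        G = parse_composition("H(2)N(2)")
        st = build_score_table(neutral_spectrum([]), pep, G, sites_of(pep))
        best_path(st)
        assert st.dp_updates <= len(pep.sequence) * st.F**2


class TestProbabilities:
    def _localized(self, peaks, pep, G, sites, seed=1):
        st = build_score_table(
            neutral_spectrum(peaks, precursor_neutral=pep.mass + G.mass),
            pep, G, sites,
        )
        score, result, dp = best_path(st)
        return st, estimate_probabilities(st, result, dp, n_samples=400, seed=seed)

    def test_forced_unit_gets_prob_equal_r(self):
        pep = make_peptide("ATAAGGGVLK")
        G = parse_composition("H(1)N(1)")
        st, result = self._localized([], pep, G, [2])
        (u,) = result.units
        assert u.forced and u.prob_poisson == 1.0
        assert u.prob == pytest.approx(u.r)

    def test_r_is_one_when_every_cz_matches(self):
        pep = make_peptide("ASAAGGTVLK")
        G = parse_composition("H(1)N(1)")
        prefix, suffix = _prefix_suffix_masses(pep)
        L = len(pep.sequence)
        peaks = sorted(
            [prefix[p - 1] + NH3 + (G.mass if p >= 2 else 0.0) for p in range(1, L)]
            + [
                suffix[p - 1] + WATER - NH3 + H_MASS + (0.0 if p >= 2 else G.mass)
                for p in range(1, L)
            ]
        )
        st, result = self._localized(peaks, pep, G, [2, 7])
        assert result.best_score == 2 * (L - 1)
        assert all(u.r == pytest.approx(1.0) for u in result.units)
        assert all(u.prob == pytest.approx(u.prob_poisson) for u in result.units)

    def test_zero_evidence_gives_zero_probability(self):
        # all-zero table: the single site-group is forced (Prob_Poisson = 1)
        # but the best score is 0, so the regularization r drives Prob to 0
        pep = make_peptide("ASAAGGTVLK")
        G = parse_composition("H(1)N(1)")
        st, result = self._localized([], pep, G, [2, 7])
        (u,) = result.units
        assert u.forced and u.prob_poisson == 1.0
        assert u.r == 0.0
        assert u.prob == pytest.approx(0.0, abs=1e-12)

    def test_probability_bounds(self):
        rng = np.random.default_rng(7)
        pep = make_peptide("ASTAGSGTVK")
        G = parse_composition("H(2)N(1)")
        for trial in range(10):
            peaks = np.sort(rng.uniform(100, 2500, size=60))
            st, result = self._localized(peaks, pep, G, sites_of(pep), seed=trial)
            for u in result.units:
                assert 0.0 <= u.prob <= 1.0
                assert u.prob_poisson >= 0.5 - 1e-12

    def test_deterministic_given_seed(self):
        pep = make_peptide("ASTAGSGTVK")
        G = parse_composition("H(1)N(1)")
        rng = np.random.default_rng(3)
        peaks = np.sort(rng.uniform(100, 2200, size=50))
        _, r1 = self._localized(peaks, pep, G, sites_of(pep), seed=5)
        _, r2 = self._localized(peaks, pep, G, sites_of(pep), seed=5)
        assert [u.prob for u in r1.units] == [u.prob for u in r2.units]

    def test_localization_string_format(self):
        pep = make_peptide("ATAAGGGVLK")
        G = parse_composition("H(1)N(1)")
        result = localize(
            neutral_spectrum([], precursor_neutral=pep.mass + G.mass),
            pep, G, glycosylation_sites="ST", seed=0,
        )
        assert result.to_string().startswith("T2:H(1)N(1):")


class TestSSGLFDR:
    def test_all_certain_gives_zero(self):
        assert ssgl_fdr([1.0, 1.0], 0.75) == 0.0

    def test_printed_formula_hand_check(self):
        assert ssgl_fdr([0.9, 0.8, 0.6], 0.75) == pytest.approx(0.15)

    def test_empty_selection_is_undefined(self):
        assert ssgl_fdr([0.6], 0.75) is None


def loc_result(sequence, units, candidate_letters="JST"):
    pep = make_peptide(sequence)
    sites = tuple(i for i, a in enumerate(sequence, 1) if a in candidate_letters)
    built = [
        LocalizedUnit(0, 0, 0, 0, a, b, parse_composition("N(1)"), prob=p)
        for a, b, p in units
    ]
    return LocalizationResult(pep, parse_composition("N(1)"), built, 1, sites)


class TestValidationFDR:
    def test_entrapment_all_on_j_is_zero(self):
        gpsms = [loc_result("AAJVTAK", [(3, 3, 0.9)]) for _ in range(3)]
        assert validation_fdr(gpsms, 0.8, "entrapment") == 0.0

    def test_entrapment_one_off_j_in_four(self):
        gpsms = [loc_result("AAJVTAK", [(3, 3, 0.9)]) for _ in range(3)]
        gpsms.append(loc_result("AAJVTAK", [(5, 5, 0.9)]))  # localized on T
        assert validation_fdr(gpsms, 0.8, "entrapment") == pytest.approx(0.25)

    def test_below_threshold_gpsms_excluded(self):
        gpsms = [loc_result("AAJVTAK", [(5, 5, 0.5)])]
        assert validation_fdr(gpsms, 0.8, "entrapment") is None

    def test_operator_nterminal_site_is_true_positive(self):
        good = loc_result("SAAVTAK", [(1, 1, 0.9)], candidate_letters="ST")
        bad = loc_result("TAAVSAK", [(5, 5, 0.9)], candidate_letters="ST")
        assert validation_fdr([good], 0.8, "operator") == 0.0
        assert validation_fdr([good, bad], 0.8, "operator") == pytest.approx(0.5)

    def test_unknown_scheme_rejected(self):
        with pytest.raises(ValueError):
            validation_fdr([], 0.5, "nope")
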
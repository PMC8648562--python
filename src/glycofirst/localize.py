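"""Site-specific glycan localization by dynamic programming (pGlycoSite-style).

Given an identified peptide and glycan composition G, every glycoform (an
assignment of sub-glycans to candidate sites) determines, at each backbone
position p, the cumulative glycan carried by the c_p fragment (and G minus it
on the z fragment).  Although the number of glycoforms grows combinatorially,
the number of distinct c or z ion hypotheses is at most F*(L-1), where F is
the number of subcompositions of G and L the peptide length.  Matching all of
them once yields the ScoreTable; the best glycoform is then the best-scoring
monotone path from [empty glycan, position 0] to [G, L], found by dynamic
programming in O(L*F^2) instead of enumerating forms.

When several paths tie for the optimum, the residues they disagree on are
reported as a *site-group* — the glycan is attributed to a span rather than
a single residue.  Localization confidence is estimated by sampling random
valid paths that avoid the sub-path determining each unit, fitting a Poisson
to their scores, and comparing the p-values of the best path and the best
random path, with a small-score regularization factor.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats

from .chem import HEXNAC, NH3, WATER, ELEMENT_MASS
from .glycan import GlycanComposition, subcompositions
from .peptide import PeptideEntry, _prefix_suffix_masses
from .spectra import Spectrum

__all__ = [
    "ScoreTable",
    "LocalizedUnit",
    "LocalizationResult",
    "LocalizationError",
    "build_score_table",
    "best_path",
    "estimate_probabilities",
    "localize",
    "ssgl_fdr",
    "validation_fdr",
]

H_MASS = ELEMENT_MASS["H"]
NEG = float("-inf")


class LocalizationError(ValueError):
    pass


@dataclass
class ScoreTable:
    """c/z match scores per (subglycan row, prefix length column).

    Rows follow the fixed subcomposition order of G (F rows); columns run
    0..L.  Cells are scored for 1 <= p <= L-1 only and hold 0, 1 or 2 (one
    point for a matched c ion carrying g, one for the complementary z ion
    carrying G-g; rearrangement variants collapse into the same point).
    """

    peptide: PeptideEntry
    G: GlycanComposition
    subs: list[GlycanComposition]
    table: np.ndarray  # (F, L+1) int16
    candidate_sites: tuple[int, ...]  # 1-based residue positions
    n_c_hypotheses: int = 0
    n_z_hypotheses: int = 0
    dp_updates: int = 0

    @property
    def F(self) -> int:
        return len(self.subs)

    @property
    def L(self) -> int:
        return len(self.peptide.sequence)

    def row_of(self, comp: GlycanComposition) -> int:
        return self._row_index[comp.counts]

    def __post_init__(self) -> None:
        self._row_index = {g.counts: i for i, g in enumerate(self.subs)}


@dataclass
class LocalizedUnit:
    """One localized attachment: a single site or a tied site-group.

    ``col_start``/``col_end`` bracket the determining sub-path (table columns
    a and b); residues ``site_start..site_end`` are the candidate positions
    the increment may sit on (equal for a single site).
    """

    col_start: int
    col_end: int
    row_start: int
    row_end: int
    site_start: int
    site_end: int
    increment: GlycanComposition
    prob_poisson: float = 0.0
    r: float = 0.0
    prob: float = 0.0
    random_best: Optional[int] = None
    forced: bool = False

    @property
    def is_group(self) -> bool:
        return self.site_start != self.site_end

    def label(self, sequence: str) -> str:
        if not self.is_group:
            return f"{sequence[self.site_start - 1]}{self.site_start}"
        return (
            f"{{{sequence[self.site_start - 1]}{self.site_start}:"
            f"{sequence[self.site_end - 1]}{self.site_end}}}"
        )

    def covers(self, position: int) -> bool:
        return self.site_start <= position <= self.site_end


@dataclass
class LocalizationResult:
    peptide: PeptideEntry
    G: GlycanComposition
    units: list[LocalizedUnit]
    best_score: int
    candidate_sites: tuple[int, ...]

    def to_string(self) -> str:
        seq = self.peptide.sequence
        return ";".join(
            f"{u.label(seq)}:{u.increment}:{u.prob:.3f}" for u in self.units
        )


# ---------------------------------------------------------------------------
# ScoreTable construction


def _remove_matched(
    masses: np.ndarray,
    intensities: np.ndarray,
    targets: Sequence[float],
    tol_ppm: float,
) -> tuple[np.ndarray, np.ndarray]:
    keep = np.ones(len(masses), dtype=bool)
    for t in targets:
        keep &= np.abs(masses - t) > tol_ppm * 1e-6 * max(t, 1.0)
    return masses[keep], intensities[keep]


def _matches(masses: np.ndarray, t: float, tol_ppm: float) -> bool:
    tol = tol_ppm * 1e-6 * t
    j = int(np.searchsorted(masses, t))
    for jj in (j - 1, j):
        if 0 <= jj < len(masses) and abs(masses[jj] - t) <= tol:
            return True
    return False


def build_score_table(
    spectrum: Spectrum,
    peptide: PeptideEntry,
    G: GlycanComposition,
    candidate_sites: Sequence[int],
    tol_ppm: float = 20.0,
) -> ScoreTable:
    """Match glycan-carrying c/z ions for every (subglycan, position) cell.

    Theoretical Y ions (the full subcomposition ladder on the peptide) and
    plain and HexNAc-carrying b/y ions are removed from the peak list first,
    so that the c/z evidence is not double-counted from HCD fragments.
    """
    subs = subcompositions(G)
    L = len(peptide.sequence)
    F = len(subs)
    table = np.zeros((F, L + 1), dtype=np.int16)
    st = ScoreTable(
        peptide=peptide,
        G=G,
        subs=subs,
        table=table,
        candidate_sites=tuple(sorted(candidate_sites)),
    )
    if L < 2 or len(spectrum.masses) == 0:
        return st

    prefix, suffix = _prefix_suffix_masses(peptide)
    pep_mass = peptide.mass
    removal: list[float] = [pep_mass + y.mass for y in subs]
    for i in range(1, L):
        b = prefix[i - 1]
        y = suffix[i - 1] + WATER
        removal += [b, y, b + HEXNAC, y + HEXNAC]
    masses, _ = _remove_matched(
        spectrum.masses, spectrum.intensities, removal, tol_ppm
    )

    for gi, g in enumerate(subs):
        gm = g.mass
        zm = G.mass - gm
        for p in range(1, L):
            c = prefix[p - 1] + NH3 + gm
            z = suffix[p - 1] + WATER - NH3 + H_MASS + zm
            st.n_c_hypotheses += 1
            st.n_z_hypotheses += 1
            cell = 0
            if _matches(masses, c, tol_ppm) or _matches(masses, c + H_MASS, tol_ppm):
                cell += 1
            if _matches(masses, z, tol_ppm) or _matches(masses, z + H_MASS, tol_ppm):
                cell += 1
            table[gi, p] = cell
    return st


# ---------------------------------------------------------------------------
# dynamic programming


def _subset_rows(subs: list[GlycanComposition]) -> list[list[int]]:
    """preds[i] = rows j with subs[j] <= subs[i] (including i)."""
    return [
        [j for j, gj in enumerate(subs) if gj <= gi] for i, gi in enumerate(subs)
    ]


@dataclass
class _DPTables:
    forward: np.ndarray
    backward: np.ndarray
    preds: list[list[int]]
    succs: list[list[int]]


def _run_dp(st: ScoreTable) -> _DPTables:
    F, L = st.F, st.L
    subs = st.subs
    sites = set(st.candidate_sites)
    preds = _subset_rows(subs)
    succs: list[list[int]] = [[] for _ in range(F)]
    for i, pr in enumerate(preds):
        for j in pr:
            succs[j].append(i)

    fwd = np.full((F, L + 1), NEG)
    fwd[0, 0] = 0.0  # subs[0] is the empty composition
    for p in range(1, L + 1):
        attach = p in sites
        for i in range(F):
            allowed = preds[i] if attach else (i,)
            best = NEG
            for j in allowed:
                st.dp_updates += 1
                if fwd[j, p - 1] > best:
                    best = fwd[j, p - 1]
            if best > NEG:
                fwd[i, p] = best + st.table[i, p]

    bwd = np.full((F, L + 1), NEG)
    bwd[F - 1, L] = 0.0
    for p in range(L - 1, -1, -1):
        attach = (p + 1) in sites
        for i in range(F):
            allowed = succs[i] if attach else (i,)
            best = NEG
            for j in allowed:
                if bwd[j, p + 1] > NEG:
                    cand = bwd[j, p + 1] + st.table[j, p + 1]
                    if cand > best:
                        best = cand
            bwd[i, p] = best
    return _DPTables(fwd, bwd, preds, succs)


def best_path(st: ScoreTable) -> tuple[int, LocalizationResult, _DPTables]:
    """Best-path score, all-optimal-path consensus and the DP tables.

    The best score over all valid paths equals the brute-force maximum over
    enumerated glycoforms.  Columns where every optimal path agrees on the
    cumulative glycan give single localized sites; maximal disagreement runs
    become site-groups carrying the glycan gained across the run.
    """
    L, F = st.L, st.F
    if not st.G:
        return 0, LocalizationResult(st.peptide, st.G, [], 0, st.candidate_sites), None
    if L < 2:
        unit = LocalizedUnit(0, 1, 0, F - 1, 1, 1, st.G, forced=True)
        return 0, LocalizationResult(st.peptide, st.G, [unit], 0, st.candidate_sites), None
    if not st.candidate_sites:
        raise LocalizationError("no candidate glycosylation site in peptide")
    dp = _run_dp(st)
    best = dp.forward[F - 1, L]
    if best == NEG:
        raise LocalizationError("no valid localization path")
    best = int(best)

    on_optimal = (dp.forward + dp.backward) == best
    units: list[LocalizedUnit] = []
    a_row = 0
    a_col = 0
    p = 1
    while p <= L:
        rows = np.flatnonzero(on_optimal[:, p])
        if len(rows) == 1:
            row = int(rows[0])
            if row != a_row:
                increment = st.subs[row] - st.subs[a_row]
                sites_in = [s for s in st.candidate_sites if a_col + 1 <= s <= p]
                units.append(
                    LocalizedUnit(
                        col_start=a_col,
                        col_end=p,
                        row_start=a_row,
                        row_end=row,
                        site_start=min(sites_in),
                        site_end=max(sites_in),
                        increment=increment,
                    )
                )
            a_row, a_col = row, p
        p += 1
    result = LocalizationResult(st.peptide, st.G, units, best, st.candidate_sites)
    return best, result, dp


# ---------------------------------------------------------------------------
# probability estimation


def _reachable_end(st: ScoreTable, dp: _DPTables) -> np.ndarray:
    """R[i, p]: a valid path from (i, p) can reach (G, L)."""
    F, L = st.F, st.L
    sites = set(st.candidate_sites)
    R = np.zeros((F, L + 1), dtype=bool)
    R[F - 1, L] = True
    for p in range(L - 1, -1, -1):
        attach = (p + 1) in sites
        for i in range(F):
            allowed = dp.succs[i] if attach else (i,)
            R[i, p] = any(R[j, p + 1] for j in allowed)
    return R


def _avoiding_reach(
    st: ScoreTable, dp: _DPTables, R: np.ndarray, unit: LocalizedUnit
) -> tuple[np.ndarray, np.ndarray]:
    """Feasibility tables for paths that do not contain the unit's sub-path.

    RB[i, p] (p <= col_end): can reach (G, L) without sitting in the unit's
    end cell at its column.  RA[i, p] (p < col_start): can reach (G, L)
    without ever containing the full sub-path, for paths that have not yet
    passed the unit's start cell.
    """
    F, L = st.F, st.L
    sites = set(st.candidate_sites)
    a, b = unit.col_start, unit.col_end
    row_a, row_b = unit.row_start, unit.row_end

    RB = np.zeros((F, b + 1), dtype=bool)
    for i in range(F):
        RB[i, b] = R[i, b] and i != row_b
    for p in range(b - 1, -1, -1):
        attach = (p + 1) in sites
        for i in range(F):
            allowed = dp.succs[i] if attach else (i,)
            RB[i, p] = any(RB[j, p + 1] for j in allowed)

    RA = np.zeros((F, max(a, 1)), dtype=bool)
    if a > 0:
        for p in range(a - 1, -1, -1):
            attach = (p + 1) in sites
            for i in range(F):
                allowed = dp.succs[i] if attach else (i,)
                ok = False
                for j in allowed:
                    if p + 1 < a:
                        ok = ok or RA[j, p + 1]
                    else:  # stepping into the unit's start column
                        if j == row_a:
                            ok = ok or RB[row_a, a]
                        else:
                            ok = ok or R[j, a]
                    if ok:
                        break
                RA[i, p] = ok
    return RB, RA


def _sample_scores(
    st: ScoreTable,
    dp: _DPTables,
    R: np.ndarray,
    unit: LocalizedUnit,
    n_samples: int,
    rng: random.Random,
) -> Optional[np.ndarray]:
    """Scores of random valid paths avoiding the unit; None if the unit is
    forced (every valid path contains it).  Successors are drawn uniformly
    at each column, with transitions that would complete the forbidden
    sub-path masked out."""
    F, L = st.F, st.L
    sites = set(st.candidate_sites)
    a, b = unit.col_start, unit.col_end
    row_a, row_b = unit.row_start, unit.row_end
    RB, RA = _avoiding_reach(st, dp, R, unit)

    start_h = a == 0  # the start cell (g0, 0) is the unit's start cell
    feasible = RB[0, 0] if start_h else RA[0, 0]
    if not feasible:
        return None

    allowed_cache: dict[tuple[int, int, bool], list[int]] = {}

    def allowed_from(row: int, p: int, h: bool) -> list[int]:
        key = (row, p, h)
        hit = allowed_cache.get(key)
        if hit is not None:
            return hit
        attach = (p + 1) in sites
        base = dp.succs[row] if attach else (row,)
        out = []
        for j in base:
            h2 = h or (p + 1 == a and j == row_a)
            if h2 and p + 1 <= b:
                ok = RB[j, p + 1] if p + 1 < b else (j != row_b and R[j, p + 1])
            elif not h2 and p + 1 < a:
                ok = RA[j, p + 1]
            else:
                ok = R[j, p + 1]
            if ok:
                out.append(j)
        allowed_cache[key] = out
        return out

    scores = np.empty(n_samples, dtype=np.int64)
    tab = st.table
    for s in range(n_samples):
        row, h = 0, start_h
        total = 0
        for p in range(L):
            options = allowed_from(row, p, h)
            row = options[rng.randrange(len(options))]
            h = h or (p + 1 == a and row == row_a)
            total += int(tab[row, p + 1])
        scores[s] = total
    return scores


def _log_pvalue(score: int, lam: float) -> float:
    pv = float(_stats.poisson.sf(score - 1, lam))  # P(X >= score)
    pv = min(max(pv, 1e-16), 1.0)
    return math.log(pv)


def estimate_probabilities(
    st: ScoreTable,
    result: LocalizationResult,
    dp: Optional[_DPTables],
    n_samples: int = 1000,
    seed: int = 0,
) -> LocalizationResult:
    """Attach localization probabilities to every unit of a best-path result.

    Per unit: sample ``n_samples`` random valid paths avoiding the unit, fit
    a Poisson to their scores (lambda = sample mean, floored at 0.01), and set
    Prob_Poisson = log pv(best) / (log pv(best) + log pv(best random)),
    Prob = Prob_Poisson * (best / (2(L-1)))**alpha with alpha = 0.05.
    A unit contained in every valid path gets Prob_Poisson = 1.
    """
    L = st.L
    best = result.best_score
    alpha = 0.05
    r = (best / (2.0 * (L - 1))) ** alpha if L >= 2 else 1.0
    if dp is None:  # trivial cases (empty glycan or single residue)
        for u in result.units:
            u.prob_poisson, u.r, u.prob, u.forced = 1.0, 1.0, 1.0, True
        return result
    R = _reachable_end(st, dp)
    for k, unit in enumerate(result.units):
        rng = random.Random((seed * 1_000_003 + k * 7919) % (2**31))
        samples = _sample_scores(st, dp, R, unit, n_samples, rng)
        if samples is None:
            unit.forced = True
            unit.prob_poisson = 1.0
        else:
            lam = max(float(samples.mean()), 0.01)
            random_best = int(samples.max())
            unit.random_best = random_best
            if best <= 0:
                unit.prob_poisson = 0.5
            else:
                lb = _log_pvalue(best, lam)
                lr = _log_pvalue(random_best, lam)
                unit.prob_poisson = 0.5 if lb + lr == 0 else lb / (lb + lr)
        unit.r = r
        unit.prob = unit.prob_poisson * r
    return result


def localize(
    spectrum: Spectrum,
    peptide: PeptideEntry,
    G: GlycanComposition,
    glycosylation_sites: str = "J",
    n_samples: int = 1000,
    seed: int = 0,
    tol_ppm: float = 20.0,
) -> LocalizationResult:
    """Full localization for one GPSM: ScoreTable, best path, probabilities."""
    sites = tuple(
        i for i, aa in enumerate(peptide.sequence, start=1) if aa in glycosylation_sites
    )
    st = build_score_table(spectrum, peptide, G, sites, tol_ppm)
    _, result, dp = best_path(st)
    return estimate_probabilities(st, result, dp, n_samples, seed)


# ---------------------------------------------------------------------------
# SSGL-FDR estimators


def ssgl_fdr(probs: Sequence[float], x: float) -> Optional[float]:
    """Estimated site-specific glycan localization FDR at threshold x:
    sum(1 - Prob_i | Prob_i >= x) / #(Prob_i >= x); None if nothing passes."""
    selected = [p for p in probs if p >= x]
    if not selected:
        return None
    return sum(1.0 - p for p in selected) / len(selected)


def validation_fdr(
    gpsms: Sequence,
    x: float,
    scheme: str,
) -> Optional[float]:
    """Empirical SSGL-FDR by an orthogonal criterion.

    ``entrapment``: localization was run with widened candidate sites
    (J/S/T) on N-glycopeptides; a GPSM is a true positive iff every unit
    above threshold can only sit on J residues.  ``operator``: peptides
    produced by an O-glycoprotease start at an occupied S/T, so a GPSM is a
    true positive iff some unit above threshold covers position 1.
    GPSMs with no unit above threshold are excluded; None if none qualify.
    """
    if scheme not in ("entrapment", "operator"):
        raise ValueError(f"unknown validation scheme {scheme!r}")
    tp = fp = 0
    for g in gpsms:
        loc = getattr(g, "localization", None) or g
        if not isinstance(loc, LocalizationResult):
            continue
        seq = loc.peptide.sequence
        units = [u for u in loc.units if u.prob >= x]
        if not units:
            continue
        if scheme == "entrapment":
            def only_j(u: LocalizedUnit) -> bool:
                residues = {
                    seq[s - 1]
                    for s in loc.candidate_sites
                    if u.site_start <= s <= u.site_end
                }
                return residues == {"J"}

            if all(only_j(u) for u in units):
                tp += 1
            else:
                fp += 1
        else:
            if seq[0] not in "ST":
                continue
            if any(u.covers(1) for u in units):
                tp += 1
            else:
                fp += 1
    if tp + fp == 0:
        return None
    return fp / (tp + fp)
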
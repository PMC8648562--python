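"""Seeded glycopeptide MS2 simulation and brute-force reference scorers.

The generator emits HCD/ETxxD scan pairs for glycopeptides with known
peptide, glycan and site assignments: Y ions from the glycan topology, b/y
and b/y+HexNAc backbone fragments, c/z ions carrying the cumulative
site-specific glycans, oxonium/diagnostic ions, isotope clusters and uniform
noise peaks.  Ion series are thinned independently at one minus the per-series
coverage; intensities are log-normal.  Everything is deterministic per seed.

The brute-force functions are deliberately naive re-derivations of the two
indexed/dynamic-programming computations — per-glycan Y-ladder matching and
exhaustive glycoform enumeration — and serve as ground truth in tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .chem import HEXNAC, NH3, PROTON, WATER, ELEMENT_MASS
from .glycan import (
    EMPTY,
    GlycanComposition,
    GlycanDB,
    GlycanEntry,
    subcompositions,
)
from .index import DEFAULT_MONO_DIAGNOSTIC_IONS
from .peptide import PeptideEntry, _prefix_suffix_masses
from .spectra import Spectrum

__all__ = [
    "GroundTruth",
    "simulate_spectrum",
    "random_glycoproteins",
    "sample_ground_truths",
    "brute_force_glycan_scores",
    "brute_force_localize",
]

H_MASS = ELEMENT_MASS["H"]

# oxonium/diagnostic ions are modeled as always present: the simulator
# emulates confirmed glycopeptide scans, where they are the dominant peaks
DEFAULT_COVERAGE = {"Y": 0.9, "by": 0.9, "cz": 0.9, "oxonium": 1.0}


@dataclass
class GroundTruth:
    """Planted identity of one simulated glycopeptide spectrum."""

    peptide: PeptideEntry
    glycan: GlycanEntry
    site_glycans: dict[int, GlycanComposition]  # 1-based site -> attached glycan
    charge: int = 2
    coverage: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COVERAGE))
    n_noise: int = 30
    scan_id: int = 1

    def __post_init__(self) -> None:
        total = EMPTY
        for comp in self.site_glycans.values():
            total = total + comp
        if total.counts != self.glycan.composition.counts:
            raise ValueError("site glycans must sum to the full composition")

    @property
    def precursor_neutral_mass(self) -> float:
        return self.peptide.mass + self.glycan.composition.mass

    @property
    def precursor_mz(self) -> float:
        z = self.charge
        return (self.precursor_neutral_mass + z * PROTON) / z


def _emit(
    rng: np.random.Generator,
    mz_list: list[float],
    int_list: list[float],
    neutral: float,
    scale: float,
) -> None:
    """Append one fragment as an m/z isotope cluster at a suitable charge."""
    z = 1 if neutral <= 1800.0 else 2
    mono = (neutral + z * PROTON) / z
    base = scale * float(rng.lognormal(0.0, 0.6))
    r1 = min(0.9, max(0.1, neutral / 1800.0))
    mz_list.extend([mono, mono + 1.00335 / z])
    int_list.extend([base, base * r1])
    if neutral > 1500.0:
        mz_list.append(mono + 2 * 1.00335 / z)
        int_list.append(base * r1 * r1 * 0.5)


def simulate_spectrum(
    truth: GroundTruth,
    seed: int,
    mz_range: tuple[float, float] = (120.0, 2000.0),
) -> tuple[Spectrum, Spectrum]:
    """Simulate the (HCD, ETxxD) raw scan pair for one ground truth."""
    rng = np.random.default_rng(seed)
    pep = truth.peptide
    G = truth.glycan.composition
    L = len(pep.sequence)
    prefix, suffix = _prefix_suffix_masses(pep)
    cov = truth.coverage

    hcd_mz: list[float] = []
    hcd_int: list[float] = []
    # Y ions from the glycan topology (full-glycan Y omitted: it is the precursor)
    for y in truth.glycan.y_compositions():
        if y.counts == G.counts:
            continue
        if rng.random() < cov.get("Y", 0.9):
            _emit(rng, hcd_mz, hcd_int, pep.mass + y.mass, scale=80.0)
    # backbone b/y and b/y + HexNAc
    for i in range(1, L):
        for neutral in (
            prefix[i - 1],
            suffix[i - 1] + WATER,
            prefix[i - 1] + HEXNAC,
            suffix[i - 1] + WATER + HEXNAC,
        ):
            if rng.random() < cov.get("by", 0.9):
                _emit(rng, hcd_mz, hcd_int, neutral, scale=40.0)
    # oxonium / diagnostic ions (stored as neutral = m/z - proton at z=1)
    diagnostics: list[float] = []
    if G["N"] > 0:
        diagnostics.append(HEXNAC)
    if G["H"] > 0 or G["aH"] > 0:
        diagnostics.append(162.05282)
    if G["H"] > 0 and G["N"] > 0:
        diagnostics.append(162.05282 + HEXNAC)
    for sym, ions in DEFAULT_MONO_DIAGNOSTIC_IONS.items():
        if G[sym] > 0:
            diagnostics.extend(mz - PROTON for mz in ions)
    for neutral in diagnostics:
        if rng.random() < cov.get("oxonium", 0.95):
            _emit(rng, hcd_mz, hcd_int, neutral, scale=120.0)

    et_mz: list[float] = []
    et_int: list[float] = []
    cumulative = EMPTY
    cum_masses = []
    for p in range(1, L):
        for s, comp in truth.site_glycans.items():
            if s == p:
                cumulative = cumulative + comp
        cum_masses.append(cumulative.mass)
    for p in range(1, L):
        gm = cum_masses[p - 1]
        c = prefix[p - 1] + NH3 + gm
        z = suffix[p - 1] + WATER - NH3 + H_MASS + (G.mass - gm)
        if rng.random() < cov.get("cz", 0.9):
            _emit(rng, et_mz, et_int, c, scale=50.0)
        if rng.random() < cov.get("cz", 0.9):
            _emit(rng, et_mz, et_int, z, scale=50.0)

    for mz_list, int_list in ((hcd_mz, hcd_int), (et_mz, et_int)):
        for _ in range(truth.n_noise):
            mz_list.append(float(rng.uniform(*mz_range)))
            int_list.append(2.0 * float(rng.lognormal(0.0, 0.8)))

    hcd = Spectrum(
        scan_id=truth.scan_id,
        precursor_mz=truth.precursor_mz,
        precursor_charge=truth.charge,
        masses=np.array(hcd_mz),
        intensities=np.array(hcd_int),
        activation="HCD",
        paired_scan_id=truth.scan_id + 1,
        title=f"scan={truth.scan_id} activation=HCD pair={truth.scan_id + 1}",
    )
    et = Spectrum(
        scan_id=truth.scan_id + 1,
        precursor_mz=truth.precursor_mz,
        precursor_charge=truth.charge,
        masses=np.array(et_mz),
        intensities=np.array(et_int),
        activation="ETHCD",
        paired_scan_id=truth.scan_id,
        title=f"scan={truth.scan_id + 1} activation=ETHCD pair={truth.scan_id}",
    )
    return hcd, et


# ---------------------------------------------------------------------------
# benchmark construction


def high_mannose_structure(n_extra_hex: int) -> str:
    """Canonical string of a high-mannose N-glycan H(3+n)N(2): the
    chitobiose-trimannosyl core with extra mannoses stacked on the arms."""
    arm1 = arm2 = ""
    for k in range(n_extra_hex):
        if k % 2 == 0:
            arm1 = f"(H{arm1})"
        else:
            arm2 = f"(H{arm2})"
    return f"(N(N(H(H{arm1})(H{arm2}))))"


def builtin_glycan_db(glyco_type: str = "N") -> GlycanDB:
    """Small built-in search space used by the simulator and the examples.

    N-mode: high-mannose structures H(3..9)N(2) plus a few complex/sialylated
    compositions; O-mode: the common mucin-type cores as compositions.
    """
    if glyco_type == "N":
        items: list[str] = [high_mannose_structure(k) for k in range(0, 7)]
        items += [
            "H(3)N(3)",
            "H(3)N(4)",
            "H(4)N(3)",
            "H(4)N(4)",
            "H(5)N(4)",
            "H(3)N(2)F(1)",
            "H(4)N(4)F(1)",
            "H(5)N(4)A(1)",
            "H(5)N(4)A(2)",
            "N(2)",
            "H(1)N(2)",
            "N(1)",
        ]
        return GlycanDB.from_entries(items, "N")
    items = [
        "N(1)",
        "H(1)",
        "H(1)N(1)",
        "N(1)A(1)",
        "H(1)N(1)A(1)",
        "H(1)N(1)A(2)",
        "H(1)N(2)",
        "H(2)N(2)",
        "H(2)",
        "H(3)",
        "H(4)",
    ]
    return GlycanDB.from_entries(items, "O")

_AA = "ACDEFGHIKLMPQRSTVWY"  # no N: sequons are planted explicitly


def random_glycoproteins(
    rng: np.random.Generator,
    n_proteins: int = 20,
    length: int = 120,
    sequons_per_protein: int = 3,
) -> dict[str, str]:
    """Random protein sequences with planted N-glycosylation sequons (NxS/T)."""
    proteins = {}
    for k in range(n_proteins):
        seq = list(rng.choice(list(_AA), size=length))
        positions = rng.choice(
            np.arange(5, length - 5), size=sequons_per_protein, replace=False
        )
        for p in sorted(positions):
            seq[p] = "N"
            seq[p + 1] = "V"
            seq[p + 2] = "S" if rng.random() < 0.5 else "T"
        proteins[f"SYN{k:03d}"] = "".join(seq)
    return proteins


def sample_ground_truths(
    rng: np.random.Generator,
    store,
    db: GlycanDB,
    n: int,
    glyco_type: str = "N",
    max_sites_occupied: int = 1,
    coverage: Optional[dict[str, float]] = None,
    n_noise: int = 30,
) -> list[GroundTruth]:
    """Draw ground truths from a digested peptide store and a glycan DB."""
    site_letters = "J" if glyco_type == "N" else "ST"
    candidates = [
        e
        for e in store.entries
        if not e.is_decoy and any(a in site_letters for a in e.sequence)
    ]
    if not candidates:
        raise ValueError("no peptides with candidate sites in the store")
    truths = []
    scan = 1
    for _ in range(n):
        pep = candidates[int(rng.integers(len(candidates)))]
        sites = [i for i, a in enumerate(pep.sequence, 1) if a in site_letters]
        n_occ = int(rng.integers(1, min(max_sites_occupied, len(sites)) + 1))
        occupied = sorted(rng.choice(sites, size=n_occ, replace=False).tolist())
        entry = db.entries[int(rng.integers(len(db.entries)))]
        site_glycans = _split_composition(rng, entry.composition, occupied)
        truths.append(
            GroundTruth(
                peptide=pep,
                glycan=entry,
                site_glycans=site_glycans,
                charge=int(rng.integers(2, 4)),
                coverage=dict(coverage or DEFAULT_COVERAGE),
                n_noise=n_noise,
                scan_id=scan,
            )
        )
        scan += 2
    return truths


def _split_composition(
    rng: np.random.Generator, G: GlycanComposition, sites: list[int]
) -> dict[int, GlycanComposition]:
    """Randomly split G across the occupied sites (every site gets >= 1 unit
    when possible)."""
    n = len(sites)
    parts = [[0] * len(G.counts) for _ in range(n)]
    for t, count in enumerate(G.counts):
        for _ in range(count):
            parts[int(rng.integers(n))][t] += 1
    # ensure no empty site: move one unit to any empty site
    for i in range(n):
        if sum(parts[i]) == 0:
            donor = max(range(n), key=lambda j: sum(parts[j]))
            if sum(parts[donor]) > 1:
                t = next(t for t, c in enumerate(parts[donor]) if c > 0)
                parts[donor][t] -= 1
                parts[i][t] += 1
    out = {}
    for site, counts in zip(sites, parts):
        comp = GlycanComposition(tuple(counts))
        if comp:
            out[site] = comp
    return out


# ---------------------------------------------------------------------------
# brute-force oracles


def brute_force_glycan_scores(
    spectrum: Spectrum,
    db: GlycanDB,
    tol_ppm: float = 20.0,
) -> dict[int, tuple[int, int]]:
    """Per-glycan (ion_count, core_count) by direct Y-ladder matching.

    O(#glycans x #peaks); the reference the Y-complement index must equal.
    The full-glycan Y (the precursor itself) is excluded, as in the index.
    """
    P = spectrum.precursor_neutral_mass
    peaks = np.asarray(spectrum.masses, dtype=float)
    tols = tol_ppm * 1e-6 * peaks
    out = {}
    for entry in db:
        total = entry.composition.mass
        ys = [y for y in entry.y_compositions() if y.counts != entry.composition.counts]
        if not ys or len(peaks) == 0:
            out[entry.glycan_id] = (0, 0)
            continue
        complements = np.array([total - y.mass for y in ys])
        is_core = np.array([db.is_core(y) for y in ys])
        hit = np.abs((P - peaks)[None, :] - complements[:, None]) <= tols[None, :]
        out[entry.glycan_id] = (
            int(hit.sum()),
            int(hit[is_core].sum()),
        )
    return out


class OracleRefusedError(RuntimeError):
    """The glycoform enumeration would exceed the safety guard."""


def brute_force_localize(
    spectrum: Spectrum,
    peptide: PeptideEntry,
    G: GlycanComposition,
    candidate_sites: Sequence[int],
    tol_ppm: float = 20.0,
    max_forms: int = 100_000,
) -> tuple[int, list[tuple[int, ...]]]:
    """Exhaustive site-localization oracle.

    Enumerates every assignment of G across the candidate sites
    (stars-and-bars per monosaccharide type), scores each glycoform's c/z
    ions exactly as the ScoreTable does (same peak removal, same variants),
    and returns the best score together with the cumulative-glycan-mass
    profiles (as subcomposition index tuples per column 1..L-1) of all
    argmax forms.
    """
    sites = sorted(candidate_sites)
    S = len(sites)
    if S == 0:
        raise ValueError("no candidate sites")
    n_forms = 1
    for count in G.counts:
        if count:
            n_forms *= math.comb(S + count - 1, S - 1)
    if n_forms > max_forms:
        raise OracleRefusedError(f"{n_forms} glycoforms exceed the guard")

    L = len(peptide.sequence)
    prefix, suffix = _prefix_suffix_masses(peptide)

    # independent peak removal: Y ladder, b/y, b/y + HexNAc
    masses = np.array(spectrum.masses, dtype=float)
    removal = [peptide.mass + y.mass for y in subcompositions(G)]
    for i in range(1, L):
        removal += [
            prefix[i - 1],
            suffix[i - 1] + WATER,
            prefix[i - 1] + HEXNAC,
            suffix[i - 1] + WATER + HEXNAC,
        ]
    keep = np.ones(len(masses), dtype=bool)
    for t in removal:
        keep &= np.abs(masses - t) > tol_ppm * 1e-6 * max(t, 1.0)
    masses = masses[keep]

    def matched(t: float) -> bool:
        tol = tol_ppm * 1e-6 * t
        j = int(np.searchsorted(masses, t))
        return any(
            0 <= jj < len(masses) and abs(masses[jj] - t) <= tol for jj in (j - 1, j)
        )

    subs = subcompositions(G)
    sub_row = {g.counts: i for i, g in enumerate(subs)}

    # per-type weak compositions over the S sites
    per_type: list[list[tuple[int, ...]]] = []
    for count in G.counts:
        per_type.append(_weak_compositions(count, S))

    score_cache: dict[tuple[int, int], int] = {}

    def cell_score(row: int, p: int) -> int:
        key = (row, p)
        val = score_cache.get(key)
        if val is None:
            g = subs[row]
            c = prefix[p - 1] + NH3 + g.mass
            z = suffix[p - 1] + WATER - NH3 + H_MASS + (G.mass - g.mass)
            val = 0
            if matched(c) or matched(c + H_MASS):
                val += 1
            if matched(z) or matched(z + H_MASS):
                val += 1
            score_cache[key] = val
        return val

    best = -1
    argmax: list[tuple[int, ...]] = []
    for combo in itertools.product(*per_type):
        # combo[t][s] = count of type t on site s -> cumulative rows per column
        profile = []
        cum = [0] * len(G.counts)
        site_iter = 0
        score = 0
        for p in range(1, L):
            while site_iter < S and sites[site_iter] <= p:
                for t in range(len(G.counts)):
                    cum[t] += combo[t][site_iter]
                site_iter += 1
            row = sub_row[tuple(cum)]
            profile.append(row)
            score += cell_score(row, p)
        if score > best:
            best = score
            argmax = [tuple(profile)]
        elif score == best:
            argmax.append(tuple(profile))
    # distinct profiles only (different site splits can share a profile only
    # when sites coincide, which cannot happen; keep the dedup for safety)
    argmax = list(dict.fromkeys(argmax))
    return best, argmax


def _weak_compositions(total: int, parts: int) -> list[tuple[int, ...]]:
    if parts == 1:
        return [(total,)]
    out = []
    for first in range(total + 1):
        for rest in _weak_compositions(total - first, parts - 1):
            out.append((first,) + rest)
    return out
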
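"""Glycan-first scoring via a Y-complementary-ion index.

For a peak of neutral mass m in a spectrum of precursor neutral mass P,
``P - m`` equals ``glycan mass - Y-ion glycan mass`` for whichever glycan/Y
pair the peak came from — a quantity independent of the peptide.  Indexing
every (glycan, Y composition) pair by this complement mass lets one pass over
the peak list score every glycan in the database at once, instead of matching
the spectrum once per glycan.

Entries are packed into 32-bit integers: the glycan id occupies the low 31
bits and the top bit flags whether the Y composition is a core ion (the
reducing-end ladder used as the confidence gate).  Glycan decoys — the same Y
ladder under a per-glycan random mass offset — are interleaved in the same
index so targets and decoys compete peak-for-peak.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .glycan import GlycanComposition, GlycanDB, GlycanEntry, MAX_GLYCAN_ID
from .spectra import Spectrum, has_diagnostic_ion

__all__ = [
    "YComplementIndex",
    "GlycanScore",
    "build_index",
    "score_glycans",
    "select_candidates",
    "fine_score_glycan",
    "DEFAULT_MONO_DIAGNOSTIC_IONS",
]

CORE_BIT = np.uint32(1 << 31)

#: Oxonium ions required as in-spectrum evidence before a glycan containing
#: the symbol may survive candidate selection.  NeuAc/NeuGc: the oxonium and
#: its water loss; Fuc: the HexNAc+Hex+Fuc B ion.
DEFAULT_MONO_DIAGNOSTIC_IONS: dict[str, tuple[float, ...]] = {
    "A": (274.092, 292.103),
    "G": (290.087, 308.098),
    "F": (512.197,),
}


@dataclass
class GlycanScore:
    glycan_id: int
    ion_count: int = 0
    core_count: int = 0
    fine_score: float = 0.0
    is_decoy: bool = False

    @property
    def rank_score(self) -> int:
        return self.ion_count + self.core_count


@dataclass
class YComplementIndex:
    """Sorted Y-complement mass table with an integer-keyed bucket directory."""

    masses: np.ndarray  # sorted complement masses, Da
    packed: np.ndarray  # uint32: glycan id | core bit
    decoy: np.ndarray  # bool per entry
    db: GlycanDB
    decoy_offsets: Optional[np.ndarray] = None  # per-glycan-id decoy mass shift
    bucket_width: float = 1.0
    _buckets: dict[int, tuple[int, int]] = field(default_factory=dict, repr=False)
    entries_visited: int = 0  # cumulative matched-entry visits (for cost audits)

    def __post_init__(self) -> None:
        keys = np.floor(self.masses / self.bucket_width).astype(np.int64)
        starts = np.searchsorted(keys, np.unique(keys), side="left")
        ends = np.searchsorted(keys, np.unique(keys), side="right")
        for k, lo, hi in zip(np.unique(keys), starts, ends):
            self._buckets[int(k)] = (int(lo), int(hi))

    def __len__(self) -> int:
        return len(self.masses)

    def query(self, mass: float, tol: float) -> np.ndarray:
        """Indices of entries with |complement - mass| <= tol."""
        k_lo = int(np.floor((mass - tol) / self.bucket_width))
        k_hi = int(np.floor((mass + tol) / self.bucket_width))
        hits = []
        for k in range(k_lo, k_hi + 1):
            span = self._buckets.get(k)
            if span is None:
                continue
            lo, hi = span
            seg = self.masses[lo:hi]
            a = lo + int(np.searchsorted(seg, mass - tol, side="left"))
            b = lo + int(np.searchsorted(seg, mass + tol, side="right"))
            if b > a:
                hits.append(np.arange(a, b))
        if not hits:
            return np.empty(0, dtype=np.int64)
        out = np.concatenate(hits)
        self.entries_visited += len(out)
        return out


def build_index(
    db: GlycanDB,
    decoy_seed: Optional[int] = None,
    decoy_offset_range: tuple[float, float] = (1.0, 30.0),
) -> YComplementIndex:
    """Build the Y-complement index; one entry per (glycan, Y composition).

    With ``decoy_seed`` set, every target glycan also contributes a decoy
    whose complement masses are uniformly shifted by a per-glycan offset drawn
    from ``decoy_offset_range``; decoy entries carry the same packed id but a
    decoy flag.
    """
    masses: list[float] = []
    packed: list[int] = []
    decoy: list[bool] = []
    offsets: Optional[np.ndarray] = None
    if decoy_seed is not None:
        rng = np.random.default_rng(decoy_seed)
        max_id = max((e.glycan_id for e in db.entries), default=0)
        offsets = rng.uniform(*decoy_offset_range, size=max_id + 1)
    for entry in db:
        if entry.glycan_id > MAX_GLYCAN_ID:
            raise ValueError(f"glycan id {entry.glycan_id} overflows 31 bits")
        total = entry.composition.mass
        for y in entry.y_compositions():
            complement = total - y.mass
            word = entry.glycan_id | (int(CORE_BIT) if db.is_core(y) else 0)
            masses.append(complement)
            packed.append(word)
            decoy.append(False)
            if offsets is not None and complement > 1e-6:
                masses.append(complement + offsets[entry.glycan_id])
                packed.append(word)
                decoy.append(True)
    masses_arr = np.asarray(masses, dtype=float)
    order = np.argsort(masses_arr, kind="stable")
    return YComplementIndex(
        masses=masses_arr[order],
        packed=np.asarray(packed, dtype=np.uint32)[order],
        decoy=np.asarray(decoy, dtype=bool)[order],
        db=db,
        decoy_offsets=offsets,
    )


def score_glycans(
    spectrum: Spectrum,
    index: YComplementIndex,
    tol_ppm: float = 20.0,
) -> dict[tuple[int, bool], GlycanScore]:
    """Matched-ion counts of every (glycan, target/decoy) for one spectrum.

    One pass over the peaks: each peak queries the index at
    ``precursor - peak`` and increments the hit glycans' ion counts (core
    counts when the core bit is set).  The full-glycan Y entry (complement 0)
    never scores — its peak is the precursor, which preprocessing removed.
    Results are identical to matching each glycan's Y ladder one by one.
    """
    P = spectrum.precursor_neutral_mass
    scores: dict[tuple[int, bool], GlycanScore] = {}
    for m in spectrum.masses:
        target = P - m
        if target < -0.5:
            continue
        tol = tol_ppm * 1e-6 * m
        for j in index.query(target, tol):
            if index.masses[j] <= 1e-6 and not index.decoy[j]:
                continue  # complement 0 = precursor itself
            word = int(index.packed[j])
            gid = word & MAX_GLYCAN_ID
            is_core = bool(word & int(CORE_BIT))
            key = (gid, bool(index.decoy[j]))
            sc = scores.get(key)
            if sc is None:
                sc = scores[key] = GlycanScore(gid, is_decoy=key[1])
            sc.ion_count += 1
            if is_core:
                sc.core_count += 1
    return scores


def select_candidates(
    scores: dict[tuple[int, bool], GlycanScore],
    index: YComplementIndex,
    spectrum: Spectrum,
    core_count_min: Optional[int] = None,
    top_glycans: int = 100,
    small_glycan_units: int = 3,
    mono_diagnostic_ions: Optional[dict[str, tuple[float, ...]]] = None,
    tol_ppm: float = 20.0,
) -> list[tuple[GlycanEntry, bool, GlycanScore]]:
    """Candidate-filter cascade after glycan scoring.

    1. keep glycans with >= n core Y ions matched (n=2 for N-, 1 for O-mode);
    2. drop glycans containing a monosaccharide whose diagnostic oxonium ion
       is absent from the raw spectrum;
    3. rank by ion count + core count, keep the top ``top_glycans`` (ties at
       the cut broken toward the smaller glycan id);
    4. unconditionally re-admit small glycans (<= ``small_glycan_units``
       units), which have too few Y ions to score well.

    Candidates are also required to leave a positive peptide mass
    (glycan mass <= precursor mass + tolerance).
    """
    db = index.db
    if core_count_min is None:
        core_count_min = 2 if db.glyco_type == "N" else 1
    if mono_diagnostic_ions is None:
        mono_diagnostic_ions = DEFAULT_MONO_DIAGNOSTIC_IONS
    by_id = {e.glycan_id: e for e in db.entries}
    P = spectrum.precursor_neutral_mass

    diag_cache: dict[str, bool] = {}

    def diagnostics_ok(comp: GlycanComposition) -> bool:
        for sym, ions in mono_diagnostic_ions.items():
            if comp[sym] > 0:
                if sym not in diag_cache:
                    diag_cache[sym] = has_diagnostic_ion(spectrum, ions, tol_ppm)
                if not diag_cache[sym]:
                    return False
        return True

    def glycan_mass(entry: GlycanEntry, is_decoy: bool) -> float:
        mass = entry.composition.mass
        if is_decoy and index.decoy_offsets is not None:
            mass += index.decoy_offsets[entry.glycan_id]
        return mass

    survivors: list[tuple[GlycanEntry, bool, GlycanScore]] = []
    for (gid, is_decoy), sc in scores.items():
        entry = by_id.get(gid)
        if entry is None:
            continue
        if glycan_mass(entry, is_decoy) > P + max(1e-6 * 20 * P, 0.01):
            continue
        if sc.core_count < core_count_min:
            continue
        if not diagnostics_ok(entry.composition):
            continue
        survivors.append((entry, is_decoy, sc))

    survivors.sort(key=lambda t: (-t[2].rank_score, t[0].glycan_id, t[1]))
    kept = survivors[:top_glycans]
    kept_keys = {(e.glycan_id, d) for e, d, _ in kept}

    # small glycans are always searched, scored or not
    for entry in db.entries:
        if entry.composition.total_units <= small_glycan_units:
            for is_decoy in (False,) if index.decoy_offsets is None else (False, True):
                key = (entry.glycan_id, is_decoy)
                if key in kept_keys:
                    continue
                if glycan_mass(entry, is_decoy) > P + 0.01:
                    continue
                if not diagnostics_ok(entry.composition):
                    continue
                sc = scores.get(key, GlycanScore(entry.glycan_id, is_decoy=is_decoy))
                kept.append((entry, is_decoy, sc))
                kept_keys.add(key)
    return kept


def fine_score_glycan(
    spectrum: Spectrum,
    entry: GlycanEntry,
    peptide_mass: float,
    core_y_set,
    tol_ppm: float = 20.0,
) -> float:
    """Intensity-aware Y-ion score for one candidate glycan.

    Sum over matched theoretical Y ions of w * (1 + log10 relative intensity)
    with the relative intensity clamped to [0.1, 1], w=2 for core ions and 1
    otherwise, normalized by the number of theoretical Y ions.  Monotone in
    the matched-ion set; the full-glycan Y (the precursor) is excluded.
    """
    y_comps = entry.y_compositions()
    theoretical = [y for y in y_comps if y.counts != entry.composition.counts]
    if not theoretical:
        return 0.0
    masses = spectrum.masses
    intens = spectrum.intensities
    base = float(intens.max()) if len(intens) else 1.0
    score = 0.0
    for y in theoretical:
        t = peptide_mass + y.mass
        tol = tol_ppm * 1e-6 * t
        j = int(np.searchsorted(masses, t))
        best_int = None
        for jj in (j - 1, j):
            if 0 <= jj < len(masses) and abs(masses[jj] - t) <= tol:
                if best_int is None or intens[jj] > best_int:
                    best_int = float(intens[jj])
        if best_int is not None:
            rel = min(max(best_int / base, 0.1), 1.0)
            w = 2.0 if y in core_y_set else 1.0
            score += w * (1.0 + np.log10(rel))
    return score / len(theoretical)
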
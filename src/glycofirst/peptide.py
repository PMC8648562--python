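"""Protein digestion, mass-indexed peptide lookup, GPSM assembly and FDR.

Candidate N-glycosylation sites are marked before digestion: every Asn in an
N-X-S/T/C sequon (X != P) is rewritten to 'J' on the protein, so sequon
context that straddles a cleavage site is still seen.  'J' keeps the mass and
elements of Asn.  O-mode uses Ser/Thr as candidate sites.

FDR is estimated at three levels from two independent decoy channels:
reversed proteins for the peptide level and mass-shifted glycan decoys for
the glycan level; the glycopeptide-level FDR combines them as
Fg + Fp - Fg*Fp.  Glycans of at most three units skip glycan FDR (their Y
ladders are too short to score) and inherit the peptide-level value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from pyteomics import fasta as _fasta
from pyteomics import mass as _pmass

from .chem import HEXNAC, ISOTOPE_SPACING, NH3, PROTON, WATER, ELEMENT_MASS
from .glycan import GlycanEntry
from .index import fine_score_glycan
from .spectra import FROM_ETXXD, FROM_HCD, Spectrum

__all__ = [
    "AA_MASS",
    "Modification",
    "PeptideEntry",
    "PeptideStore",
    "GPSM",
    "digest",
    "apply_sequon",
    "search_peptides",
    "chimera_filter",
    "estimate_fdrs",
]

AA_MASS: dict[str, float] = dict(_pmass.std_aa_mass)
AA_MASS["J"] = AA_MASS["N"]  # sequon-marked Asn, identical mass/elements

H_MASS = ELEMENT_MASS["H"]


@dataclass(frozen=True)
class Modification:
    residue: str  # one-letter residue, or 'nterm'/'cterm'
    delta: float
    name: str = ""
    fixed: bool = False

    @classmethod
    def parse(cls, text: str, fixed: bool) -> "Modification":
        """Parse ``C:57.02146`` or ``C:57.02146:carbamidomethyl``."""
        parts = text.split(":")
        if len(parts) < 2:
            raise ValueError(f"bad modification spec {text!r}")
        return cls(parts[0], float(parts[1]), parts[2] if len(parts) > 2 else "", fixed)


@dataclass(frozen=True)
class PeptideEntry:
    sequence: str  # J-substituted
    mods: tuple[tuple[int, float, str], ...]  # (1-based position, delta, name)
    mass: float
    proteins: tuple[str, ...]
    is_decoy: bool = False
    missed: int = 0

    def __str__(self) -> str:
        return self.sequence


def peptide_mass(sequence: str, mods: Sequence[tuple[int, float, str]] = ()) -> float:
    return sum(AA_MASS[a] for a in sequence) + WATER + sum(d for _, d, _ in mods)


def apply_sequon(protein: str) -> str:
    """Rewrite sequon Asn (N-X-S/T/C, X != P) to 'J' on the full protein."""
    chars = list(protein)
    for i in range(len(chars) - 2):
        if chars[i] == "N" and chars[i + 1] != "P" and chars[i + 2] in "STC":
            chars[i] = "J"
    return "".join(chars)


_ENZYMES = {
    "trypsin": ("KR", "P"),  # cut C-terminal of K/R unless next is P
    "chymotrypsin": ("FWYL", "P"),
    "gluc": ("DE", ""),
}


def _cleavage_rule(enzyme: str) -> tuple[str, str]:
    if enzyme in _ENZYMES:
        return _ENZYMES[enzyme]
    # custom "KR|not-P" style: cut residues, optional excluded next residue
    parts = enzyme.split("|")
    residues = parts[0]
    blocked = parts[1].replace("not-", "") if len(parts) > 1 else ""
    return residues, blocked


def _digest_sequence(seq: str, residues: str, blocked: str, missed: int) -> Iterable[tuple[str, int]]:
    cuts = [0]
    for i, aa in enumerate(seq[:-1]):
        if aa in residues and (not blocked or seq[i + 1] not in blocked):
            cuts.append(i + 1)
    cuts.append(len(seq))
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + missed, len(cuts))):
            yield seq[cuts[a] : cuts[b]], b - a - 1


class PeptideStore:
    """Mass-bucketed peptide entries for O(1)-per-query window lookup."""

    def __init__(self, entries: list[PeptideEntry]) -> None:
        entries.sort(key=lambda e: e.mass)
        self.entries = entries
        self._masses = np.array([e.mass for e in entries])

    def __len__(self) -> int:
        return len(self.entries)

    def query(self, mass: float, tol: float) -> list[PeptideEntry]:
        lo = int(np.searchsorted(self._masses, mass - tol, side="left"))
        hi = int(np.searchsorted(self._masses, mass + tol, side="right"))
        return self.entries[lo:hi]


def digest(
    fasta_path: str | Path | None = None,
    *,
    proteins: Optional[dict[str, str]] = None,
    enzyme: str = "trypsin",
    missed_cleavages: int = 2,
    fixed_mods: Sequence[Modification] = (),
    var_mods: Sequence[Modification] = (),
    max_var_mods: int = 3,
    min_length: int = 6,
    max_length: int = 40,
    with_decoys: bool = True,
) -> PeptideStore:
    """Digest a FASTA (or an accession->sequence map) into a mass-indexed store.

    Sequon marking happens on the protein, decoys are whole-protein reversals
    (re-marked and re-digested), and variable modifications are expanded up
    to ``max_var_mods`` per peptide.
    """
    if proteins is None:
        if fasta_path is None:
            raise ValueError("either fasta_path or proteins is required")
        proteins = {}
        try:
            with _fasta.read(str(fasta_path)) as reader:
                for header, seq in reader:
                    proteins[header.split()[0]] = seq.upper()
        except OSError as exc:
            raise IOError(f"cannot read FASTA {fasta_path}: {exc}") from exc

    residues, blocked = _cleavage_rule(enzyme)
    collected: dict[tuple[str, tuple, bool], set[str]] = {}
    pools = [(False, proteins)]
    if with_decoys:
        pools.append(
            (True, {f"DECOY_{acc}": seq[::-1] for acc, seq in proteins.items()})
        )
    peptide_missed: dict[tuple[str, bool], int] = {}
    for is_decoy, pool in pools:
        for acc, seq in pool.items():
            marked = apply_sequon(seq)
            for pep, nm in _digest_sequence(marked, residues, blocked, missed_cleavages):
                if not (min_length <= len(pep) <= max_length):
                    continue
                if any(a not in AA_MASS for a in pep):
                    continue
                collected.setdefault((pep, (), is_decoy), set()).add(acc)
                key = (pep, is_decoy)
                peptide_missed[key] = min(peptide_missed.get(key, nm), nm)

    entries: list[PeptideEntry] = []
    for (pep, _, is_decoy), accs in collected.items():
        for mods in _expand_mods(pep, fixed_mods, var_mods, max_var_mods):
            entries.append(
                PeptideEntry(
                    sequence=pep,
                    mods=mods,
                    mass=peptide_mass(pep, mods),
                    proteins=tuple(sorted(accs)),
                    is_decoy=is_decoy,
                    missed=peptide_missed[(pep, is_decoy)],
                )
            )
    return PeptideStore(entries)


def _expand_mods(
    pep: str,
    fixed: Sequence[Modification],
    variable: Sequence[Modification],
    cap: int,
) -> list[tuple[tuple[int, float, str], ...]]:
    base: list[tuple[int, float, str]] = []
    for mod in fixed:
        for i, aa in enumerate(pep, start=1):
            if aa == mod.residue:
                base.append((i, mod.delta, mod.name or f"{mod.residue}{mod.delta:+.4f}"))
    var_positions: list[tuple[int, float, str]] = []
    for mod in variable:
        for i, aa in enumerate(pep, start=1):
            if aa == mod.residue:
                var_positions.append((i, mod.delta, mod.name or f"{mod.residue}{mod.delta:+.4f}"))
    out = []
    for k in range(0, min(cap, len(var_positions)) + 1):
        for combo in itertools.combinations(var_positions, k):
            if len({p for p, _, _ in combo}) != len(combo):
                continue
            out.append(tuple(sorted(base + list(combo))))
    return out


# ---------------------------------------------------------------------------
# GPSM assembly


@dataclass
class GPSM:
    scan_id: int
    precursor_mz: float
    precursor_charge: int
    isotope_k: int
    peptide: PeptideEntry
    glycan: GlycanEntry
    glycan_decoy: bool
    glycan_mass: float  # decoy-shifted when glycan_decoy
    glycan_score: float
    peptide_score: float
    total_score: float
    glycan_fdr: float = 1.0
    peptide_fdr: float = 1.0
    glycopeptide_fdr: float = 1.0
    localization: object = None  # LocalizationResult, filled by the localizer
    spectrum: Optional[Spectrum] = field(default=None, repr=False)

    @property
    def corrected_precursor_mass(self) -> float:
        z = self.precursor_charge
        return self.precursor_mz * z - z * PROTON - self.isotope_k * ISOTOPE_SPACING

    @property
    def is_decoy(self) -> bool:
        return self.peptide.is_decoy or self.glycan_decoy


def _prefix_suffix_masses(pep: PeptideEntry) -> tuple[np.ndarray, np.ndarray]:
    L = len(pep.sequence)
    res = np.array([AA_MASS[a] for a in pep.sequence])
    for pos, delta, _ in pep.mods:
        res[pos - 1] += delta
    prefix = np.cumsum(res)
    total = prefix[-1]
    suffix = total - prefix  # suffix[i] = sum of residues i+1..L
    return prefix, suffix


def _match_one(masses: np.ndarray, ok: np.ndarray, t: float, tol_ppm: float) -> bool:
    tol = tol_ppm * 1e-6 * t
    j = int(np.searchsorted(masses, t))
    for jj in (j - 1, j):
        if 0 <= jj < len(masses) and ok[jj] and abs(masses[jj] - t) <= tol:
            return True
    return False


def score_peptide(
    spectrum: Spectrum,
    pep: PeptideEntry,
    mode: str,
    tol_ppm: float = 20.0,
) -> float:
    """Backbone-fragment score: matched b/y and 'b/y + HexNAc' (HCD peaks),
    plus c/z with their one-hydrogen-rearranged variants in merged mode
    (ETxxD peaks).  Each (series, position) counts once; contributions are
    1 + log10 of the clamped relative intensity; normalized by 2(L-1)."""
    L = len(pep.sequence)
    if L < 2 or len(spectrum.masses) == 0:
        return 0.0
    prefix, suffix = _prefix_suffix_masses(pep)
    masses = spectrum.masses
    intens = spectrum.intensities
    prov = spectrum.provenance
    base = float(intens.max())
    hcd_ok = (prov & FROM_HCD) > 0
    et_ok = (prov & FROM_ETXXD) > 0
    if spectrum.activation.upper() != "MERGED":
        hcd_ok = np.ones(len(masses), dtype=bool)
        et_ok = hcd_ok

    def contribution(targets: Sequence[float], ok: np.ndarray) -> float:
        for t in targets:
            tol = tol_ppm * 1e-6 * t
            j = int(np.searchsorted(masses, t))
            best = None
            for jj in (j - 1, j):
                if 0 <= jj < len(masses) and ok[jj] and abs(masses[jj] - t) <= tol:
                    if best is None or intens[jj] > best:
                        best = float(intens[jj])
            if best is not None:
                rel = min(max(best / base, 0.1), 1.0)
                return 1.0 + float(np.log10(rel))
        return 0.0

    score = 0.0
    for i in range(1, L):
        b = prefix[i - 1]
        y = suffix[i - 1] + WATER
        score += contribution([b], hcd_ok)
        score += contribution([y], hcd_ok)
        score += contribution([b + HEXNAC], hcd_ok)
        score += contribution([y + HEXNAC], hcd_ok)
        if mode == "merged":
            c = b + NH3
            z = y - NH3 + H_MASS  # z-dot
            score += contribution([c, c + H_MASS], et_ok)
            score += contribution([z, z + H_MASS], et_ok)
    return score / (2.0 * (L - 1))


def search_peptides(
    spectrum: Spectrum,
    candidates: Sequence[tuple[GlycanEntry, bool, object]],
    store: PeptideStore,
    mode: str = "hcd",
    glyco_type: str = "N",
    core_y_set=frozenset(),
    decoy_offsets: Optional[np.ndarray] = None,
    glycosylation_sites: Optional[str] = None,
    precursor_tol_ppm: float = 10.0,
    fragment_tol_ppm: float = 20.0,
    isotope_range: Sequence[int] = (0, 1, -1, 2, -2),
) -> list[GPSM]:
    """Score peptides for every candidate glycan; return the best GPSM per
    precursor isotope hypothesis.

    For each candidate glycan the peptide mass is deduced as
    ``corrected precursor mass - glycan mass`` and looked up in the
    mass-indexed store; peptides must contain at least one candidate
    glycosylation residue (J in N-mode, S/T in O-mode).
    """
    sites = glycosylation_sites or ("J" if glyco_type == "N" else "ST")
    P0 = spectrum.precursor_neutral_mass
    best_per_k: dict[int, GPSM] = {}
    pep_score_cache: dict[tuple[str, tuple], float] = {}
    for k in isotope_range:
        P = P0 - k * ISOTOPE_SPACING
        for entry, glycan_decoy, _sc in candidates:
            gmass = entry.composition.mass
            if glycan_decoy:
                if decoy_offsets is None:
                    continue
                gmass += decoy_offsets[entry.glycan_id]
            pep_mass = P - gmass
            if pep_mass <= 0:
                continue
            tol = precursor_tol_ppm * 1e-6 * P
            for pep in store.query(pep_mass, tol):
                if not any(a in sites for a in pep.sequence):
                    continue
                cache_key = (pep.sequence, pep.mods)
                psc = pep_score_cache.get(cache_key)
                if psc is None:
                    psc = score_peptide(spectrum, pep, mode, fragment_tol_ppm)
                    pep_score_cache[cache_key] = psc
                gsc = fine_score_glycan(
                    spectrum, entry, pep_mass, core_y_set, fragment_tol_ppm
                )
                total = gsc + psc
                cur = best_per_k.get(k)
                if cur is None or total > cur.total_score:
                    best_per_k[k] = GPSM(
                        scan_id=spectrum.scan_id,
                        precursor_mz=spectrum.precursor_mz,
                        precursor_charge=spectrum.precursor_charge,
                        isotope_k=k,
                        peptide=pep,
                        glycan=entry,
                        glycan_decoy=glycan_decoy,
                        glycan_mass=gmass,
                        glycan_score=gsc,
                        peptide_score=psc,
                        total_score=total,
                        spectrum=spectrum,
                    )
    return sorted(best_per_k.values(), key=lambda g: -g.total_score)


def chimera_filter(gpsms: Sequence[GPSM], isotope_window_da: float = 0.02) -> list[GPSM]:
    """Remove isotope-shadow co-identifications within one MS2 scan.

    If two GPSMs of the same scan have corrected precursor masses differing
    by 1 or 2 isotope spacings (within a window wide enough to catch
    near-isobaric compositions such as NeuAc(1) vs Fuc(2), which differ by
    1.02 Da), the lower-scoring one is dropped.
    """
    by_scan: dict[int, list[GPSM]] = {}
    for g in gpsms:
        by_scan.setdefault(g.scan_id, []).append(g)
    out: list[GPSM] = []
    for scan_gpsms in by_scan.values():
        scan_gpsms.sort(key=lambda g: -g.total_score)
        kept: list[GPSM] = []
        for g in scan_gpsms:
            shadowed = False
            for h in kept:
                d = abs(g.corrected_precursor_mass - h.corrected_precursor_mass)
                for k in (1, 2):
                    if abs(d - k * ISOTOPE_SPACING) <= isotope_window_da:
                        shadowed = True
            if not shadowed:
                kept.append(g)
        out.extend(kept)
    out.sort(key=lambda g: (g.scan_id, -g.total_score))
    return out


# ---------------------------------------------------------------------------
# FDR


def _q_values(scores: np.ndarray, is_decoy: np.ndarray) -> np.ndarray:
    """Target-decoy q-values: #decoy/#target above each score, monotonized."""
    order = np.argsort(-scores, kind="stable")
    d_cum = np.cumsum(is_decoy[order])
    t_cum = np.cumsum(~is_decoy[order])
    fdr = d_cum / np.maximum(t_cum, 1)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    out = np.empty(len(scores))
    out[order] = np.minimum(q, 1.0)
    return out


def estimate_fdrs(
    gpsms: Sequence[GPSM],
    small_glycan_units: int = 3,
) -> list[GPSM]:
    """Attach glycan-, peptide- and glycopeptide-level FDRs to every GPSM.

    Peptide q-values come from reversed-protein decoys on the peptide score;
    glycan q-values from mass-shifted glycan decoys on the glycan score;
    the combined level is Fg + Fp - Fg*Fp.  Small glycans (<= 3 units) skip
    glycan FDR (reported as 0), so their combined FDR equals the peptide one.
    """
    gpsms = list(gpsms)
    if not gpsms:
        return []
    pep_scores = np.array([g.peptide_score for g in gpsms])
    pep_decoy = np.array([g.peptide.is_decoy for g in gpsms])
    gly_scores = np.array([g.glycan_score for g in gpsms])
    gly_decoy = np.array([g.glycan_decoy for g in gpsms])
    if not pep_decoy.any():
        pep_q = np.zeros(len(gpsms))
    else:
        pep_q = _q_values(pep_scores, pep_decoy)
    if not gly_decoy.any():
        gly_q = np.zeros(len(gpsms))
    else:
        gly_q = _q_values(gly_scores, gly_decoy)
    for g, fp, fg in zip(gpsms, pep_q, gly_q):
        if g.glycan.composition.total_units <= small_glycan_units:
            fg = 0.0
        g.peptide_fdr = float(fp)
        g.glycan_fdr = float(fg)
        g.glycopeptide_fdr = float(fg + fp - fg * fp)
    return gpsms
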
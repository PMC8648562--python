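"""MS2 spectrum handling: MGF I/O, deisotoping, deconvolution, HCD/ETxxD merging.

All search stages downstream of :func:`preprocess` operate on *neutral*
fragment masses (charge-deconvoluted, deisotoped); the raw m/z peak list is
kept alongside for oxonium/diagnostic-ion checks, which live in the low-m/z
region that deconvolution does not need.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
from pyteomics import mgf as _mgf

from .chem import ISOTOPE_SPACING, PROTON

__all__ = [
    "Spectrum",
    "MGFParseError",
    "PairingError",
    "read_mgf",
    "write_mgf",
    "preprocess",
    "merge_paired",
    "has_diagnostic_ion",
    "hex_diagnostic_fraction",
]

# peak provenance flags after merging
FROM_HCD = 1
FROM_ETXXD = 2

ETXXD_ACTIVATIONS = ("ETD", "ETHCD", "ETCID")


class MGFParseError(ValueError):
    pass


class PairingError(ValueError):
    pass


@dataclass
class Spectrum:
    """One MS2 scan (or a merged HCD+ETxxD pair).

    Before :func:`preprocess`, ``masses`` are raw m/z values; afterwards they
    are neutral fragment masses.  ``provenance`` is a bitmask per peak
    (HCD=1, ETxxD=2) that matters only for merged spectra, where b/y matching
    uses HCD-derived peaks and c/z matching ETxxD-derived ones.
    """

    scan_id: int
    precursor_mz: float
    precursor_charge: int
    masses: np.ndarray
    intensities: np.ndarray
    activation: str = "HCD"
    paired_scan_id: Optional[int] = None
    title: str = ""
    provenance: Optional[np.ndarray] = None
    raw_mz: Optional[np.ndarray] = None
    raw_intensity: Optional[np.ndarray] = None
    is_preprocessed: bool = False

    def __post_init__(self) -> None:
        self.masses = np.asarray(self.masses, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        order = np.argsort(self.masses, kind="stable")
        if not np.array_equal(order, np.arange(len(order))):
            self.masses = self.masses[order]
            self.intensities = self.intensities[order]
            if self.provenance is not None:
                self.provenance = np.asarray(self.provenance)[order]
        if self.provenance is None:
            flag = FROM_ETXXD if self.activation.upper() in ETXXD_ACTIVATIONS else FROM_HCD
            self.provenance = np.full(len(self.masses), flag, dtype=np.int8)

    @property
    def precursor_neutral_mass(self) -> float:
        z = self.precursor_charge
        return self.precursor_mz * z - z * PROTON

    def __len__(self) -> int:
        return len(self.masses)


def _activation_from(params: dict, title: str) -> str:
    for source in (str(params.get("activation", "")), title):
        up = source.upper()
        for act in ("ETHCD", "ETCID", "ETD", "HCD"):
            if act in up:
                return act
    return "HCD"


def _scan_from(params: dict, title: str, default: int) -> int:
    if "scans" in params:
        try:
            return int(str(params["scans"]).split("-")[0])
        except ValueError:
            pass
    import re

    m = re.search(r"scan[=: ]*(\d+)", title, flags=re.I)
    return int(m.group(1)) if m else default


def read_mgf(path: str | Path) -> list[Spectrum]:
    """Read an MGF file and link HCD-pd-ETxxD scan pairs.

    Pairs are recognized by an explicit ``pair=<scan>`` token in the TITLE,
    or by two scans of different activation sharing a precursor m/z (within
    1e-4) with adjacent scan numbers.
    """
    _check_block_structure(path)
    spectra: list[Spectrum] = []
    with _mgf.read(str(path), use_index=False) as reader:
        for i, rec in enumerate(reader):
            params = rec.get("params", {})
            title = str(params.get("title", ""))
            pepmass = params.get("pepmass", (0.0,))
            mz0 = float(pepmass[0] if isinstance(pepmass, (tuple, list)) else pepmass)
            charge = params.get("charge", [2])
            z = int(charge[0]) if isinstance(charge, (list, tuple)) else int(charge)
            spectra.append(
                Spectrum(
                    scan_id=_scan_from(params, title, default=i + 1),
                    precursor_mz=mz0,
                    precursor_charge=abs(z),
                    masses=np.asarray(rec.get("m/z array", []), dtype=float),
                    intensities=np.asarray(rec.get("intensity array", []), dtype=float),
                    activation=_activation_from(params, title),
                    title=title,
                )
            )
    _link_pairs(spectra)
    return spectra


def _check_block_structure(path: str | Path) -> None:
    depth = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        token = line.strip().upper()
        if token == "BEGIN IONS":
            if depth:
                raise MGFParseError(f"{path}:{lineno}: nested BEGIN IONS")
            depth = 1
        elif token == "END IONS":
            if not depth:
                raise MGFParseError(f"{path}:{lineno}: END IONS without BEGIN IONS")
            depth = 0
    if depth:
        raise MGFParseError(f"{path}: unterminated BEGIN IONS block")


def _link_pairs(spectra: list[Spectrum]) -> None:
    import re

    by_scan = {s.scan_id: s for s in spectra}
    for s in spectra:
        m = re.search(r"pair[=: ]*(\d+)", s.title, flags=re.I)
        if m and int(m.group(1)) in by_scan:
            s.paired_scan_id = int(m.group(1))
    unpaired = [s for s in spectra if s.paired_scan_id is None]
    for a in unpaired:
        if a.activation.upper() in ETXXD_ACTIVATIONS:
            continue
        for delta in (1, -1):
            b = by_scan.get(a.scan_id + delta)
            if (
                b is not None
                and b.activation.upper() in ETXXD_ACTIVATIONS
                and abs(b.precursor_mz - a.precursor_mz) < 1e-4
            ):
                a.paired_scan_id = b.scan_id
                b.paired_scan_id = a.scan_id
                break


def write_mgf(spectra: Iterable[Spectrum], path: str | Path) -> None:
    records = []
    for s in spectra:
        title = s.title or f"scan={s.scan_id} activation={s.activation}"
        if s.paired_scan_id is not None and "pair=" not in title:
            title += f" pair={s.paired_scan_id}"
        records.append(
            {
                "m/z array": s.masses,
                "intensity array": s.intensities,
                "params": {
                    "title": title,
                    "pepmass": s.precursor_mz,
                    "charge": s.precursor_charge,
                    "scans": s.scan_id,
                },
            }
        )
    _mgf.write(records, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# preprocessing


def preprocess(spectrum: Spectrum, fragment_tol_ppm: float = 20.0) -> Spectrum:
    """Deisotope, charge-deconvolute and strip precursor peaks.

    Isotope clusters are collapsed greedily, strongest peak first, trying
    charge states 1..precursor charge and walking +1.00335/z steps while the
    intensity profile stays compatible (each next isotope <= 1.25x the
    previous).  Unclustered peaks are treated as singly charged.  Peaks
    within tolerance of the precursor (any charge state, +/-3 isotopes) are
    removed.  Idempotent: a preprocessed spectrum passes through unchanged.
    """
    if spectrum.is_preprocessed:
        return spectrum
    mz = spectrum.masses
    inten = spectrum.intensities
    if len(mz) == 0:
        return replace(
            spectrum,
            raw_mz=mz.copy(),
            raw_intensity=inten.copy(),
            is_preprocessed=True,
        )

    keep = _precursor_window_mask(spectrum, fragment_tol_ppm)
    mz, inten = mz[keep], inten[keep]

    neutral, out_int = _deisotope(
        mz, inten, spectrum.precursor_charge, fragment_tol_ppm
    )
    flag = FROM_ETXXD if spectrum.activation.upper() in ETXXD_ACTIVATIONS else FROM_HCD
    return replace(
        spectrum,
        masses=neutral,
        intensities=out_int,
        provenance=np.full(len(neutral), flag, dtype=np.int8),
        raw_mz=spectrum.masses.copy(),
        raw_intensity=spectrum.intensities.copy(),
        is_preprocessed=True,
    )


def _precursor_window_mask(spectrum: Spectrum, tol_ppm: float) -> np.ndarray:
    mz = spectrum.masses
    keep = np.ones(len(mz), dtype=bool)
    M = spectrum.precursor_neutral_mass
    for z in range(1, spectrum.precursor_charge + 1):
        for k in range(-3, 4):
            center = (M + k * ISOTOPE_SPACING + z * PROTON) / z
            keep &= np.abs(mz - center) > tol_ppm * 1e-6 * center
    return keep


def _deisotope(
    mz: np.ndarray, inten: np.ndarray, max_charge: int, tol_ppm: float
) -> tuple[np.ndarray, np.ndarray]:
    n = len(mz)
    claimed = np.zeros(n, dtype=bool)
    out: list[tuple[float, float]] = []
    for seed in np.argsort(-inten, kind="stable"):
        if claimed[seed]:
            continue
        best_chain: list[int] = [seed]
        best_z = 1
        for z in range(1, max_charge + 1):
            chain = [int(seed)]
            current = mz[seed]
            last_int = inten[seed]
            while True:
                target = current + ISOTOPE_SPACING / z
                j = np.searchsorted(mz, target)
                cand = None
                for jj in (j - 1, j):
                    if 0 <= jj < n and not claimed[jj] and jj not in chain:
                        if abs(mz[jj] - target) <= tol_ppm * 1e-6 * target:
                            if cand is None or abs(mz[jj] - target) < abs(mz[cand] - target):
                                cand = jj
                if cand is None or inten[cand] > 1.25 * last_int:
                    break
                chain.append(int(cand))
                current = mz[cand]
                last_int = inten[cand]
            if len(chain) > len(best_chain):
                best_chain, best_z = chain, z
        claimed[best_chain] = True
        neutral = (mz[seed] - PROTON) * best_z
        out.append((neutral, float(inten[best_chain].sum())))
    out.sort()
    masses = np.array([m for m, _ in out])
    intensities = np.array([i for _, i in out])
    return masses, intensities


def merge_paired(hcd: Spectrum, etxxd: Spectrum, tol_ppm: float = 20.0) -> Spectrum:
    """Merge a preprocessed HCD/ETxxD scan pair into one neutral-mass spectrum.

    Peaks within tolerance collapse to their intensity-weighted mean mass with
    summed intensity; each merged peak remembers which scan(s) it came from.
    """
    if not (hcd.is_preprocessed and etxxd.is_preprocessed):
        raise ValueError("merge_paired expects preprocessed spectra")
    pm = hcd.precursor_neutral_mass
    if abs(etxxd.precursor_neutral_mass - pm) > max(20e-6 * pm, 0.01) + 2.5 * ISOTOPE_SPACING:
        raise PairingError(
            f"precursor mismatch: {pm:.4f} vs {etxxd.precursor_neutral_mass:.4f}"
        )
    masses = np.concatenate([hcd.masses, etxxd.masses])
    intensities = np.concatenate([hcd.intensities, etxxd.intensities])
    provenance = np.concatenate([hcd.provenance, etxxd.provenance])
    order = np.argsort(masses, kind="stable")
    masses, intensities, provenance = masses[order], intensities[order], provenance[order]

    out_m: list[float] = []
    out_i: list[float] = []
    out_p: list[int] = []
    for m, i, p in zip(masses, intensities, provenance):
        if out_m and abs(m - out_m[-1]) <= tol_ppm * 1e-6 * m:
            tot = out_i[-1] + i
            out_m[-1] = (out_m[-1] * out_i[-1] + m * i) / tot
            out_i[-1] = tot
            out_p[-1] |= int(p)
        else:
            out_m.append(float(m))
            out_i.append(float(i))
            out_p.append(int(p))
    raw_mz = hcd.raw_mz if hcd.raw_mz is not None else np.empty(0)
    raw_int = hcd.raw_intensity if hcd.raw_intensity is not None else np.empty(0)
    return Spectrum(
        scan_id=hcd.scan_id,
        precursor_mz=hcd.precursor_mz,
        precursor_charge=hcd.precursor_charge,
        masses=np.array(out_m),
        intensities=np.array(out_i),
        activation="merged",
        paired_scan_id=etxxd.scan_id,
        title=hcd.title,
        provenance=np.array(out_p, dtype=np.int8),
        raw_mz=raw_mz,
        raw_intensity=raw_int,
        is_preprocessed=True,
    )


def _raw_peaks(spectrum: Spectrum) -> tuple[np.ndarray, np.ndarray]:
    if spectrum.raw_mz is not None:
        return spectrum.raw_mz, spectrum.raw_intensity
    return spectrum.masses, spectrum.intensities


def has_diagnostic_ion(
    spectrum: Spectrum,
    diagnostic_mz: Sequence[float] = (204.087,),
    tol_ppm: float = 20.0,
) -> bool:
    """True iff any glycopeptide-diagnostic oxonium m/z is present in the raw
    (m/z-domain) HCD peaks.  Default: HexNAc oxonium at 204.087."""
    mz, _ = _raw_peaks(spectrum)
    for target in diagnostic_mz:
        tol = max(tol_ppm * 1e-6 * target, 0.002)
        j = np.searchsorted(mz, target)
        for jj in (j - 1, j):
            if 0 <= jj < len(mz) and abs(mz[jj] - target) <= tol:
                return True
    return False


def hex_diagnostic_fraction(spectrum: Spectrum, tol_ppm: float = 20.0) -> float:
    """Summed intensity of the Hex-diagnostic ions (163.060, 366.139 m/z)
    relative to the base peak of the raw spectrum.  Used as a report column
    for validating Hex-containing assignments (threshold 10% of base peak)."""
    mz, inten = _raw_peaks(spectrum)
    if len(mz) == 0:
        return 0.0
    total = 0.0
    for target in (163.060, 366.139):
        tol = max(tol_ppm * 1e-6 * target, 0.002)
        sel = np.abs(mz - target) <= tol
        total += float(inten[sel].sum())
    return total / float(inten.max())
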
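"""End-to-end search pipeline and GPSM report writing.

Stage order: spectrum preprocessing -> diagnostic-ion prefilter ->
glycan-first scoring and candidate selection -> peptide search -> chimera
(isotope-shadow) filtering -> three-level FDR -> site localization on
merged HCD+ETxxD spectra.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

from .config import SearchConfig
from .glycan import GlycanDB
from .index import YComplementIndex, build_index, score_glycans, select_candidates
from .localize import localize
from .peptide import (
    GPSM,
    Modification,
    PeptideStore,
    chimera_filter,
    digest,
    estimate_fdrs,
    search_peptides,
)
from .spectra import (
    Spectrum,
    has_diagnostic_ion,
    hex_diagnostic_fraction,
    merge_paired,
    preprocess,
    read_mgf,
)

__all__ = ["run_search", "search_spectra", "prepare_spectra", "write_report", "REPORT_COLUMNS"]

log = logging.getLogger("glycofirst")

REPORT_COLUMNS = (
    "scan",
    "precursor_mz",
    "charge",
    "isotope_k",
    "peptide",
    "mods",
    "proteins",
    "glycan_composition",
    "glycan_structure",
    "glycan_score",
    "peptide_score",
    "total_score",
    "glycan_FDR",
    "peptide_FDR",
    "glycopeptide_FDR",
    "localization",
    "hex_diag_frac",
)


def prepare_spectra(
    spectra: Sequence[Spectrum],
    cfg: SearchConfig,
) -> list[Spectrum]:
    """Preprocess all scans and merge HCD-pd-ETxxD pairs.

    Returns searchable spectra: merged pairs where both halves exist,
    otherwise standalone HCD scans.  ETxxD scans without an HCD partner are
    dropped (no glycan-diagnostic evidence to search on).
    """
    by_scan = {s.scan_id: s for s in spectra}
    processed: dict[int, Spectrum] = {
        s.scan_id: preprocess(s, cfg.fragment_tol_ppm) for s in spectra
    }
    out: list[Spectrum] = []
    consumed: set[int] = set()
    for s in spectra:
        if s.scan_id in consumed or s.activation.upper() not in ("HCD",):
            continue
        partner = by_scan.get(s.paired_scan_id) if s.paired_scan_id else None
        if partner is not None and cfg.activation_mode != "HCD":
            merged = merge_paired(
                processed[s.scan_id], processed[partner.scan_id], cfg.fragment_tol_ppm
            )
            consumed.update((s.scan_id, partner.scan_id))
            out.append(merged)
        else:
            consumed.add(s.scan_id)
            out.append(processed[s.scan_id])
    return out


def search_spectra(
    spectra: Sequence[Spectrum],
    store: PeptideStore,
    index: YComplementIndex,
    cfg: SearchConfig,
    localization_sites: Optional[str] = None,
) -> list[GPSM]:
    """Search preprocessed (possibly merged) spectra; returns all GPSMs
    (targets and decoys) with FDRs attached and localization filled in for
    merged target GPSMs."""
    db = index.db
    diag = cfg.diagnostic_ion_list()
    mono_table = cfg.mono_diagnostic_table()
    all_gpsms: list[GPSM] = []
    n_pass_diag = 0
    for spectrum in spectra:
        if diag and not has_diagnostic_ion(spectrum, diag, cfg.fragment_tol_ppm):
            continue
        n_pass_diag += 1
        scores = score_glycans(spectrum, index, cfg.fragment_tol_ppm)
        candidates = select_candidates(
            scores,
            index,
            spectrum,
            core_count_min=cfg.core_count_min,
            top_glycans=cfg.top_glycans,
            small_glycan_units=cfg.small_glycan_units,
            mono_diagnostic_ions=mono_table,
            tol_ppm=cfg.fragment_tol_ppm,
        )
        mode = "merged" if spectrum.activation.upper() == "MERGED" else "hcd"
        gpsms = search_peptides(
            spectrum,
            candidates,
            store,
            mode=mode,
            glyco_type=cfg.glyco_type,
            core_y_set=db.core_y_set,
            decoy_offsets=index.decoy_offsets,
            precursor_tol_ppm=cfg.precursor_tol_ppm,
            fragment_tol_ppm=cfg.fragment_tol_ppm,
        )
        all_gpsms.extend(gpsms)
    log.info("%d/%d spectra passed the diagnostic-ion filter", n_pass_diag, len(spectra))
    all_gpsms = chimera_filter(all_gpsms)
    all_gpsms = estimate_fdrs(all_gpsms, cfg.small_glycan_units)
    log.info("%d GPSMs after chimera filtering", len(all_gpsms))

    if cfg.run_localization != "off":
        sites = localization_sites or cfg.sites
        for g in all_gpsms:
            want = cfg.run_localization == "on" or (
                g.spectrum is not None and g.spectrum.activation.upper() == "MERGED"
            )
            if (
                want
                and not g.is_decoy
                and g.glycan.composition
                and g.glycopeptide_fdr <= cfg.fdr_threshold
            ):
                try:
                    g.localization = localize(
                        g.spectrum,
                        g.peptide,
                        g.glycan.composition,
                        glycosylation_sites=sites,
                        n_samples=cfg.ssgl_samples,
                        seed=cfg.ssgl_seed + g.scan_id,
                        tol_ppm=cfg.fragment_tol_ppm,
                    )
                except ValueError as exc:
                    log.warning("scan %d: localization failed: %s", g.scan_id, exc)
    return all_gpsms


def load_glycan_db(cfg: SearchConfig) -> GlycanDB:
    db = GlycanDB.read(cfg.glycan_db, glyco_type=cfg.glyco_type)
    if cfg.modified_units:
        for spec in cfg.modified_units.split(";"):
            base, mod, cap = spec.split(":")
            db = db.expand_modified_units(base, mod, int(cap))
    return db


def run_search(cfg: SearchConfig) -> list[dict]:
    """Execute the full pipeline from the paths in ``cfg``; write the TSV
    report and return its rows."""
    raw = read_mgf(cfg.mgf)
    log.info("read %d scans from %s", len(raw), cfg.mgf)
    spectra = prepare_spectra(raw, cfg)
    db = load_glycan_db(cfg)
    index = build_index(db, decoy_seed=cfg.decoy_seed)
    store = digest(
        cfg.fasta,
        enzyme=cfg.enzyme,
        missed_cleavages=cfg.missed_cleavages,
        fixed_mods=[Modification.parse(s, True) for s in cfg.fixed_mods.split(";") if s],
        var_mods=[Modification.parse(s, False) for s in cfg.var_mods.split(";") if s],
        max_var_mods=cfg.max_var_mods,
        min_length=cfg.peptide_len_min,
        max_length=cfg.peptide_len_max,
    )
    log.info("peptide store: %d entries; glycan index: %d entries", len(store), len(index))
    gpsms = search_spectra(spectra, store, index, cfg)
    rows = report_rows(gpsms, cfg.fdr_threshold)
    if cfg.output:
        write_report(rows, cfg.output)
        log.info("wrote %d GPSMs to %s", len(rows), cfg.output)
    return rows


def report_rows(gpsms: Sequence[GPSM], fdr_threshold: float = 1.0) -> list[dict]:
    rows = []
    for g in gpsms:
        if g.is_decoy or g.glycopeptide_fdr > fdr_threshold:
            continue
        loc = g.localization.to_string() if g.localization is not None else ""
        hexfrac = (
            hex_diagnostic_fraction(g.spectrum) if g.spectrum is not None else 0.0
        )
        rows.append(
            {
                "scan": g.scan_id,
                "precursor_mz": f"{g.precursor_mz:.5f}",
                "charge": g.precursor_charge,
                "isotope_k": g.isotope_k,
                "peptide": g.peptide.sequence,
                "mods": ";".join(
                    f"{p}:{n}" if n else f"{p}:{d:+.5f}" for p, d, n in g.peptide.mods
                ),
                "proteins": ";".join(g.peptide.proteins),
                "glycan_composition": str(g.glycan.composition),
                "glycan_structure": g.glycan.structure.canonical_string()
                if g.glycan.structure
                else "",
                "glycan_score": f"{g.glycan_score:.4f}",
                "peptide_score": f"{g.peptide_score:.4f}",
                "total_score": f"{g.total_score:.4f}",
                "glycan_FDR": f"{g.glycan_fdr:.5f}",
                "peptide_FDR": f"{g.peptide_fdr:.5f}",
                "glycopeptide_FDR": f"{g.glycopeptide_fdr:.5f}",
                "localization": loc,
                "hex_diag_frac": f"{hexfrac:.4f}",
            }
        )
    return rows


def write_report(rows: Sequence[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# glycofirst GPSM report v1\n")
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in REPORT_COLUMNS) + "\n")
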
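"""Plain-text ``key=value`` search configuration."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

__all__ = ["SearchConfig", "parse_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class SearchConfig:
    """All tunables of the search pipeline; every key has a default.

    ``glycosylation_sites`` is the candidate-residue alphabet for
    localization — "J" (sequon Asn) in N-mode, "ST" in O-mode, "JST" for
    entrapment-style validation runs; empty means the mode default.
    """

    # inputs / outputs
    mgf: str = ""
    fasta: str = ""
    glycan_db: str = ""
    output: str = "gpsm_report.tsv"
    # mode
    glyco_type: str = "N"  # N | O
    activation_mode: str = "auto"  # auto | HCD | HCD+ETxxD
    # tolerances
    fragment_tol_ppm: float = 20.0
    precursor_tol_ppm: float = 10.0
    # preprocessing
    diagnostic_ions: str = "204.087"
    # digestion
    enzyme: str = "trypsin"
    missed_cleavages: int = 2
    fixed_mods: str = "C:57.02146:carbamidomethyl"
    var_mods: str = "M:15.99491:oxidation"
    max_var_mods: int = 3
    peptide_len_min: int = 6
    peptide_len_max: int = 40
    # glycan search
    glycosylation_sites: str = ""
    core_count_N: int = 2
    core_count_O: int = 1
    top_glycans: int = 100
    small_glycan_units: int = 3
    mono_diagnostic_ions: str = "A:274.092|292.103;G:290.087|308.098;F:512.197"
    modified_units: str = ""  # e.g. "H:aH:2"
    decoy_seed: int = 1
    # reporting
    fdr_threshold: float = 0.01
    # localization
    run_localization: str = "auto"  # auto | on | off
    ssgl_samples: int = 1000
    ssgl_alpha: float = 0.05
    ssgl_seed: int = 0

    def __post_init__(self) -> None:
        if self.glyco_type not in ("N", "O"):
            raise ConfigError(f"glyco_type must be N or O, got {self.glyco_type!r}")
        if self.activation_mode not in ("auto", "HCD", "HCD+ETxxD"):
            raise ConfigError(f"bad activation_mode {self.activation_mode!r}")
        if self.run_localization not in ("auto", "on", "off"):
            raise ConfigError(f"bad run_localization {self.run_localization!r}")

    @property
    def sites(self) -> str:
        if self.glycosylation_sites:
            return self.glycosylation_sites
        return "J" if self.glyco_type == "N" else "ST"

    @property
    def core_count_min(self) -> int:
        return self.core_count_N if self.glyco_type == "N" else self.core_count_O

    def diagnostic_ion_list(self) -> list[float]:
        return [float(x) for x in self.diagnostic_ions.split(",") if x.strip()]

    def mono_diagnostic_table(self) -> dict[str, tuple[float, ...]]:
        table: dict[str, tuple[float, ...]] = {}
        for block in self.mono_diagnostic_ions.split(";"):
            block = block.strip()
            if not block:
                continue
            sym, ions = block.split(":")
            table[sym] = tuple(float(x) for x in ions.split("|"))
        return table


_FIELDS = {f.name: f for f in fields(SearchConfig)}


def parse_config(path: str | Path) -> SearchConfig:
    """Parse a ``key=value`` file (# comments); unknown keys and bad types
    are errors naming the offending line."""
    values: dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected key=value, got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        f = _FIELDS.get(key)
        if f is None:
            raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
        try:
            if f.type in ("int", int):
                values[key] = int(value)
            elif f.type in ("float", float):
                values[key] = float(value)
            else:
                values[key] = value
        except ValueError:
            raise ConfigError(
                f"{path}:{lineno}: cannot parse {value!r} for key {key!r}"
            ) from None
    try:
        return SearchConfig(**values)
    except ConfigError as exc:
        raise ConfigError(f"{path}: {exc}") from None
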
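import numpy as np
import pytest

from glycofirst.glycan import GlycanDB, O_GLYCAN_CORE, parse_composition, parse_structure
from glycofirst.peptide import PeptideEntry, peptide_mass
from glycofirst.spectra import Spectrum


def neutral_spectrum(masses, intensities=None, precursor_neutral=None, scan_id=1,
                     activation="merged"):
    """A preprocessed spectrum given directly as neutral masses."""
    masses = np.asarray(masses, dtype=float)
    if intensities is None:
        intensities = np.full(len(masses), 100.0)
    if precursor_neutral is None:
        precursor_neutral = (masses.max() if len(masses) else 1000.0) + 500.0
    from glycofirst.chem import PROTON

    return Spectrum(
        scan_id=scan_id,
        precursor_mz=precursor_neutral + PROTON,
        precursor_charge=1,
        masses=masses,
        intensities=np.asarray(intensities, dtype=float),
        activation=activation,
        is_preprocessed=True,
    )


@pytest.fixture
def linear_h2_db():
    """Single linear H-H glycan as a structure, O-mode core (Y0 only)."""
    return GlycanDB.from_entries(["(H(H))"], glyco_type="O")


@pytest.fixture
def trimannosyl():
    return parse_structure("(N(N(H(H)(H))))")


def make_peptide(sequence, mods=()):
    return PeptideEntry(sequence, tuple(mods), peptide_mass(sequence, mods), ("TEST",))
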
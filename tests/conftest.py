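import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from hdxkit.envelopes import (
    Peptide,
    natural_isotope_envelope,
    peptide_composition,
)


@pytest.fixture(scope="session")
def myoglobin_peptide() -> Peptide:
    """A realistic tryptic-sized peptide (19 exchangeable amides)."""
    return Peptide.from_sequence("mb1", "GLSDGEWQLVLNVWGKVEAD", 1)


@pytest.fixture(scope="session")
def natural_mb(myoglobin_peptide):
    return natural_isotope_envelope(peptide_composition(myoglobin_peptide.sequence))


@pytest.fixture(scope="session")
def paper_times_s() -> np.ndarray:
    """The five labeling exposures in seconds: 15 s, 1, 10, 60, 480 min."""
    return np.array([15.0, 60.0, 600.0, 3600.0, 28800.0])
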
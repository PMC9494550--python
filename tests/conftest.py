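import numpy as np
import pytest

from pbsneutron.response import ConversionTable
from pbsneutron.spectra import EnergyGrid, NeutronSpectrum, build_lethargy_grid


@pytest.fixture
def flat_conversion():
    """Conversion table with h* = 400 pSv cm^2 everywhere (easy arithmetic)."""
    e = np.logspace(-9, np.log10(300.0), 40)
    return ConversionTable(energies=e, coefficients=np.full_like(e, 400.0))


@pytest.fixture
def small_grid():
    return build_lethargy_grid(1e-9, 240.0, 0.26)


def make_spectrum(grid: EnergyGrid, pairs, label="fixture") -> NeutronSpectrum:
    """Spectrum with fluence placed in the bins containing the given energies."""
    fl = np.zeros(grid.n_bins)
    for energy, fluence in pairs:
        idx = int(np.searchsorted(grid.edges, energy, side="right")) - 1
        fl[idx] += fluence
    return NeutronSpectrum(grid, fl, label)
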
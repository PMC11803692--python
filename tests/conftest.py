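"""Shared fixtures: expensive forward simulations are session-scoped."""

from __future__ import annotations

import numpy as np
import pytest

from elastomap.phantom import homogeneous_phantom
from elastomap.recon import reconstruct_elastogram
from elastomap.wavesim import encode_wave_phases, solve_heterogeneous_helmholtz


@pytest.fixture(scope="session")
def fd_recon_elastic():
    """FD forward solve + full reconstruction, homogeneous 5 kPa elastic."""
    phantom = homogeneous_phantom(5000.0, 0.0)
    field = solve_heterogeneous_helmholtz(phantom)
    acq = encode_wave_phases(field, scale=3.5 / np.abs(field.displacement).max())
    elast = reconstruct_elastogram(acq)
    return phantom, field, elast


@pytest.fixture(scope="session")
def fd_recon_viscoelastic():
    """Same chain for the 5 + 2i kPa viscoelastic phantom."""
    phantom = homogeneous_phantom(5000.0, 2000.0)
    field = solve_heterogeneous_helmholtz(phantom)
    acq = encode_wave_phases(field, scale=3.5 / np.abs(field.displacement).max())
    elast = reconstruct_elastogram(acq)
    return phantom, field, elast
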
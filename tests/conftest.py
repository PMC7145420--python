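"""Shared fixtures: distance model, coarse Ca2+ fields, toy transients.

Expensive session-scoped fixtures (PDE fields, numba compilation) are shared
across test modules; per-test randomness is always explicitly seeded.
"""

import numpy as np
import pytest

from synapstp.calcium import CalciumField, FieldParams, simulate_field
from synapstp.geometry import SIGMA_DEFAULT, DistanceModel


@pytest.fixture(scope="session")
def distance_model() -> DistanceModel:
    return DistanceModel(SIGMA_DEFAULT)


@pytest.fixture(scope="session")
def coarse_field_params() -> FieldParams:
    """Reduced-resolution grid for quick end-to-end runs."""
    return FieldParams(n_r=36, n_z=51)


@pytest.fixture(scope="session")
def field_single_15(coarse_field_params) -> CalciumField:
    """Coarse-grid field for the single-sensor best fit at 1.5 mM."""
    from dataclasses import replace

    params = replace(coarse_field_params, q_max=8.42)
    return simulate_field(params, 1.5, 22.0)


def make_toy_field(basal: float = 0.05, amp: float = 20.0,
                   decay_um: float = 0.10, t_end: float = 22.0,
                   peaks=(2.0, 12.0), sigma_ms: float = 0.25) -> CalciumField:
    """Analytic stand-in transient: Gaussian pulses decaying with distance.

    Synthetic in every respect — used where tests need a Ca2+ input with a
    controlled shape rather than a PDE solution.
    """
    times = np.arange(0.0, t_end + 0.01, 0.01)
    r = np.linspace(0.0, 0.62399, 40)
    profile = np.exp(-r / decay_um)
    readout = np.full((len(times), len(r)), basal)
    for tp in peaks:
        readout += amp * np.exp(-((times - tp) ** 2) / (2 * sigma_ms**2))[:, None] * profile[None, :]
    return CalciumField(times=times, r=r, readout=readout, basal=basal,
                        ca_ext=np.nan, params=None)


@pytest.fixture(scope="session")
def toy_field() -> CalciumField:
    return make_toy_field()
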
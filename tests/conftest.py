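"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")

from sonodry import (  # noqa: E402
    AirState,
    ArrheniusParams,
    GABParams,
    MaterialSpec,
    ShrinkageLaw,
    simulate_drying,
)
from sonodry.config import (  # noqa: E402
    default_config,
    material_from_config,
    numerics_from_config,
    scenario_from_config,
)
from sonodry.published import MODES  # noqa: E402


def exact_sphere_mr(t, D, r, terms=50):
    """Exact moisture-ratio series for diffusion out of a sphere whose surface
    is held at the equilibrium moisture: MR = (6/pi^2) sum exp(-n^2 pi^2 Fo)/n^2.

    Independent analytic oracle for the PDE solver and the slope method.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n = np.arange(1, terms + 1)[:, None]
    mr = 6.0 / np.pi**2 * np.sum(
        np.exp(-(n**2) * np.pi**2 * D * t[None, :] / r**2) / n**2, axis=0
    )
    return np.minimum(mr, 1.0)


@pytest.fixture(scope="session")
def default_gab():
    return GABParams(W_m=0.10, C=10.0, K=0.85)


@pytest.fixture(scope="session")
def hot_air():
    return AirState(T_air=338.15, RH=10.0)


@pytest.fixture(scope="session")
def isothermal_material(default_gab):
    """Constant-diffusivity, non-shrinking sphere starting at air temperature."""
    return MaterialSpec(
        M0=3.5e-3,
        f_dm=0.138,
        r0=0.0125,
        T0=338.15,
        gab=default_gab,
        arrhenius=ArrheniusParams(D0=1e-9, b=0.0),
        shrinkage=ShrinkageLaw(slope=0.0),
    )


@pytest.fixture(scope="session")
def mode_results():
    """The three default-condition drying runs (air-only, airborne, contact),
    each stopped shortly after the 1.0 kg/kg DM target is crossed."""
    cfg = default_config()
    out = {}
    for mode in MODES:
        spec = material_from_config(cfg, mode)
        scenario = scenario_from_config(cfg, mode)
        out[mode] = simulate_drying(
            spec, scenario, numerics_from_config(cfg), stop_when_below=0.95
        )
    return out
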
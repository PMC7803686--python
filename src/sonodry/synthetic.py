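"""Seeded synthetic versions of the four experimental input datasets.

Each generator draws from the statistical model its estimator assumes —
exponential decay plus noise for drying kinetics and sphere cooling, a linear
temperature rise for calorimetry, GAB-shaped points for sorption — so every
estimator can be exercised in a closed loop without any laboratory data.
Noise magnitudes are plausibility defaults (no measured noise levels exist
for these experiments) and are always applied through a seeded generator:
identical seeds give identical series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .estimation import (
    CalorimetrySeries,
    CoolingSeries,
    CopperSphere,
    KineticsSeries,
    SorptionTable,
)
from .properties import GABParams, MaterialSpec, arrhenius_diffusivity, gab_moisture
from .simulator import DryingScenario, NumericsConfig, simulate_drying

__all__ = [
    "NoiseSpec",
    "DEFAULT_AW_GRID",
    "generate_drying_kinetics",
    "generate_copper_cooling",
    "generate_calorimetry",
    "generate_sorption_points",
]

#: nominal water activities of seven saturated salt solutions
#: (LiCl ... KCl) near 65 degC; synthetic stand-ins, the study prints none
DEFAULT_AW_GRID = (0.11, 0.22, 0.33, 0.43, 0.69, 0.75, 0.84)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: kind, magnitude and seed.

    ``sigma`` is absolute (units of the target variable) for
    ``gaussian_additive`` and relative for ``gaussian_multiplicative``.
    """

    kind: str = "gaussian_additive"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian_additive", "gaussian_multiplicative"):
            raise DomainError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise DomainError(f"sigma must be non-negative, got {self.sigma}")

    def apply(self, values: np.ndarray) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        eps = rng.standard_normal(values.shape)
        if self.kind == "gaussian_additive":
            return values + self.sigma * eps
        return values * (1.0 + self.sigma * eps)


def _one_term_moisture(t, w0, w_eq, De, r):
    """Dry-basis moisture from the one-term sphere-diffusion series.

    The truncation is only valid away from t = 0 (its moisture ratio there is
    6/pi^2, not 1), so the fresh sample is anchored at W0 explicitly, as a
    balance measurement would be.
    """
    mr = np.minimum(1.0, 6.0 / np.pi**2 * np.exp(-De * np.pi**2 * t / r**2))
    w = w_eq + (w0 - w_eq) * mr
    w[t == 0] = w0
    return w


def generate_drying_kinetics(
    spec: MaterialSpec,
    scenario: DryingScenario,
    sampling,
    noise: NoiseSpec,
    generator: str = "one_term",
) -> KineticsSeries:
    """Drying-kinetics series at the scenario's air temperature.

    ``generator="one_term"`` evaluates the one-term analytic sphere solution
    with D_e from the material's Arrhenius law at T_air (the model the slope
    method inverts); ``"full_model"`` runs the coupled simulator and samples
    its volume-average moisture at exactly the requested times.  Noise is
    applied afterwards and the series floored at the equilibrium moisture.
    """
    t = np.asarray(sampling, dtype=float)
    w_eq = gab_moisture(scenario.air.RH / 100.0, spec.gab)
    if generator == "one_term":
        De = arrhenius_diffusivity(scenario.air.T_air, spec.arrhenius)
        w = _one_term_moisture(t, spec.W0, w_eq, De, spec.r0)
    elif generator == "full_model":
        numerics = NumericsConfig(output_times=t[t > 0])
        result = simulate_drying(spec, scenario, numerics)
        w = np.interp(t, result.times, result.w_avg)
    else:
        raise DomainError(f"unknown generator {generator!r}")
    w = np.maximum(noise.apply(w), w_eq)
    return KineticsSeries(
        time=t, moisture=w, temperature_label=scenario.air.T_air, mode=scenario.mode
    )


def generate_copper_cooling(
    h_true: float,
    sphere: CopperSphere,
    T0: float,
    T_air: float,
    sampling,
    noise: NoiseSpec,
) -> CoolingSeries:
    """Copper-sphere temperature response under a known h (lumped model)."""
    if T0 == T_air:
        raise DomainError("T0 must differ from T_air to produce a response")
    t = np.asarray(sampling, dtype=float)
    k = h_true * 3.0 / (sphere.rho * sphere.Cp * sphere.radius)
    T = T_air + (T0 - T_air) * np.exp(-k * t)
    return CoolingSeries(time=t, T_surface=noise.apply(T), sphere=sphere)


def generate_calorimetry(
    P_true: float,
    sphere: CopperSphere,
    T0: float,
    sampling,
    noise: NoiseSpec,
) -> CalorimetrySeries:
    """Insulated-sphere heating under a known absorbed acoustic power."""
    if P_true < 0:
        raise DomainError(f"P_true must be non-negative, got {P_true}")
    t = np.asarray(sampling, dtype=float)
    T = T0 + P_true / (sphere.mass * sphere.Cp) * t
    return CalorimetrySeries(time=t, temperature=noise.apply(T))


def generate_sorption_points(
    params: GABParams,
    a_w_grid=DEFAULT_AW_GRID,
    noise: NoiseSpec = NoiseSpec(),
) -> SorptionTable:
    """Equilibrium (a_w, W_eq) points on a salt-solution water-activity grid."""
    aw = np.asarray(a_w_grid, dtype=float)
    if np.any(aw <= 0) or np.any(aw >= 1):
        raise DomainError("water-activity grid must lie strictly inside (0, 1)")
    w = gab_moisture(aw, params)
    w = np.maximum(noise.apply(w), 1e-9)
    return SorptionTable(a_w=aw, w_eq=w)
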
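"""Thermophysical correlations, sorption isotherm and geometry of a drying berry.

Everything here is a pure, stateless function of its arguments, in SI units
(K, s, m, kg, J).  Moisture content ``W`` is always dry-basis
(kg water per kg dry matter); water activity ``a_w`` is a fraction of
saturation.  These primitives are consumed by the estimators and by the
coupled heat/mass simulator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DomainError

logger = logging.getLogger(__name__)

__all__ = [
    "GAS_CONSTANT_KJ_PER_MOL_K",
    "GABParams",
    "ArrheniusParams",
    "ShrinkageLaw",
    "MaterialSpec",
    "AirState",
    "saturation_vapor_pressure",
    "specific_heat",
    "latent_heat",
    "thermal_conductivity",
    "gab_moisture",
    "gab_water_activity",
    "vapor_concentration_surface",
    "vapor_concentration_air",
    "solid_density",
    "bulk_density",
    "radius_from_moisture",
    "arrhenius_diffusivity",
]

GAS_CONSTANT_KJ_PER_MOL_K = 8.314e-3
"""Universal gas constant, kJ mol^-1 K^-1 (used for activation energies)."""

#: clamp ceiling for water activity; keeps the GAB denominator away from its pole
AW_CEILING = 0.9999

_PVS_T_MIN = 273.15
_PVS_T_MAX = 473.15
_T_CRITICAL = 647.3


def _as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _scalar_like(value: np.ndarray, template):
    """Return a python float when the input was scalar, else the array."""
    if np.ndim(template) == 0:
        return float(value)
    return value


# ---------------------------------------------------------------------------
# moist-air / water correlations
# ---------------------------------------------------------------------------

def _pvs_unchecked(T):
    T = _as_float_array(T)
    return np.exp(
        -5.8e3 / T
        + 1.391
        - 4.864e-2 * T
        + 4.176e-5 * T**2
        - 1.445e-8 * T**3
        + 6.545 * np.log(T)
    )


def saturation_vapor_pressure(T):
    """Saturation pressure of water vapour, Pa.

    Standard polynomial-logarithmic correlation for the vapour pressure over
    liquid water, valid on [273.15, 473.15] K.  Reproduces the normal boiling
    point (~101.3 kPa at 373.15 K) to better than 1%.
    """
    arr = _as_float_array(T)
    if np.any(arr < _PVS_T_MIN) or np.any(arr > _PVS_T_MAX):
        raise DomainError(
            f"temperature must lie in [{_PVS_T_MIN}, {_PVS_T_MAX}] K, got {T!r}"
        )
    return _scalar_like(_pvs_unchecked(arr), T)


def specific_heat(W):
    """Specific heat of the fruit, J kg^-1 K^-1, linear in dry-basis moisture."""
    arr = _as_float_array(W)
    if np.any(arr < 0):
        raise DomainError(f"moisture content must be non-negative, got {W!r}")
    return _scalar_like((0.837 + 1.256 * arr) * 1000.0, W)


def _latent_heat_unchecked(T):
    T = _as_float_array(T)
    return 2501.05e3 * ((_T_CRITICAL - T) / (_T_CRITICAL - 273.15)) ** 0.3298


def latent_heat(T):
    """Latent heat of water evaporation, J/kg; vanishes at the critical point."""
    arr = _as_float_array(T)
    if np.any(arr >= _T_CRITICAL):
        raise DomainError(
            f"temperature must stay below the critical point {_T_CRITICAL} K, got {T!r}"
        )
    return _scalar_like(_latent_heat_unchecked(arr), T)


def thermal_conductivity(W):
    """Thermal conductivity of the fruit, W m^-1 K^-1.

    Interpolates between the dry-matter value 0.149 (W = 0) and the
    water-dominated asymptote 0.493 as moisture grows.
    """
    arr = _as_float_array(W)
    if np.any(arr < 0):
        raise DomainError(f"moisture content must be non-negative, got {W!r}")
    return _scalar_like((0.149 + 0.493 * arr) / (1.0 + arr), W)


# ---------------------------------------------------------------------------
# sorption isotherm (GAB)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GABParams:
    """Three-parameter GAB sorption isotherm.

    W_m is the monolayer moisture (kg/kg DM), C the energy constant and K the
    multilayer correction constant.  K must stay below 1/a_w over the working
    range of water activity so the isotherm denominator stays positive.
    """

    W_m: float
    C: float
    K: float

    def __post_init__(self):
        if not self.W_m > 0:
            raise DomainError(f"W_m must be positive, got {self.W_m}")
        if not self.C > 0:
            raise DomainError(f"C must be positive, got {self.C}")
        if not 0 < self.K <= 1.0:
            raise DomainError(f"K must lie in (0, 1], got {self.K}")


def gab_moisture(a_w, params: GABParams):
    """Equilibrium dry-basis moisture at water activity ``a_w`` (GAB model)."""
    arr = _as_float_array(a_w)
    if np.any(arr < 0) or np.any(arr * params.K >= 1.0):
        raise DomainError(
            f"water activity must lie in [0, 1/K) = [0, {1.0 / params.K:.4f}), got {a_w!r}"
        )
    u = params.K * arr
    w = params.W_m * params.C * u / ((1.0 - u) * (1.0 - u + params.C * u))
    return _scalar_like(w, a_w)


def _gab_activity_core(W: np.ndarray, params: GABParams) -> np.ndarray:
    """Analytic inverse of the GAB isotherm, clamped to [0, AW_CEILING].

    The isotherm is quadratic in u = K*a_w:
        W(C-1) u^2 + [W_m C - W(C-2)] u - W = 0
    and the physical branch is the root continuous with u -> 0 as W -> 0.
    """
    Wm, C, K = params.W_m, params.C, params.K
    W = np.asarray(W, dtype=float)
    b = Wm * C - W * (C - 2.0)
    if abs(C - 1.0) < 1e-12:
        u = W / (Wm + W)
    else:
        a = W * (C - 1.0)
        disc = b * b + 4.0 * a * W
        with np.errstate(divide="ignore", invalid="ignore"):
            root = (-b + np.sqrt(disc)) / (2.0 * a)
        u = np.where(W > 0, root, 0.0)
    return np.clip(u / K, 0.0, AW_CEILING)


def gab_water_activity(W, params: GABParams):
    """Water activity in equilibrium with dry-basis moisture ``W`` (inverse GAB).

    Moistures above the isotherm's range (free water, e.g. fresh fruit) have no
    root in [0, 1); those are clamped to AW_CEILING with a logged warning.
    """
    arr = _as_float_array(W)
    if np.any(arr < 0):
        raise DomainError(f"moisture content must be non-negative, got {W!r}")
    aw = _gab_activity_core(arr, params)
    if np.any(aw >= AW_CEILING):
        logger.warning(
            "GAB inversion clamped: moisture above the isotherm range, "
            "returning a_w = %s", AW_CEILING,
        )
    return _scalar_like(aw, W)


# ---------------------------------------------------------------------------
# vapour concentrations (ideal-gas)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AirState:
    """Bulk drying-air conditions and transport properties.

    RH is in percent (0-100).  The default density, specific heat, thermal
    diffusivity and vapour diffusivity are the hot-air values used with the
    Chilton-Colburn analogy at 65 degC.
    """

    T_air: float
    RH: float
    rho_air: float = 1.029
    Cp_air: float = 1.0e3
    alpha_air: float = 2.5e-5
    D_air: float = 2.18e-5

    def __post_init__(self):
        if not 0 <= self.RH <= 100:
            raise DomainError(f"RH must lie in [0, 100] %, got {self.RH}")
        for name in ("T_air", "rho_air", "Cp_air", "alpha_air", "D_air"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")


def vapor_concentration_surface(T_s, a_w):
    """Water-vapour concentration at the sample surface, kg m^-3 (ideal gas)."""
    arr = _as_float_array(a_w)
    if np.any(arr < 0) or np.any(arr > 1):
        raise DomainError(f"water activity must lie in [0, 1], got {a_w!r}")
    Tarr = _as_float_array(T_s)
    if np.any(Tarr < _PVS_T_MIN) or np.any(Tarr > _PVS_T_MAX):
        raise DomainError(
            f"temperature must lie in [{_PVS_T_MIN}, {_PVS_T_MAX}] K, got {T_s!r}"
        )
    val = 2.1667e-3 * arr * _pvs_unchecked(Tarr) / Tarr
    if np.ndim(T_s) == 0 and np.ndim(a_w) == 0:
        return float(val)
    return val


def vapor_concentration_air(air: AirState) -> float:
    """Water-vapour concentration in the bulk drying air, kg m^-3."""
    return 2.1667e-3 * (air.RH / 100.0) * saturation_vapor_pressure(air.T_air) / air.T_air


# ---------------------------------------------------------------------------
# densities and shrinkage geometry
# ---------------------------------------------------------------------------

def solid_density(M0, f_dm, r):
    """Dry-solid density, kg m^-3: the (fixed) dry mass over the current volume."""
    arr = _as_float_array(r)
    if np.any(arr <= 0):
        raise DomainError(f"radius must be positive, got {r!r}")
    return _scalar_like(M0 * f_dm / (4.0 / 3.0 * np.pi * arr**3), r)


def bulk_density(W, M0, f_dm, r):
    """Bulk density, kg m^-3: water plus dry mass over the current volume."""
    arrw = _as_float_array(W)
    if np.any(arrw < 0):
        raise DomainError(f"moisture content must be non-negative, got {W!r}")
    val = (arrw + 1.0) * solid_density(M0, f_dm, r)
    if np.ndim(W) == 0 and np.ndim(r) == 0:
        return float(val)
    return val


@dataclass(frozen=True)
class ShrinkageLaw:
    """Linear shrinkage: radius ratio = intercept + slope * (W/W0).

    A fresh sample (moisture ratio 1) must have radius ratio 1, so the
    intercept is pinned at 1 - slope; passing it explicitly is allowed but
    validated.  Slopes differ by drying mode: stronger sonication preserves
    more of the fresh volume (smaller slope).
    """

    slope: float
    intercept: float | None = None

    def __post_init__(self):
        if self.intercept is None:
            object.__setattr__(self, "intercept", 1.0 - self.slope)
        if abs(self.intercept + self.slope - 1.0) > 1e-9:
            raise DomainError(
                f"radius ratio at moisture ratio 1 must be 1: "
                f"intercept {self.intercept} + slope {self.slope} != 1"
            )
        if self.intercept <= 0:
            raise DomainError(
                f"radius ratio must stay positive on [0, 1]; intercept = {self.intercept}"
            )

    def radius_ratio(self, moisture_ratio):
        return self.intercept + self.slope * _as_float_array(moisture_ratio)


# ---------------------------------------------------------------------------
# Arrhenius diffusivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrheniusParams:
    """Arrhenius law for the effective moisture diffusivity.

    D_e(T) = D0 * exp(-b / T) with D0 in m^2 s^-1 and b = Ea / R_g in K.
    """

    D0: float
    b: float

    def __post_init__(self):
        if not self.D0 > 0:
            raise DomainError(f"D0 must be positive, got {self.D0}")

    @property
    def Ea(self) -> float:
        """Activation energy, kJ mol^-1."""
        return self.b * GAS_CONSTANT_KJ_PER_MOL_K

    @classmethod
    def from_activation_energy(cls, D0: float, Ea: float) -> "ArrheniusParams":
        """Build from D0 (m^2 s^-1) and an activation energy in kJ mol^-1."""
        return cls(D0=D0, b=Ea / GAS_CONSTANT_KJ_PER_MOL_K)

    @classmethod
    def from_per_minute(cls, D0_per_min: float, b: float) -> "ArrheniusParams":
        """Build from a pre-exponential factor printed in m^2 min^-1."""
        return cls(D0=D0_per_min / 60.0, b=b)


def arrhenius_diffusivity(T, params: ArrheniusParams):
    """Effective moisture diffusivity D_e(T), m^2 s^-1."""
    arr = _as_float_array(T)
    if np.any(arr <= 0):
        raise DomainError(f"absolute temperature must be positive, got {T!r}")
    return _scalar_like(params.D0 * np.exp(-params.b / arr), T)


# ---------------------------------------------------------------------------
# material specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaterialSpec:
    """All intrinsic parameters of the fruit being dried.

    M0 is the fresh mass (kg), f_dm the dry-mass fraction, r0 the fresh radius
    (m) and T0 the initial temperature (K).  The initial dry-basis moisture is
    derived: W0 = (1 - f_dm) / f_dm.
    """

    M0: float
    f_dm: float
    r0: float
    gab: GABParams
    arrhenius: ArrheniusParams
    shrinkage: ShrinkageLaw
    T0: float = 298.15

    def __post_init__(self):
        if not 0 < self.f_dm < 1:
            raise DomainError(f"f_dm must lie in (0, 1), got {self.f_dm}")
        for name in ("M0", "r0", "T0"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def W0(self) -> float:
        """Initial dry-basis moisture content, kg water / kg DM."""
        return (1.0 - self.f_dm) / self.f_dm


def radius_from_moisture(W_avg, spec: MaterialSpec):
    """Current radius (m) from the volume-average moisture via the shrinkage law."""
    arr = _as_float_array(W_avg)
    if np.any(arr < 0) or np.any(arr > spec.W0 * (1.0 + 1e-12)):
        raise DomainError(
            f"average moisture must lie in [0, W0 = {spec.W0:.4f}], got {W_avg!r}"
        )
    return _scalar_like(spec.r0 * spec.shrinkage.radius_ratio(arr / spec.W0), W_avg)
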
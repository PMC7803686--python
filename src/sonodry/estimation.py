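"""Parameter estimation from drying, cooling, calorimetry and sorption series.

Each estimator inverts the generating model that the corresponding experiment
assumes:

* :func:`fit_gab` — nonlinear least squares of the GAB isotherm on
  (a_w, W_eq) equilibration points;
* :func:`estimate_de_slope` — the slope method: the one-term truncation of the
  exact sphere-diffusion series is a straight line in ln(moisture ratio) vs
  time, whose slope is -D_e pi^2 / r^2;
* :func:`fit_arrhenius` — linear regression of ln D_e against 1/T;
* :func:`fit_h_lumped` — lumped-capacitance fit of a copper sphere's cooling
  (or heating) curve, valid because the sphere's Biot number is small;
* :func:`hm_from_h` — Chilton-Colburn analogy through the Lewis number of the
  drying air;
* :func:`calorimetric_power` — ultrasound power from the initial linear
  temperature-rise rate of an insulated copper sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .errors import DomainError, EstimationError
from .properties import AirState, ArrheniusParams, GABParams, gab_moisture
from .reporting import FitMetrics, fit_metrics

__all__ = [
    "ArrheniusParams",
    "CopperSphere",
    "KineticsSeries",
    "CoolingSeries",
    "CalorimetrySeries",
    "SorptionTable",
    "FitReport",
    "fit_gab",
    "estimate_de_slope",
    "fit_arrhenius",
    "fit_h_lumped",
    "hm_from_h",
    "calorimetric_power",
    "ultrasound_intensity",
]


# ---------------------------------------------------------------------------
# input series containers
# ---------------------------------------------------------------------------

def _validated_time(time) -> np.ndarray:
    t = np.asarray(time, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise DomainError("time must be a 1-D array with at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise DomainError("time must be strictly increasing")
    return t


@dataclass(frozen=True)
class CopperSphere:
    """Copper reference sphere used for h estimation and calorimetry."""

    diameter: float = 0.025
    rho: float = 8.96e3
    Cp: float = 390.0

    def __post_init__(self):
        for name in ("diameter", "rho", "Cp"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be positive, got {getattr(self, name)}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius**3

    @property
    def area(self) -> float:
        return 4.0 * np.pi * self.radius**2

    @property
    def mass(self) -> float:
        return self.rho * self.volume


@dataclass(frozen=True)
class KineticsSeries:
    """Drying kinetics: dry-basis moisture vs time at one air temperature."""

    time: np.ndarray
    moisture: np.ndarray
    temperature_label: float
    mode: str = "none"

    def __post_init__(self):
        t = _validated_time(self.time)
        w = np.asarray(self.moisture, dtype=float)
        if w.shape != t.shape:
            raise DomainError("time and moisture must have the same length")
        if np.any(w < 0):
            raise DomainError("moisture must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "moisture", w)


@dataclass(frozen=True)
class CoolingSeries:
    """Surface-temperature response of the copper sphere in the dryer."""

    time: np.ndarray
    T_surface: np.ndarray
    sphere: CopperSphere = field(default_factory=CopperSphere)

    def __post_init__(self):
        t = _validated_time(self.time)
        T = np.asarray(self.T_surface, dtype=float)
        if T.shape != t.shape:
            raise DomainError("time and T_surface must have the same length")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "T_surface", T)


@dataclass(frozen=True)
class CalorimetrySeries:
    """Temperature rise of the insulated copper sphere under sonication."""

    time: np.ndarray
    temperature: np.ndarray

    def __post_init__(self):
        t = _validated_time(self.time)
        T = np.asarray(self.temperature, dtype=float)
        if T.shape != t.shape:
            raise DomainError("time and temperature must have the same length")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "temperature", T)


@dataclass(frozen=True)
class SorptionTable:
    """(water activity, equilibrium moisture) pairs from static-gravimetric
    equilibration over saturated salt solutions."""

    a_w: np.ndarray
    w_eq: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a_w, dtype=float)
        w = np.asarray(self.w_eq, dtype=float)
        if a.shape != w.shape or a.ndim != 1:
            raise DomainError("a_w and w_eq must be 1-D arrays of equal length")
        if np.any(a <= 0) or np.any(a >= 1):
            raise DomainError("water activities must lie strictly inside (0, 1)")
        if np.any(w < 0):
            raise DomainError("equilibrium moistures must be non-negative")
        object.__setattr__(self, "a_w", a)
        object.__setattr__(self, "w_eq", w)

    def __len__(self) -> int:
        return self.a_w.size


@dataclass(frozen=True)
class FitReport:
    """An estimated parameter set with its goodness-of-fit metrics."""

    params: object
    r_squared: float
    rmse: float
    aad_percent: float

    @classmethod
    def from_metrics(cls, params, metrics: FitMetrics) -> "FitReport":
        return cls(params, metrics.r_squared, metrics.rmse, metrics.aad_percent)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

#: deterministic multi-start grid for the GAB fit (W_m, C, K)
GAB_START_GRID: tuple[tuple[float, float, float], ...] = tuple(
    (wm, c, k)
    for wm in (0.05, 0.1, 0.2)
    for c in (1.0, 10.0, 50.0)
    for k in (0.5, 0.7, 0.9)
)


def fit_gab(
    table: SorptionTable,
    start_grid: Sequence[tuple[float, float, float]] = GAB_START_GRID,
) -> tuple[GABParams, FitReport]:
    """Nonlinear least-squares fit of the GAB isotherm to a sorption table.

    Runs a local trust-region fit from every point of a fixed start grid and
    keeps the lowest final residual (ties broken by grid order), which makes
    the result deterministic.  Requires at least 5 points for the 3-parameter
    model.
    """
    if len(table) < 5:
        raise EstimationError(
            f"need at least 5 sorption points for a 3-parameter fit, got {len(table)}"
        )
    aw, w = table.a_w, table.w_eq
    k_max = min(1.0, (1.0 - 1e-9) / aw.max()) - 1e-9
    lower = np.array([1e-9, 1e-9, 1e-9])
    upper = np.array([10.0, 1e4, k_max])

    def residuals(theta):
        wm, c, k = theta
        u = k * aw
        return wm * c * u / ((1.0 - u) * (1.0 - u + c * u)) - w

    best = None
    best_start = None
    for p0 in start_grid:
        x0 = np.clip(p0, lower, upper)
        try:
            res = least_squares(residuals, x0, bounds=(lower, upper), method="trf")
        except Exception:  # singular start; try the next grid point
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        if best is None or res.cost < best.cost:
            best, best_start = res, p0
    if best is None:
        raise EstimationError(
            f"GAB fit did not converge from any start of the grid {list(start_grid)}"
        )
    params = GABParams(W_m=float(best.x[0]), C=float(best.x[1]), K=float(best.x[2]))
    metrics = fit_metrics(gab_moisture(aw, params), w)
    report = FitReport.from_metrics(params, metrics)
    return params, report


def estimate_de_slope(
    series: KineticsSeries,
    r: float,
    w_eq: float | None = None,
    mr_threshold: float = 0.6,
) -> float:
    """Effective diffusivity (m^2 s^-1) by the slope method.

    Fits an ordinary least-squares line to ln[(W - W_eq)/(W0 - W_eq)] vs time
    over the points with t > 0 and moisture ratio below ``mr_threshold``
    (where the one-term series truncation dominates) and converts the slope:
    D_e = -slope * r^2 / pi^2.  W_eq defaults to the mean of the last three
    samples of the series.
    """
    t, w = series.time, series.moisture
    if w_eq is None:
        w_eq = float(w[-3:].mean())
    w0 = float(w[0])
    span = w0 - w_eq
    if span <= 1e-12:
        raise EstimationError(
            "series shows no moisture decay (W0 equals the equilibrium tail)"
        )
    mr = (w - w_eq) / span
    mask = (t > 0) & (mr < mr_threshold)
    if mask.sum() < 2:
        raise EstimationError(
            f"fewer than 2 points with moisture ratio below {mr_threshold}; "
            "series too short for the slope method"
        )
    if np.any(mr[mask] <= 0):
        raise EstimationError(
            "nonpositive moisture ratio among retained points; "
            "equilibrium subtraction too aggressive"
        )
    slope = float(np.polyfit(t[mask], np.log(mr[mask]), 1)[0])
    if slope >= 0:
        raise EstimationError("no moisture decay detected (nonnegative slope)")
    return -slope * r**2 / np.pi**2


def fit_arrhenius(pairs: Sequence[tuple[float, float]]) -> ArrheniusParams:
    """Arrhenius parameters from (T, D_e) pairs by regressing ln D_e on 1/T."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise EstimationError("need at least two (T, D_e) pairs")
    T, D = arr[:, 0], arr[:, 1]
    if np.any(T <= 0) or np.any(D <= 0):
        raise DomainError("temperatures and diffusivities must be positive")
    if np.unique(T).size < 2:
        raise EstimationError("duplicate temperatures: the regression is rank-deficient")
    slope, intercept = np.polyfit(1.0 / T, np.log(D), 1)
    return ArrheniusParams(D0=float(np.exp(intercept)), b=float(-slope))


def fit_h_lumped(
    series: CoolingSeries,
    T_air: float,
    T0: float | None = None,
) -> tuple[float, FitReport]:
    """Heat transfer coefficient (W m^-2 K^-1) from a copper-sphere response.

    Fits T(t) = T_air + (T0 - T_air) exp(-h A t / (rho Cp V)) by nonlinear
    least squares; for a sphere A/V = 3/radius.  Valid under the
    lumped-capacitance assumption of a negligible internal temperature
    gradient.
    """
    sphere = series.sphere
    t, T = series.time, series.T_surface
    if t.size < 5:
        raise EstimationError(f"need at least 5 cooling points, got {t.size}")
    if T0 is None:
        T0 = float(T[0])
    if abs(T0 - T_air) <= 1.0:
        raise EstimationError(
            f"|T0 - T_air| = {abs(T0 - T_air):.3f} K is too small to resolve h"
        )
    scale = 3.0 / (sphere.rho * sphere.Cp * sphere.radius)  # A/(rho Cp V)

    def model(tt, h):
        return T_air + (T0 - T_air) * np.exp(-h * scale * tt)

    # initial guess from the log-linear decay of the positive excess temperatures
    theta = (T - T_air) / (T0 - T_air)
    ok = (theta > 1e-6) & (t > 0)
    if ok.sum() >= 2:
        k0 = -float(np.polyfit(t[ok], np.log(theta[ok]), 1)[0])
        h0 = max(k0 / scale, 1e-3)
    else:
        h0 = 20.0
    try:
        popt, _ = curve_fit(model, t, T, p0=[h0], maxfev=10000)
    except Exception as exc:
        raise EstimationError(f"lumped-capacitance fit did not converge: {exc}") from exc
    h = float(popt[0])
    if not np.isfinite(h) or h <= 0:
        raise EstimationError(f"lumped-capacitance fit returned invalid h = {h}")
    metrics = fit_metrics(model(t, h), T)
    return h, FitReport.from_metrics({"h": h}, metrics)


def hm_from_h(h: float, air: AirState) -> float:
    """Mass transfer coefficient (m s^-1) from h via the Chilton-Colburn analogy.

    Uses h_m = h * Le^(2/3) / (rho_air * Cp_air) with the Lewis number
    Le = alpha_air / D_air of the drying air.  With the hot-air properties of
    :class:`AirState` this reproduces the measured (h, h_m) pairs of the
    copper-sphere experiments to four significant figures; see
    ``docs/methods.md`` for the relation to the textbook form of the analogy.
    """
    Le = air.alpha_air / air.D_air
    return h * Le ** (2.0 / 3.0) / (air.rho_air * air.Cp_air)


def calorimetric_power(
    series: CalorimetrySeries,
    sphere: CopperSphere | None = None,
    window_s: float = 60.0,
    min_points: int = 10,
) -> float:
    """Ultrasound power (W) from the initial temperature-rise rate.

    Takes dT/dt as the OLS slope over the initial window — the first
    ``window_s`` seconds or the first ``min_points`` samples, whichever spans
    more points — and returns P = m_Cu * Cp_Cu * dT/dt.
    """
    if sphere is None:
        sphere = CopperSphere()
    t, T = series.time, series.temperature
    if t.size < 3:
        raise EstimationError(f"need at least 3 calorimetry points, got {t.size}")
    n_window = int(np.count_nonzero(t <= t[0] + window_s))
    n_sel = min(max(n_window, min_points), t.size)
    slope = float(np.polyfit(t[:n_sel], T[:n_sel], 1)[0])
    if slope <= 0:
        raise EstimationError(
            f"no heating detected: fitted temperature slope {slope:.3e} K/s"
        )
    return sphere.mass * sphere.Cp * slope


def ultrasound_intensity(P: float, r: float) -> float:
    """Acoustic heat flux on a sphere's surface, W m^-2: Q_US = P / (4 pi r^2)."""
    if P < 0:
        raise DomainError(f"power must be non-negative, got {P}")
    if r <= 0:
        raise DomainError(f"radius must be positive, got {r}")
    return P / (4.0 * np.pi * r**2)
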
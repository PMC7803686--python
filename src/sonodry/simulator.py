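"""Coupled heat and moisture transport in a shrinking spherical fruit.

The model solves, on the normalized radial coordinate xi = x/r(t):

* conduction:  rho_b(W) Cp(W) dT/dt = (1/x^2) d/dx [ x^2 lambda(W) dT/dx ]
* diffusion:   dW/dt = (1/x^2) d/dx [ x^2 D_e(T) dW/dx ]

with symmetry at the centre and, at the moving surface x = r(t),

* energy:  lambda dT/dx = h (T_air - T_s) + Q_US - h_fg(T_s) j_m
* mass:    -rho_s D_e dW/dx = j_m = h_m (C_s - C_air)

where C_s is the ideal-gas vapour concentration at the surface water activity
(the GAB inverse of the surface moisture) and Q_US = P_US / (4 pi r^2) is the
acoustic power spread over the current surface.  Evaporation cools the
surface; absorbed ultrasound heats it.

Shrinkage is quasi-static: the radius follows the volume-average moisture
through the linear shrinkage law and is frozen within each output interval
(operator splitting); the grid-velocity advection term is neglected, so
shrinkage acts purely through the diffusion/conduction path length and the
densities.  Space is discretized by a conservative finite-volume scheme on a
uniform xi grid, which makes the discrete water inventory balance the
boundary evaporation flux identically; time integration is stiff (LSODA with
a banded Jacobian).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DomainError, SimulationError
from .properties import (
    AirState,
    MaterialSpec,
    _gab_activity_core,
    _latent_heat_unchecked,
    _pvs_unchecked,
    radius_from_moisture,
    vapor_concentration_air,
)

__all__ = [
    "DryingScenario",
    "NumericsConfig",
    "SimulationResult",
    "simulate_drying",
    "average_moisture",
    "time_to_moisture",
    "surface_center_difference",
]

MODES = ("none", "airborne", "contact")


@dataclass(frozen=True)
class DryingScenario:
    """External drying conditions: air state, sonication mode and coefficients.

    ``P_US`` is the acoustic power dissipated on the sample (W); it must be
    zero exactly when ``mode`` is "none".  ``h`` and ``h_m`` are the surface
    heat (W m^-2 K^-1) and mass (m s^-1) transfer coefficients; ``duration``
    the simulated time span in seconds.
    """

    air: AirState
    mode: str
    P_US: float
    h: float
    h_m: float
    duration: float

    def __post_init__(self):
        if self.mode not in MODES:
            raise DomainError(f"mode must be one of {MODES}, got {self.mode!r}")
        if (self.P_US == 0) != (self.mode == "none"):
            raise DomainError(
                f"P_US = {self.P_US} inconsistent with mode {self.mode!r}: "
                "acoustic power must be zero exactly for unsonicated drying"
            )
        if self.P_US < 0:
            raise DomainError(f"P_US must be non-negative, got {self.P_US}")
        if not (self.h > 0 and self.h_m > 0):
            raise DomainError("transfer coefficients h and h_m must be positive")
        if not self.duration > 0:
            raise DomainError(f"duration must be positive, got {self.duration}")


@dataclass(frozen=True)
class NumericsConfig:
    """Discretization and output control for :func:`simulate_drying`.

    The radius is divided into ``n_nodes`` points including both endpoints.
    Output (and the quasi-static radius update) happens every ``output_dt``
    seconds, refined to ``early_dt`` during the first ``early_window`` seconds
    to resolve the fast initial surface transient.  ``output_times`` overrides
    the whole schedule when given.
    """

    n_nodes: int = 121
    rtol: float = 1e-6
    atol: float = 1e-8
    output_dt: float = 10.0
    early_dt: float = 0.5
    early_window: float = 60.0
    radius_update_every: int = 1
    output_times: np.ndarray | None = None

    def __post_init__(self):
        if self.n_nodes < 11:
            raise DomainError(f"n_nodes must be at least 11, got {self.n_nodes}")
        if not (self.rtol > 0 and self.atol > 0):
            raise DomainError("tolerances must be positive")
        if self.radius_update_every < 1:
            raise DomainError("radius_update_every must be a positive step count")

    def schedule(self, duration: float) -> np.ndarray:
        if self.output_times is not None:
            t = np.asarray(self.output_times, dtype=float)
            t = t[(t > 0) & (t <= duration)]
            return np.unique(np.concatenate([t, [duration]]))
        early = np.arange(self.early_dt, min(self.early_window, duration), self.early_dt)
        late = np.arange(
            max(self.early_window, self.early_dt), duration, self.output_dt
        )
        return np.unique(np.concatenate([early, late, [duration]]))


@dataclass
class SimulationResult:
    """Time-stamped radial profiles, radius history and diagnostics.

    Profiles are stored on the fixed normalized grid ``xi`` in [0, 1];
    ``w_avg`` is the volume-average moisture (cell-weighted, consistent with
    the conservative scheme) and ``evaporated_mass`` the cumulative water mass
    (kg) that left through the surface, integrated from the boundary flux.
    """

    times: np.ndarray
    xi: np.ndarray
    T_profiles: np.ndarray
    W_profiles: np.ndarray
    radius: np.ndarray
    w_avg: np.ndarray
    t_surface: np.ndarray
    t_center: np.ndarray
    evaporated_mass: np.ndarray
    spec: MaterialSpec
    scenario: DryingScenario

    def mass_balance_residuals(self) -> np.ndarray:
        """Per-interval relative mismatch between the loss of water inventory
        and the evaporated mass integrated from the boundary flux."""
        dry_mass = self.spec.M0 * self.spec.f_dm
        lost = dry_mass * (self.w_avg[0] - self.w_avg)
        d_lost = np.diff(lost)
        d_evap = np.diff(self.evaporated_mass)
        floor = max(1e-9 * max(self.evaporated_mass[-1], 0.0), 1e-18)
        return np.abs(d_lost - d_evap) / np.maximum(np.abs(d_evap), floor)


def simulate_drying(
    spec: MaterialSpec,
    scenario: DryingScenario,
    numerics: NumericsConfig | None = None,
    stop_when_below: float | None = None,
) -> SimulationResult:
    """Solve the coupled heat/moisture problem; see the module docstring.

    ``stop_when_below`` ends the run early once the volume-average moisture
    falls below the given dry-basis value (the final accepted state is kept).
    """
    num = numerics or NumericsConfig()
    n = num.n_nodes
    xi = np.linspace(0.0, 1.0, n)
    dxi = xi[1] - xi[0]
    faces = 0.5 * (xi[:-1] + xi[1:])
    face_sq = faces**2
    edges = np.concatenate(([0.0], faces, [1.0]))
    w_cell = np.diff(edges**3) / 3.0
    w_sum = w_cell.sum()  # = 1/3

    air = scenario.air
    c_air = vapor_concentration_air(air)
    gab = spec.gab
    arr = spec.arrhenius
    h, h_m, P_us, T_air = scenario.h, scenario.h_m, scenario.P_US, air.T_air
    dry_mass = spec.M0 * spec.f_dm
    w0 = spec.W0

    # frozen-radius holder, updated between integration windows
    r_box = [spec.r0]

    def rhs(t, y):
        r = r_box[0]
        # trial steps of the error-controlled integrator may probe unphysical
        # states; clip property evaluations to keep the RHS finite and smooth
        T = np.clip(y[0 : 2 * n : 2], 250.0, 640.0)
        W = y[1 : 2 * n : 2]
        Wc = np.maximum(W, 0.0)

        De = arr.D0 * np.exp(-arr.b / T)
        lam = (0.149 + 0.493 * Wc) / (1.0 + Wc)
        cp = (0.837 + 1.256 * Wc) * 1000.0
        rho_s = dry_mass / (4.0 / 3.0 * np.pi * r**3)
        rho_b = rho_s * (1.0 + Wc)

        dW_face = np.diff(W) / dxi
        dT_face = np.diff(T) / dxi
        FW = face_sq * 0.5 * (De[:-1] + De[1:]) * dW_face
        FT = face_sq * 0.5 * (lam[:-1] + lam[1:]) * dT_face

        Ts = T[-1]
        aw_s = float(_gab_activity_core(np.asarray(Wc[-1]), gab))
        c_s = 2.1667e-3 * aw_s * float(_pvs_unchecked(Ts)) / Ts
        j_m = h_m * (c_s - c_air)  # outward evaporation flux, kg m^-2 s^-1
        q_us = P_us / (4.0 * np.pi * r**2)
        h_fg = float(_latent_heat_unchecked(Ts))
        FW_out = -j_m * r / rho_s
        FT_out = r * (h * (T_air - Ts) + q_us - h_fg * j_m)

        dy = np.empty_like(y)
        inv_r2 = 1.0 / (r * r)
        dy[1 : 2 * n : 2] = (
            np.diff(np.concatenate(([0.0], FW, [FW_out]))) * inv_r2 / w_cell
        )
        dy[0 : 2 * n : 2] = (
            np.diff(np.concatenate(([0.0], FT, [FT_out])))
            * inv_r2
            / (w_cell * rho_b * cp)
        )
        dy[2 * n] = 4.0 * np.pi * r**2 * j_m
        return dy

    y = np.empty(2 * n + 1)
    y[0 : 2 * n : 2] = spec.T0
    y[1 : 2 * n : 2] = w0
    y[2 * n] = 0.0

    times = [0.0]
    T_hist = [np.full(n, spec.T0)]
    W_hist = [np.full(n, w0)]
    r_hist = [spec.r0]
    wavg_hist = [w0]
    evap_hist = [0.0]

    prev_t = 0.0
    for step, t_next in enumerate(num.schedule(scenario.duration)):
        if step % num.radius_update_every == 0:
            w_avg_now = min(float(w_cell @ np.maximum(y[1 : 2 * n : 2], 0.0)) / w_sum, w0)
            r_box[0] = float(radius_from_moisture(w_avg_now, spec))
        sol = solve_ivp(
            rhs,
            (prev_t, t_next),
            y,
            method="LSODA",
            rtol=num.rtol,
            atol=num.atol,
            lband=3,
            uband=3,
            t_eval=[t_next],
        )
        if not sol.success:
            raise SimulationError(
                f"integrator failed between t={prev_t:.2f} and t={t_next:.2f} s: "
                f"{sol.message}; last accepted state had "
                f"W_avg={wavg_hist[-1]:.4f}, r={r_hist[-1]:.5f} m"
            )
        y = sol.y[:, -1]
        W = y[1 : 2 * n : 2]
        if W.min() < -1e-6:
            raise SimulationError(
                f"moisture went negative (min W = {W.min():.3e}) at t={t_next:.2f} s"
            )
        np.maximum(W, 0.0, out=W)
        w_avg = float(w_cell @ W) / w_sum

        times.append(t_next)
        T_hist.append(y[0 : 2 * n : 2].copy())
        W_hist.append(W.copy())
        r_hist.append(r_box[0])
        wavg_hist.append(w_avg)
        evap_hist.append(float(y[2 * n]))
        prev_t = t_next
        if stop_when_below is not None and w_avg < stop_when_below:
            break

    T_arr = np.array(T_hist)
    W_arr = np.array(W_hist)
    return SimulationResult(
        times=np.array(times),
        xi=xi,
        T_profiles=T_arr,
        W_profiles=W_arr,
        radius=np.array(r_hist),
        w_avg=np.array(wavg_hist),
        t_surface=T_arr[:, -1],
        t_center=T_arr[:, 0],
        evaporated_mass=np.array(evap_hist),
        spec=spec,
        scenario=scenario,
    )


def average_moisture(profile, xi) -> float:
    """Volume-weighted mean of a radial profile on the normalized grid:
    integral of W xi^2 dxi over integral of xi^2 dxi, composite trapezoid."""
    profile = np.asarray(profile, dtype=float)
    xi = np.asarray(xi, dtype=float)
    if profile.shape != xi.shape:
        raise DomainError("profile and xi must have the same shape")
    return float(np.trapezoid(profile * xi**2, xi) / np.trapezoid(xi**2, xi))


def time_to_moisture(result: SimulationResult, w_target: float) -> float:
    """Time (s) at which the volume-average moisture first reaches ``w_target``,
    linearly interpolated between the bracketing output samples."""
    t, w = result.times, result.w_avg
    if w_target >= w[0]:
        return 0.0
    below = np.nonzero(w <= w_target)[0]
    if below.size == 0:
        raise SimulationError(
            f"target moisture {w_target} never reached; final W_avg = {w[-1]:.4f}"
        )
    i = int(below[0])
    if i == 0:
        return float(t[0])
    frac = (w[i - 1] - w_target) / (w[i - 1] - w[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def surface_center_difference(result: SimulationResult) -> pd.DataFrame:
    """Surface-minus-centre temperature and centre-minus-surface moisture
    differences at every stored time."""
    return pd.DataFrame(
        {
            "time_s": result.times,
            "delta_T_K": result.t_surface - result.t_center,
            "delta_W_db": result.W_profiles[:, 0] - result.W_profiles[:, -1],
        }
    )
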
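"""CSV schemas for the four experimental inputs and the simulator outputs.

All files are UTF-8, comma-separated, decimal point, with a mandatory header:

* kinetics:    ``time_s, moisture_db``
* cooling:     ``time_s, temp_K``
* calorimetry: ``time_s, temp_K``
* sorption:    ``aw, weq_db``
* profiles:    ``time_s, xi, temp_K, moisture_db`` (tidy long form)
* summary:     ``time_s, radius_m, w_avg_db, t_surface_K, t_center_K``
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError
from .estimation import (
    CalorimetrySeries,
    CoolingSeries,
    CopperSphere,
    KineticsSeries,
    SorptionTable,
)
from .simulator import SimulationResult


def _read_columns(path, columns) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DomainError(f"{path}: missing required column(s) {missing}")
    return df


def read_kinetics(path, temperature_label: float, mode: str = "none") -> KineticsSeries:
    df = _read_columns(path, ["time_s", "moisture_db"])
    return KineticsSeries(
        time=df["time_s"].to_numpy(),
        moisture=df["moisture_db"].to_numpy(),
        temperature_label=temperature_label,
        mode=mode,
    )


def write_kinetics(series: KineticsSeries, path) -> None:
    pd.DataFrame({"time_s": series.time, "moisture_db": series.moisture}).to_csv(
        path, index=False
    )


def read_cooling(path, sphere: CopperSphere | None = None) -> CoolingSeries:
    df = _read_columns(path, ["time_s", "temp_K"])
    return CoolingSeries(
        time=df["time_s"].to_numpy(),
        T_surface=df["temp_K"].to_numpy(),
        sphere=sphere or CopperSphere(),
    )


def write_cooling(series: CoolingSeries, path) -> None:
    pd.DataFrame({"time_s": series.time, "temp_K": series.T_surface}).to_csv(
        path, index=False
    )


def read_calorimetry(path) -> CalorimetrySeries:
    df = _read_columns(path, ["time_s", "temp_K"])
    return CalorimetrySeries(
        time=df["time_s"].to_numpy(), temperature=df["temp_K"].to_numpy()
    )


def write_calorimetry(series: CalorimetrySeries, path) -> None:
    pd.DataFrame({"time_s": series.time, "temp_K": series.temperature}).to_csv(
        path, index=False
    )


def read_sorption(path) -> SorptionTable:
    df = _read_columns(path, ["aw", "weq_db"])
    return SorptionTable(a_w=df["aw"].to_numpy(), w_eq=df["weq_db"].to_numpy())


def write_sorption(table: SorptionTable, path) -> None:
    pd.DataFrame({"aw": table.a_w, "weq_db": table.w_eq}).to_csv(path, index=False)


def write_profiles(result: SimulationResult, path) -> None:
    """Tidy long-form radial profiles, one row per (time, node)."""
    n_t, n_x = result.T_profiles.shape
    pd.DataFrame(
        {
            "time_s": np.repeat(result.times, n_x),
            "xi": np.tile(result.xi, n_t),
            "temp_K": result.T_profiles.ravel(),
            "moisture_db": result.W_profiles.ravel(),
        }
    ).to_csv(path, index=False)


def write_summary(result: SimulationResult, path) -> None:
    summary_frame(result).to_csv(path, index=False)


def summary_frame(result: SimulationResult) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": result.times,
            "radius_m": result.radius,
            "w_avg_db": result.w_avg,
            "t_surface_K": result.t_surface,
            "t_center_K": result.t_center,
        }
    )


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
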
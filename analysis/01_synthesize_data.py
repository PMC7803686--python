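"""Generate the four synthetic experimental datasets.

Writes, under results/data/: drying kinetics of 5-mm fruit spheres at
50/60/70 degC for each sonication mode (the diffusivity protocol), copper
sphere cooling curves at 65 degC for each mode (the h protocol), insulated
sphere calorimetry for the two sonication modes, and a 7-point sorption
table.  Truth parameters are the published per-mode values plus the
configured isotherm; noise levels are the declared defaults.
"""

import argparse
from pathlib import Path

import numpy as np

from sonodry import CopperSphere, MaterialSpec
from sonodry.config import default_config, material_from_config, scenario_from_config
from sonodry import io, published
from sonodry.simulator import DryingScenario
from sonodry.properties import AirState
from sonodry.synthetic import (
    NoiseSpec,
    generate_calorimetry,
    generate_copper_cooling,
    generate_drying_kinetics,
    generate_sorption_points,
)

DE_TEMPS_K = (323.15, 333.15, 343.15)  # 50/60/70 degC small-sphere protocol


def main(seed: int, out: Path) -> None:
    cfg = default_config()
    out = io.ensure_dir(out)
    sphere = CopperSphere(**published.COPPER_SPHERE)
    noise_cfg = cfg["noise"]

    print("== synthetic dataset generation ==")
    k = 0
    for mode in published.MODES:
        spec = material_from_config(cfg, mode)
        small = MaterialSpec(M0=spec.M0, f_dm=spec.f_dm, r0=2.5e-3, T0=spec.T0,
                             gab=spec.gab, arrhenius=spec.arrhenius,
                             shrinkage=spec.shrinkage)
        for T in DE_TEMPS_K:
            # sample until the moisture ratio decays to ~0.02, comfortably
            # above the noise floor at equilibrium
            De_true = spec.arrhenius.D0 * np.exp(-spec.arrhenius.b / T)
            t_end = np.log(0.61 / 0.02) / (De_true * np.pi**2 / 2.5e-3**2)
            t_kin = np.linspace(0.0, t_end, 61)
            base = scenario_from_config(cfg, mode)
            scn = DryingScenario(air=AirState(T_air=T, RH=cfg["air"]["RH_percent"]),
                                 mode=base.mode, P_US=base.P_US, h=base.h,
                                 h_m=base.h_m, duration=t_end)
            series = generate_drying_kinetics(
                small, scn, t_kin,
                NoiseSpec("gaussian_multiplicative", noise_cfg["kinetics_relative"],
                          seed + k),
            )
            io.write_kinetics(series, out / f"kinetics_{mode}_{T:.2f}K.csv")
            k += 1
    print(f"  kinetics: {k} series (61 samples each)")

    t_cool = np.arange(0.0, 1801.0, 10.0)
    for i, mode in enumerate(published.MODES):
        h_true = published.TRANSFER_COEFFICIENTS[mode][0]
        series = generate_copper_cooling(
            h_true, sphere, T0=cfg["material"]["T0_K"], T_air=cfg["air"]["T_air_K"],
            sampling=t_cool,
            noise=NoiseSpec("gaussian_additive", noise_cfg["cooling_K"], seed + 50 + i),
        )
        io.write_cooling(series, out / f"cooling_{mode}.csv")
    print(f"  cooling: {len(published.MODES)} series")

    t_cal = np.arange(0.0, 121.0, 2.0)
    for i, mode in enumerate(("airborne", "contact")):
        series = generate_calorimetry(
            published.ULTRASOUND_POWER_W[mode], sphere, T0=cfg["material"]["T0_K"],
            sampling=t_cal,
            noise=NoiseSpec("gaussian_additive", noise_cfg["calorimetry_K"],
                            seed + 60 + i),
        )
        io.write_calorimetry(series, out / f"calorimetry_{mode}.csv")
    print("  calorimetry: 2 series")

    gab = material_from_config(cfg, "none").gab
    table = generate_sorption_points(
        gab, cfg["sorption_aw_grid"],
        NoiseSpec("gaussian_multiplicative", noise_cfg["sorption_relative"], seed + 70),
    )
    io.write_sorption(table, out / "sorption.csv")
    print(f"  sorption: {len(table)} points; all files in {out}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    main(args.seed, args.out)
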
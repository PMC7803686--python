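"""Estimate every model parameter from the synthetic datasets.

Reads the CSVs written by 01_synthesize_data.py and runs the full estimation
chain: GAB isotherm fit, slope-method diffusivities at three temperatures per
mode followed by an Arrhenius regression, lumped-capacitance h with the
Chilton-Colburn h_m, and calorimetric ultrasound powers.  Writes
results/estimates.csv with the recovered values next to their generating
truths.
"""

import argparse
from pathlib import Path

import pandas as pd

from sonodry import (
    CopperSphere,
    arrhenius_diffusivity,
    calorimetric_power,
    estimate_de_slope,
    fit_arrhenius,
    fit_gab,
    fit_h_lumped,
    gab_moisture,
    hm_from_h,
)
from sonodry.config import air_from_config, default_config, material_from_config
from sonodry import io, published

DE_TEMPS_K = (323.15, 333.15, 343.15)


def main(data_dir: Path, out: Path) -> None:
    cfg = default_config()
    out = io.ensure_dir(out)
    sphere = CopperSphere(**published.COPPER_SPHERE)
    air = air_from_config(cfg)
    rows = []

    print("== parameter estimation ==")
    gab_truth = material_from_config(cfg, "none").gab
    params, report = fit_gab(io.read_sorption(data_dir / "sorption.csv"))
    print(f"  GAB: W_m={params.W_m:.4f} (truth {gab_truth.W_m}), C={params.C:.2f} "
          f"(truth {gab_truth.C}), K={params.K:.4f} (truth {gab_truth.K}), "
          f"R^2={report.r_squared:.4f}")
    for name, got, true in (("W_m", params.W_m, gab_truth.W_m),
                            ("C", params.C, gab_truth.C),
                            ("K", params.K, gab_truth.K)):
        rows.append({"quantity": f"gab_{name}", "estimate": got, "truth": true})
    w_eq = gab_moisture(air.RH / 100.0, gab_truth)

    for mode in published.MODES:
        truth = published.ARRHENIUS[mode]
        pairs = []
        for T in DE_TEMPS_K:
            series = io.read_kinetics(data_dir / f"kinetics_{mode}_{T:.2f}K.csv",
                                      temperature_label=T, mode=mode)
            de = estimate_de_slope(series, r=2.5e-3, w_eq=w_eq)
            pairs.append((T, de))
            rows.append({"quantity": f"De_{mode}_{T:.0f}K", "estimate": de,
                         "truth": arrhenius_diffusivity(T, truth)})
        fitted = fit_arrhenius(pairs)
        print(f"  {mode}: D0={fitted.D0:.4e} m^2/s (truth {truth.D0:.4e}), "
              f"b={fitted.b:.1f} K (truth {truth.b:.1f})")
        rows.append({"quantity": f"arrhenius_D0_{mode}", "estimate": fitted.D0,
                     "truth": truth.D0})
        rows.append({"quantity": f"arrhenius_b_{mode}", "estimate": fitted.b,
                     "truth": truth.b})

    for mode in published.MODES:
        h_truth, hm_truth = published.TRANSFER_COEFFICIENTS[mode]
        series = io.read_cooling(data_dir / f"cooling_{mode}.csv", sphere)
        h, rep = fit_h_lumped(series, T_air=air.T_air)
        hm = hm_from_h(h, air)
        print(f"  {mode}: h={h:.2f} W/m^2/K (truth {h_truth}), "
              f"h_m={hm:.5f} m/s (printed {hm_truth})")
        rows.append({"quantity": f"h_{mode}", "estimate": h, "truth": h_truth})
        rows.append({"quantity": f"hm_{mode}", "estimate": hm, "truth": hm_truth})

    for mode in ("airborne", "contact"):
        series = io.read_calorimetry(data_dir / f"calorimetry_{mode}.csv")
        p = calorimetric_power(series, sphere)
        truth = published.ULTRASOUND_POWER_W[mode]
        print(f"  {mode}: P_US={p:.4f} W (truth {truth})")
        rows.append({"quantity": f"P_US_{mode}", "estimate": p, "truth": truth})

    frame = pd.DataFrame(rows)
    frame["relative_error"] = (frame["estimate"] - frame["truth"]) / frame["truth"]
    frame.to_csv(out / "estimates.csv", index=False)
    print(f"  wrote {out / 'estimates.csv'} "
          f"(max |rel err| = {frame['relative_error'].abs().max():.3f})")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    main(args.data, args.out)
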
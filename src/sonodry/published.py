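"""Published experimental inputs for the blackberry drying study.

These are measured quantities reported for hot-air drying of blackberry at
65 degC under three treatments — plain air drying ("none"), air drying with
airborne sonication ("airborne") and air drying with contact sonication
("contact") — and are consumed as *inputs* by the simulator, the analysis
drivers and the comparison arithmetic.  Nothing here is fitted by this
package; see :mod:`sonodry.estimation` for the estimators that produce the
same kinds of numbers from raw series.
"""

from __future__ import annotations

import pandas as pd

from .properties import ArrheniusParams, ShrinkageLaw

MODES = ("none", "airborne", "contact")

#: dry-mass fraction of the fresh fruit (AOAC oven method)
DRY_MASS_FRACTION = 0.138

#: Arrhenius laws for the effective moisture diffusivity, fitted per treatment
#: on 5-mm fruit spheres dried at 50/60/70 degC.  Printed as
#: D_e [m^2 min^-1] = D0' * exp(-b / T); converted here to SI (m^2 s^-1).
ARRHENIUS_PER_MINUTE: dict[str, tuple[float, float]] = {
    "none": (2.608e-6, 1159.0),
    "airborne": (0.007628, 3562.0),
    "contact": (2.98e-5, 1650.0),
}

ARRHENIUS: dict[str, ArrheniusParams] = {
    mode: ArrheniusParams.from_per_minute(*vals)
    for mode, vals in ARRHENIUS_PER_MINUTE.items()
}

#: convective heat transfer coefficient h (W m^-2 K^-1) and mass transfer
#: coefficient h_m (m s^-1) on the sample surface at 65 degC
TRANSFER_COEFFICIENTS: dict[str, tuple[float, float]] = {
    "none": (10.61, 0.01130),
    "airborne": (24.54, 0.02613),
    "contact": (26.61, 0.02833),
}

#: calorimetric ultrasound power actually dissipated on one fruit, W
ULTRASOUND_POWER_W: dict[str, float] = {
    "none": 0.0,
    "airborne": 0.245,
    "contact": 0.299,
}

#: slope of the linear shrinkage law r/r0 = (1 - slope) + slope * (W/W0)
SHRINKAGE_SLOPES: dict[str, float] = {
    "none": 0.6068,
    "airborne": 0.4365,
    "contact": 0.3656,
}

SHRINKAGE: dict[str, ShrinkageLaw] = {
    mode: ShrinkageLaw(slope) for mode, slope in SHRINKAGE_SLOPES.items()
}

#: electricity consumed to dry down to 1.0 kg water/kg DM, kWh
ENERGY_KWH: dict[str, float] = {
    "none": 2.67,
    "airborne": 1.89,
    "contact": 1.38,
}

#: measured time to dry down to 1.0 kg water/kg DM, minutes
DRYING_TIME_MIN: dict[str, float] = {
    "none": 390.0,
    "airborne": 205.0,
    "contact": 150.0,
}

#: copper reference sphere used for h estimation and ultrasound calorimetry
COPPER_SPHERE = {"diameter": 0.025, "rho": 8.96e3, "Cp": 390.0}

#: hot-air transport properties used with the Chilton-Colburn analogy
AIR_PROPERTIES = {
    "rho_air": 1.029,       # kg m^-3
    "Cp_air": 1.0e3,        # J kg^-1 K^-1
    "alpha_air": 2.5e-5,    # m^2 s^-1
    "D_air": 2.18e-5,       # m^2 s^-1
}


def quality_table() -> pd.DataFrame:
    """Mean quality indices of the dried fruit, one column per treatment.

    Rows are, in order: total phenolics (mg gallic acid/g DM), total
    anthocyanins (mg cyanidin-3-O-glucoside/g DM), three individual
    anthocyanins and four organic acids (ug/g DM), ABTS radical scavenging
    (umol Trolox/g DM) and ferric reducing antioxidant power (umol Fe2+/g DM).
    """
    data = {
        "freeze_drying": [60.49, 6.57, 5993.1, 1201.9, 148.6,
                          1681.9, 59201.6, 8896.4, 10562.7, 2114.8, 0.935],
        "none": [58.08, 5.47, 4622.5, 726.6, 84.7,
                 671.7, 36001.2, 4755.1, 4403.7, 2328.7, 0.962],
        "airborne": [62.14, 5.62, 5242.3, 901.0, 115.0,
                     1002.5, 33530.7, 5853.2, 4058.8, 2521.6, 1.031],
        "contact": [69.71, 6.66, 5935.8, 1139.8, 146.5,
                    1427.1, 35972.2, 5114.9, 5639.8, 2610.4, 1.055],
    }
    index = [
        "total_phenolic_content",
        "total_anthocyanin_content",
        "cyanidin_3_O_glucoside",
        "peonidin_3_O_glucoside",
        "malvidin_3_O_glucoside",
        "oxalic_acid",
        "malic_acid",
        "tartaric_acid",
        "citric_acid",
        "abts_scavenging",
        "frap",
    ]
    return pd.DataFrame(data, index=index)
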
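"""Parameter estimators: exact recovery, oracle agreement and error paths."""

import numpy as np
import pytest

from conftest import exact_sphere_mr
from sonodry import (
    AirState,
    ArrheniusParams,
    CalorimetrySeries,
    CoolingSeries,
    CopperSphere,
    GABParams,
    KineticsSeries,
    SorptionTable,
    arrhenius_diffusivity,
    calorimetric_power,
    estimate_de_slope,
    fit_arrhenius,
    fit_gab,
    fit_h_lumped,
    gab_moisture,
    hm_from_h,
    ultrasound_intensity,
)
from sonodry.errors import DomainError, EstimationError
from sonodry.synthetic import (
    NoiseSpec,
    generate_calorimetry,
    generate_copper_cooling,
    generate_sorption_points,
)

SPHERE = CopperSphere()


class TestFitGAB:
    def test_noiseless_recovery(self, default_gab):
        table = generate_sorption_points(default_gab, noise=NoiseSpec())
        params, report = fit_gab(table)
        assert params.W_m == pytest.approx(default_gab.W_m, rel=1e-4)
        assert params.C == pytest.approx(default_gab.C, rel=1e-4)
        assert params.K == pytest.approx(default_gab.K, rel=1e-4)
        assert report.r_squared > 1 - 1e-10

    def test_deterministic(self, default_gab):
        noise = NoiseSpec(kind="gaussian_multiplicative", sigma=0.02, seed=7)
        table = generate_sorption_points(default_gab, noise=noise)
        p1, _ = fit_gab(table)
        p2, _ = fit_gab(table)
        assert (p1.W_m, p1.C, p1.K) == (p2.W_m, p2.C, p2.K)

    def test_moderate_noise_stays_near_truth(self, default_gab):
        errs = []
        for seed in range(10):
            noise = NoiseSpec(kind="gaussian_multiplicative", sigma=0.02, seed=seed)
            params, _ = fit_gab(generate_sorption_points(default_gab, noise=noise))
            errs.append(abs(params.W_m - default_gab.W_m) / default_gab.W_m)
        assert np.median(errs) < 0.10

    def test_too_few_rows_rejected(self):
        table = SorptionTable(a_w=[0.2, 0.4, 0.6, 0.8], w_eq=[0.05, 0.08, 0.12, 0.2])
        with pytest.raises(EstimationError, match="at least 5"):
            fit_gab(table)


class TestSlopeMethod:
    R = 2.5e-3  # small-sphere protocol radius, m

    def _one_term_series(self, De, w0=6.2464, w_eq=0.05, dt=60.0, t_end=3600.0):
        t = np.arange(0.0, t_end + 1, dt)
        mr = np.minimum(1.0, 6 / np.pi**2 * np.exp(-De * np.pi**2 * t / self.R**2))
        return KineticsSeries(
            time=t, moisture=w_eq + (w0 - w_eq) * mr, temperature_label=338.15
        )

    def test_inverts_one_term_solution_exactly(self):
        series = self._one_term_series(1e-9)
        assert estimate_de_slope(series, r=self.R, w_eq=0.05) == pytest.approx(
            1e-9, rel=1e-3
        )

    def test_invariant_to_uniform_resampling(self):
        d1 = estimate_de_slope(self._one_term_series(1e-9, dt=60.0), self.R, w_eq=0.05)
        d2 = estimate_de_slope(self._one_term_series(1e-9, dt=20.0), self.R, w_eq=0.05)
        assert d1 == pytest.approx(d2, rel=1e-9)

    def test_recovers_multi_term_series_within_ten_percent(self):
        # data from the 50-term exact solution; the one-term slope fit is only
        # asymptotically unbiased, hence the looser tolerance
        t = np.arange(0.0, 3601.0, 30.0)
        w = 0.05 + (6.2464 - 0.05) * exact_sphere_mr(t, 1e-9, self.R)
        series = KineticsSeries(time=t, moisture=w, temperature_label=338.15)
        de = estimate_de_slope(series, r=self.R, w_eq=0.05, mr_threshold=0.6)
        assert de == pytest.approx(1e-9, rel=0.10)

    def test_constant_series_rejected(self):
        t = np.arange(0.0, 601.0, 60.0)
        series = KineticsSeries(time=t, moisture=np.full_like(t, 3.0),
                                temperature_label=338.15)
        with pytest.raises(EstimationError):
            estimate_de_slope(series, r=self.R)

    def test_aggressive_equilibrium_subtraction_rejected(self):
        series = self._one_term_series(1e-9)
        with pytest.raises(EstimationError, match="too aggressive"):
            estimate_de_slope(series, r=self.R, w_eq=0.2)


class TestFitArrhenius:
    def test_two_exact_points_recovered_exactly(self):
        truth = ArrheniusParams(D0=4e-8, b=1500.0)
        pairs = [(T, arrhenius_diffusivity(T, truth)) for T in (320.0, 350.0)]
        fitted = fit_arrhenius(pairs)
        assert fitted.D0 == pytest.approx(truth.D0, rel=1e-10)
        assert fitted.b == pytest.approx(truth.b, rel=1e-10)

    def test_consistency_with_published_air_drying_law(self):
        truth = ArrheniusParams.from_per_minute(2.608e-6, 1159.0)
        pairs = [(T, arrhenius_diffusivity(T, truth))
                 for T in (323.15, 333.15, 343.15)]
        assert fit_arrhenius(pairs).b == pytest.approx(1159.0, rel=1e-6)

    def test_single_point_rejected(self):
        with pytest.raises(EstimationError):
            fit_arrhenius([(338.15, 1e-9)])

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(EstimationError, match="duplicate"):
            fit_arrhenius([(338.15, 1e-9), (338.15, 2e-9)])


class TestLumpedCapacitance:
    T_AIR, T0 = 338.15, 298.15
    T_GRID = np.arange(0.0, 1801.0, 10.0)

    def test_noiseless_recovery(self):
        series = generate_copper_cooling(24.54, SPHERE, self.T0, self.T_AIR,
                                         self.T_GRID, NoiseSpec())
        h, report = fit_h_lumped(series, T_air=self.T_AIR)
        assert h == pytest.approx(24.54, rel=1e-3)
        assert report.r_squared > 1 - 1e-10

    def test_decay_rate_identity(self):
        # h = 26.61 with the 25-mm copper sphere gives rate constant
        # h*3/(rho Cp R) = 1.82761e-3 1/s (hand evaluation)
        series = generate_copper_cooling(26.61, SPHERE, self.T0, self.T_AIR,
                                         self.T_GRID, NoiseSpec())
        h, _ = fit_h_lumped(series, T_air=self.T_AIR)
        rate = h * 3.0 / (SPHERE.rho * SPHERE.Cp * SPHERE.radius)
        assert rate == pytest.approx(1.82761e-3, rel=1e-4)

    def test_noisy_median_recovery(self):
        errs = []
        for seed in range(20):
            series = generate_copper_cooling(
                24.54, SPHERE, self.T0, self.T_AIR, self.T_GRID,
                NoiseSpec(sigma=0.2, seed=seed),
            )
            h, _ = fit_h_lumped(series, T_air=self.T_AIR, T0=self.T0)
            errs.append(abs(h - 24.54) / 24.54)
        assert np.median(errs) < 0.05

    def test_degenerate_temperature_difference_rejected(self):
        series = CoolingSeries(time=[0, 1, 2, 3, 4, 5],
                               T_surface=[338.0, 338.0, 338.1, 338.0, 338.1, 338.0])
        with pytest.raises(EstimationError, match="too small"):
            fit_h_lumped(series, T_air=338.15)


class TestChiltonColburn:
    AIR = AirState(T_air=338.15, RH=10.0)

    @pytest.mark.parametrize(
        "h, hm_expected",
        [(10.61, 0.01130), (24.54, 0.02613), (26.61, 0.02833)],
    )
    def test_reproduces_measured_pairs(self, h, hm_expected):
        assert hm_from_h(h, self.AIR) == pytest.approx(hm_expected, rel=5e-4)

    def test_linear_in_h(self):
        assert hm_from_h(0.0, self.AIR) == 0.0
        assert hm_from_h(20.0, self.AIR) == pytest.approx(
            2 * hm_from_h(10.0, self.AIR), rel=1e-12
        )


class TestCalorimetry:
    def test_recovers_constructed_power(self):
        series = generate_calorimetry(0.299, SPHERE, 298.15,
                                      np.arange(0.0, 121.0, 2.0), NoiseSpec())
        assert calorimetric_power(series, SPHERE) == pytest.approx(0.299, rel=1e-3)

    def test_doubling_slope_doubles_power(self):
        t = np.arange(0.0, 121.0, 2.0)
        s1 = generate_calorimetry(0.15, SPHERE, 298.15, t, NoiseSpec())
        s2 = generate_calorimetry(0.30, SPHERE, 298.15, t, NoiseSpec())
        assert calorimetric_power(s2, SPHERE) == pytest.approx(
            2 * calorimetric_power(s1, SPHERE), rel=1e-9
        )

    def test_constant_temperature_rejected(self):
        series = CalorimetrySeries(time=np.arange(0.0, 61.0, 2.0),
                                   temperature=np.full(31, 298.15))
        with pytest.raises(EstimationError, match="no heating"):
            calorimetric_power(series, SPHERE)


class TestUltrasoundIntensity:
    def test_hand_value(self):
        assert ultrasound_intensity(0.299, 0.0125) == pytest.approx(152.28, abs=0.2)

    def test_inverse_square_scaling(self):
        assert ultrasound_intensity(0.299, 0.0125 / 2) == pytest.approx(
            4 * ultrasound_intensity(0.299, 0.0125), rel=1e-12
        )

    def test_zero_power(self):
        assert ultrasound_intensity(0.0, 0.0125) == 0.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            ultrasound_intensity(-1.0, 0.0125)
        with pytest.raises(DomainError):
            ultrasound_intensity(0.299, 0.0)
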
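"""Correlations, sorption isotherm, shrinkage geometry and densities."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import brentq

from sonodry import (
    AirState,
    ArrheniusParams,
    GABParams,
    MaterialSpec,
    ShrinkageLaw,
    arrhenius_diffusivity,
    bulk_density,
    gab_moisture,
    gab_water_activity,
    latent_heat,
    radius_from_moisture,
    saturation_vapor_pressure,
    solid_density,
    specific_heat,
    thermal_conductivity,
    vapor_concentration_air,
    vapor_concentration_surface,
)
from sonodry.errors import DomainError


class TestSaturationPressure:
    @pytest.mark.parametrize(
        "T, expected, rel_tol",
        [
            (373.15, 1.013e5, 0.01),   # normal boiling point, steam tables
            (298.15, 3.17e3, 0.02),    # ambient value, steam tables
        ],
    )
    def test_steam_table_values(self, T, expected, rel_tol):
        assert saturation_vapor_pressure(T) == pytest.approx(expected, rel=rel_tol)

    def test_increases_with_temperature(self):
        assert saturation_vapor_pressure(338.15) > saturation_vapor_pressure(323.15)

    @pytest.mark.parametrize("T", [200.0, 500.0])
    def test_out_of_range_rejected(self, T):
        with pytest.raises(DomainError, match="273.15"):
            saturation_vapor_pressure(T)


class TestMoistureCorrelations:
    @pytest.mark.parametrize(
        "fn, W, expected",
        [
            (specific_heat, 0.0, 837.0),
            (specific_heat, 1.0, 2093.0),
            (specific_heat, 6.2464, 8682.48),
            (thermal_conductivity, 0.0, 0.149),
            (thermal_conductivity, 1.0, 0.321),
        ],
    )
    def test_point_values(self, fn, W, expected):
        assert fn(W) == pytest.approx(expected, abs=0.1)

    def test_conductivity_water_asymptote(self):
        assert thermal_conductivity(1e6) == pytest.approx(0.493, abs=1e-3)

    @pytest.mark.parametrize("fn", [specific_heat, thermal_conductivity])
    def test_negative_moisture_rejected(self, fn):
        with pytest.raises(DomainError):
            fn(-0.1)


class TestLatentHeat:
    def test_reference_temperature(self):
        assert latent_heat(273.15) == pytest.approx(2501.05e3)

    def test_vanishes_at_critical_point(self):
        assert latent_heat(647.3 - 1e-6) < 2e4

    def test_spreadsheet_value(self):
        # independent hand evaluation of the power law at 338.15 K
        assert latent_heat(338.15) == pytest.approx(2348495.35, rel=1e-6)

    def test_supercritical_rejected(self):
        with pytest.raises(DomainError, match="critical"):
            latent_heat(650.0)


gab_params_st = st.builds(
    GABParams,
    W_m=st.floats(0.02, 0.5),
    C=st.floats(0.5, 80.0),
    K=st.floats(0.1, 0.98),
)


class TestGAB:
    def test_zero_activity_gives_zero_moisture(self, default_gab):
        assert gab_moisture(0.0, default_gab) == 0.0
        assert gab_water_activity(0.0, default_gab) == 0.0

    def test_direct_substitution(self):
        # W_m C K a_w / [(1-Ka)(1-Ka+CKa)] evaluated by hand
        p = GABParams(W_m=0.1, C=10.0, K=0.8)
        assert gab_moisture(0.5, p) == pytest.approx(0.14492754, rel=1e-7)

    @given(params=gab_params_st, a_w=st.floats(0.01, 0.95))
    def test_round_trip_identity(self, params, a_w):
        w = gab_moisture(a_w, params)
        assert gab_water_activity(w, params) == pytest.approx(a_w, abs=1e-8)

    @given(params=gab_params_st, a_w=st.floats(0.01, 0.95))
    def test_agrees_with_bisection_root_finder(self, params, a_w):
        w = gab_moisture(a_w, params)
        root = brentq(
            lambda a: gab_moisture(a, params) - w, 0.0, min(0.9999, 0.9999 / params.K),
            xtol=1e-13,
        )
        assert gab_water_activity(w, params) == pytest.approx(root, abs=1e-8)

    def test_round_trip_over_moisture_grid(self, default_gab):
        w_grid = np.linspace(1e-4, gab_moisture(0.95, default_gab), 100)
        aw = gab_water_activity(w_grid, default_gab)
        assert np.allclose(gab_moisture(aw, default_gab), w_grid, rtol=1e-8)

    def test_moisture_above_isotherm_range_clamps(self, default_gab):
        # fresh fruit moisture has no root in [0, 1): clamped near saturation
        assert gab_water_activity(6.25, default_gab) == pytest.approx(0.9999)

    def test_out_of_domain_rejected(self, default_gab):
        with pytest.raises(DomainError):
            gab_moisture(1.3, default_gab)
        with pytest.raises(DomainError):
            gab_water_activity(-0.1, default_gab)

    @pytest.mark.parametrize("kwargs", [
        {"W_m": -0.1, "C": 10.0, "K": 0.8},
        {"W_m": 0.1, "C": 0.0, "K": 0.8},
        {"W_m": 0.1, "C": 10.0, "K": 1.5},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(DomainError):
            GABParams(**kwargs)


class TestVaporConcentrations:
    def test_surface_linear_in_activity(self):
        full = vapor_concentration_surface(338.15, 1.0)
        assert vapor_concentration_surface(338.15, 0.5) == pytest.approx(0.5 * full)
        assert vapor_concentration_surface(338.15, 0.0) == 0.0
        assert full == pytest.approx(0.159498, rel=1e-5)  # hand evaluation

    def test_air_linear_in_rh_and_matches_surface_form(self):
        assert vapor_concentration_air(AirState(338.15, 0.0)) == 0.0
        c100 = vapor_concentration_air(AirState(338.15, 100.0))
        assert c100 == pytest.approx(vapor_concentration_surface(338.15, 1.0), rel=1e-12)
        c30 = vapor_concentration_air(AirState(338.15, 30.0))
        assert c30 == pytest.approx(0.0478493, rel=1e-5)  # hand evaluation


class TestDensities:
    def test_solid_density_hand_value(self):
        assert solid_density(0.0035, 0.138, 0.0125) == pytest.approx(59.04, abs=0.1)

    def test_cubic_scaling(self):
        assert solid_density(0.0035, 0.138, 0.0125 / 2) == pytest.approx(
            8 * solid_density(0.0035, 0.138, 0.0125), rel=1e-12
        )

    def test_bulk_equals_solid_at_zero_moisture(self):
        assert bulk_density(0.0, 0.0035, 0.138, 0.0125) == pytest.approx(
            solid_density(0.0035, 0.138, 0.0125), rel=1e-12
        )

    def test_bulk_hand_value(self):
        assert bulk_density(6.2464, 0.0035, 0.138, 0.0125) == pytest.approx(427.81, abs=0.1)

    @given(
        W=st.floats(0.0, 10.0),
        M0=st.floats(1e-4, 0.1),
        r=st.floats(1e-3, 0.05),
    )
    def test_bulk_solid_identity(self, W, M0, r):
        rho_s = solid_density(M0, 0.138, r)
        assert bulk_density(W, M0, 0.138, r) == pytest.approx((1 + W) * rho_s, rel=1e-12)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(DomainError):
            solid_density(0.0035, 0.138, 0.0)


class TestShrinkage:
    def test_intercept_defaults_to_one_minus_slope(self):
        law = ShrinkageLaw(slope=0.6068)
        assert law.intercept == pytest.approx(0.3932, abs=1e-12)

    def test_inconsistent_intercept_rejected(self):
        with pytest.raises(DomainError):
            ShrinkageLaw(slope=0.5, intercept=0.6)

    def test_fresh_fruit_keeps_initial_radius(self, material):
        assert radius_from_moisture(material.W0, material) == pytest.approx(
            material.r0, rel=1e-12
        )

    def test_fully_dry_radius_air_mode(self, material):
        # air-drying shrinkage slope 0.6068: dried radius ratio 0.3932
        assert radius_from_moisture(0.0, material) == pytest.approx(
            0.3932 * material.r0, rel=1e-9
        )

    def test_monotone_in_moisture(self, material):
        w = np.linspace(0, material.W0, 20)
        r = np.array([radius_from_moisture(x, material) for x in w])
        assert np.all(np.diff(r) >= 0)

    def test_moisture_above_initial_rejected(self, material):
        with pytest.raises(DomainError):
            radius_from_moisture(material.W0 * 1.01, material)

    @pytest.fixture()
    def material(self, default_gab):
        return MaterialSpec(
            M0=3.5e-3,
            f_dm=0.138,
            r0=0.0125,
            gab=default_gab,
            arrhenius=ArrheniusParams(D0=1e-9, b=0.0),
            shrinkage=ShrinkageLaw(slope=0.6068),
        )


class TestArrhenius:
    def test_zero_activation_energy_is_constant(self):
        p = ArrheniusParams(D0=1e-9, b=0.0)
        assert arrhenius_diffusivity(300.0, p) == arrhenius_diffusivity(400.0, p) == 1e-9

    def test_increasing_in_temperature(self):
        p = ArrheniusParams.from_per_minute(2.608e-6, 1159.0)
        T = np.linspace(300, 360, 10)
        assert np.all(np.diff(arrhenius_diffusivity(T, p)) > 0)

    def test_published_air_drying_row(self):
        # (2.608e-6 / 60) * exp(-1159 / 338.15), hand-evaluated
        p = ArrheniusParams.from_per_minute(2.608e-6, 1159.0)
        assert arrhenius_diffusivity(338.15, p) == pytest.approx(1.41131e-9, rel=1e-5)

    def test_activation_energy_round_trip(self):
        p = ArrheniusParams.from_activation_energy(D0=1e-8, Ea=29.0)
        assert p.Ea == pytest.approx(29.0, rel=1e-12)
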
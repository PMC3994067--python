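"""Jarvis-Stewart conductance and its big-leaf / dual-leaf upscaling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyflux.radiation import canopy_absorption, derive_optics, layer_irradiance
from canopyflux.resistances import conductance_to_resistance
from canopyflux.solar import partition_incident
from canopyflux.stomatal import (
    SoilMoistureState,
    StomatalParams,
    bigleaf_gsc,
    dualleaf_gsc,
    effective_lai,
    fit_jarvis_params,
    leaf_gs,
    stress_light,
    stress_soil,
    stress_vpd,
)


class TestStressFunctions:
    def test_light_dark_and_half_saturation(self):
        assert stress_light(0.0, 150.0) == 0.0
        assert stress_light(150.0, 150.0) == 0.5
        assert stress_light(600.0, 150.0) == pytest.approx(0.8)

    def test_vpd_forms(self):
        assert stress_vpd(0.0, 0.2) == 1.0
        assert stress_vpd(5.0, 0.2) == pytest.approx(math.exp(-1.0), rel=1e-12)
        assert stress_vpd(3.0, 0.2) < stress_vpd(1.0, 0.2)
        assert stress_vpd(2.0, 0.2, form="inverse") == pytest.approx(1.0 / 1.4)

    def test_soil_normalised_endpoints_and_midpoint(self):
        assert stress_soil(0.0, 7.5) == 0.0
        assert stress_soil(1.0, 7.5) == pytest.approx(1.0)
        expected = (1 - math.exp(-3.75)) / (1 - math.exp(-7.5))
        assert stress_soil(0.5, 7.5) == pytest.approx(expected, rel=1e-12)
        assert stress_soil(0.5, 7.5) == pytest.approx(0.9770, abs=1e-4)

    def test_soil_clips_out_of_range_with_warning(self):
        with pytest.warns(UserWarning):
            assert stress_soil(1.2, 7.5) == pytest.approx(1.0)

    def test_extractable_water_from_moisture_state(self):
        s = SoilMoistureState(theta=0.21, theta_field=0.30, theta_wilt=0.12)
        assert s.extractable == pytest.approx(0.5)
        assert SoilMoistureState(theta=0.05).extractable == 0.0


class TestLeafConductance:
    def test_approaches_gsmax(self, default_params):
        g = leaf_gs(1e6, 0.0, 1.0, default_params)
        assert g == pytest.approx(7.5, rel=1e-3)

    def test_half_saturating_light(self, default_params):
        assert leaf_gs(150.0, 0.0, 1.0, default_params) == pytest.approx(3.75)

    def test_product_of_pinned_factors(self, default_params):
        expected = 7.5 * (300 / 450) * math.exp(-0.2 * 1.5) * stress_soil(0.8, 7.5)
        assert leaf_gs(300.0, 1.5, 0.8, default_params) == pytest.approx(expected, rel=1e-12)


class TestEffectiveLai:
    @pytest.mark.parametrize("lai,expected", [(1.5, 1.5), (2.0, 2.0), (3.0, 2.0), (4.0, 2.0), (5.0, 2.5)])
    def test_piecewise_rule(self, lai, expected):
        assert effective_lai(lai) == expected


def _absorption(lai, zenith=30.0, q_o=400.0, f_d=0.2, alpha=0.8):
    optics = derive_optics(alpha=alpha, zenith_deg=zenith)
    return optics, canopy_absorption(lai, optics, partition_incident(q_o, f_d))


class TestBigleaf:
    def test_dark_canopy_closed(self, default_params):
        _, ab = _absorption(2.0, q_o=0.0)
        assert bigleaf_gsc(ab, 0.0, 1.0, default_params).g_canopy_bigleaf == 0.0

    def test_composition_of_pinned_pieces(self, default_params):
        _, ab = _absorption(2.0)
        q_mean = ab.q_canopy / 2.0
        expected = 7.5 * q_mean / (q_mean + 150.0) * 2.0
        res = bigleaf_gsc(ab, 0.0, 1.0, default_params)
        assert res.g_canopy_bigleaf == pytest.approx(expected, rel=1e-12)

    def test_dense_canopy_uses_effective_lai(self, default_params):
        _, ab = _absorption(5.0)
        res = bigleaf_gsc(ab, 0.0, 1.0, default_params)
        assert res.lai_effective == 2.5
        assert res.g_canopy_bigleaf == pytest.approx(res.g_leaf_bigleaf * 2.5, rel=1e-12)


def multilayer_gsc(lai, optics, inc, vpd, theta_e, params, n_layers=1000):
    """Oracle: integrate leaf conductance over sunlit and shaded leaf profiles."""
    xi = np.linspace(0.0, lai, n_layers + 1)
    g_sl, g_sh = [], []
    q_direct_per_sunlit = (
        params_absorbed_direct(optics, inc)
    )
    for x in xi:
        layer = layer_irradiance(float(x), optics, inc)
        shade_q = layer.diffuse + layer.scattered
        f = layer.sunlit_fraction
        g_sl.append(leaf_gs(q_direct_per_sunlit + shade_q, vpd, theta_e, params) * f)
        g_sh.append(leaf_gs(shade_q, vpd, theta_e, params) * (1.0 - f))
    return np.trapezoid(np.array(g_sl) + np.array(g_sh), xi)


def params_absorbed_direct(optics, inc):
    # direct beam absorbed per unit *sunlit* leaf area is depth-independent
    return optics.leaf_absorptivity * optics.kappa_b * inc.beam


class TestDualleaf:
    def test_all_light_on_sunlit_fraction(self, default_params):
        optics = derive_optics(alpha=0.8, zenith_deg=30.0)
        ab = canopy_absorption(2.0, optics, partition_incident(300.0, 0.0))
        res = dualleaf_gsc(ab, 0.0, 1.0, default_params)
        assert res.g_canopy_dualleaf == pytest.approx(
            res.g_canopy_sunlit + res.g_canopy_shaded
        )
        assert res.g_canopy_sunlit > res.g_canopy_shaded

    def test_linear_light_limit_equals_bigleaf_with_total_lai(self, default_params):
        # with F_Q ~ Q/k_Q both routes reduce to g_smax Q_c / k_Q (x other stresses)
        params = StomatalParams(g_smax=7.5, k_q=1e9, k_d=0.2, k_w=7.5)
        _, ab = _absorption(3.5)
        dual = dualleaf_gsc(ab, 1.2, 0.7, params).g_canopy_dualleaf
        q_mean = ab.q_canopy / ab.lai
        big_total_lai = leaf_gs(q_mean, 1.2, 0.7, params) * ab.lai
        assert dual == pytest.approx(big_total_lai, rel=1e-6)

    def test_fixed_scenario_against_multilayer_oracle(self, default_params):
        optics = derive_optics(alpha=0.8, zenith_deg=30.0)
        inc = partition_incident(400.0, 0.2)
        ab = canopy_absorption(5.0, optics, inc)
        dual = dualleaf_gsc(ab, 0.0, 1.0, default_params).g_canopy_dualleaf
        oracle = multilayer_gsc(5.0, optics, inc, 0.0, 1.0, default_params)
        # evaluating the concave light response at the class means leaves a
        # small Jensen gap; at this dense-canopy scenario the oracle puts it
        # at 1.07%, always on the over-prediction side
        assert dual >= oracle
        assert dual == pytest.approx(oracle, rel=0.015)

    def test_zero_canopy(self, default_params):
        _, ab = _absorption(0.0)
        assert dualleaf_gsc(ab, 0.0, 1.0, default_params).g_canopy_dualleaf == 0.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        lai=st.floats(0.1, 8.0),
        q_o=st.floats(0.0, 600.0),
        f_d=st.floats(0.0, 1.0),
        zenith=st.floats(0.0, 80.0),
        vpd=st.floats(0.0, 4.0),
        theta_e=st.floats(0.0, 1.0),
    )
    def test_bounded_by_gsmax_times_lai(self, lai, q_o, f_d, zenith, vpd, theta_e):
        params = StomatalParams()
        optics = derive_optics(alpha=0.8, zenith_deg=zenith)
        ab = canopy_absorption(lai, optics, partition_incident(q_o, f_d))
        dual = dualleaf_gsc(ab, vpd, theta_e, params)
        big = bigleaf_gsc(ab, vpd, theta_e, params)
        assert 0.0 <= dual.g_canopy_dualleaf <= params.g_smax * lai + 1e-9
        assert 0.0 <= big.g_canopy_bigleaf <= params.g_smax * lai + 1e-9

    def test_jensen_direction_and_dualleaf_wins(self, default_params):
        # pooling all leaves at the mean light over-predicts (concave response);
        # the dual-leaf split must beat the pooled big leaf against the oracle
        for lai in (2.0, 5.0):
            for q_o in (100.0, 300.0, 600.0):
                optics = derive_optics(alpha=0.8, zenith_deg=35.0)
                inc = partition_incident(q_o, 0.2)
                ab = canopy_absorption(lai, optics, inc)
                oracle = multilayer_gsc(lai, optics, inc, 0.0, 1.0, default_params)
                pooled = leaf_gs(ab.q_canopy / lai, 0.0, 1.0, default_params) * lai
                dual = dualleaf_gsc(ab, 0.0, 1.0, default_params).g_canopy_dualleaf
                assert pooled >= oracle - 1e-9
                assert abs(dual - oracle) < abs(pooled - oracle)


def test_conductance_resistance_round_trip(rng):
    for g in rng.uniform(0.05, 40.0, size=50):
        r = conductance_to_resistance(float(g))
        assert 1000.0 / r == pytest.approx(g, rel=1e-15)
    assert conductance_to_resistance(10.0) == pytest.approx(100.0)
    assert conductance_to_resistance(0.0) == math.inf


class TestFitJarvis:
    @staticmethod
    def _light_curve(params, q_levels):
        q = np.asarray(q_levels, dtype=float)
        return np.column_stack([q, params.g_smax * q / (q + params.k_q)])

    @staticmethod
    def _diurnal(params, rng, n=24, noise=0.0):
        q = rng.uniform(20, 600, n)
        vpd = rng.uniform(0.2, 4.0, n)
        th = rng.uniform(0.2, 1.0, n)
        gs = np.array([leaf_gs(qi, vi, ti, params) for qi, vi, ti in zip(q, vpd, th)])
        gs = gs * (1.0 + noise * rng.standard_normal(n))
        return np.column_stack([q, vpd, th, gs])

    def test_noiseless_exact_recovery(self, default_params, rng):
        truth = default_params
        lc = self._light_curve(truth, [25, 50, 100, 200, 400, 800])
        di = self._diurnal(truth, rng)
        fitted, diag = fit_jarvis_params(lc, di)
        assert fitted.g_smax == pytest.approx(truth.g_smax, rel=1e-6)
        assert fitted.k_q == pytest.approx(truth.k_q, rel=1e-6)
        assert fitted.k_d == pytest.approx(truth.k_d, rel=1e-6)
        assert fitted.k_w == pytest.approx(truth.k_w, rel=1e-6)
        assert diag["rss_light_curve"] < 1e-12

    def test_noisy_recovery_median_within_ten_percent(self, default_params):
        truth = default_params
        rng = np.random.default_rng(7)
        recovered = []
        for _ in range(50):
            lc = self._light_curve(truth, [25, 50, 100, 200, 400, 800])
            lc[:, 1] *= 1.0 + 0.05 * rng.standard_normal(lc.shape[0])
            di = self._diurnal(truth, rng, noise=0.05)
            fitted, _ = fit_jarvis_params(lc, di)
            recovered.append([fitted.g_smax, fitted.k_q, fitted.k_d, fitted.k_w])
        med = np.median(recovered, axis=0)
        truth_vec = [truth.g_smax, truth.k_q, truth.k_d, truth.k_w]
        assert np.all(np.abs(med / truth_vec - 1.0) < 0.10)

    def test_instrument_par_levels_design(self, default_params, rng):
        # the usual gas-exchange PAR staircase (in umol, converted to W m-2)
        levels_umol = np.array([2000, 1600, 1300, 1000, 800, 600, 400, 200, 100, 50, 20])
        lc = self._light_curve(default_params, levels_umol / 4.57)
        fitted, _ = fit_jarvis_params(lc, self._diurnal(default_params, rng))
        assert fitted.g_smax == pytest.approx(default_params.g_smax, rel=1e-6)
        assert fitted.k_q == pytest.approx(default_params.k_q, rel=1e-6)

    def test_degenerate_inputs_rejected(self, default_params, rng):
        flat = np.column_stack([np.full(6, 100.0), np.full(6, 3.0)])
        with pytest.raises(ValueError):
            fit_jarvis_params(flat, self._diurnal(default_params, rng))
        with pytest.raises(ValueError):
            fit_jarvis_params(self._light_curve(default_params, [50, 100, 200, 400]),
                              self._diurnal(default_params, rng)[:4])
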
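"""Fluorescence isotherm models, prediction under competition, and fitting."""

import dataclasses

import numpy as np
import pytest

from coopbind import fluor as fl
from coopbind import speciation as sp
from coopbind import synthetic as syn
from coopbind._fitting import FitOptions

from conftest import free_metal_bisection_oracle


class TestResponses:
    def test_one_site_values(self):
        assert fl.response_one_site(0.0, 3.7e6, -1.0) == 0.0
        assert fl.response_one_site(1 / 3.7e6, 3.7e6, -1.0) == pytest.approx(-0.5)
        assert fl.response_one_site(1e-6, 3.7e6, -1.0) == pytest.approx(-3.7 / 4.7, rel=1e-12)

    def test_one_site_monotone_and_bounded(self):
        m = np.geomspace(1e-10, 1e-3, 50)
        r = fl.response_one_site(m, 3.7e6, -1.0)
        assert np.all(np.diff(r) < 0)
        assert np.all((r <= 0) & (r >= -1.0))

    def test_two_site_values_and_limits(self):
        assert fl.response_two_site(10.0, 3.5e7, 7.4e6, -0.6, -1.0) == pytest.approx(-1.0, rel=1e-6)
        val = fl.response_two_site(1e-7, 3.5e7, 7.4e6, -0.6, -1.0)
        assert val == pytest.approx((-2.1 - 2.59) / 7.09, rel=1e-10)

    def test_two_site_reduces_to_one_site(self):
        # model nesting: K2 -> 0 recovers the 1:1 isotherm
        m = np.geomspace(1e-9, 1e-5, 30)
        K1 = 3.7e6
        diffs = []
        for eps_factor in (1e-5, 1e-6, 1e-7):
            two = fl.response_two_site(m, K1, eps_factor * K1, -1.0, -0.5)
            one = fl.response_one_site(m, K1, -1.0)
            diffs.append(np.max(np.abs(two - one)))
        assert diffs[1] < 1e-4
        # vanishes linearly with K2
        assert diffs[2] < diffs[1] < diffs[0]
        assert diffs[2] < 1e-5


class TestDeltaF:
    def _series(self, F, totals=None):
        totals = totals or tuple(np.linspace(0, 1e-5, len(F)))
        design = fl.FluorDesign(1e-5, 0.0, 6.0, totals)
        return fl.FluorTitrationSeries(design, tuple(F))

    def test_baseline_subtraction(self):
        np.testing.assert_allclose(fl.delta_F(self._series([100, 80, 60])), [0, 20, 40])
        np.testing.assert_allclose(fl.delta_F(self._series([50, 50, 50])), [0, 0, 0])

    def test_rising_signal_gives_negative_delta(self):
        dF = fl.delta_F(self._series([100, 120, 140]))
        assert np.all(dF[1:] < 0)

    def test_missing_baseline_rejected(self):
        design = fl.FluorDesign(1e-5, 0.0, 6.0, (1e-6, 2e-6, 3e-6))
        series = fl.FluorTitrationSeries(design, (1.0, 2.0, 3.0))
        with pytest.raises(ValueError, match="baseline"):
            fl.delta_F(series)


class TestPredictSeries:
    def test_saturation_without_chelator(self):
        design = fl.FluorDesign(1e-6, 0.0, 6.0, (0.0, 1e-4, 1e-3))
        params = fl.FluorModelParams("one-site", 1e7, 500 / 1e-6)
        dF = fl.predict_series(params, design)
        assert dF[0] == 0.0
        assert dF[-1] == pytest.approx(500.0, rel=1e-3)

    def test_competition_reduces_signal(self, ida):
        design = fl.FluorDesign(1e-5, 5e-4, 6.0, tuple(np.linspace(0, 1e-4, 8)))
        params = fl.FluorModelParams("one-site", 3.7e6, 8e7)
        with_chel = fl.predict_series(params, design, ida)
        free_design = dataclasses.replace(design, chelator_total=0.0)
        without = fl.predict_series(params, free_design)
        assert np.all(np.abs(with_chel[1:]) < np.abs(without[1:]))

    def test_matches_per_point_bisection_oracle(self, ida):
        design = fl.FluorDesign(1e-5, 5e-4, 6.0,
                                syn.fluor_titration_schedule(1e-5, 5e-4))
        params = fl.FluorModelParams("one-site", 3.7e6, 8e7)
        dF = fl.predict_series(params, design, ida)
        pep = params.peptide_model()
        m, l, p = design.totals_per_point()
        for i in range(len(m)):
            m_free = free_metal_bisection_oracle(m[i], l[i], p[i], 6.0, ida, pep)
            expected = fl.response_one_site(m_free, 3.7e6, 8e7) * p[i]
            assert dF[i] == pytest.approx(expected, rel=1e-8, abs=1e-9)

    def test_dilution_rescales_totals_analytically(self):
        totals = (0.0, 1e-5, 2e-5, 4e-5)
        vols = (0.0, 10.0, 10.0, 20.0)
        base = fl.FluorDesign(1e-5, 0.0, 6.0, totals)
        diluted = fl.FluorDesign(1e-5, 0.0, 6.0, totals,
                                 initial_volume_uL=2000.0, added_volumes_uL=vols)
        params = fl.FluorModelParams("one-site", 1e5, 8e7)
        dF0 = fl.predict_series(params, base)
        dF1 = fl.predict_series(params, diluted)
        # in the weak-binding linear regime dF scales with C_P and free M barely
        # moves, so each point shrinks by very nearly the dilution factor
        f = diluted.dilution_factors()
        np.testing.assert_allclose(dF1[1:] / dF0[1:], f[1:], rtol=5e-3)


class TestFitSeries:
    @pytest.mark.parametrize("true_K", [1e5, 3.7e6, 1e9])
    def test_noise_free_one_site_recovery(self, ida, true_K):
        design = fl.FluorDesign(1e-5, 5e-4, 6.0,
                                syn.fluor_titration_schedule(1e-5, 5e-4))
        params = fl.FluorModelParams("one-site", true_K, 8e7)
        dF = fl.predict_series(params, design, ida)
        series = fl.FluorTitrationSeries(design, tuple(1000.0 - dF))
        res = fl.fit_series(series, "one-site", ida)
        assert abs(res.parameters["log10K1"].value - np.log10(true_K)) < 1e-6

    def test_noisy_replicates_within_three_sd(self, scenario_lib, ida):
        sc = scenario_lib["fluor/CaM Y II"]
        reps = syn.gen_fluor(sc, syn.NoiseModel("relative", 0.01, seed=7), 3, ida)
        res = fl.fit_series(reps, "one-site", ida)
        est = res.parameters["K1"]
        assert res.stderr_source == "replicate-sd"
        assert len(res.per_replicate) == 3
        assert abs(est.value - sc.params.K1) <= 3 * est.stderr

    def test_two_site_data_prefers_two_site_model(self, scenario_lib, ida):
        sc = scenario_lib["fluor/CaM Y I-II"]
        series = syn.gen_fluor(sc, syn.NoiseModel("relative", 0.005, seed=3), 1, ida)[0]
        res2 = fl.fit_series(series, "two-site", ida)
        res1 = fl.fit_series(series, "one-site", ida)
        assert res2.rss < res1.rss

    def test_one_site_data_flags_two_site_fit(self, ida):
        design = fl.FluorDesign(1e-5, 5e-4, 6.0,
                                syn.fluor_titration_schedule(1e-5, 5e-4))
        params = fl.FluorModelParams("one-site", 3.7e6, 8e7)
        dF = fl.predict_series(params, design, ida)
        rng = np.random.default_rng(1)
        series = fl.FluorTitrationSeries(design, tuple(1000.0 - dF + rng.normal(0, 8.0, len(dF))))
        res = fl.fit_series(series, "two-site", ida)
        assert "one_site_vs_two_site_p" in res.diagnostics
        assert res.diagnostics["one_site_vs_two_site_p"] > 0.05
        assert "warning" in res.diagnostics

    def test_too_few_points_rejected(self, ida):
        design = fl.FluorDesign(1e-5, 0.0, 6.0, (0.0, 1e-5, 2e-5))
        series = fl.FluorTitrationSeries(design, (100.0, 90.0, 80.0))
        with pytest.raises(ValueError, match="requires"):
            fl.fit_series(series, "one-site", None)
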
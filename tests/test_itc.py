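"""ITC displacement bookkeeping, heat models, and the staged fitters."""

import numpy as np
import pytest
from scipy.optimize import brentq

from coopbind import itc
from coopbind import speciation as sp
from coopbind import synthetic as syn


def _design(n_inj=10, syringe=1e-3, metal=1e-4, chelator=0.0, first=2.0):
    vols = (first,) + (2.0,) * (n_inj - 1)
    return itc.ITCDesign(200.0, syringe, metal, chelator, vols)


class TestInjectionConcentrations:
    def test_single_injection_displacement(self):
        d = itc.injection_concentrations(_design(n_inj=1))
        assert d["peptide"][0] == pytest.approx(1e-3 * 0.01 / 1.005, rel=1e-12)
        assert d["metal"][0] == pytest.approx(1e-4 * 0.995 / 1.005, rel=1e-12)

    def test_totals_monotone(self):
        d = itc.injection_concentrations(_design(n_inj=15, chelator=2e-4))
        assert np.all(np.diff(d["peptide"]) > 0)
        assert np.all(np.diff(d["metal"]) < 0)
        assert np.all(np.diff(d["chelator"]) < 0)

    def test_large_cumulative_volume_warns(self):
        with pytest.warns(UserWarning, match="half the cell volume"):
            itc.ITCDesign(200.0, 1e-3, 1e-4, 0.0, (60.0, 60.0))


class TestHeatModels:
    def test_zero_enthalpy_gives_zero_heat(self):
        q = itc.predict_heats_one_site(_design(), 1e6, 0.0)
        np.testing.assert_array_equal(q, 0.0)
        params = itc.ITCModelParams(4e7, 4.2e6, 5.7e6, 0.0, 0.0, 0.0)
        q2 = itc.predict_heats_two_site(_design(chelator=2e-4), params)
        np.testing.assert_array_equal(q2, 0.0)

    def test_stoichiometric_limit(self):
        # strong binding, metal in large excess: each 2 uL of 1e-3 M peptide
        # binds completely, releasing dH * 2 nmol = -20 uJ
        q = itc.predict_heats_one_site(_design(n_inj=5, metal=1e-2), 1e12, -10.0)
        assert q[0] == pytest.approx(-20.0, rel=0.01)

    def test_one_site_total_heat_telescopes(self, ida):
        design = _design(n_inj=15, chelator=2e-4)
        K, dH = 4.2e6, -2.0
        q = itc.predict_heats_one_site(design, K, dH, ida)
        mp, _ = itc._species_trajectory(design, sp.PeptideBindingModel(1, K), ida)
        total = dH * (mp[-1] - mp[0]) * design.cell_volume_uL * 1e3
        assert np.sum(q) == pytest.approx(total, rel=1e-10)

    def test_two_site_total_heat_telescopes(self, ida):
        design = _design(n_inj=15, syringe=2e-3, metal=2e-4, chelator=4e-4)
        p = itc.ITCModelParams(4.0e7, 4.2e6, 5.7e6, -40.2, -2.0, 25.0)
        q = itc.predict_heats_two_site(design, p, ida)
        pep = sp.PeptideBindingModel(2, p.K1, p.K2)
        mp, m2p = itc._species_trajectory(design, pep, ida)
        fI = p.KI / p.K1
        scale = design.cell_volume_uL * 1e3
        total = (
            p.dH_I * (mp[-1] - mp[0]) * fI
            + p.dH_II * (mp[-1] - mp[0]) * (1 - fI)
            + (p.dH_I + p.dH_II + p.dH_c) * (m2p[-1] - m2p[0])
        ) * scale
        assert np.sum(q) == pytest.approx(total, rel=1e-10)

    def test_independent_sites_superpose(self):
        # dH_c = 0 and K2 chosen for independent sites: the heats must equal
        # the per-site heats of the factorized model, computed here by a
        # scalar free-metal solve (two independent sites behave exactly like
        # two separate 1:1 binders at the same total concentration)
        KI, KII = 4.0e7, 4.2e6
        K2_indep = KI * KII / (KI + KII)
        design = _design(n_inj=12, syringe=2e-3, metal=2e-4)
        params = itc.ITCModelParams(KI, KII, K2_indep, -40.2, -2.0, 0.0)
        q = itc.predict_heats_two_site(design, params)

        totals = itc.injection_concentrations(design)
        Ms = np.concatenate([[design.cell_metal_concentration], totals["metal"]])
        Ps = np.concatenate([[0.0], totals["peptide"]])
        nI, nII = [0.0], [0.0]
        for C_M, C_P in zip(Ms[1:], Ps[1:]):
            def balance(m):
                return m + C_P * (KI * m / (1 + KI * m) + KII * m / (1 + KII * m)) - C_M
            m = brentq(balance, 0.0, C_M, xtol=1e-30, rtol=1e-15)
            nI.append(C_P * KI * m / (1 + KI * m))
            nII.append(C_P * KII * m / (1 + KII * m))
        scale = design.cell_volume_uL * 1e3
        q_oracle = -40.2 * np.diff(nI) * scale + -2.0 * np.diff(nII) * scale
        np.testing.assert_allclose(q, q_oracle, rtol=1e-6)


class TestBlankSubtraction:
    def test_identity_and_zero_blank(self):
        s = itc.ITCSeries((1.0, -2.0, 3.0))
        assert itc.subtract_blank(s, s).heats == (0.0, 0.0, 0.0)
        zero = itc.ITCSeries((0.0, 0.0, 0.0))
        assert itc.subtract_blank(s, zero).heats == s.heats

    def test_unit_mismatch_rejected(self):
        s = itc.ITCSeries((1.0,), unit="ucal")
        b = itc.ITCSeries((1.0,), unit="uJ")
        with pytest.raises(ValueError, match="unit"):
            itc.subtract_blank(s, b)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal numbers"):
            itc.subtract_blank(itc.ITCSeries((1.0, 2.0)), itc.ITCSeries((1.0,)))

    def test_ucal_conversion(self):
        s = itc.ITCSeries((1.0,), unit="ucal")
        assert s.heats_uJ()[0] == pytest.approx(4.184)


class TestOneSiteFit:
    def test_noise_free_recovery(self, scenario_lib, ida):
        sc = scenario_lib["itc/CaM Y II"]
        series = syn.gen_itc(sc, syn.NoiseModel("absolute", 0.0), chelator=ida)[0]
        res = itc.fit_itc_one_site(series, sc.design, ida)
        assert res.value("K") == pytest.approx(4.2e6, rel=1e-4)
        assert res.value("dH") == pytest.approx(-2.0, rel=1e-4)

    def test_noisy_replicates_within_three_sd(self, scenario_lib, ida):
        sc = scenario_lib["itc/CaM Y II"]
        reps = syn.gen_itc(sc, syn.NoiseModel("absolute", 0.5, seed=5), n_replicates=3, chelator=ida)
        Ks = [itc.fit_itc_one_site(r, sc.design, ida).value("K") for r in reps]
        assert abs(np.mean(Ks) - 4.2e6) <= 3 * np.std(Ks, ddof=1)

    def test_all_zero_heats_flagged(self, ida):
        design = _design(n_inj=10, chelator=2e-4)
        series = itc.ITCSeries((0.0,) * 10)
        res = itc.fit_itc_one_site(series, design, ida)
        assert abs(res.value("dH")) < 1e-9
        assert "unidentifiable" in res.diagnostics


class TestTwoSiteFit:
    TRUTH = dict(KI=4.0e7, KII=4.2e6, K2=5.7e6, dH_I=-40.2, dH_II=-2.0, dH_c=25.0)

    def _fit(self, ida, **kwargs):
        params = itc.ITCModelParams(**self.TRUTH)
        design = _design(n_inj=20, syringe=2e-3, metal=2e-4, chelator=4e-4, first=0.4)
        q = itc.predict_heats_two_site(design, params, ida)
        series = itc.ITCSeries(tuple(q))
        return itc.fit_itc_two_site(
            series, design, (self.TRUTH["KII"], self.TRUTH["dH_II"]), ida, **kwargs
        ), design

    def test_noise_free_recovery_and_K1_closure(self, ida):
        res, _ = self._fit(ida)
        assert res.fit.value("KI") == pytest.approx(self.TRUTH["KI"], rel=0.01)
        assert res.fit.value("K2") == pytest.approx(self.TRUTH["K2"], rel=0.01)
        assert res.fit.value("dH_I") == pytest.approx(self.TRUTH["dH_I"], rel=0.01)
        assert res.fit.value("dH_c") == pytest.approx(self.TRUTH["dH_c"], rel=0.01)
        assert res.K1 == pytest.approx(self.TRUTH["KI"] + self.TRUTH["KII"], rel=0.01)

    def test_derived_quantities_recomputed(self, ida):
        res, _ = self._fit(ida)
        coop = res.cooperativity()
        micro = res.micro()
        assert coop.Kc == pytest.approx(micro.KII_I / micro.KII, rel=1e-12)
        terms = res.entropy_terms()
        assert set(terms) == {"TdS_I", "TdS_II", "TdS_c"}

    def test_sensitivity_diagnostic_reported(self, ida):
        res, _ = self._fit(ida, sensitivity=True)
        shift = res.fit.diagnostics["KI_shift_for_10pct_fixed_perturbation"]
        assert np.isfinite(shift) and shift != 0.0

    def test_correlation_diagnostic(self, ida):
        res, _ = self._fit(ida)
        assert abs(res.fit.diagnostics["KI_K2_correlation"]) <= 1.0

    def test_requires_enough_injections(self, ida):
        design = _design(n_inj=7, chelator=2e-4)
        series = itc.ITCSeries((0.0,) * 7)
        with pytest.raises(ValueError, match="8 usable"):
            itc.fit_itc_two_site(series, design, (1e6, -1.0), ida)
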
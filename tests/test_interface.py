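"""Configuration validation, file round-trips, CLI and workflow wiring."""

import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from coopbind import cli, io as cio, itc, synthetic as syn, workflow
from coopbind.config import AnalysisConfig, SystemConfig, default_system, load_config


class TestConfig:
    def test_default_system_loads(self):
        system = default_system()
        chel = system.chelator.to_model()
        assert len(chel.complex_species) == 3

    def test_unknown_keys_rejected(self, tmp_path):
        payload = {"system": {"chelator": {"pKa": [9.0], "species": [
            {"m": 1, "l": 1, "log10_beta": 8.0}], "typo_key": 1}}}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(Exception, match="typo_key"):
            load_config(path)

    def test_two_site_requires_K2(self):
        with pytest.raises(Exception, match="K2"):
            SystemConfig.model_validate({"peptide": {"n_sites": 2, "K1": 1e7}})

    def test_bare_system_block_accepted(self, tmp_path):
        path = tmp_path / "sys.json"
        path.write_text(json.dumps({"peptide": {"n_sites": 1, "K1": 1e6}}))
        cfg = load_config(path)
        assert cfg.system.peptide.K1 == 1e6


class TestFileRoundTrips:
    def test_fluor_series_lossless(self, tmp_path, scenario_lib, ida):
        sc = scenario_lib["fluor/CaM Y II"]
        series = syn.gen_fluor(sc, syn.NoiseModel(sd=0.01, seed=1), 1, ida)[0]
        path = tmp_path / "fluor.csv"
        cio.write_fluor_series(series, path)
        back = cio.build_fluor_series(
            cio.read_fluor_table(path), sc.design.peptide_total,
            sc.design.chelator_total, sc.design.pH,
        )
        assert back.intensities == series.intensities
        assert back.design.metal_totals == series.design.metal_totals

    def test_itc_series_lossless(self, tmp_path, scenario_lib, ida):
        sc = scenario_lib["itc/CaM Y II"]
        series = syn.gen_itc(sc, syn.NoiseModel("absolute", 0.5, seed=2), chelator=ida)[0]
        path, blank_path = tmp_path / "itc.csv", tmp_path / "blank.csv"
        cio.write_itc_series(series, sc.design, path, blank_path)
        df, unit = cio.read_itc_table(path)
        blank_df, _ = cio.read_itc_table(blank_path)
        back = cio.build_itc_series(df, unit, blank_df)
        assert back.heats == series.heats
        assert back.blank == series.blank
        assert tuple(df["volume_uL"]) == sc.design.injection_volumes_uL

    def test_results_json_roundtrip(self, tmp_path):
        record = {"K": 3.141592653589793e7, "nested": {"dH": -2.0000000000000004}}
        path = tmp_path / "res.json"
        cio.write_results_json(record, path)
        assert cio.read_results_json(path) == record


class TestDeriveTable:
    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            workflow.derive_table(pd.DataFrame({"peptide": ["x"], "K1": [1e7]}))

    def test_derived_cells_recomputable(self):
        table = pd.DataFrame([
            {"peptide": "A", "pH": 6, "K1": 3.5e7, "K2": 7.4e6, "KII": 3.7e6},
        ])
        out = workflow.derive_table(table)
        row = out.iloc[0]
        assert row["KI"] == pytest.approx(3.5e7 - 3.7e6)
        assert row["KII_I"] == pytest.approx(3.5e7 * 7.4e6 / row["KI"], rel=1e-12)
        assert row["Kc"] == pytest.approx(row["KII_I"] / row["KII"], rel=1e-12)


class TestWorkflow:
    def _bundle(self, scenario_lib, ida):
        one = scenario_lib["itc/CaM Y II"]
        two = scenario_lib["itc/CaM Y I-II"]
        noise = syn.NoiseModel("absolute", 0.1, seed=11)
        s1 = syn.gen_itc(one, noise, chelator=ida)[0]
        s2 = syn.gen_itc(two, noise, chelator=ida)[0]
        exp1 = workflow.ITCExperiment("CaM Y II", one.design, s1)
        exp2 = workflow.ITCExperiment("CaM Y I-II", two.design, s2, one_site_label="CaM Y II")
        return exp1, exp2

    def _config(self):
        system = default_system()
        return AnalysisConfig.model_validate({"system": system.model_dump()})

    def test_end_to_end_report(self, scenario_lib, ida):
        exp1, exp2 = self._bundle(scenario_lib, ida)
        report, results = workflow.run_workflow(self._config(), [exp1], [exp2])
        assert len(report) == 1
        row = report.iloc[0]
        for col in ["K1", "K2", "KI", "KII", "KI_II", "KII_I", "Kc",
                    "ddG_kJ_mol", "TdS_I", "TdS_II", "TdS_c"]:
            assert np.isfinite(row[col])
        # cooperative system from the generator: ddG must come out negative
        assert row["ddG_kJ_mol"] < 0
        assert "CaM Y II" in results["one_site"]

    def test_unpaired_two_site_rejected(self, scenario_lib, ida):
        exp1, exp2 = self._bundle(scenario_lib, ida)
        exp2_unpaired = workflow.ITCExperiment(exp2.label, exp2.design, exp2.series)
        with pytest.raises(ValueError, match="KII"):
            workflow.run_workflow(self._config(), [exp1], [exp2_unpaired])

    def test_report_regenerates_from_stored_results(self, tmp_path, scenario_lib, ida):
        exp1, exp2 = self._bundle(scenario_lib, ida)
        report, results = workflow.run_workflow(self._config(), [exp1], [exp2])
        path = tmp_path / "results.json"
        cio.write_results_json(results, path)
        regenerated = pd.DataFrame(cio.read_results_json(path)["report"])
        pd.testing.assert_frame_equal(
            regenerated, report.reset_index(drop=True), check_exact=True
        )


class TestCLI:
    def test_speciate(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "spec.csv"
        result = runner.invoke(cli.main, [
            "speciate", "--metal", "1e-5", "--peptide-total", "0", "--out", str(out),
        ])
        assert result.exit_code == 0, result.output
        df = pd.read_csv(out)
        assert {"species", "concentration_M"} <= set(df.columns)
        assert df.set_index("species").loc["M_free", "concentration_M"] == pytest.approx(1e-5)

    def test_simulate_then_fit_fluor(self, tmp_path):
        runner = CliRunner()
        prefix = tmp_path / "sim"
        r = runner.invoke(cli.main, [
            "simulate-fluor", "--scenario", "fluor/CaM Y II", "--replicates", "2",
            "--seed", "3", "--out", str(prefix),
        ])
        assert r.exit_code == 0, r.output
        files = sorted(tmp_path.glob("sim.rep*.csv"))
        assert len(files) == 2
        out = tmp_path / "fit.json"
        r = runner.invoke(cli.main, [
            "fit-fluor", "--model", "one-site", "--peptide-total", "1e-5",
            "--chelator-total", "5e-4", "--out", str(out),
            str(files[0]), str(files[1]),
        ])
        assert r.exit_code == 0, r.output
        record = cio.read_results_json(out)
        K1 = record["parameters"]["K1"]["value"]
        assert K1 == pytest.approx(3.7e6, rel=0.2)

    def test_derive_cli(self, tmp_path):
        runner = CliRunner()
        table = tmp_path / "macro.csv"
        pd.DataFrame([
            {"peptide": "CaM Y I-II", "pH": 6, "K1": 3.5e7, "K2": 7.4e6, "KII": 3.7e6},
        ]).to_csv(table, index=False)
        out = tmp_path / "derived.csv"
        r = runner.invoke(cli.main, ["derive", "--out", str(out), str(table)])
        assert r.exit_code == 0, r.output
        row = pd.read_csv(out).iloc[0]
        assert row["ddG_kJ_mol"] == pytest.approx(-2.0, abs=0.1)
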
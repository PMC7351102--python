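"""Results assembly, printed summary, plots, pipeline artifacts, CLI."""

import numpy as np
import pandas as pd
import pytest
import yaml
from click.testing import CliRunner

from gformula.cli import main as cli_main
from gformula.config import ConfigurationError
from gformula.pipeline import run_gformula, run_pipeline
from gformula.results import render_summary


@pytest.fixture(scope="module")
def toy_results(toy_dgp_mod, toy_table_mod):
    cfg = toy_dgp_mod.analysis_config(nsimul=2000, seed=3)
    return run_gformula(toy_table_mod, cfg)


@pytest.fixture(scope="module")
def toy_dgp_mod():
    from gformula.dgp import get_dgp
    return get_dgp("survival_toy", n=800)


@pytest.fixture(scope="module")
def toy_table_mod(toy_dgp_mod):
    from gformula.dgp import generate_dataset
    return generate_dataset(toy_dgp_mod, seed=42)


class TestRenderSummary:
    def test_legend_and_header_lines(self, toy_results):
        text = render_summary(toy_results)
        assert "PREDICTED RISK UNDER MULTIPLE INTERVENTIONS" in text
        assert "0\tNatural course" in text
        assert "1\tNever treat" in text
        assert "Sample size = 800, Monte Carlo sample size = 2000" in text
        assert "Number of bootstrap samples = 0" in text
        assert "Reference intervention = natural course (0)" in text

    def test_no_se_columns_without_bootstrap(self, toy_results):
        text = render_summary(toy_results)
        assert "SE" not in text
        assert "95% CI" not in text

    def test_idempotent(self, toy_results):
        assert render_summary(toy_results) == render_summary(toy_results)

    def test_natural_course_only_run(self, toy_dgp_mod, toy_table_mod):
        cfg = toy_dgp_mod.analysis_config(nsimul=500, interventions=[])
        res = run_gformula(toy_table_mod, cfg)
        assert res.legend == [(0, "Natural course")]
        assert set(res.table["intervention"]) == {0}


class TestResultsObject:
    def test_table_has_np_estimate_for_natural_course_only(self, toy_results):
        tab = toy_results.table
        nc = tab[tab.intervention == 0]
        other = tab[tab.intervention != 0]
        assert nc["np_estimate"].notna().all()
        assert other["np_estimate"].isna().all()

    def test_csv_roundtrip_preserves_numerics(self, toy_results, tmp_path):
        path = tmp_path / "results.csv"
        toy_results.to_csv(path)
        again = pd.read_csv(path, float_precision="round_trip")
        for col in ("estimate", "ratio", "difference"):
            np.testing.assert_array_equal(again[col].to_numpy(),
                                          toy_results.table[col].to_numpy())

    def test_model_summaries_cover_all_models(self, toy_results):
        models = set(toy_results.model_summaries["model"])
        assert {"L", "A", "outcome"} <= models
        assert (toy_results.model_summaries["se"] > 0).all()


class TestPlots:
    def test_panels_and_files(self, toy_results, tmp_path):
        from gformula.plots import plot_natural_course
        fig = plot_natural_course(toy_results, out_dir=tmp_path)
        visible = [ax for ax in fig.axes if ax.get_visible()]
        # risk panel + one per covariate
        assert len(visible) == 1 + len(toy_results.nc_parametric_cov_means.columns)
        assert (tmp_path / "natural_course.png").exists()

    def test_correctly_specified_run_agrees_with_np(self, toy_results):
        """The plotted parametric and nonparametric natural-course series
        should agree within Monte Carlo tolerance."""
        par = toy_results.nc_parametric_risk.to_numpy()
        npr = toy_results.np_benchmarks.risks.to_numpy()
        assert np.max(np.abs(par - npr)) < 0.05


class TestPipelineFiles:
    def _write_inputs(self, tmp_path, dgp, table, **cfg_extra):
        cfg = dict(dgp.config)
        cfg.update(cfg_extra)
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        data_path = tmp_path / "obs.csv"
        table.write_csv(data_path)
        return cfg_path, data_path

    def test_artifacts_written(self, toy_dgp_mod, toy_table_mod, tmp_path):
        cfg_path, data_path = self._write_inputs(tmp_path, toy_dgp_mod,
                                                 toy_table_mod, nsimul=300)
        out = tmp_path / "out"
        run_pipeline(cfg_path, data_path, out)
        for name in ("results.csv", "results.json", "models.csv",
                     "summary.txt", "natural_course.png"):
            assert (out / name).exists(), name

    def test_invalid_covtype_lists_allowed_values(self, toy_dgp_mod,
                                                  toy_table_mod, tmp_path):
        cfg_path, data_path = self._write_inputs(
            tmp_path, toy_dgp_mod, toy_table_mod,
            covtypes=["binary", "bogus"])
        with pytest.raises(ConfigurationError, match="binary"):
            run_pipeline(cfg_path, data_path, tmp_path / "out")

    def test_missing_data_file(self, toy_dgp_mod, toy_table_mod, tmp_path):
        cfg_path, _ = self._write_inputs(tmp_path, toy_dgp_mod, toy_table_mod)
        with pytest.raises(FileNotFoundError):
            run_pipeline(cfg_path, tmp_path / "nope.csv", tmp_path / "out")


class TestCli:
    def test_simulate_fixture_and_validate(self, tmp_path):
        runner = CliRunner()
        out_csv = tmp_path / "fixture.csv"
        r = runner.invoke(cli_main, ["simulate-fixture", "--dgp",
                                     "survival_toy", "--n", "50",
                                     "--seed", "1", "--out", str(out_csv)])
        assert r.exit_code == 0, r.output
        assert out_csv.exists()

        from gformula.dgp import get_dgp
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(get_dgp("survival_toy").config))
        r = runner.invoke(cli_main, ["validate", "--config", str(cfg_path),
                                     "--data", str(out_csv)])
        assert r.exit_code == 0, r.output
        assert "passed" in r.output

    def test_run_command_writes_artifacts(self, tmp_path):
        from gformula.dgp import generate_dataset, get_dgp
        dgp = get_dgp("survival_toy", n=300)
        table = generate_dataset(dgp, seed=2)
        data_path = tmp_path / "obs.csv"
        table.write_csv(data_path)
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(dgp.config))
        runner = CliRunner()
        r = runner.invoke(cli_main, [
            "run", "--config", str(cfg_path), "--data", str(data_path),
            "--out", str(tmp_path / "out"), "--nsimul", "300",
            "--seed", "3", "--no-plots"])
        assert r.exit_code == 0, r.output
        assert "PREDICTED RISK" in r.output
        assert (tmp_path / "out" / "results.csv").exists()

    def test_unknown_dgp_fails_cleanly(self, tmp_path):
        runner = CliRunner()
        r = runner.invoke(cli_main, ["simulate-fixture", "--dgp", "nope",
                                     "--out", str(tmp_path / "x.csv")])
        assert r.exit_code == 1
        assert "available" in r.output
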
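"""Loading, coding-rule validation, and horizon resolution."""

import numpy as np
import pandas as pd
import pytest

from gformula.config import ConfigurationError, OutcomeSpec, load_config
from gformula.data import (
    LongitudinalTable,
    load_table,
    resolve_horizon,
    validate_longitudinal_table,
)
from gformula.dgp import DGP_NAMES, generate_dataset, get_dgp


def _toy_config(**extra):
    raw = dict(
        id="id", time_name="t0", outcome_name="Y", outcome_type="survival",
        covnames=["L", "A"], covtypes=["binary", "binary"],
        covmodels=["L ~ lag1_L", "A ~ L"], ymodel="Y ~ A + L + t0",
        basecovs=["B0"],
    )
    raw.update(extra)
    return load_config(raw)


class TestLoadTable:
    def test_blank_outcomes_stay_missing(self, tiny_survival_frame, tmp_path):
        path = tmp_path / "obs.csv"
        tiny_survival_frame.to_csv(path, index=False)
        table = load_table(path, _toy_config())
        assert len(table.data) == len(tiny_survival_frame)
        b_last = table.data[(table.data.id == "b") & (table.data.t0 == 1)]
        assert b_last["Y"].isna().all()
        assert table.n == 3
        assert table.K == 3

    def test_missing_column_is_named(self, tiny_survival_frame, tmp_path):
        path = tmp_path / "obs.csv"
        tiny_survival_frame.drop(columns=["A"]).to_csv(path, index=False)
        with pytest.raises(ConfigurationError, match="A"):
            load_table(path, _toy_config())

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("id,t0,L,A,B0,Y\n")
        with pytest.raises(ValueError, match="no rows"):
            load_table(path, _toy_config())

    def test_non_integer_time_rejected(self, tiny_survival_frame, tmp_path):
        df = tiny_survival_frame.copy()
        df["t0"] = df["t0"].astype(float)
        df.loc[0, "t0"] = 0.5
        path = tmp_path / "obs.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="non-integer"):
            load_table(path, _toy_config())

    def test_roundtrip_preserves_table(self, toy_table, tmp_path):
        path = tmp_path / "round.csv"
        toy_table.write_csv(path)
        again = load_table(path, load_config(dict(
            id="id", time_name="t0", outcome_name="Y", outcome_type="survival",
            covnames=["L", "A"], covtypes=["binary", "binary"],
            covmodels=["L ~ lag1_L", "A ~ L"], ymodel="Y ~ A + L + t0",
        )))
        pd.testing.assert_frame_equal(toy_table.data, again.data,
                                      check_dtype=False)


class TestValidation:
    @pytest.mark.parametrize("name", DGP_NAMES)
    def test_generated_tables_pass(self, name):
        dgp = get_dgp(name, n=300)
        table = generate_dataset(dgp, seed=3)
        ospec = dgp.analysis_config().outcome
        report = validate_longitudinal_table(table, ospec)
        assert report.passed, str(report)

    def test_time_gap_flagged(self, tiny_survival_frame):
        df = tiny_survival_frame.copy()
        df.loc[(df.id == "c") & (df.t0 == 1), "t0"] = 9  # create a gap
        table = LongitudinalTable(df, "id", "t0", ["L", "A"], ["B0"], "Y")
        report = validate_longitudinal_table(
            table, OutcomeSpec("survival", "Y"))
        assert not report.passed
        assert any(v["rule"] == "non-consecutive time index"
                   for v in report.violations)

    def test_records_after_event_flagged(self, tiny_survival_frame):
        extra = pd.DataFrame([{"id": "a", "t0": 3, "L": 0.0, "A": 0.0,
                               "B0": 1.5, "Y": 0.0}])
        df = pd.concat([tiny_survival_frame, extra], ignore_index=True)
        table = LongitudinalTable(df, "id", "t0", ["L", "A"], ["B0"], "Y")
        report = validate_longitudinal_table(
            table, OutcomeSpec("survival", "Y"))
        assert any(v["rule"] == "records after event"
                   for v in report.violations)

    def test_varying_baseline_covariate_flagged(self, tiny_survival_frame):
        df = tiny_survival_frame.copy()
        df.loc[(df.id == "c") & (df.t0 == 2), "B0"] = 99.0
        table = LongitudinalTable(df, "id", "t0", ["L", "A"], ["B0"], "Y")
        report = validate_longitudinal_table(
            table, OutcomeSpec("survival", "Y"))
        assert any(v["rule"] == "baseline covariate varies"
                   for v in report.violations)

    def test_outcome_present_at_competing_event_flagged(self):
        df = pd.DataFrame({
            "id": [1, 1], "t0": [0, 1], "L": [0.0, 1.0], "A": [0.0, 0.0],
            "Y": [0.0, 0.0], "D": [0.0, 1.0],
        })
        table = LongitudinalTable(df, "id", "t0", ["L", "A"], [], "Y", "D")
        report = validate_longitudinal_table(
            table, OutcomeSpec("survival", "Y", compevent_name="D"))
        assert any(v["rule"] == "outcome not missing at competing event"
                   for v in report.violations)

    def test_survival_row_counts_match_event_times(self, toy_table):
        # per-subject row count reconstructs as (event-or-last interval) + 1
        for _, g in toy_table.subject_groups():
            y = g["Y"].to_numpy()
            events = np.flatnonzero(y == 1)
            if events.size:
                assert events[0] == len(g) - 1


class TestHorizon:
    def test_defaults_to_K_plus_1(self, toy_table):
        assert resolve_horizon(toy_table, OutcomeSpec("survival", "Y")) == 3

    def test_user_override(self, toy_table):
        ospec = OutcomeSpec("survival", "Y")
        assert resolve_horizon(toy_table, ospec, time_points=2) == 2

    @pytest.mark.parametrize("bad", [0, -1, 99])
    def test_out_of_range_rejected(self, toy_table, bad):
        with pytest.raises(ConfigurationError):
            resolve_horizon(toy_table, OutcomeSpec("survival", "Y"),
                            time_points=bad)


class TestConfig:
    def test_compevent_requires_modeling_mode(self):
        with pytest.raises(ConfigurationError, match="censoring"):
            OutcomeSpec("survival", "Y", compevent_name="D",
                        treat_compevent_as_censoring=True)

    def test_compevent_only_for_survival(self):
        with pytest.raises(ConfigurationError):
            OutcomeSpec("binary_eof", "Y", compevent_name="D")

    def test_unknown_covtype_lists_allowed(self):
        with pytest.raises(ConfigurationError, match="binary"):
            _toy_config(covtypes=["binary", "bogus"])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ConfigurationError, match="same length"):
            _toy_config(covtypes=["binary"])

    def test_compevent_model_without_column(self):
        with pytest.raises(ConfigurationError, match="compevent_model"):
            _toy_config(compevent_model="D ~ A")

    def test_yaml_roundtrip(self, tmp_path):
        import yaml
        raw = dict(id="id", time_name="t0", outcome_name="Y",
                   outcome_type="survival", covnames=["L"],
                   covtypes=["binary"], covmodels=["L ~ lag1_L"],
                   ymodel="Y ~ L")
        path = tmp_path / "cfg.yaml"
        path.write_text(yaml.safe_dump(raw))
        cfg = load_config(path)
        assert cfg.covnames == ["L"]
        assert cfg.outcome.outcome_type == "survival"
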
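"""File readers/writers, protocol validation, pipeline contracts."""

import json

import numpy as np
import pandas as pd
import pytest

import anwc
from anwc import synthetic_athlete as sa
from anwc.core_data_io import (
    BreathDialect,
    BreathSeries,
    PowerSeries,
    SessionProtocol,
    read_breath_series,
    read_power_series,
    read_protocol,
    write_breath_series,
    write_power_series,
    write_protocol,
)


class TestPowerReader:
    def write(self, tmp_path, df):
        p = tmp_path / "power.csv"
        df.to_csv(p, index=False)
        return p

    def test_identity_read(self, tmp_path):
        df = pd.DataFrame({"t": np.arange(180), "po": np.linspace(300, 400, 180)})
        series = read_power_series(self.write(tmp_path, df))
        assert len(series) == 180
        np.testing.assert_allclose(series.po, df["po"])

    def test_shuffled_rows_rejected(self, tmp_path):
        df = pd.DataFrame({"t": [0, 2, 1], "po": [300.0, 302, 301]})
        with pytest.raises(ValueError, match="non-monotone"):
            read_power_series(self.write(tmp_path, df))

    def test_single_missing_second_interpolated(self, tmp_path):
        df = pd.DataFrame({"t": [0, 1, 3], "po": [299.0, 300.0, 302.0]})
        series = read_power_series(self.write(tmp_path, df))
        assert len(series) == 4
        assert series.po[2] == pytest.approx(301.0)

    def test_long_gap_rejected(self, tmp_path):
        df = pd.DataFrame({"t": [0, 1, 6], "po": [300.0, 300, 300]})
        with pytest.raises(ValueError, match="gap"):
            read_power_series(self.write(tmp_path, df))

    def test_missing_column_rejected(self, tmp_path):
        df = pd.DataFrame({"t": [0, 1], "watts": [1.0, 2.0]})
        with pytest.raises(ValueError, match="missing column"):
            read_power_series(self.write(tmp_path, df))


class TestBreathReader:
    def test_native_spacing_read(self, tmp_path):
        df = pd.DataFrame(
            {
                "t": 5.0 + 10 * np.arange(18),
                "vo2": np.full(18, 3.0),
                "vco2": np.full(18, 2.7),
                "ve": np.full(18, 80.0),
            }
        )
        p = tmp_path / "breath.csv"
        df.to_csv(p, index=False)
        series = read_breath_series(p)
        assert len(series) == 18
        np.testing.assert_allclose(series.rer, 0.9)

    def test_ml_per_min_dialect_converts(self, tmp_path):
        df = pd.DataFrame(
            {
                "t": [5.0, 15.0],
                "vo2": [3000.0, 3100.0],
                "vco2": [2700.0, 2800.0],
                "ve": [80.0, 81.0],
            }
        )
        p = tmp_path / "breath.csv"
        df.to_csv(p, index=False)
        series = read_breath_series(p, BreathDialect(gas_units="ml/min"))
        np.testing.assert_allclose(series.vo2, [3.0, 3.1])

    def test_negative_gas_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"t": [5.0, 15.0], "vo2": [-0.1, 3.0], "vco2": [2.0, 2.0], "ve": [80, 80]}
        )
        p = tmp_path / "breath.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="negative vo2"):
            read_breath_series(p)

    def test_wrong_spacing_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"t": [5.0, 20.0], "vo2": [3.0, 3.0], "vco2": [2.7, 2.7], "ve": [80, 80]}
        )
        p = tmp_path / "breath.csv"
        df.to_csv(p, index=False)
        with pytest.raises(ValueError, match="spacing"):
            read_breath_series(p)


class TestRoundTrips:
    def test_power_round_trip_full_precision(self, tmp_path, rng):
        series = PowerSeries(
            t=np.arange(200.0),
            po=rng.uniform(0, 700, 200),
            cadence=rng.uniform(60, 130, 200),
        )
        write_power_series(series, tmp_path / "p.csv")
        back = read_power_series(tmp_path / "p.csv")
        np.testing.assert_array_equal(back.po, series.po)
        np.testing.assert_array_equal(back.cadence, series.cadence)

    def test_breath_round_trip_full_precision(self, tmp_path, rng):
        series = BreathSeries(
            t=5.0 + 10 * np.arange(30),
            vo2=rng.uniform(0.3, 5, 30),
            vco2=rng.uniform(0.3, 5, 30),
            ve=rng.uniform(10, 150, 30),
        )
        write_breath_series(series, tmp_path / "b.csv")
        back = read_breath_series(tmp_path / "b.csv")
        np.testing.assert_array_equal(back.vo2, series.vo2)
        np.testing.assert_array_equal(back.vco2, series.vco2)

    def test_protocol_round_trip(self, tmp_path):
        proto = sa.default_protocol(sa.SyntheticAthleteParams())
        write_protocol(proto, tmp_path / "proto.yaml")
        assert read_protocol(tmp_path / "proto.yaml") == proto


class TestProtocolValidation:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="non-overlapping"):
            SessionProtocol(
                body_mass=78.5,
                stage_windows=((0, 240), (230, 470)),
                tt_window=(500, 680),
            )

    def test_session_requires_coverage(self):
        proto = SessionProtocol(body_mass=78.5, tt_window=(0.0, 180.0))
        short_breath = BreathSeries(
            t=5.0 + 10 * np.arange(10),  # covers only 100 s
            vo2=np.full(10, 3.0),
            vco2=np.full(10, 2.7),
            ve=np.full(10, 80.0),
        )
        power = PowerSeries(t=np.arange(180.0), po=np.full(180, 400.0))
        with pytest.raises(ValueError, match="does not cover"):
            anwc.AthleteSession(id="x", protocol=proto, breath=short_breath, power=power)


class TestPipelineContracts:
    def test_tt_only_session_runs_cp_model_only(self):
        session, _ = sa.simulate_tt_allout(seed=11)
        res = anwc.run_pipeline(session)
        assert list(res.decompositions) == ["CP_3AO"]
        assert set(res.errors) == {"7+Y_LIN", "7-Y_LIN", "GE_LAST"}
        assert res.decompositions["CP_3AO"].cp > 0

    def test_repeated_runs_byte_identical(self):
        session, _ = sa.simulate_full_session(seed=5)
        out = [
            json.dumps(anwc.run_pipeline(session).summary_dict(), sort_keys=True)
            for _ in range(2)
        ]
        assert out[0] == out[1]

    def test_summary_rows_carry_units(self, noise_free_result):
        summary = noise_free_result.summary
        assert set(summary.columns) == {"athlete", "model", "quantity", "value", "units"}
        assert (summary["units"].str.len() > 0).all()

    def test_result_write_outputs(self, tmp_path, noise_free_result):
        noise_free_result.write(tmp_path)
        assert (tmp_path / "summary.json").exists()
        assert (tmp_path / "results.csv").exists()
        data = json.loads((tmp_path / "summary.json").read_text())
        assert set(data["models"]) == {"7+Y_LIN", "7-Y_LIN", "GE_LAST", "CP_3AO"}
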
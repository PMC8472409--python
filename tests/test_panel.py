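import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import panelkink as pk
from panelkink.exceptions import (DataIntegrityError, ParseError, SchemaError)
from tests.conftest import make_panel


class TestKinkTransform:
    @pytest.mark.parametrize("q, gamma, expected", [
        (32.0, 30.0, 2.0),     # above-threshold linear excess
        (28.0, 30.0, 0.0),     # below threshold
        (30.0, 30.0, 0.0),     # continuity at the kink
    ])
    def test_values(self, q, gamma, expected):
        assert pk.kink_transform(q, gamma) == expected

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pk.kink_transform(np.nan, 30.0)
        with pytest.raises(ValueError):
            pk.kink_transform(25.0, np.inf)

    @settings(max_examples=200, derandomize=True)
    @given(q=st.floats(-100, 100), q2=st.floats(-100, 100), g=st.floats(-100, 100))
    def test_piecewise_linear_and_lipschitz(self, q, q2, g):
        v = pk.kink_transform(q, g)
        assert v == (q - g if q >= g else 0.0)
        assert abs(v - pk.kink_transform(q2, g)) <= abs(q - q2) + 1e-9


class TestFirstDifference:
    def test_hand_arithmetic(self, toy_panel):
        rows = pk.first_difference(toy_panel).set_index("id")
        assert rows.loc["a", "d_hours"] == 4.0
        assert rows.loc["a", "d_bmi"] == 2.5
        assert rows.loc["a", "d_x1"] == 1.0
        assert rows.loc["b", "d_hours"] == -2.0
        assert (rows.loc["c", ["d_hours", "d_bmi", "d_x1"]] == 0).all()
        assert rows.loc["a", "bmi_1"] == 24.0 and rows.loc["a", "bmi_2"] == 26.5

    def test_duplicated_period_rejected(self):
        recs = [dict(id="a", period=1, hours=30, bmi=24, x1=0),
                dict(id="a", period=1, hours=31, bmi=25, x1=0)]
        with pytest.raises(DataIntegrityError):
            make_panel(recs)

    def test_unbalanced_rejected(self):
        recs = [dict(id="a", period=1, hours=30, bmi=24, x1=0)]
        with pytest.raises(DataIntegrityError):
            pk.first_difference(make_panel(recs))

    def test_inverse_recovers_levels(self):
        rng = np.random.default_rng(42)
        recs = []
        for i in range(25):
            for period in (1, 2):
                recs.append(dict(id=i, period=period, hours=rng.normal(35, 8),
                                 bmi=rng.uniform(18, 40), x1=rng.normal()))
        panel = make_panel(recs)
        rows = pk.first_difference(panel).set_index("id")
        df = panel.df
        p1 = df[df.period == 1].set_index("id")
        p2 = df[df.period == 2].set_index("id")
        np.testing.assert_allclose(p1["hours"] + rows["d_hours"], p2["hours"], rtol=1e-12)
        np.testing.assert_allclose(p1["bmi"] + rows["d_bmi"], p2["bmi"], rtol=1e-12)


class TestSampleFilters:
    def _panel(self, extra):
        base = [dict(id="keep", period=p, hours=35, bmi=25, x1=0) for p in (1, 2)]
        return make_panel(base + extra)

    @pytest.mark.parametrize("hours, kept", [(9.0, False), (10.0, True),
                                             (70.0, True), (70.5, False)])
    def test_hours_bounds_inclusive(self, hours, kept):
        extra = [dict(id="x", period=1, hours=hours, bmi=25, x1=0),
                 dict(id="x", period=2, hours=40, bmi=25, x1=0)]
        filtered, audit = pk.apply_sample_filters(self._panel(extra))
        assert ("x" in set(filtered.df["id"])) is kept
        audit.validate()

    def test_pregnancy_drops_both_records(self):
        extra = [dict(id="p", period=1, hours=35, bmi=25, x1=0, pregnant=False),
                 dict(id="p", period=2, hours=35, bmi=25, x1=0, pregnant=True)]
        filtered, _ = pk.apply_sample_filters(self._panel(extra))
        assert "p" not in set(filtered.df["id"])

    def test_self_employed_period1_dropped_but_period2_ok(self):
        extra = [dict(id="s1", period=1, hours=35, bmi=25, x1=0, employment_status="self_employed"),
                 dict(id="s1", period=2, hours=35, bmi=25, x1=0),
                 dict(id="s2", period=1, hours=35, bmi=25, x1=0),
                 dict(id="s2", period=2, hours=35, bmi=25, x1=0, employment_status="self_employed")]
        filtered, _ = pk.apply_sample_filters(self._panel(extra))
        ids = set(filtered.df["id"])
        assert "s1" not in ids and "s2" in ids

    def test_not_working_dropped(self):
        extra = [dict(id="n", period=1, hours=0, bmi=25, x1=0, employment_status="not_working"),
                 dict(id="n", period=2, hours=35, bmi=25, x1=0)]
        filtered, _ = pk.apply_sample_filters(self._panel(extra))
        assert "n" not in set(filtered.df["id"])

    def test_audit_chain_consistent(self):
        rng = np.random.default_rng(3)
        recs = []
        for i in range(40):
            for period in (1, 2):
                recs.append(dict(
                    id=i, period=period, hours=float(rng.integers(5, 80)),
                    bmi=25.0, x1=0.0,
                    employment_status=rng.choice(["employee", "self_employed", "not_working"]),
                    pregnant=bool(rng.random() < 0.2)))
        _, audit = pk.apply_sample_filters(make_panel(recs))
        audit.validate()
        frame = audit.to_frame()
        assert list(frame["rule"])[0] == "balanced_panel"
        assert (frame["n_after"] == frame["n_before"] - frame["n_excluded"]).all()


class TestCsvIO:
    def test_round_trip(self, toy_panel, tmp_path):
        path = tmp_path / "panel.csv"
        pk.write_panel_csv(toy_panel, path)
        back = pk.read_panel_csv(path, ["x1"])
        pd.testing.assert_frame_equal(
            back.df.sort_values(["id", "period"]).reset_index(drop=True),
            toy_panel.df.sort_values(["id", "period"]).reset_index(drop=True),
            check_dtype=False)

    def test_instruments_round_trip(self, toy_instruments, tmp_path):
        path = tmp_path / "inst.csv"
        pk.write_instruments_csv(toy_instruments, path)
        back = pk.read_instruments_csv(path)
        pd.testing.assert_frame_equal(back.df, toy_instruments.df, check_dtype=False)

    def test_missing_column_is_schema_error(self, toy_panel, tmp_path):
        path = tmp_path / "panel.csv"
        toy_panel.df.drop(columns=["bmi"]).to_csv(path, index=False)
        with pytest.raises(SchemaError, match="bmi"):
            pk.read_panel_csv(path, ["x1"])

    def test_unparseable_cell_cites_row(self, toy_panel, tmp_path):
        path = tmp_path / "panel.csv"
        df = toy_panel.df.copy()
        df["hours"] = df["hours"].astype(object)
        df.loc[2, "hours"] = "abc"
        df.to_csv(path, index=False)
        with pytest.raises(ParseError, match="line 4"):
            pk.read_panel_csv(path, ["x1"])
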
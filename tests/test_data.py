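"""Long-table I/O and interval-pairing behaviour."""

import io

import numpy as np
import pandas as pd
import pytest

from quadhaz import (LongitudinalRecords, load_long_table, prepare_data,
                     write_long_table)
from quadhaz.errors import FormatError, ParseError, ValidationError

from conftest import make_records


TABLE1_STYLE = """ID,IndicatorDeath,Age,AgeNext,DBP,BMI
10,0,30,32,80,25.00
10,0,32,34,80,26.6
10,0,34,35.34,NA,NA
20,0,30,38,77,32.40
20,0,38,40,94,31.92
20,1,40,40.56,88,32.89
"""


class TestLoad:
    def test_table1_layout(self):
        rec = load_long_table(io.StringIO(TABLE1_STYLE))
        assert rec.k == 2
        assert rec.covariate_names == ["DBP", "BMI"]
        s10 = rec.frame[rec.frame["id"] == 10]
        assert len(s10) == 3
        assert (s10["event"] == 0).all()          # subject 10 censored
        assert np.isnan(s10["DBP"].iloc[-1])
        assert rec.n_events == 1                   # subject 20 died

    def test_covariate_subset(self):
        rec = load_long_table(io.StringIO(TABLE1_STYLE), covariate_names=["BMI"])
        assert rec.covariate_names == ["BMI"]
        assert rec.k == 1

    def test_unknown_covariate_errors(self):
        with pytest.raises(FormatError, match="SBP"):
            load_long_table(io.StringIO(TABLE1_STYLE), covariate_names=["SBP"])

    def test_header_only_file(self):
        rec = load_long_table(io.StringIO("ID,Death,Age,AgeNext,DBP\n"))
        assert len(rec) == 0 and rec.k == 1
        assert rec.covariate_names == ["DBP"]

    def test_too_few_columns(self):
        with pytest.raises(FormatError):
            load_long_table(io.StringIO("ID,Death,Age\n1,0,30\n"))

    def test_non_numeric_age_reports_row(self):
        txt = "ID,D,Age,AgeNext,DBP\n1,0,30,31,80\n1,0,thirty-one,32,81\n"
        with pytest.raises(ParseError, match="row 1"):
            load_long_table(io.StringIO(txt))

    def test_duplicate_visit_rejected(self):
        txt = "ID,D,Age,AgeNext,DBP\n1,0,30,31,80\n1,0,30,31,81\n"
        with pytest.raises(ValidationError, match="duplicate"):
            load_long_table(io.StringIO(txt))

    def test_inverted_interval_dropped_with_warning(self):
        txt = "ID,D,Age,AgeNext,DBP\n1,0,30,29,80\n2,0,30,31,80\n"
        with pytest.warns(UserWarning, match="t2 > t1"):
            rec = load_long_table(io.StringIO(txt))
        assert len(rec) == 1

    def test_event_before_last_rejected(self):
        txt = "ID,D,Age,AgeNext,DBP\n1,1,30,31,80\n1,0,31,32,81\n"
        with pytest.raises(ValidationError, match="before the final"):
            load_long_table(io.StringIO(txt))


class TestRoundTrip:
    def test_write_then_load_identical(self, tmp_path):
        rec = make_records({
            1: ([30.0, 31.5, 33.2], 35.7, 1, [80.1234567890123, 81.0, 79.5]),
            2: ([40.0, 41.0], 44.0, 0, [90.0, np.nan]),
        })
        path = tmp_path / "cohort.csv"
        write_long_table(rec, path)
        back = load_long_table(str(path))
        assert back.equals(rec)

    def test_empty_records_header_only(self, tmp_path):
        rec = LongitudinalRecords(
            frame=pd.DataFrame({c: pd.Series(dtype=float)
                                for c in ["id", "event", "t1", "t2", "DBP"]}),
            covariate_names=["DBP"])
        path = tmp_path / "empty.csv"
        write_long_table(rec, path)
        assert path.read_text().strip() == "ID,IndicatorDeath,Age,AgeNext,DBP"

    def test_column_schema_k2(self, tmp_path):
        rec = make_records({1: ([30.0], 31.0, 0, [[80.0, 25.0]])},
                           covariate_names=("DBP", "BMI"))
        path = tmp_path / "two.csv"
        write_long_table(rec, path)
        header = path.read_text().splitlines()[0].split(",")
        assert header == ["ID", "IndicatorDeath", "Age", "AgeNext", "DBP", "BMI"]


class TestPrepare:
    def test_midpoint_interpolation(self):
        rec = make_records({1: ([30.0, 32.0], 33.0, 0, [80.0, 82.0])})
        fixed, _ = prepare_data(rec, interval=1.0)
        f = fixed.frame
        np.testing.assert_allclose(f["t1"], [30, 31, 32])
        np.testing.assert_allclose(f["t2"], [31, 32, 33])
        np.testing.assert_allclose(f["DBP"], [80.0, 81.0, 82.0])
        np.testing.assert_allclose(f["DBP.next"][:2], [81.0, 82.0])
        assert np.isnan(f["DBP.next"].iloc[-1])

    def test_trailing_missing_pair_excluded_without_impute(self):
        # DBP missing at the final visit: that terminal pair is dropped
        rec = make_records({10: ([30.0, 32.0, 34.0], 35.34, 0,
                                 [80.0, 80.0, np.nan])})
        _, arb = prepare_data(rec, interval=1.0, impute=False)
        assert len(arb) == 2
        assert arb.frame["t1"].tolist() == [30.0, 32.0]

    def test_interior_gap_imputed_linearly(self):
        rec = make_records({1: ([30.0, 31.0, 32.0], 33.0, 0,
                                [80.0, np.nan, 84.0])})
        _, arb = prepare_data(rec, interval=1.0, impute=True)
        assert arb.frame["DBP"].tolist() == [80.0, 82.0, 84.0]
        _, arb_raw = prepare_data(rec, interval=1.0, impute=False)
        assert len(arb_raw) == 2  # the NaN row is dropped un-imputed

    def test_exact_grid_fixed_equals_arbitrary(self):
        rec = make_records({
            1: ([30.0, 31.0, 32.0], 33.0, 0, [80.0, 81.0, 82.5]),
            2: ([45.0, 46.0], 47.0, 1, [70.0, 71.0]),
        })
        fixed, arb = prepare_data(rec, interval=1.0)
        pd.testing.assert_frame_equal(fixed.frame, arb.frame)

    def test_events_preserved(self):
        rec = make_records({
            1: ([30.0, 32.0], 34.5, 1, [80.0, 82.0]),
            2: ([30.0, 31.0], 32.0, 0, [75.0, 76.0]),
            3: ([50.0], 51.0, 1, [60.0]),
        })
        fixed, arb = prepare_data(rec, interval=1.0)
        assert int(fixed.frame["case"].sum()) == 2
        assert int(arb.frame["case"].sum()) == 2

    def test_fixed_interval_invariant(self):
        rec = make_records({
            1: ([30.0, 31.7, 33.1], 34.9, 1, [80.0, 81.0, 82.0]),
            2: ([41.2, 42.9], 44.0, 0, [75.0, 76.0]),
        })
        fixed, _ = prepare_data(rec, interval=1.0)
        dt = fixed.interval_lengths()
        assert np.max(np.abs(dt - 1.0)) <= 1e-9

    def test_all_missing_subject_dropped_with_warning(self):
        rec = make_records({1: ([30.0, 31.0], 32.0, 0, [np.nan, np.nan])})
        with pytest.warns(UserWarning, match="missing"):
            fixed, arb = prepare_data(rec, interval=1.0)
        assert len(fixed) == 0 and len(arb) == 0

    def test_nonpositive_interval_rejected(self):
        rec = make_records({1: ([30.0, 31.0], 32.0, 0, [80.0, 81.0])})
        with pytest.raises(ValueError, match="interval"):
            prepare_data(rec, interval=0.0)
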
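"""Latin hypercube sampling, experimental-range computation and calibration
filtering."""

import numpy as np
import pandas as pd
import pytest

from repolpop.population import (CONDUCTANCE_COLUMNS, CalibrationRanges,
                                 OutlierRule, SamplingSpec, calibrate,
                                 compute_experimental_ranges, lhs_sample,
                                 load_population, save_population)


class TestLhsSample:
    def test_stratification_one_sample_per_stratum(self):
        df = lhs_sample(SamplingSpec(4, seed=3))
        for col in CONDUCTANCE_COLUMNS:
            strata = np.floor(df[col] / 0.5).astype(int).clip(upper=3)
            assert sorted(strata) == [0, 1, 2, 3]

    def test_seed_reproducibility(self):
        a = lhs_sample(SamplingSpec(25, seed=11))
        b = lhs_sample(SamplingSpec(25, seed=11))
        pd.testing.assert_frame_equal(a, b)
        c = lhs_sample(SamplingSpec(25, seed=12))
        assert not a.drop(columns="model_id").equals(c.drop(columns="model_id"))

    def test_large_sample_mean_matches_uniform_moments(self):
        # U(0,2): mean 1, SD = 2/sqrt(12); LHS variance is below iid, so the
        # iid bound 2*SD/sqrt(n) is conservative
        n = 10_000
        df = lhs_sample(SamplingSpec(n, seed=0))
        bound = 2.0 * (2.0 / np.sqrt(12.0)) / np.sqrt(n)
        for col in CONDUCTANCE_COLUMNS:
            assert abs(df[col].mean() - 1.0) < bound

    def test_custom_range_respected(self):
        spec = SamplingSpec(16, ranges={"g_kr": (0.5, 1.5)}, seed=2)
        df = lhs_sample(spec)
        assert df["g_kr"].between(0.5, 1.5).all()
        assert df["g_na"].max() > 1.5  # default range still 0-2

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SamplingSpec(0)
        with pytest.raises(ValueError):
            SamplingSpec(4, ranges={"g_kr": (1.0, 0.5)})

    def test_per_dimension_seeding_is_stable(self):
        """Each dimension's draws depend only on (seed, dimension), so the
        same column is produced regardless of the others."""
        full = lhs_sample(SamplingSpec(50, seed=7))
        again = lhs_sample(SamplingSpec(50, seed=7,
                                        ranges={"g_nak": (0.0, 1.0)}))
        # changing g_nak's range must not reshuffle g_na's column
        np.testing.assert_array_equal(full["g_na"], again["g_na"])


class TestExperimentalRanges:
    def test_default_rule_excludes_exactly_planted_outliers(self, cohort):
        ranges, excluded = compute_experimental_ranges(cohort)
        assert len(excluded) == 3
        assert ranges.intervals["apd90"][1] < 543.0
        assert ranges.intervals["vm_time"][1] < 26.0

    def test_identical_rows_give_degenerate_ranges(self):
        row = {"recording_id": "r0", "vm_peak": 30.0, "vm_time": 5.0,
               "apd40": 200.0, "apd50": 230.0, "apd90": 290.0,
               "triangulation": 90.0, "rmp": -85.0}
        df = pd.DataFrame([{**row, "recording_id": f"r{i}"} for i in range(4)])
        ranges, excluded = compute_experimental_ranges(df)
        assert excluded == []
        for lo, hi in ranges.intervals.values():
            assert lo == hi

    def test_hand_computed_toy_table(self):
        vals = {"vm_peak": [30, 31, 29, 35, 28],
                "vm_time": [4, 6, 5, 7, 3],
                "apd40": [180, 190, 170, 200, 175],
                "apd50": [200, 210, 190, 220, 195],
                "apd90": [260, 280, 250, 300, 255],
                "triangulation": [80, 90, 80, 100, 80],
                "rmp": [-84, -86, -83, -88, -85]}
        df = pd.DataFrame(vals)
        df.insert(0, "recording_id", [f"r{i}" for i in range(5)])
        ranges, _ = compute_experimental_ranges(df)
        assert ranges.intervals["apd90"] == (250.0, 300.0)
        assert ranges.intervals["rmp"] == (-88.0, -83.0)
        assert ranges.intervals["vm_time"] == (3.0, 7.0)

    def test_all_excluded_is_an_error(self):
        df = pd.DataFrame({"recording_id": ["a", "b"],
                           "apd90": [600.0, 700.0], "vm_time": [5.0, 6.0],
                           "vm_peak": [30.0, 31.0], "apd40": [1, 1],
                           "apd50": [2, 2], "triangulation": [1, 1],
                           "rmp": [-85, -85]})
        with pytest.raises(ValueError):
            compute_experimental_ranges(df)


def _bm_row(model_id, ranges, where="inside"):
    row = {"model_id": model_id}
    for name, (lo, hi) in ranges.intervals.items():
        mid = 0.5 * (lo + hi)
        row[name] = {"inside": mid, "min": lo, "above": hi + abs(hi) * 0.1 + 1.0
                     }[where]
    return row


class TestCalibrate:
    def test_inclusive_bounds(self, cal_ranges):
        table = pd.DataFrame([_bm_row("at_min", cal_ranges, "min")])
        assert calibrate(table, cal_ranges) == ["at_min"]

    def test_one_biomarker_above_max_rejects(self, cal_ranges):
        row = _bm_row("bad", cal_ranges, "inside")
        row["apd90"] = cal_ranges.intervals["apd90"][1] + 1.0
        assert calibrate(pd.DataFrame([row]), cal_ranges) == []

    def test_inside_accepts_outside_rejects(self, cal_ranges):
        inside = [_bm_row(f"in{i}", cal_ranges, "inside") for i in range(5)]
        outside = [_bm_row(f"out{i}", cal_ranges, "above") for i in range(5)]
        acc = calibrate(pd.DataFrame(inside + outside), cal_ranges)
        assert acc == [f"in{i}" for i in range(5)]

    def test_nan_biomarkers_rejected(self, cal_ranges):
        row = _bm_row("nan", cal_ranges, "inside")
        row["apd50"] = np.nan
        assert calibrate(pd.DataFrame([row]), cal_ranges) == []

    def test_monotone_in_ranges(self, cal_ranges):
        """Widening every range never removes an accepted model."""
        rng = np.random.default_rng(5)
        rows = []
        for i in range(30):
            row = {"model_id": f"m{i}"}
            for name, (lo, hi) in cal_ranges.intervals.items():
                w = hi - lo
                row[name] = lo + rng.uniform(-0.5, 1.5) * w
            rows.append(row)
        table = pd.DataFrame(rows)
        acc = set(calibrate(table, cal_ranges))
        acc_wide = set(calibrate(table, cal_ranges.widened(0.5)))
        assert acc <= acc_wide


class TestIO:
    def test_population_round_trip(self, tmp_path):
        df = lhs_sample(SamplingSpec(8, seed=1))
        path = tmp_path / "pop.csv"
        save_population(df, path)
        back = load_population(path)
        pd.testing.assert_frame_equal(df, back)

    def test_column_mapping_for_foreign_tables(self, tmp_path):
        df = lhs_sample(SamplingSpec(4, seed=1))
        foreign = df.rename(columns={"g_kr": "GKr_scaling"})
        path = tmp_path / "foreign.csv"
        foreign.to_csv(path, index=False)
        back = load_population(path, column_map={"GKr_scaling": "g_kr"})
        np.testing.assert_allclose(back["g_kr"], df["g_kr"], rtol=1e-14)
        with pytest.raises(ValueError):
            load_population(path)

    def test_ranges_round_trip(self, cal_ranges, tmp_path):
        path = tmp_path / "ranges.csv"
        cal_ranges.save_csv(path)
        back = CalibrationRanges.load_csv(path)
        assert back.intervals == cal_ranges.intervals
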
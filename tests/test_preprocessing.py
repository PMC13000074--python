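"""Preprocessing contracts: aggregation rules, forward-fill cap, filters,
imputation, normalization, labels, and the cohort split."""

import numpy as np
import pandas as pd
import pytest

from phenoguide.features import default_feature_specs
from phenoguide.preprocessing import (
    NormalizationStats,
    aggregate_windows,
    compute_stats,
    derive_labels,
    filter_missingness,
    forward_fill,
    impute_and_flag,
    normalize,
    remove_outliers,
    split_cohort,
)
from .conftest import make_admissions, make_events

SPECS = default_feature_specs()
ADM1 = make_admissions([(0, 24.0, 60.0, 80.0, 170.0, 1, 0)])


class TestRemoveOutliers:
    def test_bound_violation_dropped_and_counted(self):
        ev = make_events([(0, 1.0, "heart_rate", 300.0), (0, 2.0, "heart_rate", 80.0)])
        out, counts = remove_outliers(ev, SPECS)
        assert len(out) == 1 and out.iloc[0]["value"] == 80.0
        assert counts["heart_rate"] == 1

    def test_bounds_are_inclusive(self):
        ev = make_events([(0, 1.0, "heart_rate", 20.0), (0, 2.0, "heart_rate", 250.0)])
        out, _ = remove_outliers(ev, SPECS)
        assert len(out) == 2

    def test_all_in_range_is_identity(self):
        ev = make_events([(0, 1.0, "sodium", 140.0), (0, 5.0, "lactate", 2.0)])
        out, counts = remove_outliers(ev, SPECS)
        pd.testing.assert_frame_equal(out, ev)
        assert counts.sum() == 0

    def test_unregistered_variable_listed(self):
        ev = make_events([(0, 1.0, "troponin", 1.0)])
        with pytest.raises(ValueError, match="troponin"):
            remove_outliers(ev, SPECS)


class TestAggregateWindows:
    def test_aggregation_rules(self):
        ev = make_events(
            [
                (0, 0.5, "gcs_motor", 5.0), (0, 3.9, "gcs_motor", 3.0),  # min
                (0, 1.0, "iv_fluid", 100.0), (0, 2.0, "iv_fluid", 200.0),  # sum
                (0, 1.5, "heart_rate", 80.0), (0, 2.5, "heart_rate", 90.0),  # mean
                (0, 1.0, "vasopressor", 0.1), (0, 3.0, "vasopressor", 0.3),  # max
                (0, 2.0, "peep", 8.0),
                (0, 4.0, "heart_rate", 100.0),  # belongs to window 1 (half-open)
            ]
        )
        t = aggregate_windows(ev, ADM1, SPECS)[0]
        j = t.feature_names.index
        assert t.features[0, j("gcs_motor")] == 3.0
        assert t.fluid_total[0] == 300.0
        assert t.features[0, j("heart_rate")] == 85.0
        assert t.features[1, j("heart_rate")] == 100.0
        assert t.vaso_max[0] == 0.3
        assert t.peep_documented[0] and not t.peep_documented[1]
        assert t.n_windows == 6  # ceil(24/4)

    def test_demographics_broadcast_and_missing_cells(self):
        ev = make_events([(0, 1.0, "sodium", 140.0)])
        t = aggregate_windows(ev, ADM1, SPECS)[0]
        j = t.feature_names.index
        assert (t.features[:, j("age")] == 60.0).all()
        assert np.isnan(t.features[2, j("sodium")])
        assert t.observed_mask[0, j("sodium")] == 1

    def test_event_after_discharge_dropped_with_warning(self):
        ev = make_events([(0, 30.0, "sodium", 140.0)])
        with pytest.warns(UserWarning, match="after discharge"):
            t = aggregate_windows(ev, ADM1, SPECS)[0]
        assert np.isnan(t.features[:, t.feature_names.index("sodium")]).all()


class TestForwardFill:
    def _tensor(self, observed_windows, value=7.0, T=12):
        ev = make_events([(0, 4.0 * w + 0.5, "sodium", value) for w in observed_windows])
        adm = make_admissions([(0, 4.0 * T, 60.0, 80.0, 170.0, 1, 0)])
        return aggregate_windows(ev, adm, SPECS)[0]

    def test_fill_within_six_window_cap(self):
        t = forward_fill(self._tensor([2]))
        j = t.feature_names.index("sodium")
        assert (t.observed_mask[3:9, j] == 1).all()
        assert (t.features[3:9, j] == 7.0).all()
        assert np.isnan(t.features[9, j]) and np.isnan(t.features[10, j])

    def test_no_backfill_before_first_observation(self):
        t = forward_fill(self._tensor([5]))
        j = t.feature_names.index("sodium")
        assert np.isnan(t.features[:5, j]).all()

    def test_never_observed_stays_missing(self):
        t = forward_fill(self._tensor([]))
        j = t.feature_names.index("sodium")
        assert np.isnan(t.features[:, j]).all()

    def test_forward_fill_is_idempotent(self):
        once = forward_fill(self._tensor([0, 4]))
        twice = forward_fill(once)
        np.testing.assert_array_equal(
            np.nan_to_num(once.features), np.nan_to_num(twice.features)
        )
        np.testing.assert_array_equal(once.observed_mask, twice.observed_mask)


class TestFilterMissingness:
    def _cohort(self, missing_frac_by_patient, T=100):
        """Patients whose sodium column is missing in the given fraction."""
        tensors = []
        for pid, frac in enumerate(missing_frac_by_patient):
            ev_rows = []
            n_missing = int(round(frac * T))
            for w in range(T):
                if w >= n_missing:
                    ev_rows.append((pid, 4.0 * w + 0.1, "sodium", 140.0))
                for var, val in (("heart_rate", 80.0), ("lactate", 1.5)):
                    ev_rows.append((pid, 4.0 * w + 0.2, var, val))
            adm = make_admissions([(pid, 4.0 * T, 60.0, 80.0, 170.0, 1, 0)])
            tensors.append(aggregate_windows(make_events(ev_rows), adm, SPECS)[0])
        return tensors

    def test_feature_dropped_above_sixty_percent(self):
        tensors, report = filter_missingness(self._cohort([1.0]), 0.60, 1.0)
        assert "sodium" in report.dropped_features.index
        assert "sodium" not in tensors[0].feature_names
        assert "heart_rate" in tensors[0].feature_names

    def test_patient_threshold_is_strict(self):
        # most features fully missing except three -> patient fractions
        # depend only on the sodium column once features are kept
        n_feats = len(self._cohort([0.0])[0].feature_names)
        # fabricate masks directly for exact boundary control
        base = self._cohort([0.0, 0.0])
        for t, frac in zip(base, (0.300, 0.305)):
            m = np.ones_like(t.observed_mask)
            cells = m.size
            k = int(round(frac * cells))
            m.flat[:k] = 0
            t.observed_mask = m
        kept, report = filter_missingness(base, feature_threshold=1.1, patient_threshold=0.30)
        assert [t.patient_id for t in kept] == [0]
        assert list(report.excluded_patients.index) == [1]

    def test_fully_observed_cohort_untouched(self):
        base = self._cohort([0.0, 0.0])
        for t in base:  # every cell observed
            t.observed_mask = np.ones_like(t.observed_mask)
        tensors, report = filter_missingness(base)
        assert len(tensors) == 2
        assert report.dropped_features.empty and report.excluded_patients.empty
        assert tensors[0].feature_names == base[0].feature_names

    def test_feature_filter_precedes_patient_filter(self):
        # patient 0 is sparse ONLY via sodium; once sodium is dropped
        # cohort-wide the patient survives the 30% rule
        tensors = self._cohort([1.0, 1.0])
        kept, report = filter_missingness(tensors, 0.60, 0.30)
        assert "sodium" in report.dropped_features.index
        assert len(kept) == 2 and report.excluded_patients.empty


class TestImputeNormalizeLabels:
    def _stats(self):
        return NormalizationStats(
            mean=pd.Series({"sodium": 140.0, "heart_rate": 80.0}),
            sd=pd.Series({"sodium": 5.0, "heart_rate": 10.0}),
            median=pd.Series({"sodium": 141.0, "heart_rate": 82.0}),
        )

    def test_training_median_fills_and_flags(self, small_splits):
        splits, stats, _ = small_splits
        t = splits["val"][0]
        assert not np.isnan(t.features).any()
        for flag in ("weight_missing", "height_missing"):
            j = t.feature_names.index(flag)
            assert set(np.unique(t.features[:, j])) <= {0.0, 1.0}
        # a patient with observed weight carries flag 0
        jw = t.feature_names.index("weight_missing")
        flags = [tt.features[0, tt.feature_names.index("weight_missing")]
                 for tt in splits["val"]]
        assert 0.0 in flags

    def test_validation_uses_training_median(self, small_splits):
        splits, stats, _ = small_splits
        # all imputed cells equal a training median value, never a val median
        t = splits["val"][0]
        for j, name in enumerate(t.feature_names):
            if name in stats.median.index:
                hole = t.observed_mask[:, j] == 0
                if hole.any():
                    vals = np.unique(t.features_raw[hole, j])
                    assert set(vals) <= {stats.median[name]}

    def test_zscore_example(self):
        ev = make_events([(0, 1.0, "heart_rate", 90.0)])
        t = aggregate_windows(ev, ADM1, SPECS)[0]
        stats = compute_stats([t])
        stats.mean["heart_rate"], stats.sd["heart_rate"] = 80.0, 10.0
        out = normalize([t], stats)[0]
        assert out.features[0, out.feature_names.index("heart_rate")] == pytest.approx(1.0)

    def test_degenerate_sd_maps_to_zero(self):
        ev = make_events([(0, 1.0, "sodium", 140.0), (0, 5.0, "sodium", 140.0)])
        t = aggregate_windows(ev, ADM1, SPECS)[0]
        stats = compute_stats([t])
        assert "sodium" in stats.degenerate and stats.sd["sodium"] == 1.0
        out = normalize([t], stats)[0]
        assert out.features[0, out.feature_names.index("sodium")] == 0.0

    def test_labels(self):
        ev = make_events(
            [(0, 21.0, "peep", 8.0), (0, 9.0, "rrt", 1.0)]
        )
        adm = make_admissions([(0, 48.0, 60.0, 80.0, 170.0, 1, 1)])
        t = derive_labels(aggregate_windows(ev, adm, SPECS)[0], adm.iloc[0])
        assert t.n_windows == 12
        assert t.remaining_los_days[0] == pytest.approx(2.0)
        assert t.remaining_los_days[1] == pytest.approx(2.0 - 4 / 24)
        assert t.mv_next[4] == 1.0  # PEEP documented in window 5
        assert t.rrt_next[1] == 1.0  # RRT documented in window 2
        assert np.isnan(t.mv_next[-1]) and np.isnan(t.rrt_next[-1])
        assert t.died_90d == 1


class TestSplitCohort:
    def test_rounded_sizes(self):
        tr, va, te = split_cohort(range(1000), seed=3)
        assert (len(tr), len(va), len(te)) == (700, 150, 150)

    def test_partition_properties(self):
        ids = list(range(101))
        tr, va, te = split_cohort(ids, seed=4)
        parts = set(tr) | set(va) | set(te)
        assert parts == set(ids)
        assert len(tr) + len(va) + len(te) == 101

    def test_same_seed_reproducible(self):
        a = split_cohort(range(50), seed=8)
        b = split_cohort(range(50), seed=8)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            split_cohort([1, 2], seed=0)


def test_fluid_conservation(small_cohort):
    """Per patient, window totals of IV fluid equal the raw event sum."""
    _, events, admissions, _ = small_cohort
    clean, _ = remove_outliers(events, SPECS)
    tensors = aggregate_windows(clean, admissions, SPECS)
    raw = clean[clean["variable"] == "iv_fluid"].groupby("patient_id")["value"].sum()
    for t in tensors[:40]:
        assert t.fluid_total.sum() == pytest.approx(raw.get(t.patient_id, 0.0))
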
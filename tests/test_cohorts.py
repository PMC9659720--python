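"""Cohort IO and preparation: first-day medians, sparsity filter,
feature intersection, site-median imputation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hullshift import (
    CohortTable,
    TimeSeriesRecord,
    aggregate_first_day,
    filter_sparse_features,
    impute_site_median,
    intersect_features,
    load_cohort,
)

from conftest import make_cohort


# ---------------------------------------------------------------------------
# load_cohort
# ---------------------------------------------------------------------------

class TestLoadCohort:
    def test_shape_and_order(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "patient_id,site_id,hr,map\np1,A,80,65\np2,A,90,70\np3,A,100,75\n"
        )
        c = load_cohort(p)
        assert c.site_id == "A"
        assert c.n_patients == 3
        assert c.features == ["hr", "map"]
        assert c.patient_ids == ["p1", "p2", "p3"]
        assert c.data.loc["p2", "hr"] == 90

    def test_duplicate_patient_id_rejected_by_name(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("patient_id,site_id,hr\np1,A,80\np1,A,90\n")
        with pytest.raises(ValueError, match="p1"):
            load_cohort(p)

    def test_na_cells_become_missing(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("patient_id,site_id,hr,map\np1,A,NA,65\np2,A,90,NA\np3,A,NA,75\n")
        c = load_cohort(p)
        assert int(c.missing_mask.to_numpy().sum()) == 3

    def test_non_numeric_cell_rejected_with_location(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("patient_id,site_id,hr\np1,A,80\np2,A,high\n")
        with pytest.raises(ValueError, match="hr"):
            load_cohort(p)

    def test_parquet_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {"patient_id": ["p1", "p2"], "site_id": "A", "hr": [1.5, 2.5]}
        )
        p = tmp_path / "a.parquet"
        df.to_parquet(p)
        c = load_cohort(p)
        assert c.n_patients == 2 and c.features == ["hr"]

    def test_endpoint_and_codes_columns(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "patient_id,site_id,hr,endpoint,codes\np1,A,80,1,J80;I10\np2,A,90,0,\n"
        )
        c = load_cohort(p)
        assert c.endpoint.tolist() == [1, 0]
        assert c.codes["p1"] == frozenset({"J80", "I10"})


def test_timeseries_record_rejects_negative_time():
    with pytest.raises(ValueError, match="time_h"):
        TimeSeriesRecord("p1", "PaO2", -1.0, 90.0)


# ---------------------------------------------------------------------------
# aggregate_first_day
# ---------------------------------------------------------------------------

class TestAggregateFirstDay:
    def test_median_of_in_window_values(self):
        recs = [
            TimeSeriesRecord("p1", "PaO2", 1, 80),
            TimeSeriesRecord("p1", "PaO2", 5, 100),
            TimeSeriesRecord("p1", "PaO2", 30, 90),
        ]
        c = aggregate_first_day(recs)
        assert c.data.loc["p1", "PaO2"] == 90.0  # median of {80, 100}

    def test_out_of_window_only_gives_missing(self):
        recs = [TimeSeriesRecord("p1", "PaO2", 30, 90)]
        c = aggregate_first_day(recs)
        assert np.isnan(c.data.loc["p1", "PaO2"])

    def test_boundary_exactly_24h_excluded(self):
        recs = [
            TimeSeriesRecord("p1", "PaO2", 24.0, 50),
            TimeSeriesRecord("p1", "PaO2", 23.9, 70),
        ]
        c = aggregate_first_day(recs)
        assert c.data.loc["p1", "PaO2"] == 70.0

    def test_empty_input_gives_empty_cohort(self):
        c = aggregate_first_day([])
        assert c.n_patients == 0

    def test_against_brute_force_median(self, rng):
        """Random records: medians equal an independent sort-and-middle."""
        pids = [f"p{i}" for i in range(5)]
        params = ["PaO2", "FiO2", "HR"]
        recs = [
            TimeSeriesRecord(
                rng.choice(pids),
                rng.choice(params),
                float(rng.uniform(0, 48)),
                float(rng.normal(100, 20)),
            )
            for _ in range(50)
        ]
        c = aggregate_first_day(recs, window_h=24)

        def middle(vals):
            s = sorted(vals)
            m = len(s) // 2
            return s[m] if len(s) % 2 else (s[m - 1] + s[m]) / 2

        for pid in {r.patient_id for r in recs}:
            for par in params:
                vals = [
                    r.value
                    for r in recs
                    if r.patient_id == pid and r.parameter == par and r.time_h < 24
                ]
                got = c.data.loc[pid, par]
                if vals:
                    assert got == pytest.approx(middle(vals))
                else:
                    assert np.isnan(got)


# ---------------------------------------------------------------------------
# filter_sparse_features
# ---------------------------------------------------------------------------

class TestSparsityFilter:
    def _cohort_with_missing(self, n_missing: int, n: int = 100):
        vals = np.ones((n, 2))
        vals[:n_missing, 0] = np.nan
        return make_cohort("A", vals, features=["sparse", "dense"])

    def test_feature_over_threshold_dropped(self):
        c = filter_sparse_features(self._cohort_with_missing(31), 0.30)
        assert c.features == ["dense"]

    def test_feature_at_exact_threshold_retained(self):
        c = filter_sparse_features(self._cohort_with_missing(30), 0.30)
        assert c.features == ["sparse", "dense"]

    def test_fully_observed_identity(self):
        c0 = self._cohort_with_missing(0)
        c = filter_sparse_features(c0, 0.30)
        pd.testing.assert_frame_equal(c.data, c0.data)

    @given(st.integers(0, 100), st.floats(0, 1))
    @settings(max_examples=30, deadline=None)
    def test_idempotent(self, n_missing, frac):
        c0 = self._cohort_with_missing(n_missing)
        once = filter_sparse_features(c0, frac)
        twice = filter_sparse_features(once, frac)
        assert once.features == twice.features


# ---------------------------------------------------------------------------
# intersect_features
# ---------------------------------------------------------------------------

class TestIntersectFeatures:
    def test_intersection_and_shared_order(self):
        a = make_cohort("A", np.ones((3, 3)), features=["a", "b", "c"])
        b = make_cohort("B", np.ones((3, 3)), features=["b", "c", "d"])
        ra, rb = intersect_features([a, b])
        assert ra.features == rb.features == ["b", "c"]

    def test_identical_sets_unchanged(self):
        a = make_cohort("A", np.ones((3, 2)), features=["a", "b"])
        b = make_cohort("B", np.ones((3, 2)), features=["a", "b"])
        ra, rb = intersect_features([a, b])
        assert ra.features == ["a", "b"] and rb.features == ["a", "b"]

    def test_disjoint_sets_error(self):
        a = make_cohort("A", np.ones((3, 1)), features=["a"])
        b = make_cohort("B", np.ones((3, 1)), features=["b"])
        with pytest.raises(ValueError, match="no features shared"):
            intersect_features([a, b])

    def test_equal_feature_sets_across_many_cohorts(self, rng):
        cohorts = [
            make_cohort(s, rng.normal(size=(4, 3)), features=list(f))
            for s, f in [("A", "abc"), ("B", "bcd"), ("C", "cab")]
        ]
        out = intersect_features(cohorts)
        sets = {tuple(c.features) for c in out}
        assert len(sets) == 1


# ---------------------------------------------------------------------------
# impute_site_median
# ---------------------------------------------------------------------------

class TestImputeSiteMedian:
    def test_simple_median(self):
        c = make_cohort("A", np.array([[1.0], [np.nan], [3.0]]), features=["x"])
        out = impute_site_median(c)
        assert out.data["x"].tolist() == [1.0, 2.0, 3.0]

    def test_no_missing_identity(self, rng):
        c = make_cohort("A", rng.normal(size=(10, 3)))
        out = impute_site_median(c)
        pd.testing.assert_frame_equal(out.data, c.data)

    def test_fully_missing_feature_named_in_error(self):
        c = make_cohort("A", np.array([[np.nan, 1.0], [np.nan, 2.0]]), features=["bad", "ok"])
        with pytest.raises(ValueError, match="bad"):
            impute_site_median(c)

    def test_against_brute_force_and_observed_untouched(self, rng):
        vals = rng.normal(size=(100, 5))
        mask = rng.random((100, 5)) < 0.2
        mask[0] = False  # keep every feature observed at least once
        vals[mask] = np.nan
        c = make_cohort("A", vals)
        out = impute_site_median(c)
        assert not out.has_missing()
        for j, f in enumerate(c.features):
            observed = vals[~mask[:, j], j]
            s = sorted(observed)
            m = len(s) // 2
            med = s[m] if len(s) % 2 else (s[m - 1] + s[m]) / 2
            imputed = out.data.to_numpy()[mask[:, j], j]
            assert np.allclose(imputed, med)
            # observed entries are never altered
            assert np.array_equal(
                out.data.to_numpy()[~mask[:, j], j], observed
            )


def test_cohort_rejects_non_binary_endpoint():
    with pytest.raises(ValueError, match="0,1"):
        make_cohort("A", np.ones((2, 1)), endpoint=[1, 2])


def test_cohort_rejects_categorical_feature():
    df = pd.DataFrame({"sex": ["m", "f"]}, index=pd.Index(["p1", "p2"]))
    with pytest.raises(ValueError, match="numeric"):
        CohortTable("A", df)
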
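"""Bootstrap coverage estimation, per-feature aggregation, Tukey
flagging and the site coverage matrix."""

import dataclasses

import numpy as np
import pytest

from hullshift import (
    CoverageAnalysis,
    DegenerateHullError,
    PairCoverage,
    bootstrap_pair_coverage,
    feature_coverage,
    flag_low_coverage,
)

from conftest import make_cohort


class TestBootstrapPairCoverage:
    def test_self_coverage_without_resampling(self, two_feature_cohorts):
        a, _ = two_feature_cohorts
        pc = bootstrap_pair_coverage(
            a, a, ("x", "y"), n_boot=1, seed=0, denoise=False, resample="none"
        )
        assert pc.mean_coverage == 1.0
        assert pc.sd_coverage == 0.0

    def test_seeded_determinism(self, two_feature_cohorts):
        a, b = two_feature_cohorts
        p1 = bootstrap_pair_coverage(a, b, ("x", "y"), n_boot=10, seed=42)
        p2 = bootstrap_pair_coverage(a, b, ("x", "y"), n_boot=10, seed=42)
        assert p1 == p2

    def test_area_ratio_scaled_square(self, rng):
        """Uniform square vs the same points shrunk x0.5 about the center:
        coverage of big by small hull tracks the 0.25 area ratio and
        small by big is complete."""
        pts = rng.uniform(size=(600, 2))
        big = make_cohort("big", pts, features=["x", "y"])
        small = make_cohort("small", 0.5 + 0.5 * (pts - 0.5), features=["x", "y"])
        big_by_small = bootstrap_pair_coverage(big, small, ("x", "y"), n_boot=20, seed=0)
        small_by_big = bootstrap_pair_coverage(small, big, ("x", "y"), n_boot=20, seed=1)
        assert big_by_small.mean_coverage == pytest.approx(0.25, abs=0.06)
        assert small_by_big.mean_coverage == 1.0

    def test_constant_feature_degenerate(self):
        a = make_cohort("A", np.column_stack([np.ones(20), np.arange(20.0)]),
                        features=["x", "y"])
        with pytest.raises(DegenerateHullError, match="x"):
            bootstrap_pair_coverage(a, a, ("x", "y"), n_boot=1, seed=0, denoise=False)

    def test_unimputed_cohort_rejected(self, two_feature_cohorts):
        a, b = two_feature_cohorts
        data = a.data.copy()
        data.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="imputed"):
            bootstrap_pair_coverage(a.replace(data=data), b, ("x", "y"))


def _pc(fi, fj, cov, q="A", h="B"):
    return PairCoverage(q, h, (fi, fj), cov, 0.0, 1, 0)


class TestFeatureCoverage:
    def test_constant_pairs_give_constant_medians(self):
        feats = ["a", "b", "c", "d"]
        pcs = [_pc(x, y, 0.8) for i, x in enumerate(feats) for y in feats[i + 1:]]
        dist = feature_coverage(pcs, feats)
        assert all(v == 0.8 for v in dist.per_feature.values())

    def test_hand_listed_medians(self):
        # 4 features; per-feature value is the middle of its 3 pair values
        vals = {("a", "b"): 0.9, ("a", "c"): 0.8, ("a", "d"): 0.7,
                ("b", "c"): 0.6, ("b", "d"): 0.5, ("c", "d"): 0.4}
        pcs = [_pc(x, y, v) for (x, y), v in vals.items()]
        dist = feature_coverage(pcs, ["a", "b", "c", "d"])
        assert dist.per_feature == pytest.approx(
            {"a": 0.8, "b": 0.6, "c": 0.6, "d": 0.5}
        )

    def test_two_features_single_pair(self):
        dist = feature_coverage([_pc("a", "b", 0.7)], ["a", "b"])
        assert dist.per_feature == {"a": 0.7, "b": 0.7}
        assert dist.threshold is None and dist.flagged == frozenset()

    def test_missing_pair_named(self):
        pcs = [_pc("a", "b", 0.9), _pc("a", "c", 0.8)]
        with pytest.raises(ValueError, match="'b'.*'c'|'c'.*'b'"):
            feature_coverage(pcs, ["a", "b", "c"])

    def test_skipped_pairs_excluded_from_medians(self):
        feats = ["a", "b", "c", "d"]
        pcs = [
            _pc(x, y, 0.8)
            for i, x in enumerate(feats)
            for y in feats[i + 1:]
            if {x, y} != {"a", "b"}
        ]
        dist = feature_coverage(pcs, feats, skipped=[("a", "b")])
        assert dist.per_feature["a"] == 0.8
        assert dist.skipped_pairs == (("a", "b"),)


class TestFlagLowCoverage:
    def test_worked_example(self):
        vals = {"v": 0.5, "w": 0.9, "x": 0.92, "y": 0.95, "z": 0.96}
        threshold, flagged = flag_low_coverage(vals)
        assert threshold == pytest.approx(0.825)
        assert flagged == {"v"}

    def test_all_equal_flags_nothing(self):
        threshold, flagged = flag_low_coverage({f: 0.7 for f in "abcd"})
        assert threshold == pytest.approx(0.7)
        assert flagged == frozenset()

    def test_spread_but_min_above_threshold(self):
        threshold, flagged = flag_low_coverage({"a": 0.90, "b": 0.92, "c": 0.94, "d": 0.96})
        assert flagged == frozenset()

    def test_fewer_than_four_features_error(self):
        with pytest.raises(ValueError, match="4"):
            flag_low_coverage({"a": 0.5, "b": 0.6, "c": 0.7})


class TestCoverageMatrix:
    def _cohorts(self, rng, p=4, n=150):
        vals = rng.normal(size=(n, p))
        return (
            make_cohort("A", vals),
            make_cohort("B", vals.copy()),
        )

    def test_identical_cohorts_full_coverage(self, rng):
        a, b = self._cohorts(rng)
        res = CoverageAnalysis([a, b], n_boot=1, seed=0, denoise=False,
                               resample="none").fit()
        assert res.matrix["A", "B"] == 1.0
        assert res.matrix["B", "A"] == 1.0

    def test_diagonal_is_one(self, rng):
        a, b = self._cohorts(rng)
        res = CoverageAnalysis([a, b], n_boot=1, seed=0, denoise=False).fit()
        assert res.matrix["A", "A"] == 1.0

    def test_bitwise_determinism(self, rng):
        a, b = self._cohorts(rng)
        r1 = CoverageAnalysis([a, b], n_boot=3, seed=7).fit()
        r2 = CoverageAnalysis([a, b], n_boot=3, seed=7).fit()
        assert r1.matrix.values.equals(r2.matrix.values)
        assert r1.distributions[("A", "B")] == r2.distributions[("A", "B")]

    def test_permutation_equivariance(self, rng):
        a, b = self._cohorts(rng)
        r_ab = CoverageAnalysis([a, b], n_boot=2, seed=3).fit()
        r_ba = CoverageAnalysis([b, a], n_boot=2, seed=3).fit()
        assert r_ab.matrix["A", "B"] == r_ba.matrix["A", "B"]
        assert r_ab.matrix["B", "A"] == r_ba.matrix["B", "A"]

    def test_degenerate_pair_skipped_and_logged(self, rng):
        vals = rng.normal(size=(100, 4))
        vals[:, 3] = 2.5  # protocol-constant feature
        a = make_cohort("A", vals)
        b = make_cohort("B", rng.normal(size=(100, 4)))
        res = CoverageAnalysis([a, b], n_boot=1, seed=0, denoise=False).fit()
        skipped = {
            (e["feature_i"], e["feature_j"])
            for e in res.qc_log
            if e["hull_site"] == "A"
        }
        assert all("f03" in pair for pair in skipped) and skipped
        # per-feature medians taken over surviving pairs only
        assert "f00" in res.distributions[("B", "A")].per_feature

    def test_mismatched_features_rejected(self, rng):
        a = make_cohort("A", rng.normal(size=(50, 3)), features=["a", "b", "c"])
        b = make_cohort("B", rng.normal(size=(50, 3)), features=["a", "b", "d"])
        with pytest.raises(ValueError, match="identical"):
            CoverageAnalysis([a, b])

    def test_range_invariant(self, rng):
        a = make_cohort("A", rng.normal(size=(120, 4)))
        b = make_cohort("B", rng.normal(1.0, 2.0, size=(120, 4)))
        res = CoverageAnalysis([a, b], n_boot=2, seed=0).fit()
        m = res.matrix.values.to_numpy()
        assert ((m >= 0) & (m <= 1)).all()


def test_pair_coverage_out_of_range_rejected():
    with pytest.raises(ValueError, match="0,1|out of"):
        dataclasses.replace(_pc("a", "b", 0.5), mean_coverage=1.2)
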
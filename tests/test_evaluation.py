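import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from ewsfusion.evaluation import (
    c_statistic,
    c_statistic_ci,
    calibration_table,
    matched_specificity_threshold,
    roc_curve,
    threshold_report,
)

from _oracles import pairwise_auc


class TestCStatistic:
    def test_perfect_separation(self):
        assert c_statistic([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0

    def test_pure_ties_give_half(self):
        assert c_statistic([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            c_statistic([1, 2], [1, 1])

    def test_matches_pairwise_oracle_and_sklearn(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(10, 200))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.random(n) < 0.3
            if labels.all() or not labels.any():
                continue
            ours = c_statistic(scores, labels)
            assert ours == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    @given(
        shift=st.floats(min_value=0.01, max_value=5, allow_nan=False),
        scale=st.floats(min_value=0.1, max_value=10, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_invariant_under_increasing_transforms(self, shift, scale):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=80)
        labels = rng.random(80) < 0.4
        base = c_statistic(scores, labels)
        assert c_statistic(scale * scores + shift, labels) == pytest.approx(base, abs=1e-12)
        assert c_statistic(np.exp(scores), labels) == pytest.approx(base, abs=1e-12)


class TestCStatisticCI:
    def test_perfect_separation_clips_to_one(self):
        scores = np.r_[np.zeros(50), np.ones(50)]
        labels = np.r_[np.zeros(50, bool), np.ones(50, bool)]
        lo, hi = c_statistic_ci(scores, labels)
        assert hi == 1.0

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=300)
        labels = rng.random(300) < 0.3
        auc = c_statistic(scores, labels)
        lo, hi = c_statistic_ci(scores, labels)
        assert lo <= auc <= hi

    def test_all_ties_flagged_with_wide_interval(self):
        with pytest.warns(UserWarning):
            lo, hi = c_statistic_ci(np.ones(40), np.r_[np.ones(20, bool), np.zeros(20, bool)])
        assert (lo, hi) == (0.0, 1.0)

    def test_coverage_of_binormal_auc(self):
        """Scores from two unit-variance normals 1 SD apart: CI should cover
        the closed-form AUROC Phi(1/sqrt(2)) in >= 90% of replicates."""
        target = norm.cdf(1 / np.sqrt(2))
        rng = np.random.default_rng(17)
        covered = 0
        for _ in range(100):
            neg = rng.normal(0, 1, 500)
            pos = rng.normal(1, 1, 500)
            scores = np.r_[neg, pos]
            labels = np.r_[np.zeros(500, bool), np.ones(500, bool)]
            lo, hi = c_statistic_ci(scores, labels)
            covered += lo <= target <= hi
        assert covered >= 90


class TestRocCurve:
    def test_perfect_separation_passes_through_corner(self):
        curve = roc_curve([1, 2, 3, 4], [0, 0, 1, 1])
        assert ((curve["fpr"] == 0) & (curve["tpr"] == 1)).any()

    def test_trapezoid_area_equals_c_statistic(self):
        rng = np.random.default_rng(23)
        scores = np.round(rng.normal(size=400), 1)
        labels = rng.random(400) < 0.35
        curve = roc_curve(scores, labels)
        area = np.trapezoid(curve["tpr"], curve["fpr"])
        assert area == pytest.approx(c_statistic(scores, labels), abs=1e-12)

    def test_monotone_staircase_from_origin_to_corner(self):
        rng = np.random.default_rng(29)
        scores = rng.normal(size=200)
        labels = rng.random(200) < 0.5
        curve = roc_curve(scores, labels)
        assert curve["fpr"].iloc[0] == 0 and curve["tpr"].iloc[0] == 0
        assert curve["fpr"].iloc[-1] == 1 and curve["tpr"].iloc[-1] == 1
        assert (curve["fpr"].diff().dropna() >= 0).all()
        assert (curve["tpr"].diff().dropna() >= 0).all()

    def test_sign_reversal_flips_auc(self):
        rng = np.random.default_rng(31)
        scores = rng.normal(size=150)
        labels = rng.random(150) < 0.4
        a = c_statistic(scores, labels)
        assert c_statistic(-scores, labels) == pytest.approx(1 - a, abs=1e-12)


class TestCalibration:
    def test_labels_drawn_at_score_rate_are_calibrated(self):
        rng = np.random.default_rng(37)
        n = 20_000
        scores = rng.beta(2, 8, n)
        labels = rng.random(n) < scores
        out = calibration_table(scores, labels)
        for _, row in out.iterrows():
            if row["n"] < 50:
                continue
            se = np.sqrt(row["mean_score"] * (1 - row["mean_score"]) / row["n"])
            assert abs(row["observed_rate"] - row["mean_score"]) < 1.96 * se + 0.01

    def test_all_negative_labels(self):
        out = calibration_table([0.1, 0.2, 0.8], [False, False, False])
        assert (out["observed_rate"] == 0).all()

    def test_bin_counts_partition_total(self):
        rng = np.random.default_rng(41)
        scores = rng.random(1000)
        out = calibration_table(scores, rng.random(1000) < 0.2)
        assert out["n"].sum() == 1000

    def test_scores_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            calibration_table([1.2], [True])


class TestMatchedSpecificityThreshold:
    def _data(self):
        rng = np.random.default_rng(43)
        n = 2000
        labels = rng.random(n) < 0.1
        ref = np.where(labels, rng.normal(7, 2, n), rng.normal(3, 2, n))
        return ref, labels

    def test_identity_returns_reference_threshold(self):
        ref, labels = self._data()
        ref = np.round(ref)  # integer trigger-style score with negatives below 5
        res = matched_specificity_threshold(ref, 5.0, ref, labels)
        assert res.target_threshold == 5.0
        assert res.specificity_attained
        assert res.target == res.reference

    def test_monotone_rescaling_scales_threshold(self):
        ref, labels = self._data()
        ref = np.round(ref)
        res = matched_specificity_threshold(ref, 5.0, ref / 20.0, labels)
        assert res.target_threshold == pytest.approx(5.0 / 20.0)
        assert res.target.sensitivity == pytest.approx(res.reference.sensitivity)

    def test_unattainable_specificity_flagged(self):
        labels = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        ref = np.r_[np.ones(50), np.zeros(50)]  # spec 1.0 at threshold 1
        target = np.zeros(100)  # any threshold flags all or none
        res = matched_specificity_threshold(ref, 1.0, target, labels)
        assert res.specificity_attained  # threshold above all scores flags none: spec 1
        assert res.target.n_flagged == 0
        assert res.target.ppv is None

    def test_report_rates_bounded(self):
        ref, labels = self._data()
        rep = threshold_report(ref, labels, 5.0)
        for r in (rep.sensitivity, rep.specificity, rep.ppv, rep.npv):
            assert 0.0 <= r <= 1.0
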
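"""ROC/AUC, bootstrap validation, Youden cutoffs, composite score, logistic fit."""

import numpy as np
import pandas as pd
import pytest

from rbdge.clinical import mann_whitney
from rbdge.scoring import (
    ScoringError,
    auc,
    bootstrap_auc,
    composite_score,
    fit_probability_model,
    make_marker,
    predict_probability,
    roc_curve,
    score_performance,
    youden_cutoff,
)

URB, DRB = "URB", "DRB"
VALUES = np.array([3.0, 5.0, 1.0, 2.0, 4.0])
LABELS = np.array([URB, URB, DRB, DRB, DRB])


class TestROC:
    def test_threshold_grid_and_operating_points(self):
        roc = roc_curve(VALUES, LABELS)
        assert len(roc.thresholds) == 6  # 4 midpoints + two infinities
        i = np.where(roc.thresholds == 2.5)[0][0]
        assert roc.sensitivity[i] == 1.0
        assert roc.specificity[i] == pytest.approx(2 / 3)
        # endpoints (sens 1, spec 0) and (sens 0, spec 1) always present
        assert roc.sensitivity[0] == 1.0 and roc.specificity[0] == 0.0
        assert roc.sensitivity[-1] == 0.0 and roc.specificity[-1] == 1.0

    def test_perfect_separation_reaches_corner(self):
        roc = roc_curve(np.array([10.0, 11, 1, 2]), np.array([URB, URB, DRB, DRB]))
        assert np.any((roc.sensitivity == 1.0) & (roc.specificity == 1.0))

    def test_identical_values_have_endpoints_only(self):
        roc = roc_curve(np.full(4, 7.0), np.array([URB, URB, DRB, DRB]))
        assert len(roc.thresholds) == 2

    def test_single_class_rejected(self):
        with pytest.raises(ScoringError):
            roc_curve(VALUES, np.array([URB] * 5))


class TestAUC:
    def test_pair_counting(self):
        assert auc(VALUES, LABELS) == pytest.approx(5 / 6)

    def test_perfect_marker(self):
        assert auc(np.array([9.0, 8, 1, 2]), np.array([URB, URB, DRB, DRB])) == 1.0

    def test_null_marker_is_half(self, rng):
        values = rng.normal(size=400)
        labels = np.array([URB, DRB] * 200)
        assert abs(auc(values, labels) - 0.5) < 0.08

    def test_complement_identity(self, rng):
        values = rng.normal(size=30)
        values[3] = values[10]  # force a tie
        labels = np.array([URB] * 12 + [DRB] * 18)
        assert auc(values, labels) + auc(-values, labels) == pytest.approx(1.0)

    def test_equals_normalized_mann_whitney_u(self, rng):
        values = rng.normal(size=21)
        labels = np.array([URB] * 11 + [DRB] * 10)
        u = mann_whitney(values[labels == URB], values[labels == DRB]).statistic
        assert auc(values, labels) == pytest.approx(u / (11 * 10))


class TestBootstrap:
    def test_deterministic_given_seed(self, rng):
        values = rng.normal(size=20)
        labels = np.array([URB] * 10 + [DRB] * 10)
        a = bootstrap_auc(values, labels, B=200, seed=5)
        b = bootstrap_auc(values, labels, B=200, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_perfect_marker_has_high_lower_bound(self):
        values = np.concatenate([np.arange(10, 20), np.arange(0, 10)]).astype(float)
        labels = np.array([URB] * 10 + [DRB] * 10)
        est = bootstrap_auc(values, labels, B=500, seed=1)
        assert est.auc == 1.0
        assert est.ci_low >= 0.8

    def test_single_resample_collapses_ci(self, rng):
        values = rng.normal(size=12)
        labels = np.array([URB] * 6 + [DRB] * 6)
        est = bootstrap_auc(values, labels, B=1, seed=2)
        assert est.ci_low == pytest.approx(est.ci_high)

    def test_b_zero_rejected(self):
        with pytest.raises(ScoringError):
            bootstrap_auc(VALUES, LABELS, B=0, seed=0)


class TestYouden:
    def test_maximizes_j_on_small_example(self):
        cutoff, j = youden_cutoff(roc_curve(VALUES, LABELS))
        assert cutoff == 2.5
        assert j == pytest.approx(2 / 3)

    def test_perfect_marker_hits_j_one(self):
        roc = roc_curve(np.array([9.0, 8, 1, 2]), np.array([URB, URB, DRB, DRB]))
        cutoff, j = youden_cutoff(roc)
        assert j == pytest.approx(1.0)
        assert 2 < cutoff < 8

    def test_degenerate_roc_is_an_error(self):
        roc = roc_curve(np.full(4, 7.0), np.array([URB, URB, DRB, DRB]))
        with pytest.raises(ScoringError):
            youden_cutoff(roc)

    def test_anti_marker_direction_flips(self):
        # high values in DRB: AUC below 0.5 flips direction
        marker = make_marker(
            "g", np.array([1.0, 2.0, 8.0, 9.0, 10.0]), LABELS, list("abcde")
        )
        assert marker.direction == "down-in-URB"
        assert marker.auc >= 0.5
        # binarized bit = 1 on the URB (low) side
        assert marker.binarized.tolist() == [1, 1, 0, 0, 0]


class TestCompositeScore:
    def _marker(self, bits, gene="g"):
        return make_marker(
            gene,
            np.array(bits, dtype=float),
            np.array([URB, URB, DRB, DRB]),
            ["s1", "s2", "s3", "s4"],
        )

    def test_sums_binarized_markers(self):
        markers = [
            self._marker([5, 6, 1, 2], "g1"),
            self._marker([5, 1, 6, 2], "g2"),
            self._marker([9, 8, 1, 2], "g3"),
        ]
        score = composite_score(markers)
        assert score.scores.loc["s1"] == 3
        assert 0 <= score.scores.min() and score.scores.max() <= 3

    def test_empty_panel_is_an_error(self):
        with pytest.raises(ScoringError):
            composite_score([])

    def test_invariant_under_marker_order(self):
        markers = [self._marker([5, 6, 1, 2], "g1"), self._marker([9, 8, 1, 2], "g2")]
        a = composite_score(markers).scores
        b = composite_score(markers[::-1]).scores
        assert a.equals(b)

    def test_perfect_markers_saturate(self):
        markers = [self._marker([9, 8, 1, 2], f"g{i}") for i in range(4)]
        score = composite_score(markers)
        assert score.scores.tolist() == [4, 4, 0, 0]


class TestScorePerformance:
    def _perfect_score(self):
        bits = pd.Series([3, 3, 0, 0], index=["s1", "s2", "s3", "s4"])
        return type("S", (), {"scores": bits, "genes": ["a", "b", "c"]})()

    def test_threshold_sweep_endpoints(self):
        score = self._perfect_score()
        labels = np.array([URB, URB, DRB, DRB])
        sens, spec, sweep = score_performance(score, labels, threshold=3)
        assert (sens, spec) == (1.0, 1.0)
        sens0, spec0, _ = score_performance(score, labels, threshold=0)
        assert (sens0, spec0) == (1.0, 0.0)
        assert sweep.threshold.tolist() == [0, 1, 2, 3, 4]


class TestProbabilityModel:
    def test_flat_model_predicts_half(self):
        from rbdge.scoring import ProbabilityModel

        model = ProbabilityModel(0.0, 0.0, "converged", 0)
        assert predict_probability(model, 3.0) == 0.5

    def test_symmetric_scores_cross_half_at_midpoint(self):
        # mirror-symmetric, non-separable: (0,DRB)<->(4,URB), (0,URB)<->(4,DRB)
        scores = np.array([0, 0, 0, 4, 4, 4], dtype=float)
        labels = np.array([DRB, DRB, URB, URB, URB, DRB])
        model = fit_probability_model(scores, labels)
        assert predict_probability(model, 2.0) == pytest.approx(0.5, abs=1e-6)

    def test_separated_scores_hit_slope_boundary(self):
        scores = np.array([0, 0, 1, 3, 4, 4], dtype=float)
        labels = np.array([DRB, DRB, DRB, URB, URB, URB])
        model = fit_probability_model(scores, labels)
        assert model.converged == "boundary"
        assert predict_probability(model, 4.0) >= 0.99
        assert predict_probability(model, 0.0) <= 0.01

    def test_monotone_when_slope_positive(self):
        scores = np.array([0, 1, 2, 3, 4, 5], dtype=float)
        labels = np.array([DRB, DRB, URB, DRB, URB, URB])
        model = fit_probability_model(scores, labels)
        assert model.slope > 0
        grid = predict_probability(model, np.linspace(0, 5, 20))
        assert np.all(np.diff(grid) > 0)

    def test_probability_recovery_from_logistic_truth(self, rng):
        a_true, b_true = -3.0, 1.2
        s = rng.integers(0, 6, size=200).astype(float)
        p_true = 1 / (1 + np.exp(-(a_true + b_true * s)))
        labels = np.where(rng.random(200) < p_true, URB, DRB)
        model = fit_probability_model(s, labels)
        mae = np.mean(np.abs(predict_probability(model, s) - p_true))
        assert mae <= 0.1

    def test_single_class_or_constant_scores_rejected(self):
        with pytest.raises(ScoringError):
            fit_probability_model(np.array([1.0, 2.0]), np.array([URB, URB]))
        with pytest.raises(ScoringError):
            fit_probability_model(np.array([2.0, 2.0]), np.array([URB, DRB]))
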
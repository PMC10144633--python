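"""Fusion: FDR selection, domain scoring, weighted fusion, weight search."""

import itertools
import math

import numpy as np
import pytest

from fatiguefusion.errors import (
    InvalidParameterError,
    NotFittedError,
    ValidationError,
)
from fatiguefusion.fusion import (
    ALERT,
    FATIGUED,
    WEIGHT_PRESETS,
    DomainScorer,
    FatigueFusionModel,
    FusionWeights,
    classify,
    fisher_discriminant_ratio,
    fit_domain_scorer,
    fuse,
    optimize_weights,
    select_features,
    simplex_grid,
)


class TestFisherDiscriminantRatio:
    def test_identical_samples_give_zero(self):
        assert fisher_discriminant_ratio([1, 2, 3], [1, 2, 3]) == 0.0

    def test_direct_substitution(self):
        # mu_a=2, mu_b=0, var_a=var_b=1 -> 4/2 = 2
        a = [1.0, 3.0]  # mean 2, sample var 2 -> use exact construction below
        a = [2 - math.sqrt(0.5), 2 + math.sqrt(0.5)]  # mean 2, var 1
        b = [-math.sqrt(0.5), math.sqrt(0.5)]  # mean 0, var 1
        assert fisher_discriminant_ratio(a, b) == pytest.approx(2.0)

    def test_symmetric_under_label_swap(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(1, 1, 20), rng.normal(0, 2, 20)
        assert fisher_discriminant_ratio(a, b) == pytest.approx(
            fisher_discriminant_ratio(b, a)
        )

    def test_degenerate_variances(self):
        assert fisher_discriminant_ratio([5, 5], [5, 5]) == 0.0
        assert math.isinf(fisher_discriminant_ratio([5, 5], [7, 7]))

    def test_too_few_values_rejected(self):
        with pytest.raises(InvalidParameterError):
            fisher_discriminant_ratio([1.0], [1.0, 2.0])


class TestSelectFeatures:
    def make_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        y = np.array([0] * 10 + [1] * 10)
        signal = y * 10.0 + rng.normal(0, 0.1, 20)
        noise = rng.normal(0, 1, (20, 3))
        return np.column_stack([noise[:, 0], signal, noise[:, 1], noise[:, 2]]), y

    def test_perfect_separator_ranked_first(self):
        X, y = self.make_matrix()
        assert select_features(X, y, k=2)[0] == 1

    def test_duplicate_column_blocked_by_corr_cap(self):
        X, y = self.make_matrix()
        X2 = np.column_stack([X[:, 1], X[:, 1], X[:, 0]])
        picked = select_features(X2, y, k=3, corr_cap=0.9)
        assert 0 in picked and 1 not in picked

    def test_no_exclusion_returns_fdr_order(self):
        X, y = self.make_matrix()
        picked = select_features(X, y, k=4, corr_cap=1.0)
        assert len(picked) == 4 and picked[0] == 1


class TestDomainScorer:
    def test_polarities_flip_with_labels(self, separable_records):
        flipped = [
            type(r)(
                subject_id=r.subject_id,
                visual=r.visual, thermal=r.thermal,
                keystroke=r.keystroke, vocal=r.vocal,
                label=1 - r.label,
            )
            for r in separable_records
        ]
        s1 = fit_domain_scorer(separable_records, "keystroke")
        s2 = fit_domain_scorer(flipped, "keystroke")
        assert np.array_equal(s1.selected, s2.selected)
        assert np.array_equal(s1.polarities, -s2.polarities)

    def test_training_means_score_to_extremes(self, separable_records):
        scorer = fit_domain_scorer(separable_records, "keystroke")
        n_features = len(separable_records[0].domain_array("keystroke"))
        fatigued_mean = np.zeros(n_features)
        fatigued_mean[scorer.selected] = scorer.mean_fatigued
        alert_mean = np.zeros(n_features)
        alert_mean[scorer.selected] = scorer.mean_alert
        assert scorer.score(fatigued_mean) == 1.0
        assert scorer.score(alert_mean) == 0.0

    def test_half_votes_give_half_score(self):
        scorer = DomainScorer(k=6)
        scorer.selected = list(range(6))
        scorer.midpoints = np.zeros(6)
        scorer.polarities = np.ones(6)
        scorer.mean_alert = -np.ones(6)
        scorer.mean_fatigued = np.ones(6)
        scorer.pooled_sd = np.ones(6)
        assert scorer.score(np.array([1, 1, 1, -1, -1, -1.0])) == 0.5

    def test_unfitted_scorer_rejected(self):
        with pytest.raises(NotFittedError):
            DomainScorer().score(np.zeros(4))

    def test_single_class_rejected(self, separable_records):
        alert_only = [r for r in separable_records if r.label == ALERT]
        with pytest.raises(InvalidParameterError):
            fit_domain_scorer(alert_only, "visual")


class TestFuseAndClassify:
    def test_all_ones_fuse_to_one(self):
        assert fuse([1, 1, 1, 1], FusionWeights(0.1, 0.2, 0.3, 0.4)) == pytest.approx(1.0)

    def test_empirical_preset_arithmetic(self):
        w = WEIGHT_PRESETS["empirical-2023"]
        assert w.as_array().tolist() == [0.29, 0.37, 0.16, 0.18]
        assert fuse([1, 1, 0, 0], w) == pytest.approx(0.66)

    def test_all_zeros_fuse_to_zero(self):
        assert fuse([0, 0, 0, 0], WEIGHT_PRESETS["uniform"]) == 0.0

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValidationError):
            fuse([1.2, 0, 0, 0], WEIGHT_PRESETS["uniform"])

    def test_threshold_boundary(self):
        assert classify(0.49) == ALERT
        assert classify(0.5) == FATIGUED  # boundary goes to fatigued
        assert classify(0.0) == ALERT

    def test_fuse_monotone_in_each_score(self):
        rng = np.random.default_rng(2)
        w = FusionWeights(*np.array([0.2, 0.3, 0.1, 0.4]))
        for _ in range(30):
            s = rng.uniform(0, 0.9, 4)
            base = fuse(s, w)
            for j in range(4):
                bumped = s.copy()
                bumped[j] += 0.1
                assert fuse(bumped, w) >= base - 1e-12

    def test_invalid_weights_rejected(self):
        with pytest.raises(InvalidParameterError):
            FusionWeights(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(InvalidParameterError):
            FusionWeights(-0.1, 0.5, 0.3, 0.3)


def brute_force_optimize(scores, labels, resolution, threshold=0.5):
    """Independent enumeration oracle with the same documented tie-breaks."""
    n = round(1 / resolution)
    y = np.asarray(labels)
    sign = np.where(y == FATIGUED, 1.0, -1.0)
    best = None
    for i, j, k in itertools.product(range(n + 1), repeat=3):
        if i + j + k > n:
            continue
        w = np.array([i, j, k, n - i - j - k], dtype=float) / n
        fused = scores @ w
        acc = np.mean((fused >= threshold) == (y == FATIGUED))
        margin = round(float(np.mean(sign * (fused - threshold))), 12)
        dist = round(float(np.linalg.norm(w - 0.25)), 12)
        key = (-acc, -margin, dist, tuple(w))
        if best is None or key < best[0]:
            best = (key, w)
    return best[1]


class TestOptimizeWeights:
    def test_identical_scores_give_uniform_weights(self):
        S = np.tile(np.array([[0.2], [0.8], [0.1], [0.9]]), (1, 4))
        w = optimize_weights(S, [0, 1, 0, 1], resolution=0.05)
        assert w.as_array().tolist() == [0.25, 0.25, 0.25, 0.25]

    def test_perfectly_separable_everywhere_gives_uniform(self):
        y = np.array([0, 1] * 4)
        S = np.tile(y[:, None], (1, 4)).astype(float)
        w = optimize_weights(S, y, resolution=0.05)
        assert w.as_array().tolist() == [0.25, 0.25, 0.25, 0.25]

    def test_informative_thermal_dominates(self):
        rng = np.random.default_rng(3)
        y = np.array([0] * 12 + [1] * 12)
        S = rng.uniform(0, 1, (24, 4))
        S[:, 1] = y  # thermal column exactly the label
        w = optimize_weights(S, y, resolution=0.05)
        assert w.beta >= max(w.alpha, w.gamma, w.delta)

    @pytest.mark.parametrize("seed", range(3))
    def test_agrees_with_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = np.array([0] * 20 + [1] * 20)
        S = np.clip(rng.uniform(0, 1, (40, 4)) + 0.2 * y[:, None], 0, 1)
        got = optimize_weights(S, y, resolution=0.05).as_array()
        expected = brute_force_optimize(S, y, resolution=0.05)
        assert np.array_equal(got, expected)

    def test_never_below_best_vertex_accuracy(self):
        rng = np.random.default_rng(7)
        y = np.array([0] * 15 + [1] * 15)
        S = np.clip(rng.uniform(0, 1, (30, 4)) + 0.3 * y[:, None], 0, 1)
        w = optimize_weights(S, y, resolution=0.05)
        fused = S @ w.as_array()
        acc = np.mean((fused >= 0.5) == (y == FATIGUED))
        vertex_accs = [
            np.mean((S[:, d] >= 0.5) == (y == FATIGUED)) for d in range(4)
        ]
        assert acc >= max(vertex_accs) - 1e-12

    def test_grid_covers_simplex(self):
        grid = simplex_grid(0.25)
        assert np.allclose(grid.sum(axis=1), 1.0)
        assert len(grid) == len({tuple(g) for g in grid}) == 35  # C(7,3)


class TestFatigueFusionModel:
    def test_fit_predict_on_separable_records(self, separable_records):
        model = FatigueFusionModel(resolution=0.05).fit(separable_records)
        preds = model.predict(separable_records)
        labels = np.array([r.label for r in separable_records])
        assert np.mean(preds == labels) >= 0.95

    def test_round_trip_through_json(self, separable_records, tmp_path):
        model = FatigueFusionModel(resolution=0.05).fit(separable_records)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = FatigueFusionModel.load(path)
        assert np.array_equal(
            loaded.weights.as_array(), model.weights.as_array()
        )
        assert np.array_equal(
            loaded.predict(separable_records), model.predict(separable_records)
        )

    def test_version_mismatch_rejected(self, separable_records, tmp_path):
        import json

        model = FatigueFusionModel(resolution=0.05).fit(separable_records)
        path = tmp_path / "model.json"
        model.save(path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValidationError):
            FatigueFusionModel.load(path)
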
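"""Supervised SOM: BMU search, training, SOMDI, prediction, CV."""

import numpy as np
import pytest

from retispec import skinet
from retispec.skinet import (SOMConfig, evaluate_repeated, find_bmu, kfold_cv,
                             predict, predict_batch, somdi, stratified_split,
                             total_steps, train)


def _brute_force_bmu(weights, x):
    best, best_sim = 0, -np.inf
    for i, w in enumerate(weights):
        sim = np.dot(w, x) / (np.linalg.norm(w) * np.linalg.norm(x))
        if sim > best_sim:
            best, best_sim = i, sim
    return best


class TestStratifiedSplit:
    def test_reserves_twenty_percent_per_class(self):
        labels = np.array(["a"] * 100 + ["b"] * 100)
        tr, te = stratified_split(labels, 0.2, seed=1)
        assert (labels[te] == "a").sum() == 20
        assert (labels[te] == "b").sum() == 20

    def test_partition_is_disjoint_and_complete(self):
        labels = np.array(["a"] * 37 + ["b"] * 13)
        tr, te = stratified_split(labels, 0.2, seed=5)
        combined = np.sort(np.concatenate([tr, te]))
        np.testing.assert_array_equal(combined, np.arange(50))

    def test_same_seed_same_partition(self):
        labels = np.array(["a", "b"] * 20)
        assert all(np.array_equal(x, y) for x, y in
                   zip(stratified_split(labels, 0.3, seed=9),
                       stratified_split(labels, 0.3, seed=9)))

    def test_degenerate_fractions_rejected(self):
        labels = np.array(["a"] * 10 + ["b"] * 10)
        for frac in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                stratified_split(labels, frac)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array(["a", "a", "b"]), 0.2)


class TestBMU:
    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(100):
            W = rng.normal(size=(25, 12))
            x = rng.normal(size=12)
            model = _toy_model(W)
            assert find_bmu(model, x) == _brute_force_bmu(W, x)

    def test_cosine_scale_invariance(self, rng):
        W = rng.normal(size=(25, 12))
        x = rng.normal(size=12)
        model = _toy_model(W)
        assert find_bmu(model, x) == find_bmu(model, 10.0 * x)

    def test_matching_ignores_class_weights(self, rng, blob_data):
        X, y = blob_data
        model = train(SOMConfig(rows=4, cols=4, epochs=2, seed=0), X, y)
        before = [find_bmu(model, x) for x in X[:20]]
        model.class_weights = model.class_weights * 7.3 + 0.1
        after = [find_bmu(model, x) for x in X[:20]]
        assert before == after

    def test_zero_norm_input_rejected(self, rng):
        model = _toy_model(rng.normal(size=(25, 12)))
        with pytest.raises(ValueError):
            find_bmu(model, np.zeros(12))


def _toy_model(W):
    rows = cols = int(np.sqrt(W.shape[0]))
    cfg = SOMConfig(rows=rows, cols=cols, epochs=1, seed=0)
    return skinet.SOMModel(cfg, W, np.full((W.shape[0], 2), 0.5),
                           skinet.hex_grid_coords(rows, cols), ["a", "b"],
                           np.ones((W.shape[0], 2)))


class TestTraining:
    def test_published_step_count_arises_from_nine_epochs(self):
        # nine epochs over 6,400 training spectra = 57,600 weight updates
        assert total_steps(SOMConfig(), 6400) == 57600
        assert total_steps(SOMConfig(steps=57600), 123) == 57600

    def test_bit_identical_models_under_fixed_seed(self, blob_data):
        X, y = blob_data
        cfg = SOMConfig(rows=5, cols=5, epochs=3, seed=11)
        m1, m2 = train(cfg, X, y), train(cfg, X, y)
        np.testing.assert_array_equal(m1.weights, m2.weights)
        np.testing.assert_array_equal(m1.class_weights, m2.class_weights)
        np.testing.assert_array_equal(m1.activation_counts, m2.activation_counts)

    def test_separated_clusters_yield_pure_neurons(self, blob_data):
        X, y = blob_data
        model = train(SOMConfig(rows=5, cols=5, epochs=5, seed=2), X, y)
        counts = model.activation_counts
        active = counts.sum(axis=1) > 0
        purity = counts[active].max(axis=1) / counts[active].sum(axis=1)
        assert np.mean(purity == 1.0) >= 0.95

    def test_default_radius_is_two_thirds_edge_length(self):
        assert SOMConfig(rows=10, cols=10).radius0 == pytest.approx(20.0 / 3.0)
        assert SOMConfig(rows=10, cols=20).radius0 == pytest.approx(40.0 / 3.0)

    def test_topographic_ordering(self, blob_data):
        X, y = blob_data
        model = train(SOMConfig(rows=5, cols=5, epochs=5, seed=4), X, y)
        W = model.weights / np.linalg.norm(model.weights, axis=1, keepdims=True)
        cos_d = 1.0 - W @ W.T
        grid_d = np.linalg.norm(
            model.grid_coords[:, None] - model.grid_coords[None], axis=-1)
        adjacent = (grid_d > 0) & (grid_d < 1.1)
        far = grid_d >= 2.0
        assert cos_d[adjacent].mean() < cos_d[far].mean()

    def test_mismatched_inputs_rejected(self, blob_data):
        X, y = blob_data
        with pytest.raises(ValueError):
            train(SOMConfig(rows=3, cols=3), X, y[:-1])
        with pytest.raises(ValueError):
            train(SOMConfig(rows=3, cols=3), X, y, axis=np.arange(5.0))


class TestSOMDI:
    def test_recovers_discriminant_band(self, rng):
        # two classes identical except one Gaussian band's amplitude
        axis = np.arange(2800.0, 3000.0, 2.0)
        band = np.exp(-0.5 * ((axis - 2930.0) / 19.0) ** 2)
        other = np.exp(-0.5 * ((axis - 2850.0) / 19.0) ** 2)
        base = 1.0 + other
        Xa = base + 2.0 * band + rng.normal(0, 0.02, (80, axis.size))
        Xb = base + 0.3 * band + rng.normal(0, 0.02, (80, axis.size))
        X = np.vstack([Xa, Xb])
        y = np.array(["high"] * 80 + ["low"] * 80)
        model = train(SOMConfig(rows=6, cols=6, epochs=6, seed=1), X, y,
                      axis=axis)
        res = somdi(model)
        top_wavenumber = res.peaks["high"][0][0]
        assert abs(top_wavenumber - 2930.0) <= 22.5  # half the band FWHM (45)

    def test_single_class_profile_is_flat_zero(self, rng):
        X = rng.normal(5.0, 1.0, (40, 16))
        y = np.array(["only"] * 40)
        model = train(SOMConfig(rows=4, cols=4, epochs=4, seed=0), X, y)
        res = somdi(model)
        assert np.max(np.abs(res.profiles)) < 1e-9

    def test_profiles_finite_and_axis_aligned(self, blob_data):
        X, y = blob_data
        model = train(SOMConfig(rows=4, cols=4, epochs=3, seed=5), X, y)
        res = somdi(model)
        assert res.profiles.shape == (2, X.shape[1])
        assert np.all(np.isfinite(res.profiles))


class TestPrediction:
    def test_training_points_recovered_on_separable_data(self, blob_data):
        X, y = blob_data
        model = train(SOMConfig(rows=5, cols=5, epochs=5, seed=3), X, y)
        assert np.mean(predict_batch(model, X) == y) >= 0.95

    def test_heldout_accuracy_on_separated_cohorts(self, blob_data):
        X, y = blob_data
        tr, te = stratified_split(y, 0.2, seed=0)
        model = train(SOMConfig(rows=5, cols=5, epochs=5, seed=3), X[tr], y[tr])
        assert np.mean(predict_batch(model, X[te]) == y[te]) >= 0.95

    def test_unactivated_bmu_falls_back_to_nearest_activated(self, blob_data):
        X, y = blob_data
        model = train(SOMConfig(rows=4, cols=4, epochs=3, seed=6), X, y)
        # force one neuron to be unactivated but maximally similar to a probe
        model.activation_counts[5] = 0.0
        probe = model.weights[5] * 3.0
        label = predict(model, probe)
        assert label in model.class_names

    def test_class_weight_tie_takes_lowest_index_class(self, rng):
        model = _toy_model(rng.normal(size=(25, 12)) + 4.0)
        model.class_weights[:] = 0.5  # exact tie everywhere
        assert predict(model, np.abs(rng.normal(size=12)) + 1.0) == "a"


class TestCrossValidation:
    def test_perfectly_separable_data_scores_one(self, blob_data):
        X, y = blob_data
        cfg = SOMConfig(rows=4, cols=4, epochs=3, seed=0)
        result = kfold_cv(cfg, X, y, k=5)
        assert result["mean"] == pytest.approx(1.0)

    def test_class_smaller_than_k_rejected(self, blob_data):
        X, y = blob_data
        with pytest.raises(ValueError):
            kfold_cv(SOMConfig(rows=3, cols=3), X, y, k=len(y))


class TestRepeatedEvaluation:
    def test_confusion_row_sums_match_test_counts(self, blob_data):
        X, y = blob_data
        tr, te = stratified_split(y, 0.2, seed=1)
        cfg = SOMConfig(rows=4, cols=4, epochs=3, seed=7)
        out = evaluate_repeated(cfg, X[tr], y[tr], X[te], y[te], n_repeats=3)
        cm = out["confusion"]
        for i, cls in enumerate(cm.class_names):
            assert cm.counts[i].sum() == pytest.approx((y[te] == cls).sum())

    def test_single_repeat_equals_one_evaluation(self, blob_data):
        X, y = blob_data
        tr, te = stratified_split(y, 0.2, seed=1)
        cfg = SOMConfig(rows=4, cols=4, epochs=3, seed=7)
        out = evaluate_repeated(cfg, X[tr], y[tr], X[te], y[te], n_repeats=1)
        np.testing.assert_array_equal(out["confusion"].counts,
                                      out["per_repeat"][0].counts)

    def test_separable_cohorts_have_small_off_diagonals(self, blob_data):
        X, y = blob_data
        tr, te = stratified_split(y, 0.2, seed=2)
        cfg = SOMConfig(rows=4, cols=4, epochs=4, seed=8)
        out = evaluate_repeated(cfg, X[tr], y[tr], X[te], y[te], n_repeats=3)
        counts = out["confusion"].counts
        for i in range(2):
            assert counts[i, 1 - i] <= 0.05 * counts[i].sum()

    def test_empty_test_set_rejected(self, blob_data):
        X, y = blob_data
        with pytest.raises(ValueError):
            evaluate_repeated(SOMConfig(rows=3, cols=3), X, y,
                              X[:0], y[:0], n_repeats=1)
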
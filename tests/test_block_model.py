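import math

import numpy as np
import pytest

from hierbg.blocks import (
    BACKGROUND,
    OBJECT,
    BlockModel,
    BlockModelConfig,
    BlockModelEntry,
    adaptive_threshold,
    background_count,
    classify_and_update,
    feature_distance,
    init_model,
)
from hierbg.btc import btc_feature


def make_model(weights, features, exemplar):
    entries = [
        BlockModelEntry(np.asarray(f, dtype=float), w) for w, f in zip(weights, features)
    ]
    return BlockModel(entries=entries, exemplar=np.asarray(exemplar, dtype=float))


class TestInitModel:
    def test_first_entry_takes_all_weight(self):
        block = np.array([[10.0, 20.0], [30.0, 40.0]])
        model = init_model(btc_feature(block), block, BlockModelConfig(K=3))
        np.testing.assert_allclose(model.weights, [1.0, 0.0, 0.0])
        np.testing.assert_array_equal(model.entries[0].feature, [40, 30, 20, 10])

    def test_single_entry_model(self):
        block = np.full((2, 2), 5.0)
        model = init_model(btc_feature(block), block, BlockModelConfig(K=1))
        assert len(model.entries) == 1 and model.entries[0].weight == 1.0

    def test_exemplar_copies_block(self):
        block = np.array([[1.0, 2.0], [3.0, 4.0]])
        model = init_model(btc_feature(block), block, BlockModelConfig())
        np.testing.assert_array_equal(model.exemplar, block)
        block[0, 0] = 99.0
        assert model.exemplar[0, 0] == 1.0


class TestBackgroundCount:
    @pytest.mark.parametrize(
        "weights,T,expected",
        [
            ((0.6, 0.3, 0.1), 0.7, 2),
            ((0.8, 0.15, 0.05), 0.7, 1),
            ((1.0, 0.0, 0.0), 0.99, 1),
        ],
    )
    def test_cumulative_threshold(self, weights, T, expected):
        model = make_model(weights, [np.zeros(4)] * len(weights), np.zeros((2, 2)))
        assert background_count(model, T) == expected


class TestFeatureDistance:
    def test_euclidean_values(self):
        assert feature_distance(np.array([40, 30, 20, 10]), np.array([40, 30, 20, 10])) == 0
        assert feature_distance(np.array([40, 30, 20, 10]), np.array([38, 30, 20, 10])) == 2
        assert feature_distance(np.array([1, 0, 0, 0]), np.zeros(4)) == 1

    def test_accepts_block_features(self):
        f = btc_feature(np.array([[10.0, 20.0], [30.0, 40.0]]))
        assert feature_distance(f, f) == 0


class TestAdaptiveThreshold:
    @pytest.mark.parametrize(
        "base,alpha,s,expected",
        [(40, 0.75, 1.0, 70.0), (40, 0.75, 0.0, 30.0), (0, 0.75, 0.5, 0.0)],
    )
    def test_scaling(self, base, alpha, s, expected):
        assert adaptive_threshold(base, alpha, s) == pytest.approx(expected)


class TestClassifyAndUpdate:
    def test_static_block_stays_background(self):
        block = np.array([[10.0, 20.0], [30.0, 40.0]])
        cfg = BlockModelConfig(K=3, T=0.7)
        model = init_model(btc_feature(block), block, cfg)
        assert classify_and_update(model, block, cfg, 2) == BACKGROUND
        np.testing.assert_allclose(model.weights, [1.0, 0.0, 0.0])

    def test_weight_update_arithmetic(self):
        # two live entries at 0.5/0.5; matching the first with rate 0.1 -> 0.55/0.45
        a = np.array([[0.0, 0.0], [0.0, 40.0]])
        b = np.array([[200.0, 200.0], [200.0, 255.0]])
        cfg = BlockModelConfig(K=2, alpha_w=0.1)
        model = make_model(
            [0.5, 0.5], [btc_feature(a).vector, btc_feature(b).vector], a
        )
        assert classify_and_update(model, a, cfg, 5) == BACKGROUND
        np.testing.assert_allclose(model.weights, [0.55, 0.45])

    def test_matched_feature_tracks_input(self):
        # stored (40,30,20,10), input (50,30,20,10), alpha_b=0.1 -> (41,30,20,10)
        old = np.array([[40.0, 30.0], [20.0, 10.0]])
        new = np.array([[50.0, 30.0], [20.0, 10.0]])
        cfg = BlockModelConfig(K=1, alpha_b=0.1, T_D_base=20.0)
        model = init_model(btc_feature(old), new, cfg)  # exemplar = new => S = high
        assert classify_and_update(model, new, cfg, 2) == BACKGROUND
        np.testing.assert_allclose(model.entries[0].feature, [41, 30, 20, 10])

    def test_no_match_replaces_weakest(self):
        block = np.array([[10.0, 20.0], [30.0, 40.0]])
        cfg = BlockModelConfig(K=3)
        model = init_model(btc_feature(block), block, cfg)
        jumped = block + 200.0 * np.eye(2)  # wildly different structure
        label = classify_and_update(model, np.clip(jumped, 0, 255), cfg, 2)
        assert label == OBJECT
        assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
        # new appearance occupies a former placeholder slot
        assert sum(e.placeholder for e in model.entries) == 1

    def test_placeholders_never_match_dark_blocks(self):
        bright = np.array([[100.0, 150.0], [200.0, 250.0]])
        cfg = BlockModelConfig(K=3)
        model = init_model(btc_feature(bright), bright, cfg)
        # a black block has feature ~0, close to the zero placeholder vectors
        assert classify_and_update(model, np.zeros((2, 2)), cfg, 2) == OBJECT

    def test_uninitialized_model_raises(self):
        with pytest.raises(ValueError):
            classify_and_update(BlockModel(), np.zeros((2, 2)), BlockModelConfig(), 1)


class TestModelDynamics:
    def test_weight_conservation_and_sorting_random_run(self, rng):
        cfg = BlockModelConfig(K=3)
        first = rng.uniform(0, 255, (8, 8))
        model = init_model(btc_feature(first), first, cfg)
        for t in range(2, 62):
            classify_and_update(model, rng.uniform(0, 255, (8, 8)), cfg, t)
            w = model.weights
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.diff(w) <= 1e-12)

    def test_constant_sequence_dominant_weight_nondecreasing(self):
        block = np.array([[10.0, 20.0], [30.0, 40.0]])
        cfg = BlockModelConfig(K=3)
        model = init_model(btc_feature(block), block, cfg)
        prev = model.weights[0]
        for t in range(2, 30):
            assert classify_and_update(model, block, cfg, t) == BACKGROUND
            assert model.weights[0] >= prev - 1e-12
            prev = model.weights[0]

    def test_geometric_feature_convergence(self):
        old = np.array([[40.0, 30.0], [20.0, 10.0]])
        new = np.array([[44.0, 30.0], [20.0, 10.0]])
        cfg = BlockModelConfig(K=1, alpha_b=0.2, T_D_base=20.0)
        model = init_model(btc_feature(old), new, cfg)
        target = btc_feature(new).vector
        err = np.linalg.norm(model.entries[0].feature - target)
        for t in range(2, 12):
            classify_and_update(model, new, cfg, t)
            new_err = np.linalg.norm(model.entries[0].feature - target)
            assert new_err == pytest.approx((1 - cfg.alpha_b) * err, rel=1e-9)
            err = new_err

    def test_sustained_change_absorbed_at_predicted_frame(self):
        """A new appearance held for n frames becomes background exactly when
        the old dominant weight decays below T; n follows in closed form from
        alpha_w and T."""
        cfg = BlockModelConfig(K=3, T=0.7, alpha_w=0.05)
        old = np.array([[10.0, 60.0], [110.0, 160.0]])
        new = np.full((2, 2), 220.0)
        model = init_model(btc_feature(old), old, cfg)
        # replacement frame: old weight becomes 1/(1+alpha_w)
        assert classify_and_update(model, new, cfg, 2) == OBJECT
        w_old = 1.0 / (1.0 + cfg.alpha_w)
        # the label is decided from the weights before each update, so the
        # first background call is the one after n_pred matches
        n_pred = next(
            n for n in range(1, 100) if w_old * (1 - cfg.alpha_w) ** n <= cfg.T
        )
        for i in range(1, n_pred + 1):
            assert classify_and_update(model, new, cfg, 2 + i) == OBJECT
        assert classify_and_update(model, new, cfg, 3 + n_pred) == BACKGROUND

    def test_labels_invariant_under_global_additive_shift(self, rng):
        cfg = BlockModelConfig(K=3)
        seq = [rng.uniform(0, 200, (8, 8)) for _ in range(20)]
        labels = []
        for shift in (0.0, 30.0):
            first = seq[0] + shift
            model = init_model(btc_feature(first), first, cfg)
            labels.append(
                [classify_and_update(model, f + shift, cfg, t) for t, f in enumerate(seq[1:], 2)]
            )
        assert labels[0] == labels[1]
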
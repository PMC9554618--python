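"""Classifier unit, oracle and property tests."""

import numpy as np
import pytest

from detext.encoding import PAD_TOKEN
from detext.model import (
    ModelConfig,
    TrainingExample,
    constrain_norms,
    convolve,
    embed,
    feature_map,
    forward,
    init_params,
    load_checkpoint,
    max_pool,
    predict,
    save_checkpoint,
    train,
)

RNG = np.random.default_rng(1234)


def conv_oracle(A, w):
    """Independent double-loop implementation of the sliding dot product."""
    d, L = A.shape
    h = w.shape[0]
    out = []
    for i in range(d - h + 1):
        acc = 0.0
        for r in range(h):
            for c in range(L):
                acc += w[r, c] * A[i + r, c]
        out.append(acc)
    return np.array(out)


class TestPrimitives:
    def test_convolution_matches_bruteforce_oracle(self):
        for _ in range(100):
            h = int(RNG.integers(2, 6))
            A = RNG.normal(size=(5, 20))
            w = RNG.normal(size=(h, 20))
            np.testing.assert_allclose(convolve(A, w), conv_oracle(A, w), atol=1e-9)

    def test_all_ones_closed_form(self):
        # h=2 filter of ones on an all-ones 5x100 input: every o_i = 2*100
        o = convolve(np.ones((5, 100)), np.ones((2, 100)))
        assert o.shape == (4,)
        np.testing.assert_allclose(o, 200.0)

    def test_full_height_filter_gives_scalar(self):
        o = convolve(RNG.normal(size=(5, 100)), RNG.normal(size=(5, 100)))
        assert o.shape == (1,)

    def test_oversized_region_rejected(self):
        with pytest.raises(ValueError):
            convolve(np.ones((5, 10)), np.ones((6, 10)))

    def test_feature_map_relu(self):
        np.testing.assert_allclose(feature_map(np.array([-1.0, 2.0]), 0.0), [0, 2])
        np.testing.assert_allclose(feature_map(np.array([1.0, 1.0]), -3.0), [0, 0])

    def test_feature_map_monotone(self):
        o = RNG.normal(size=20)
        bumped = o.copy()
        bumped[5] += 1.0
        assert np.all(feature_map(bumped, 0.3) >= feature_map(o, 0.3))

    def test_max_pool(self):
        assert max_pool(np.array([0.1, 0.5, 0.3])) == 0.5
        assert max_pool(np.full(7, 2.5)) == 2.5
        v = RNG.normal(size=30)
        assert max_pool(v) == max_pool(v[RNG.permutation(30)])
        with pytest.raises(ValueError):
            max_pool(np.array([]))

    def test_embedding_shape_and_locality(self):
        config = ModelConfig()
        params = init_params(config, np.random.default_rng(0))
        tokens = list(RNG.integers(0, 20, size=100))
        A = embed(tokens, params)
        assert A.shape == (5, 100)
        other = list(tokens)
        other[42] = (other[42] + 1) % 20
        B = embed(other, params)
        differing = np.flatnonzero(np.any(A != B, axis=0))
        assert list(differing) == [42]

    def test_all_pad_embeds_to_zero(self):
        config = ModelConfig()
        params = init_params(config, np.random.default_rng(0))
        A = embed([PAD_TOKEN] * 100, params)
        np.testing.assert_allclose(A, 0.0)


class TestForward:
    def _example(self, prior=0.3):
        tokens = tuple(int(t) for t in RNG.integers(0, 18, size=100))
        return TrainingExample(tokens=tokens, prior=prior, label=1)

    def test_probabilities_sum_to_one(self):
        config = ModelConfig()
        params = init_params(config, np.random.default_rng(3))
        for _ in range(10):
            p = forward(self._example(), params, config)
            assert p.shape == (2,)
            assert p.sum() == pytest.approx(1.0)
            assert np.all(p >= 0)

    def test_zero_dropout_train_equals_eval(self):
        config = ModelConfig(dropout_rate=0.0)
        params = init_params(config, np.random.default_rng(3))
        ex = self._example()
        p_train = forward(ex, params, config, train_mode=True,
                          rng=np.random.default_rng(0))
        p_eval = forward(ex, params, config, train_mode=False)
        np.testing.assert_allclose(p_train, p_eval)

    def test_zero_coefficient_ignores_prior(self):
        config = ModelConfig(ms_coefficient=0.0)
        params = init_params(config, np.random.default_rng(3))
        tokens = tuple(int(t) for t in RNG.integers(0, 18, size=100))
        a = forward(TrainingExample(tokens, 0.0, 1), params, config)
        b = forward(TrainingExample(tokens, 0.9, 1), params, config)
        np.testing.assert_allclose(a, b)

    def test_coefficient_feeds_prior_through(self):
        config = ModelConfig(ms_coefficient=7.0)
        params = init_params(config, np.random.default_rng(3))
        tokens = tuple(int(t) for t in RNG.integers(0, 18, size=100))
        a = forward(TrainingExample(tokens, 0.0, 1), params, config)
        b = forward(TrainingExample(tokens, 0.9, 1), params, config)
        assert not np.allclose(a, b)


class TestConstrainNorms:
    def test_oversized_row_rescaled_exactly(self):
        config = ModelConfig()
        params = init_params(config, np.random.default_rng(0))
        params.out_weight[0] *= 6.0 / np.linalg.norm(params.out_weight[0])
        params.out_weight[1] *= 2.0 / np.linalg.norm(params.out_weight[1])
        before_small = params.out_weight[1].copy()
        constrain_norms(params, 3.0)
        assert np.linalg.norm(params.out_weight[0]) == pytest.approx(3.0)
        np.testing.assert_allclose(params.out_weight[1], before_small)

    def test_idempotent(self):
        config = ModelConfig()
        params = init_params(config, np.random.default_rng(1))
        params.out_weight *= 10
        constrain_norms(params, 3.0)
        once = params.out_weight.copy()
        constrain_norms(params, 3.0)
        np.testing.assert_allclose(params.out_weight, once)


def _separable_dataset(n=200, seed=0):
    """Toy set: label 1 examples contain token 9 runs, label 0 token 13."""
    rng = np.random.default_rng(seed)
    examples = []
    for i in range(n):
        label = i % 2
        marker = 9 if label else 13
        tokens = rng.integers(2, 6, size=100)
        tokens[10:20] = marker
        examples.append(
            TrainingExample(tuple(int(t) for t in tokens), 0.4 * label, label)
        )
    return examples


class TestTraining:
    def test_separable_toy_set_fits(self):
        config = ModelConfig(max_iters=250, patience=0, seed=0)
        examples = _separable_dataset()
        params, history = train(examples, config)
        scores = predict(params, examples, config)
        labels = np.array([e.label for e in examples])
        assert np.mean((scores >= 0.5) == labels) == 1.0
        assert len(history.train_loss) <= config.max_iters

    def test_same_seed_bitwise_identical_history(self):
        config = ModelConfig(max_iters=60, patience=0, seed=11)
        examples = _separable_dataset(80)
        _, h1 = train(examples, config)
        _, h2 = train(examples, config)
        assert h1.train_loss == h2.train_loss
        assert h1.val_acc == h2.val_acc

    def test_norm_constraint_holds_after_every_step(self, monkeypatch):
        import detext.model as m

        config = ModelConfig(max_iters=40, patience=0, seed=2, norm_constraint=3.0)
        seen = []
        orig = m.constrain_norms

        def spy(params, s):
            out = orig(params, s)
            seen.append(float(np.linalg.norm(out.out_weight, axis=1).max()))
            return out

        monkeypatch.setattr(m, "constrain_norms", spy)
        m.train(_separable_dataset(80), config)
        assert len(seen) == 40
        assert all(n <= 3.0 + 1e-9 for n in seen)

    def test_single_class_dataset_rejected(self):
        examples = [e for e in _separable_dataset(40) if e.label == 1]
        with pytest.raises(ValueError, match="class"):
            train(examples, ModelConfig(max_iters=5))

    def test_training_loss_trends_down(self):
        config = ModelConfig(max_iters=100, patience=0, seed=4)
        _, history = train(_separable_dataset(), config)
        losses = np.array(history.train_loss)
        assert np.all(np.isfinite(losses))
        assert losses[-20:].mean() < losses[:20].mean()

    def test_predict_order_invariant_and_normalized(self):
        config = ModelConfig(max_iters=60, patience=0, seed=0)
        examples = _separable_dataset(60)
        params, _ = train(examples, config)
        s = predict(params, examples, config)
        s_rev = predict(params, examples[::-1], config)
        np.testing.assert_allclose(s, s_rev[::-1])
        assert np.all((s >= 0) & (s <= 1))

    def test_held_out_generalization(self):
        config = ModelConfig(max_iters=250, patience=0, seed=0)
        params, _ = train(_separable_dataset(200, seed=0), config)
        test = _separable_dataset(100, seed=99)
        scores = predict(params, test, config)
        labels = np.array([e.label for e in test])
        assert np.mean((scores >= 0.5) == labels) > 0.9


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        config = ModelConfig(max_iters=30, patience=0, seed=0)
        examples = _separable_dataset(60)
        params, _ = train(examples, config)
        path = tmp_path / "model.ckpt"
        save_checkpoint(path, params, config)
        params2, config2 = load_checkpoint(path)
        assert config2 == config
        np.testing.assert_allclose(
            predict(params, examples, config), predict(params2, examples, config2)
        )
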
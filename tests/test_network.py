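import numpy as np
import pytest

from cfnn import (
    CFNNConfig,
    ValidationError,
    build_model,
    forward,
    load_model,
    save_model,
    summarize,
    train,
)
from cfnn.fuzzy import FuzzyRuleBank, fuzzify
from cfnn.layers import BatchNorm, softmax


@pytest.fixture(scope="module")
def default_model():
    return build_model(CFNNConfig())


TINY = dict(
    input_len=9, conv1_filters=3, conv1_kernel=5, conv2_filters=2,
    conv2_kernel=3, pool_size=2, n_rules=2, epochs=5, batch_size=16,
)


class TestParameterAccounting:
    def test_per_layer_counts_match_reference_ledger(self, default_model):
        summary = summarize(default_model)
        counts = {name: count for name, _, count, _ in summary.rows}
        assert counts == {
            "conv1d": 384,
            "conv1d_1": 6176,
            "max_pooling1d": 0,
            "flatten": 0,
            "fuzzy": 4608,
            "batch_normalization": 8,
            "dense": 6,
            "defuzzy": 4,
            "activation": 0,
        }

    def test_totals(self, default_model):
        assert summarize(default_model).totals == (11186, 11182, 4)

    def test_flatten_width(self, default_model):
        assert default_model.flatten_width == 73 // 2 * 32 == 1152
        shapes = {name: shape for name, shape, _, _ in summarize(default_model).rows}
        assert shapes["flatten"] == (1152,)
        assert shapes["max_pooling1d"] == (36, 32)

    def test_totals_equal_row_sums(self, default_model):
        summary = summarize(default_model)
        assert summary.totals[0] == sum(c for _, _, c, _ in summary.rows)

    def test_summary_renders(self, default_model):
        text = str(summarize(default_model))
        assert "11,186" in text and "11,182" in text

    def test_batchnorm_accounting(self):
        bn = BatchNorm(2)
        assert bn.n_params() == 8
        assert bn.n_non_trainable() == 4


class TestForward:
    def test_rows_are_probabilities(self, default_model):
        rng = np.random.default_rng(0)
        probs = forward(default_model, rng.standard_normal((3, 73)))
        assert probs.shape == (3, 2)
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_deterministic_in_eval_mode(self, default_model):
        x = np.random.default_rng(1).standard_normal((4, 73))
        np.testing.assert_array_equal(
            forward(default_model, x), forward(default_model, x)
        )

    def test_identical_inputs_identical_outputs(self, default_model):
        x = np.tile(np.random.default_rng(2).standard_normal(73), (3, 1))
        probs = forward(default_model, x)
        assert np.allclose(probs, probs[0])

    def test_fresh_model_not_saturated(self):
        model = build_model(CFNNConfig(seed=0))
        x = np.random.default_rng(3).standard_normal((64, 73))
        mean_p1 = forward(model, x)[:, 1].mean()
        assert 0.1 < mean_p1 < 0.9

    def test_finite_on_extreme_inputs(self, default_model):
        x = np.array([np.full(73, 1e6), np.full(73, -1e6), np.zeros(73)])
        probs = forward(default_model, x)
        assert np.all(np.isfinite(probs))

    def test_width_mismatch_rejected(self):
        model = build_model(CFNNConfig(pad_features=False))
        with pytest.raises(ValidationError, match="width"):
            forward(model, np.zeros((2, 70)))

    def test_narrow_input_zero_padded(self, default_model):
        probs = forward(default_model, np.random.default_rng(4).standard_normal((2, 70)))
        assert probs.shape == (2, 2)

    def test_fuzzy_layer_matches_standalone_operator(self, default_model):
        layer = default_model.layers[4]
        x = np.random.default_rng(5).standard_normal((1, layer.n_inputs))
        bank = FuzzyRuleBank(means=layer.params["means"], sigmas=layer.sigmas())
        np.testing.assert_allclose(
            layer.forward(x)[0], fuzzify(x[0], bank), rtol=1e-12
        )


def _separable_data(n=48, width=9, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, n)
    X = rng.standard_normal((n, width)) * 0.3
    X[:, 0] += 2.0 * y  # single informative column
    return X, y


class TestTraining:
    def test_loss_decreases(self):
        cfg = CFNNConfig(**TINY)
        X, y = _separable_data()
        model = build_model(cfg)
        history = train(model, X, labels=y, cfg=cfg)
        assert history["loss"][-1] <= history["loss"][0]
        assert len(history["loss"]) == cfg.epochs

    def test_same_seed_identical_weights_and_history(self):
        cfg = CFNNConfig(**TINY, seed=7)
        X, y = _separable_data()
        runs = []
        for _ in range(2):
            model = build_model(cfg)
            history = train(model, X, labels=y, cfg=cfg)
            runs.append((model.get_weights(), history))
        for key in runs[0][0]:
            np.testing.assert_array_equal(runs[0][0][key], runs[1][0][key])
        assert runs[0][1] == runs[1][1]

    def test_single_class_rejected(self):
        cfg = CFNNConfig(**TINY)
        X, _ = _separable_data()
        with pytest.raises(ValidationError, match="class"):
            train(build_model(cfg), X, labels=np.zeros(len(X), dtype=int), cfg=cfg)

    def test_defuzz_centers_receive_gradient(self):
        cfg = CFNNConfig(**TINY)
        X, y = _separable_data()
        model = build_model(cfg)
        model.zero_grads()
        batch = model.adapt(X, fit_scaler=True)
        probs = softmax(model.logits(batch, training=True))
        onehot = np.eye(2)[y]
        model._backward((probs - onehot) / len(X))
        C_grad = model.layers[-1].grads["C"]
        assert np.all(C_grad != 0)

    def test_learns_separable_toy_problem(self):
        cfg = CFNNConfig(**{**TINY, "epochs": 100}, seed=1)
        X, y = _separable_data(n=64)
        model = build_model(cfg)
        train(model, X, labels=y, cfg=cfg)
        assert (model.predict(X) == y).mean() >= 0.9


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        cfg = CFNNConfig(**TINY, seed=3)
        X, y = _separable_data()
        model = build_model(cfg)
        train(model, X, labels=y, cfg=cfg)
        path = tmp_path / "model.json"
        save_model(model, path)
        clone = load_model(path)
        np.testing.assert_array_equal(model.predict(X), clone.predict(X))
        np.testing.assert_allclose(
            model.predict_proba(X), clone.predict_proba(X), rtol=1e-12
        )


class TestConfigValidation:
    def test_input_shorter_than_kernel_rejected(self):
        with pytest.raises(ValidationError):
            CFNNConfig(input_len=3, conv1_kernel=5)

    def test_nonbinary_head_rejected(self):
        with pytest.raises(ValidationError):
            CFNNConfig(n_classes=3)

    def test_config_hash_stable(self):
        assert CFNNConfig().hash() == CFNNConfig().hash()
        assert CFNNConfig().hash() != CFNNConfig(seed=1).hash()
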
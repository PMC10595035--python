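import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from needlesense import bnn
from needlesense.bnn import (
    BNNConfig,
    BNNModel,
    _softplus_inv,
    _VarLayer,
    confusion_matrix,
    encode_labels,
    init_model,
    kl_to_prior,
    load_model,
    loss,
    predict,
    save_model,
    train,
)
from needlesense.errors import DivergenceError, FormatError, ValidationError


def tiny_model(layer_sizes=(1, 1), w_mu=0.0, w_spread=1.0,
               b_mu=0.0, b_spread=1.0) -> BNNModel:
    """Hand-built model with every weight/bias posterior set explicitly."""
    cfg = BNNConfig(layer_sizes=layer_sizes)
    layers = []
    for n_in, n_out in zip(layer_sizes, layer_sizes[1:]):
        layers.append(
            _VarLayer(
                w_mu=np.full((n_in, n_out), float(w_mu)),
                w_rho=np.full((n_in, n_out), _softplus_inv(w_spread)),
                b_mu=np.full(n_out, float(b_mu)),
                b_rho=np.full(n_out, _softplus_inv(b_spread)),
            )
        )
    return BNNModel(config=cfg, layers=layers)


def kl_by_quadrature(mu, s, m0=0.0, s0=1.0):
    """Independent oracle: numeric integral of p log(p/q)."""
    p = stats.norm(mu, s)
    q = stats.norm(m0, s0)

    def integrand(w):
        return p.pdf(w) * (p.logpdf(w) - q.logpdf(w))

    val, _ = integrate.quad(integrand, mu - 12 * s, mu + 12 * s, limit=200)
    return val


class TestKL:
    def test_posterior_equal_prior_is_zero(self):
        model = tiny_model((1, 1), w_mu=0.0, w_spread=1.0)
        assert kl_to_prior(model) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("mu", [0.5, -1.3, 2.0])
    def test_mean_shift_closed_form(self, mu):
        # single weight N(mu, 1) vs N(0, 1): KL = mu^2 / 2 (bias kept at prior)
        model = tiny_model((1, 1), w_mu=mu, w_spread=1.0)
        expected = mu**2 / 2
        assert kl_to_prior(model) == pytest.approx(expected, rel=1e-12)
        assert kl_to_prior(model) == pytest.approx(kl_by_quadrature(mu, 1.0), rel=1e-8)

    @pytest.mark.parametrize("s", [0.3, 0.9, 2.5])
    def test_spread_change_closed_form(self, s):
        # single weight N(0, s^2) vs N(0, 1): KL = (s^2 - 1 - ln s^2) / 2
        model = tiny_model((1, 1), w_mu=0.0, w_spread=s)
        expected = (s**2 - 1 - np.log(s**2)) / 2
        assert kl_to_prior(model) == pytest.approx(expected, rel=1e-12)
        assert kl_to_prior(model) == pytest.approx(kl_by_quadrature(0.0, s), rel=1e-8)

    @settings(max_examples=100, deadline=None)
    @given(
        mu=st.floats(min_value=-5, max_value=5),
        s=st.floats(min_value=0.05, max_value=5),
    )
    def test_nonnegative_and_zero_iff_prior(self, mu, s):
        model = tiny_model((1, 1), w_mu=mu, w_spread=s)
        kl = kl_to_prior(model)
        assert kl >= -1e-12
        if abs(mu) < 1e-12 and abs(s - 1) < 1e-12:
            assert kl == pytest.approx(0.0, abs=1e-10)
        elif abs(mu) > 1e-3 or abs(s - 1) > 1e-3:
            assert kl > 0

    def test_nonpositive_spread_rejected(self):
        model = tiny_model((1, 1))
        model.layers[0].w_rho[:] = -np.inf  # softplus -> spread 0
        with pytest.raises(ValidationError):
            kl_to_prior(model)


class TestLoss:
    def test_empty_batch_rejected(self, trained_model):
        with pytest.raises(ValidationError):
            loss(np.empty((0, 15)), np.empty(0, int), trained_model)

    def test_kl_flag_off_equals_plain_ce(self, trained_model, train_features):
        x, y = train_features
        cfg_on = trained_model.config
        cfg_off = BNNConfig(**{**cfg_on.__dict__, "kl_enabled": False})
        full = loss(x, y, trained_model, cfg_on, seed=42)
        ce = loss(x, y, trained_model, cfg_off, seed=42)
        assert full == pytest.approx(ce + kl_to_prior(trained_model) / len(x), rel=1e-12)

    def test_kl_multiplier_is_one_over_526(self, trained_model, train_features):
        x, y = train_features
        assert len(x) == 526  # 150 + 81 + 149 + 146, the whole dataset as one batch
        ce = loss(x, y, trained_model,
                  BNNConfig(**{**trained_model.config.__dict__, "kl_enabled": False}),
                  seed=0)
        full = loss(x, y, trained_model, seed=0)
        assert full - ce == pytest.approx(kl_to_prior(trained_model) / 526, rel=1e-9)

    def test_perfect_separator_ce_near_zero(self):
        # deterministic limit: separating weights, spreads -> 0+, KL off
        model = tiny_model((2, 2), w_spread=1e-9, b_spread=1e-9)
        model.layers[0].w_mu[:] = np.array([[50.0, -50.0], [-50.0, 50.0]])
        x = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.1]])
        y = np.array([0, 1, 0])
        cfg = BNNConfig(layer_sizes=(2, 2), kl_enabled=False)
        assert loss(x, y, model, cfg, seed=1) == pytest.approx(0.0, abs=1e-6)


class TestTrain:
    def test_separable_blobs_high_accuracy(self):
        rng = np.random.default_rng(5)
        n = 100
        x0 = rng.normal([-4, -4], 0.5, size=(n, 2))
        x1 = rng.normal([4, 4], 0.5, size=(n, 2))
        x = np.vstack([x0, x1])
        y = np.array([0] * n + [1] * n)
        cfg = BNNConfig(layer_sizes=(2, 10, 10, 2), epochs=200, seed=0)
        model, trace = train(x, y, cfg)
        xt = np.vstack([rng.normal([-4, -4], 0.5, size=(50, 2)),
                        rng.normal([4, 4], 0.5, size=(50, 2))])
        yt = np.array([0] * 50 + [1] * 50)
        preds = [predict(f, model, seed=9).class_index for f in xt]
        assert np.mean(np.array(preds) == yt) >= 0.95

    def test_same_seed_identical_traces(self, train_features):
        x, y = train_features
        cfg = BNNConfig(epochs=50, seed=13)
        _, trace_a = train(x, y, cfg)
        _, trace_b = train(x, y, cfg)
        assert np.array_equal(trace_a, trace_b)

    def test_single_class_rejected(self):
        x = np.random.default_rng(0).normal(size=(10, 15))
        with pytest.raises(ValidationError):
            train(x, np.zeros(10, int))

    def test_nonfinite_features_rejected(self):
        x = np.zeros((4, 15))
        x[1, 3] = np.inf
        with pytest.raises(ValidationError):
            train(x, np.array([0, 1, 0, 1]))

    def test_divergence_reports_epoch(self, train_features):
        x, y = train_features
        cfg = BNNConfig(epochs=10, seed=0, lr=1e160)
        with pytest.raises(DivergenceError) as exc:
            train(x, y, cfg)
        assert 0 < exc.value.epoch < 10

    def test_final_cost_below_initial(self, cost_trace):
        assert cost_trace[-50:].mean() <= cost_trace[0]

    def test_phantom_per_class_recall(self, trained_model, test_dataset, table):
        from needlesense.phantom import remap_features

        x, y = remap_features(test_dataset, table)
        cm = confusion_matrix(trained_model, x, y, seed=17)
        recall = cm.diagonal() / cm.sum(axis=1)
        assert np.all(recall >= 0.9)


class TestPredict:
    def test_degenerate_posterior_matches_deterministic_forward(self):
        model = tiny_model((15, 4), w_spread=1e-12, b_spread=1e-12)
        rng = np.random.default_rng(3)
        model.layers[0].w_mu[:] = rng.normal(size=(15, 4))
        x = rng.normal(size=15)
        pred = predict(x, model, n_samples=1, seed=0)
        det = model.forward_deterministic(x)[0]
        assert pred.mean_probs == pytest.approx(det, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=20000), min_size=15, max_size=15))
    def test_mean_probs_normalized(self, trained_model, feats):
        pred = predict(np.array(feats), trained_model, n_samples=10, seed=1)
        assert pred.mean_probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert pred.class_label == trained_model.classes[int(np.argmax(pred.mean_probs))]
        assert pred.spread_of_max >= 0

    def test_wrong_feature_count_rejected(self, trained_model):
        with pytest.raises(ValidationError):
            predict(np.zeros(14), trained_model)

    def test_n_samples_must_be_positive(self, trained_model):
        with pytest.raises(ValidationError):
            predict(np.zeros(15), trained_model, n_samples=0)

    def test_seed_reproducibility(self, trained_model):
        x = np.full(15, 5000.0)
        a = predict(x, trained_model, n_samples=30, seed=21)
        b = predict(x, trained_model, n_samples=30, seed=21)
        assert np.array_equal(a.mean_probs, b.mean_probs)
        assert a.spread_of_max == b.spread_of_max


class TestConfusionMatrix:
    def test_perfect_classifier_diagonal_with_reference_counts(self):
        # identity-like model on one-hot features is an exact classifier
        model = tiny_model((4, 4), w_spread=1e-12, b_spread=1e-12)
        model.layers[0].w_mu[:] = 50 * np.eye(4)
        counts = [150, 81, 149, 146]
        x, y = [], []
        for cls, n in enumerate(counts):
            x += [np.eye(4)[cls]] * n
            y += [cls] * n
        cm = confusion_matrix(model, np.array(x), np.array(y), n_samples=1)
        assert np.array_equal(cm, np.diag(counts))
        assert cm.sum() == 526

    def test_constant_predictor_single_column(self):
        model = tiny_model((4, 4), w_spread=1e-12, b_spread=1e-12)
        model.layers[0].b_mu[:] = np.array([0.0, 100.0, 0.0, 0.0])
        x = np.random.default_rng(0).normal(size=(20, 4))
        y = np.arange(20) % 4
        cm = confusion_matrix(model, x, y, n_samples=1)
        assert cm[:, 1].sum() == 20
        assert cm.sum() == 20

    def test_row_sums_equal_class_counts(self, trained_model, test_dataset, table):
        from needlesense.phantom import remap_features

        x, y = remap_features(test_dataset, table)
        cm = confusion_matrix(trained_model, x, y, seed=5)
        assert np.array_equal(cm.sum(axis=1), np.bincount(y, minlength=4))


class TestSparsityTendency:
    def test_noise_feature_weights_shrink(self):
        """First-layer posterior means on pure-noise inputs end up smaller in
        magnitude than on signal-carrying inputs under the KL penalty."""
        rng = np.random.default_rng(8)
        n = 60  # small batch -> strong KL weight 1/60
        signal = rng.integers(0, 2, size=n)
        x = rng.normal(0, 1, size=(n, 15))
        x[:, :7] += 6.0 * (signal[:, None] - 0.5)  # features 0-6 carry the class
        cfg = BNNConfig(layer_sizes=(15, 10, 10, 2), epochs=800, seed=1,
                        standardize=False)
        model, _ = train(x, signal, cfg)
        w = np.abs(model.layers[0].w_mu)
        assert w[7:].mean() < w[:7].mean()


class TestSerialization:
    def test_round_trip_identical_predictions(self, trained_model, tmp_path):
        path = tmp_path / "model.json"
        save_model(trained_model, path)
        loaded = load_model(path)
        probe = np.full(15, 8000.0)
        a = predict(probe, trained_model, n_samples=20, seed=4)
        b = predict(probe, loaded, n_samples=20, seed=4)
        assert np.array_equal(a.mean_probs, b.mean_probs)
        assert a.class_label == b.class_label

    def test_unknown_version_refused(self, trained_model, tmp_path):
        import json

        path = tmp_path / "model.json"
        save_model(trained_model, path)
        data = json.loads(path.read_text())
        data["schema_version"] = 999
        path.write_text(json.dumps(data))
        with pytest.raises(FormatError):
            load_model(path)


class TestLabels:
    def test_class_order(self):
        assert bnn.CLASSES == ("skin", "fat", "ligament", "csf")
        assert np.array_equal(encode_labels(["CSF", "skin", "Fat"]), [3, 0, 1])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            encode_labels(["bone"])
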
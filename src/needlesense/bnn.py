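"""Variational Bayesian neural-network tissue classifier.

A fully connected 15-10-10-4 network whose weights carry independent Gaussian
posteriors N(mu, s^2) under a standard-normal prior.  Training minimises

    cost = CE + KLD / batch_size

by stochastic backpropagation: one reparameterized weight sample per step,
cross-entropy on the softmax outputs, and the analytic Gaussian-Gaussian KL
divergence of the posterior to the prior.  The whole dataset is one batch.
Prediction averages the softmax over posterior weight samples; the standard
deviation of the winning class's probability across samples is reported as
the confidence spread.

Implemented directly on numpy (manual gradients, hand-rolled Adam); no
autograd framework is required.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, DivergenceError, FormatError, ValidationError
from .remap import ConductivitySpectrum

__all__ = [
    "CLASSES",
    "BNNConfig",
    "BNNModel",
    "Prediction",
    "encode_labels",
    "kl_to_prior",
    "loss",
    "train",
    "predict",
    "confusion_matrix",
    "save_model",
    "load_model",
    "MODEL_SCHEMA_VERSION",
]

#: Canonical class ordering: skin=0, fat=1, ligament=2, CSF=3.
CLASSES: tuple[str, ...] = ("skin", "fat", "ligament", "csf")

MODEL_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class BNNConfig:
    """Architecture, prior and fitting hyper-parameters."""

    layer_sizes: tuple[int, ...] = (15, 10, 10, 4)
    prior_mean: float = 0.0
    prior_std: float = 1.0
    epochs: int = 2000
    lr: float = 0.01
    seed: int = 0
    kl_enabled: bool = True
    init_spread: float = 0.1
    standardize: bool = True
    n_predict_samples: int = 30

    def __post_init__(self) -> None:
        sizes = tuple(int(s) for s in self.layer_sizes)
        object.__setattr__(self, "layer_sizes", sizes)
        if len(sizes) < 2 or any(s < 1 for s in sizes):
            raise ConfigError(f"invalid layer sizes {sizes}")
        if self.prior_std <= 0:
            raise ConfigError("prior_std must be positive")
        if self.init_spread <= 0:
            raise ConfigError("init_spread must be positive")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: float) -> float:
    # inverse of log(1 + e^x); y must be > 0
    return float(np.log(np.expm1(y)))


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


@dataclass
class _VarLayer:
    """One dense layer with per-scalar Gaussian weight/bias posteriors."""

    w_mu: np.ndarray
    w_rho: np.ndarray  # spread = softplus(rho) > 0
    b_mu: np.ndarray
    b_rho: np.ndarray

    @property
    def w_spread(self) -> np.ndarray:
        return _softplus(self.w_rho)

    @property
    def b_spread(self) -> np.ndarray:
        return _softplus(self.b_rho)

    def sample(self, rng: np.random.Generator):
        eps_w = rng.standard_normal(self.w_mu.shape)
        eps_b = rng.standard_normal(self.b_mu.shape)
        w = self.w_mu + self.w_spread * eps_w
        b = self.b_mu + self.b_spread * eps_b
        return w, b, eps_w, eps_b

    def params(self) -> list[np.ndarray]:
        return [self.w_mu, self.w_rho, self.b_mu, self.b_rho]


@dataclass
class BNNModel:
    """Fitted posterior parameters plus the input standardizer."""

    config: BNNConfig
    layers: list[_VarLayer]
    classes: tuple[str, ...] = CLASSES
    feat_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    feat_std: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n_in = self.config.layer_sizes[0]
        if self.feat_mean is None:
            self.feat_mean = np.zeros(n_in)
        if self.feat_std is None:
            self.feat_std = np.ones(n_in)
        self.feat_mean = np.asarray(self.feat_mean, float)
        self.feat_std = np.asarray(self.feat_std, float)
        for layer in self.layers:
            if np.any(layer.w_spread <= 0) or np.any(layer.b_spread <= 0):
                raise ValidationError("posterior spreads must be strictly positive")

    @property
    def n_classes(self) -> int:
        return self.config.layer_sizes[-1]

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.feat_mean) / self.feat_std

    def forward_deterministic(self, x: np.ndarray) -> np.ndarray:
        """Forward pass at the posterior means (no weight sampling)."""
        h = self.standardize(np.atleast_2d(np.asarray(x, float)))
        for i, layer in enumerate(self.layers):
            h = h @ layer.w_mu + layer.b_mu
            if i < len(self.layers) - 1:
                h = np.maximum(h, 0.0)
        return _softmax(h)

    def forward_sampled(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Forward pass with one posterior weight sample."""
        h = self.standardize(np.atleast_2d(np.asarray(x, float)))
        for i, layer in enumerate(self.layers):
            w, b, _, _ = layer.sample(rng)
            h = h @ w + b
            if i < len(self.layers) - 1:
                h = np.maximum(h, 0.0)
        return _softmax(h)


def init_model(config: BNNConfig, rng: np.random.Generator | None = None) -> BNNModel:
    """Fresh model: small random posterior means, spread = init_spread."""
    rng = rng or np.random.default_rng(config.seed)
    rho0 = _softplus_inv(config.init_spread)
    layers = []
    for n_in, n_out in zip(config.layer_sizes, config.layer_sizes[1:]):
        layers.append(
            _VarLayer(
                w_mu=rng.standard_normal((n_in, n_out)) / np.sqrt(n_in),
                w_rho=np.full((n_in, n_out), rho0),
                b_mu=np.zeros(n_out),
                b_rho=np.full(n_out, rho0),
            )
        )
    return BNNModel(config=config, layers=layers)


@dataclass(frozen=True)
class Prediction:
    """Posterior-predictive classification of one spectrum."""

    class_label: str
    mean_probs: np.ndarray
    spread_of_max: float
    n_posterior_samples: int

    @property
    def class_index(self) -> int:
        return int(np.argmax(self.mean_probs))


def encode_labels(labels: Sequence[str], classes: Sequence[str] = CLASSES) -> np.ndarray:
    """Map string labels to class indices (case-insensitive)."""
    lut = {c.lower(): i for i, c in enumerate(classes)}
    out = np.empty(len(labels), dtype=int)
    for i, lab in enumerate(labels):
        key = str(lab).lower()
        if key not in lut:
            raise ValidationError(f"unknown class label {lab!r}; expected one of {classes}")
        out[i] = lut[key]
    return out


def kl_to_prior(model: BNNModel, config: BNNConfig | None = None) -> float:
    """Closed-form KL(posterior || prior), summed over every weight and bias.

    For scalar posterior N(mu, s^2) and prior N(m0, s0^2):
        KL = log(s0/s) + (s^2 + (mu - m0)^2) / (2 s0^2) - 1/2
    """
    config = config or model.config
    m0, s0 = config.prior_mean, config.prior_std
    total = 0.0
    for layer in model.layers:
        for mu, s in ((layer.w_mu, layer.w_spread), (layer.b_mu, layer.b_spread)):
            if not np.all(s > 0):
                raise ValidationError("posterior spread must be positive")
            total += float(
                np.sum(np.log(s0 / s) + (s**2 + (mu - m0) ** 2) / (2 * s0**2) - 0.5)
            )
    return total


def _kl_raw(model: BNNModel) -> float:
    """KL without parameter validation; degenerate spreads yield inf/nan so
    the training loop can report divergence instead of a parameter error."""
    m0, s0 = model.config.prior_mean, model.config.prior_std
    total = 0.0
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        for layer in model.layers:
            for mu, s in ((layer.w_mu, layer.w_spread), (layer.b_mu, layer.b_spread)):
                total += float(
                    np.sum(np.log(s0 / s) + (s**2 + (mu - m0) ** 2) / (2 * s0**2) - 0.5)
                )
    return total


def _cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(-np.mean(np.log(p)))


def loss(
    x: np.ndarray,
    y: np.ndarray,
    model: BNNModel,
    config: BNNConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """One stochastic evaluation of cost = CE + KLD / batch_size."""
    config = config or model.config
    x = np.atleast_2d(np.asarray(x, float))
    y = np.asarray(y, int)
    if len(x) == 0:
        raise ValidationError("empty batch")
    if y.min(initial=0) < 0 or y.max(initial=0) >= model.n_classes:
        raise ValidationError("labels outside class set")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = model.forward_sampled(x, rng)
    ce = _cross_entropy(probs, y)
    if config.kl_enabled:
        return ce + kl_to_prior(model, config) / len(x)
    return ce


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def _forward_backward(model: BNNModel, x_std: np.ndarray, y: np.ndarray,
                      rng: np.random.Generator, kl_scale: float):
    """One sampled forward pass, CE + scaled-KL cost, and parameter grads."""
    n = len(x_std)
    samples, acts = [], [x_std]
    h = x_std
    n_layers = len(model.layers)
    with np.errstate(over="ignore", invalid="ignore"):
        for i, layer in enumerate(model.layers):
            w, b, eps_w, eps_b = layer.sample(rng)
            samples.append((w, b, eps_w, eps_b))
            z = h @ w + b
            h = np.maximum(z, 0.0) if i < n_layers - 1 else z
            acts.append(h)
        probs = _softmax(acts[-1])
    ce = _cross_entropy(probs, y)
    cost = ce + (kl_scale * _kl_raw(model) if kl_scale else 0.0)

    grads: list[np.ndarray] = []
    onehot = np.zeros_like(probs)
    onehot[np.arange(n), y] = 1.0
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        delta = (probs - onehot) / n  # grad of mean CE wrt logits
        for i in range(n_layers - 1, -1, -1):
            layer = model.layers[i]
            w, b, eps_w, eps_b = samples[i]
            h_in = acts[i]
            g_w = h_in.T @ delta
            g_b = delta.sum(axis=0)
            sig_w = 1.0 / (1.0 + np.exp(-layer.w_rho))  # d softplus / d rho
            sig_b = 1.0 / (1.0 + np.exp(-layer.b_rho))
            g_wmu = g_w.copy()
            g_wrho = g_w * eps_w * sig_w
            g_bmu = g_b.copy()
            g_brho = g_b * eps_b * sig_b
            if kl_scale:
                m0 = model.config.prior_mean
                s0 = model.config.prior_std
                sw, sb = layer.w_spread, layer.b_spread
                g_wmu += kl_scale * (layer.w_mu - m0) / s0**2
                g_wrho += kl_scale * (sw / s0**2 - 1.0 / sw) * sig_w
                g_bmu += kl_scale * (layer.b_mu - m0) / s0**2
                g_brho += kl_scale * (sb / s0**2 - 1.0 / sb) * sig_b
            grads[:0] = [g_wmu, g_wrho, g_bmu, g_brho]
            if i > 0:
                delta = (delta @ w.T) * (acts[i] > 0)
    return cost, grads


def train(
    x: np.ndarray,
    y: np.ndarray | Sequence[str],
    config: BNNConfig | None = None,
) -> tuple[BNNModel, np.ndarray]:
    """Fit the variational posterior by full-batch stochastic backprop.

    Returns the fitted model and the per-epoch cost trace.  Deterministic for
    a fixed ``config.seed``.  Raises :class:`DivergenceError` if the cost
    becomes non-finite.
    """
    config = config or BNNConfig()
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[1] != config.layer_sizes[0]:
        raise ValidationError(
            f"feature width {x.shape[1]} != input layer {config.layer_sizes[0]}"
        )
    if not np.all(np.isfinite(x)):
        raise ValidationError("features must be finite")
    if len(x) == 0:
        raise ValidationError("empty training set")
    y_idx = np.asarray(y, int) if np.issubdtype(np.asarray(y).dtype, np.integer) \
        else encode_labels(list(y))
    if len(y_idx) != len(x):
        raise ValidationError("feature/label length mismatch")
    if len(np.unique(y_idx)) < 2:
        raise ValidationError("training set must contain at least two classes")

    rng = np.random.default_rng(config.seed)
    model = init_model(config, rng)
    if config.standardize:
        model.feat_mean = x.mean(axis=0)
        std = x.std(axis=0)
        model.feat_std = np.where(std > 0, std, 1.0)
    x_std = model.standardize(x)

    kl_scale = (1.0 / len(x)) if config.kl_enabled else 0.0
    params = [p for layer in model.layers for p in layer.params()]
    opt = _Adam(params, config.lr)
    trace = np.empty(config.epochs)
    for epoch in range(config.epochs):
        cost, grads = _forward_backward(model, x_std, y_idx, rng, kl_scale)
        if not np.isfinite(cost):
            raise DivergenceError(epoch)
        trace[epoch] = cost
        opt.step(params, grads)
    return model, trace


def predict(
    spec: ConductivitySpectrum | np.ndarray,
    model: BNNModel,
    n_samples: int | None = None,
    seed: int | np.random.Generator = 0,
) -> Prediction:
    """Posterior-predictive classification of one conductivity spectrum."""
    n_samples = n_samples if n_samples is not None else model.config.n_predict_samples
    if n_samples < 1:
        raise ValidationError("n_samples must be >= 1")
    feats = spec.sigma_us_cm if isinstance(spec, ConductivitySpectrum) else np.asarray(spec, float)
    if feats.shape != (model.config.layer_sizes[0],):
        raise ValidationError(
            f"expected {model.config.layer_sizes[0]} features, got shape {feats.shape}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = np.stack([model.forward_sampled(feats, rng)[0] for _ in range(n_samples)])
    mean_probs = draws.mean(axis=0)
    k = int(np.argmax(mean_probs))
    spread = float(draws[:, k].std())
    return Prediction(
        class_label=model.classes[k],
        mean_probs=mean_probs,
        spread_of_max=spread,
        n_posterior_samples=n_samples,
    )


def confusion_matrix(
    model: BNNModel,
    x: np.ndarray,
    y: np.ndarray | Sequence[str],
    n_samples: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Count matrix; rows are true classes, columns predicted classes."""
    x = np.atleast_2d(np.asarray(x, float))
    y_idx = np.asarray(y, int) if np.issubdtype(np.asarray(y).dtype, np.integer) \
        else encode_labels(list(y))
    rng = np.random.default_rng(seed)
    k = model.n_classes
    cm = np.zeros((k, k), dtype=int)
    for xi, yi in zip(x, y_idx):
        pred = predict(xi, model, n_samples=n_samples, seed=rng)
        cm[yi, pred.class_index] += 1
    return cm


# ---------------------------------------------------------------------------
# Model archive (single JSON file, versioned)
# ---------------------------------------------------------------------------

def _model_to_dict(model: BNNModel) -> dict:
    cfg = model.config
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "config": {
            "layer_sizes": list(cfg.layer_sizes),
            "prior_mean": cfg.prior_mean,
            "prior_std": cfg.prior_std,
            "epochs": cfg.epochs,
            "lr": cfg.lr,
            "seed": cfg.seed,
            "kl_enabled": cfg.kl_enabled,
            "init_spread": cfg.init_spread,
            "standardize": cfg.standardize,
            "n_predict_samples": cfg.n_predict_samples,
        },
        "classes": list(model.classes),
        "feat_mean": model.feat_mean.tolist(),
        "feat_std": model.feat_std.tolist(),
        "layers": [
            {
                "w_mu": layer.w_mu.tolist(),
                "w_rho": layer.w_rho.tolist(),
                "b_mu": layer.b_mu.tolist(),
                "b_rho": layer.b_rho.tolist(),
            }
            for layer in model.layers
        ],
    }


def save_model(model: BNNModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_model_to_dict(model), fh)
        fh.write("\n")


def load_model(path) -> BNNModel:
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    version = data.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"unsupported model schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    cfg = BNNConfig(
        layer_sizes=tuple(data["config"]["layer_sizes"]),
        prior_mean=data["config"]["prior_mean"],
        prior_std=data["config"]["prior_std"],
        epochs=data["config"]["epochs"],
        lr=data["config"]["lr"],
        seed=data["config"]["seed"],
        kl_enabled=data["config"]["kl_enabled"],
        init_spread=data["config"]["init_spread"],
        standardize=data["config"]["standardize"],
        n_predict_samples=data["config"]["n_predict_samples"],
    )
    layers = [
        _VarLayer(
            w_mu=np.array(layer["w_mu"], float),
            w_rho=np.array(layer["w_rho"], float),
            b_mu=np.array(layer["b_mu"], float),
            b_rho=np.array(layer["b_rho"], float),
        )
        for layer in data["layers"]
    ]
    return BNNModel(
        config=cfg,
        layers=layers,
        classes=tuple(data["classes"]),
        feat_mean=np.array(data["feat_mean"], float),
        feat_std=np.array(data["feat_std"], float),
    )
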
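"""Deep belief network regressor for model quality.

Two stacked restricted Boltzmann machines (visible units are real-valued
scores in [0, 1], hidden units are binary) are pretrained layer-wise with
one-step contrastive divergence (CD-1); a single logistic output node on
top yields a quality score in (0, 1). The whole network is then fine-tuned
as a feed-forward sigmoid net against mean squared error using BFGS with
analytic gradients. Training is deterministic for a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from modelqa.features import FeatureSetConfig, FeatureVector

MODEL_FORMAT = "modelqa-dbn-1"


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


@dataclass
class TrainConfig:
    """Hyper-parameters of the DBN.

    Defaults follow the configuration found to perform well for quality
    regression: 20 and 10 hidden nodes, CD learning rate 1e-4, weight cost
    0.007, momentum ramping from 0.5 to 0.9. ``learning_rate``,
    ``weight_cost`` and the momentum schedule apply to RBM pretraining only;
    fine-tuning is full-batch BFGS.
    """

    n1: int = 20
    n2: int = 10
    learning_rate: float = 0.0001
    weight_cost: float = 0.007
    momentum_initial: float = 0.5
    momentum_final: float = 0.9
    momentum_switch_epoch: int = 5
    pretrain_epochs: int = 100
    batch_size: int = 100
    bfgs_max_iter: int = 500
    bfgs_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("hidden layer sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.weight_cost < 0:
            raise ValueError("weight_cost must be >= 0")
        for m in (self.momentum_initial, self.momentum_final):
            if not 0.0 <= m < 1.0:
                raise ValueError("momentum must be in [0, 1)")

    def momentum_at(self, epoch: int) -> float:
        return self.momentum_initial if epoch < self.momentum_switch_epoch else self.momentum_final


@dataclass
class RBMLayer:
    """One RBM: weights (n_visible x n_hidden) and bias vectors."""

    W: np.ndarray
    vbias: np.ndarray
    hbias: np.ndarray

    def __post_init__(self) -> None:
        nv, nh = self.W.shape
        if self.vbias.shape != (nv,) or self.hbias.shape != (nh,):
            raise ValueError("RBM bias shapes inconsistent with weight matrix")
        if not (np.isfinite(self.W).all() and np.isfinite(self.vbias).all()
                and np.isfinite(self.hbias).all()):
            raise ValueError("RBM parameters must be finite")

    @property
    def n_visible(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def hidden_probabilities(self, visible: np.ndarray) -> np.ndarray:
        return sigmoid(visible @ self.W + self.hbias)


@dataclass
class RBMVelocity:
    """Momentum state accompanying an RBMLayer during CD training."""

    W: np.ndarray
    vbias: np.ndarray
    hbias: np.ndarray

    @classmethod
    def zeros_like(cls, layer: RBMLayer) -> "RBMVelocity":
        return cls(
            W=np.zeros_like(layer.W),
            vbias=np.zeros_like(layer.vbias),
            hbias=np.zeros_like(layer.hbias),
        )


@dataclass
class DBNModel:
    """Stacked-RBM regressor with a logistic output node.

    ``rbm1`` maps the input features to the first hidden layer, ``rbm2`` to
    the second; ``out_w``/``out_b`` parameterize the logistic output.
    Predictions are strictly inside (0, 1).
    """

    rbm1: RBMLayer
    rbm2: RBMLayer
    out_w: np.ndarray
    out_b: float
    feature_set: FeatureSetConfig
    config: TrainConfig
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rbm1.n_hidden != self.rbm2.n_visible:
            raise ValueError("rbm1 hidden size must equal rbm2 visible size")
        if self.out_w.shape != (self.rbm2.n_hidden,):
            raise ValueError("output weight size must equal rbm2 hidden size")

    @property
    def n_in(self) -> int:
        return self.rbm1.n_visible

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Deterministic feed-forward pass: sigmoid at both hidden layers and output."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        h1 = sigmoid(X @ self.rbm1.W + self.rbm1.hbias)
        h2 = sigmoid(h1 @ self.rbm2.W + self.rbm2.hbias)
        return sigmoid(h2 @ self.out_w + self.out_b)


def cd1_update(
    layer: RBMLayer,
    minibatch: np.ndarray,
    learning_rate: float,
    weight_cost: float,
    momentum: float,
    velocity: RBMVelocity,
    rng: np.random.Generator,
) -> float:
    """One CD-1 step on a minibatch; mutates ``layer`` and ``velocity`` in place.

    Positive phase uses hidden probabilities; the Gibbs step samples binary
    hidden states and reconstructs the visible layer as probabilities.
    The weight update is ``v_new = momentum * v + lr * (grad - weight_cost * W)``;
    biases carry momentum but no weight decay. Returns the mean squared
    reconstruction error of the minibatch.
    """
    v0 = np.atleast_2d(np.asarray(minibatch, dtype=float))
    if v0.shape[1] != layer.n_visible:
        raise ValueError(f"minibatch dim {v0.shape[1]} != n_visible {layer.n_visible}")
    n = v0.shape[0]
    h0_prob = sigmoid(v0 @ layer.W + layer.hbias)
    h0_state = (rng.random(h0_prob.shape) < h0_prob).astype(float)
    v1 = sigmoid(h0_state @ layer.W.T + layer.vbias)
    h1_prob = sigmoid(v1 @ layer.W + layer.hbias)

    grad_w = (v0.T @ h0_prob - v1.T @ h1_prob) / n
    grad_vb = (v0 - v1).mean(axis=0)
    grad_hb = (h0_prob - h1_prob).mean(axis=0)

    velocity.W = momentum * velocity.W + learning_rate * (grad_w - weight_cost * layer.W)
    velocity.vbias = momentum * velocity.vbias + learning_rate * grad_vb
    velocity.hbias = momentum * velocity.hbias + learning_rate * grad_hb
    layer.W += velocity.W
    layer.vbias += velocity.vbias
    layer.hbias += velocity.hbias
    return float(((v0 - v1) ** 2).mean())


def _train_rbm(
    X: np.ndarray, n_hidden: int, config: TrainConfig, rng: np.random.Generator
) -> Tuple[RBMLayer, List[float]]:
    """Train one RBM with CD-1 over minibatches; returns layer and per-epoch error."""
    n, nv = X.shape
    layer = RBMLayer(
        W=rng.normal(0.0, 0.01, size=(nv, n_hidden)),
        vbias=np.zeros(nv),
        hbias=np.zeros(n_hidden),
    )
    velocity = RBMVelocity.zeros_like(layer)
    errors: List[float] = []
    for epoch in range(config.pretrain_epochs):
        momentum = config.momentum_at(epoch)
        order = rng.permutation(n)
        epoch_err = []
        for start in range(0, n, config.batch_size):
            batch = X[order[start : start + config.batch_size]]
            err = cd1_update(
                layer, batch, config.learning_rate, config.weight_cost, momentum, velocity, rng
            )
            epoch_err.append(err)
        errors.append(float(np.mean(epoch_err)))
    return layer, errors


def pretrain(
    X: np.ndarray, config: TrainConfig, feature_set: Optional[FeatureSetConfig] = None
) -> DBNModel:
    """Layer-wise unsupervised pretraining of the RBM stack.

    The first RBM is trained on the feature matrix; the second on the first
    layer's hidden probabilities. The logistic output layer starts at zero
    (prediction 0.5 everywhere) and is learned during fine-tuning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("feature matrix must be non-empty and 2-D")
    if X.min() < 0.0 or X.max() > 1.0:
        raise ValueError("features must lie in [0, 1]")
    if feature_set is None:
        feature_set = _anonymous_feature_set(X.shape[1])
    rng = np.random.default_rng(config.seed)
    rbm1, err1 = _train_rbm(X, config.n1, config, rng)
    H1 = rbm1.hidden_probabilities(X)
    rbm2, err2 = _train_rbm(H1, config.n2, config, rng)
    return DBNModel(
        rbm1=rbm1,
        rbm2=rbm2,
        out_w=np.zeros(config.n2),
        out_b=0.0,
        feature_set=feature_set,
        config=config,
        metadata={
            "seed": config.seed,
            "pretrain_epochs": config.pretrain_epochs,
            "rbm1_reconstruction_error": err1,
            "rbm2_reconstruction_error": err2,
        },
    )


def _anonymous_feature_set(n: int) -> FeatureSetConfig:
    return FeatureSetConfig(name=f"generic{n}", keys=tuple(f"F{i}" for i in range(n)))


def _pack(model: DBNModel) -> np.ndarray:
    return np.concatenate(
        [
            model.rbm1.W.ravel(), model.rbm1.hbias,
            model.rbm2.W.ravel(), model.rbm2.hbias,
            model.out_w, [model.out_b],
        ]
    )


def _unpack(theta: np.ndarray, n_in: int, n1: int, n2: int):
    i = 0
    W1 = theta[i : i + n_in * n1].reshape(n_in, n1); i += n_in * n1
    b1 = theta[i : i + n1]; i += n1
    W2 = theta[i : i + n1 * n2].reshape(n1, n2); i += n1 * n2
    b2 = theta[i : i + n2]; i += n2
    w3 = theta[i : i + n2]; i += n2
    b3 = theta[i]
    return W1, b1, W2, b2, w3, b3


def mse_and_gradient(
    theta: np.ndarray, X: np.ndarray, t: np.ndarray, n_in: int, n1: int, n2: int
) -> Tuple[float, np.ndarray]:
    """Full-batch MSE of the sigmoid feed-forward net and its analytic gradient."""
    W1, b1, W2, b2, w3, b3 = _unpack(theta, n_in, n1, n2)
    n = X.shape[0]
    h1 = sigmoid(X @ W1 + b1)
    h2 = sigmoid(h1 @ W2 + b2)
    y = sigmoid(h2 @ w3 + b3)
    resid = y - t
    mse = float((resid ** 2).mean())
    d3 = (2.0 / n) * resid * y * (1.0 - y)
    g_w3 = h2.T @ d3
    g_b3 = d3.sum()
    d2 = np.outer(d3, w3) * h2 * (1.0 - h2)
    g_W2 = h1.T @ d2
    g_b2 = d2.sum(axis=0)
    d1 = (d2 @ W2.T) * h1 * (1.0 - h1)
    g_W1 = X.T @ d1
    g_b1 = d1.sum(axis=0)
    grad = np.concatenate([g_W1.ravel(), g_b1, g_W2.ravel(), g_b2, g_w3, [g_b3]])
    return mse, grad


def finetune_bfgs(model: DBNModel, X: np.ndarray, targets: np.ndarray,
                  config: Optional[TrainConfig] = None) -> DBNModel:
    """Supervised fine-tuning: BFGS on the full-batch MSE over all weights.

    The objective never increases between accepted iterates (BFGS line
    search guarantees descent); stops at ``bfgs_tol`` on the gradient or
    ``bfgs_max_iter`` iterations. Mutates and returns ``model``.
    """
    if config is None:
        config = model.config
    X = np.asarray(X, dtype=float)
    t = np.asarray(targets, dtype=float).ravel()
    if X.shape[0] != t.shape[0]:
        raise ValueError("features and targets disagree in length")
    n_in, n1, n2 = model.n_in, model.rbm1.n_hidden, model.rbm2.n_hidden
    theta0 = _pack(model)
    f0, _ = mse_and_gradient(theta0, X, t, n_in, n1, n2)
    if not np.isfinite(f0):
        raise FloatingPointError("non-finite objective at fine-tuning start")
    res = minimize(
        mse_and_gradient,
        theta0,
        args=(X, t, n_in, n1, n2),
        jac=True,
        method="BFGS",
        options={"maxiter": config.bfgs_max_iter, "gtol": config.bfgs_tol},
    )
    if not np.isfinite(res.fun):
        raise FloatingPointError("non-finite objective during fine-tuning")
    W1, b1, W2, b2, w3, b3 = _unpack(res.x, n_in, n1, n2)
    model.rbm1.W, model.rbm1.hbias = W1, b1
    model.rbm2.W, model.rbm2.hbias = W2, b2
    model.out_w, model.out_b = w3, float(b3)
    model.metadata.update(
        {"final_mse": float(res.fun), "initial_mse": f0, "bfgs_iterations": int(res.nit)}
    )
    return model


def train(X: np.ndarray, targets: np.ndarray, config: TrainConfig,
          feature_set: Optional[FeatureSetConfig] = None) -> DBNModel:
    """Pretrain then fine-tune a DBN on a feature matrix and quality targets."""
    model = pretrain(X, config, feature_set=feature_set)
    return finetune_bfgs(model, X, targets, config)


def predict_quality(model: DBNModel, features) -> float:
    """Predicted quality in (0, 1) for one feature vector."""
    if isinstance(features, FeatureVector):
        if features.config.keys != model.feature_set.keys:
            raise ValueError(
                f"feature set mismatch: vector {features.config.name} vs model "
                f"{model.feature_set.name}"
            )
        x = features.as_array()
    else:
        x = np.asarray(features, dtype=float).ravel()
        if x.shape[0] != model.n_in:
            raise ValueError(f"expected {model.n_in} features, got {x.shape[0]}")
    return float(model.forward(x)[0])


@dataclass
class CVResult:
    """5-fold cross-validation output: per-fold and mean MAE, held-out predictions."""

    per_fold_mae: List[float]
    mean_mae: float
    predictions: np.ndarray
    fold_of_sample: np.ndarray


def cross_validate(X: np.ndarray, targets: np.ndarray, config: TrainConfig, k: int = 5) -> CVResult:
    """k-fold cross-validation of the full pretrain + fine-tune pipeline.

    Samples are shuffled with the config seed and split into k folds whose
    sizes differ by at most one; each fold is predicted by a model trained
    on the remaining folds. Reports MAE per fold and its mean.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    X = np.asarray(X, dtype=float)
    t = np.asarray(targets, dtype=float).ravel()
    n = X.shape[0]
    if n < k:
        raise ValueError(f"need at least {k} samples, got {n}")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    preds = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    maes: List[float] = []
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(order, test_idx, assume_unique=True)
        model = train(X[train_idx], t[train_idx], config)
        p = model.forward(X[test_idx])
        preds[test_idx] = p
        fold_of[test_idx] = fi
        maes.append(float(np.abs(p - t[test_idx]).mean()))
    return CVResult(
        per_fold_mae=maes,
        mean_mae=float(np.mean(maes)),
        predictions=preds,
        fold_of_sample=fold_of,
    )


def save_model(model: DBNModel, path) -> None:
    """Serialize a DBN to JSON (weights as nested lists, config, feature set)."""
    payload = {
        "format": MODEL_FORMAT,
        "feature_set": {"name": model.feature_set.name, "keys": list(model.feature_set.keys)},
        "config": asdict(model.config),
        "weights": {
            "rbm1": {"W": model.rbm1.W.tolist(), "vbias": model.rbm1.vbias.tolist(),
                     "hbias": model.rbm1.hbias.tolist()},
            "rbm2": {"W": model.rbm2.W.tolist(), "vbias": model.rbm2.vbias.tolist(),
                     "hbias": model.rbm2.hbias.tolist()},
            "out_w": model.out_w.tolist(),
            "out_b": model.out_b,
        },
        "metadata": {k: v for k, v in model.metadata.items()
                     if isinstance(v, (int, float, str, list))},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> DBNModel:
    """Load a DBN saved by :func:`save_model`; predictions are bit-identical."""
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ValueError(f"{path}: corrupt model file ({e})") from e
    if payload.get("format") != MODEL_FORMAT:
        raise ValueError(f"{path}: unsupported model format {payload.get('format')!r}")
    fs = FeatureSetConfig(name=payload["feature_set"]["name"],
                          keys=tuple(payload["feature_set"]["keys"]))
    config = TrainConfig(**payload["config"])
    w = payload["weights"]
    rbm1 = RBMLayer(W=np.array(w["rbm1"]["W"]), vbias=np.array(w["rbm1"]["vbias"]),
                    hbias=np.array(w["rbm1"]["hbias"]))
    rbm2 = RBMLayer(W=np.array(w["rbm2"]["W"]), vbias=np.array(w["rbm2"]["vbias"]),
                    hbias=np.array(w["rbm2"]["hbias"]))
    if rbm1.n_visible != len(fs.keys):
        raise ValueError(
            f"{path}: weight shape {rbm1.n_visible} inconsistent with "
            f"feature set of {len(fs.keys)}"
        )
    return DBNModel(
        rbm1=rbm1, rbm2=rbm2,
        out_w=np.array(w["out_w"]), out_b=float(w["out_b"]),
        feature_set=fs, config=config, metadata=payload.get("metadata", {}),
    )
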
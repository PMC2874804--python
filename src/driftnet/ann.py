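"""A small feed-forward neural network trained by back-propagation.

The drift-time regressor is a fully connected 4-H-1 network (default H = 3):
four normalized descriptor inputs, one logistic hidden layer, one logistic
output node.  Every non-input node i computes

    net_i = sum_j w_ij a_j + theta_i,        a_i = 1 / (1 + exp(-net_i))

so the raw output lies in (0, 1).  Drift times (milliseconds, up to ~18 ms
for singly charged tryptic peptides on a travelling-wave instrument) are
affinely mapped into [margin, 1 - margin] of the output range before the
mean-squared-error loss is computed, and predictions are inverse-mapped
back to milliseconds.

Training is plain gradient descent with momentum on the full batch by
default (an online per-sample mode is available); with a fixed seed the
whole procedure — weight initialization included — is deterministic.
One model is trained per charge state, since drift time scales strongly
with charge.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DivergenceError, ValidationError
from .features import (
    FeatureMatrix,
    ModificationPolicy,
    NormalizationParams,
    Peptide,
    PKaTable,
    apply_normalization,
    featurize_dataset,
)


def logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class TrainingConfig:
    """Back-propagation hyperparameters.

    Defaults are conventional small-network settings: gradient descent with
    heavy momentum, a fixed epoch budget, an early stop when the mean
    squared error on the scaled targets drops below ``loss_tolerance``, and
    uniform weight initialization on [-init_range, init_range].

    ``learning_rate`` is the *initial* step size.  In full-batch mode the
    step size is adapted bold-driver style — grown 5% after an epoch that
    lowers the loss, halved (with a momentum reset and the step undone)
    after one that raises it — which makes convergence insensitive to the
    scale of the problem.  The online mode uses the fixed rate as given.
    """

    learning_rate: float = 0.05
    momentum: float = 0.9
    max_epochs: int = 5000
    loss_tolerance: float = 1e-5
    init_range: float = 0.5
    seed: int = 0
    online: bool = False  # per-sample updates instead of full batch

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or not math.isfinite(self.learning_rate):
            raise ValidationError("learning_rate must be positive and finite")
        if not (0 <= self.momentum < 1):
            raise ValidationError("momentum must lie in [0, 1)")
        if self.max_epochs < 1:
            raise ValidationError("max_epochs must be >= 1")
        if self.loss_tolerance <= 0:
            raise ValidationError("loss_tolerance must be positive")
        if self.init_range < 0:
            raise ValidationError("init_range must be non-negative")


@dataclass(frozen=True)
class TargetScaler:
    """Affine map between drift time (ms) and the logistic output range.

    [t_min, t_max] maps onto [margin, 1 - margin]; the margin keeps targets
    away from the activation asymptotes where gradients vanish.
    """

    t_min: float
    t_max: float
    margin: float = 0.1

    def __post_init__(self) -> None:
        if not (self.t_min < self.t_max):
            raise ConfigurationError(
                f"target scaler requires t_min < t_max, got [{self.t_min}, {self.t_max}]"
            )
        if not (0 <= self.margin < 0.5):
            raise ConfigurationError("margin must lie in [0, 0.5)")

    @classmethod
    def fit(cls, t: Sequence[float], margin: float = 0.1) -> "TargetScaler":
        t = np.asarray(t, dtype=float)
        if t.size == 0:
            raise ValidationError("cannot fit a target scaler to an empty target set")
        lo, hi = float(t.min()), float(t.max())
        if lo == hi:
            # a constant target still needs an invertible map
            lo, hi = lo - 0.5, hi + 0.5
        return cls(t_min=lo, t_max=hi, margin=margin)

    def scale(self, t):
        t = np.asarray(t, dtype=float)
        return self.margin + (1 - 2 * self.margin) * (t - self.t_min) / (self.t_max - self.t_min)

    def unscale(self, y):
        y = np.asarray(y, dtype=float)
        return self.t_min + (y - self.margin) * (self.t_max - self.t_min) / (1 - 2 * self.margin)


@dataclass
class ANNModel:
    """Weights, biases and scaling state of a 4-H-1 drift-time regressor.

    ``w_hidden`` has shape (H, 4), ``w_out`` shape (1, H); biases are the
    per-node theta terms.  ``feature_params`` and ``target_scaler`` are the
    normalization fitted on the training data, stored so prediction always
    reuses the training-time scaling.
    """

    w_hidden: np.ndarray
    b_hidden: np.ndarray
    w_out: np.ndarray
    b_out: np.ndarray
    target_scaler: TargetScaler | None = None
    feature_params: NormalizationParams | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        h, n_in = self.w_hidden.shape
        if self.b_hidden.shape != (h,) or self.w_out.shape != (1, h) or self.b_out.shape != (1,):
            raise ValidationError("weight/bias shapes are inconsistent with the layer sizes")

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w_hidden.shape[1], self.w_hidden.shape[0], 1)

    def to_dict(self) -> dict:
        d = {
            "layer_sizes": list(self.layer_sizes),
            "w_hidden": self.w_hidden.tolist(),
            "b_hidden": self.b_hidden.tolist(),
            "w_out": self.w_out.tolist(),
            "b_out": self.b_out.tolist(),
            "target_scaler": asdict(self.target_scaler) if self.target_scaler else None,
            "feature_params": (
                {"f_min": self.feature_params.f_min.tolist(),
                 "f_max": self.feature_params.f_max.tolist()}
                if self.feature_params else None
            ),
            "metadata": self.metadata,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ANNModel":
        return cls(
            w_hidden=np.asarray(d["w_hidden"], dtype=float),
            b_hidden=np.asarray(d["b_hidden"], dtype=float),
            w_out=np.asarray(d["w_out"], dtype=float),
            b_out=np.asarray(d["b_out"], dtype=float),
            target_scaler=TargetScaler(**d["target_scaler"]) if d.get("target_scaler") else None,
            feature_params=(
                NormalizationParams(
                    f_min=np.asarray(d["feature_params"]["f_min"], dtype=float),
                    f_max=np.asarray(d["feature_params"]["f_max"], dtype=float),
                )
                if d.get("feature_params") else None
            ),
            metadata=dict(d.get("metadata", {})),
        )

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ANNModel":
        return cls.from_dict(json.loads(text))


def init_network(hidden_nodes: int = 3, config: TrainingConfig = TrainingConfig(),
                 n_inputs: int = 4) -> ANNModel:
    """Seeded uniform initialization of all weights and biases.

    Draws from U[-init_range, init_range]; an identical seed reproduces the
    model bitwise.
    """
    if hidden_nodes < 1:
        raise ValidationError(f"hidden layer needs at least one node, got {hidden_nodes}")
    rng = np.random.default_rng(config.seed)
    r = config.init_range
    return ANNModel(
        w_hidden=rng.uniform(-r, r, size=(hidden_nodes, n_inputs)),
        b_hidden=rng.uniform(-r, r, size=hidden_nodes),
        w_out=rng.uniform(-r, r, size=(1, hidden_nodes)),
        b_out=rng.uniform(-r, r, size=1),
        metadata={"seed": config.seed},
    )


def forward(model: ANNModel, x: np.ndarray) -> tuple[float, np.ndarray]:
    """Single forward pass: returns (output activation, hidden activations)."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.layer_sizes[0],):
        raise ValidationError(
            f"expected input of shape ({model.layer_sizes[0]},), got {x.shape}"
        )
    a_hidden = logistic(model.w_hidden @ x + model.b_hidden)
    a_out = logistic(model.w_out @ a_hidden + model.b_out)
    return float(a_out[0]), a_hidden


def _forward_batch(model: ANNModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    A1 = logistic(model.w_hidden @ X + model.b_hidden[:, None])
    A2 = logistic(model.w_out @ A1 + model.b_out[:, None])
    return A2, A1


def loss_and_gradients(model: ANNModel, X: np.ndarray, y: np.ndarray):
    """MSE loss on scaled targets and its gradients w.r.t. all parameters.

    X is 4 x N (normalized features), y is length-N (scaled targets).
    Returns (loss, grads) with grads keyed like the model attributes.
    Exposed so the back-propagated gradients can be checked against finite
    differences.
    """
    n = X.shape[1]
    A2, A1 = _forward_batch(model, X)
    err = A2 - y[None, :]
    loss = float(np.mean(err ** 2))
    dZ2 = (2.0 / n) * err * A2 * (1 - A2)          # 1 x N
    dZ1 = (model.w_out.T @ dZ2) * A1 * (1 - A1)    # H x N
    grads = {
        "w_out": dZ2 @ A1.T,
        "b_out": dZ2.sum(axis=1),
        "w_hidden": dZ1 @ X.T,
        "b_hidden": dZ1.sum(axis=1),
    }
    return loss, grads


def train_backprop(
    model: ANNModel,
    X: FeatureMatrix | np.ndarray,
    t: Sequence[float],
    config: TrainingConfig = TrainingConfig(),
) -> tuple[ANNModel, list[float]]:
    """Gradient-descent training with momentum; returns (model, loss trace).

    Columns of X are normalized feature vectors; t holds drift times in ms,
    scaled through the model's target scaler (fitted here from t if the
    model has none).  Stops at ``max_epochs`` or when the epoch MSE drops
    below ``loss_tolerance``.  In full-batch mode a rejected step (one that
    raises the loss) is undone, so the logged loss trace is non-increasing.
    Fully deterministic for fixed (data, config, initial model).
    """
    Xv = X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float)
    if Xv.ndim != 2 or Xv.shape[1] == 0 or t.size == 0:
        raise ValidationError("training requires a non-empty feature matrix and target vector")
    if Xv.shape[1] != t.size:
        raise ValidationError(
            f"feature matrix has {Xv.shape[1]} columns but {t.size} targets were given"
        )
    scaler = model.target_scaler or TargetScaler.fit(t)
    y = scaler.scale(t)

    m = ANNModel(
        w_hidden=model.w_hidden.copy(), b_hidden=model.b_hidden.copy(),
        w_out=model.w_out.copy(), b_out=model.b_out.copy(),
        target_scaler=scaler, feature_params=model.feature_params,
        metadata=dict(model.metadata),
    )
    vel = {k: np.zeros_like(getattr(m, k)) for k in ("w_hidden", "b_hidden", "w_out", "b_out")}
    trace: list[float] = []
    rng = np.random.default_rng(config.seed)  # only used for online-order shuffling

    param_keys = ("w_hidden", "b_hidden", "w_out", "b_out")
    lr = config.learning_rate
    for epoch in range(config.max_epochs):
        if config.online:
            order = rng.permutation(Xv.shape[1])
            for i in order:
                _, grads = loss_and_gradients(m, Xv[:, [i]], y[[i]])
                for k, g in grads.items():
                    vel[k] = config.momentum * vel[k] - lr * g
                    setattr(m, k, getattr(m, k) + vel[k])
            loss, _ = loss_and_gradients(m, Xv, y)
            if not math.isfinite(loss):
                raise DivergenceError(epoch)
            trace.append(loss)
        else:
            loss, grads = loss_and_gradients(m, Xv, y)
            if not math.isfinite(loss):
                raise DivergenceError(epoch)
            trace.append(loss)
            if loss < config.loss_tolerance:
                break
            backup = {k: getattr(m, k).copy() for k in param_keys}
            for k, g in grads.items():
                vel[k] = config.momentum * vel[k] - lr * g
                setattr(m, k, getattr(m, k) + vel[k])
            new_loss, _ = loss_and_gradients(m, Xv, y)
            if not math.isfinite(new_loss) or new_loss > loss:
                # bold driver: undo the step, kill the momentum, back off
                for k in param_keys:
                    setattr(m, k, backup[k])
                    vel[k] = np.zeros_like(vel[k])
                lr *= 0.5
            else:
                lr *= 1.05
        if loss < config.loss_tolerance:
            break
    m.metadata.setdefault("training", {})
    m.metadata["training"] = {
        "epochs_run": len(trace),
        "final_loss": trace[-1],
        "config": asdict(config),
    }
    return m, trace


def predict_drift_time(
    model: ANNModel,
    peptides: Sequence[Peptide],
    pka: PKaTable | None = None,
    mods: ModificationPolicy = ModificationPolicy(),
) -> np.ndarray:
    """Predicted drift times (ms) for a peptide dataset.

    Features are normalized with the model's stored training parameters and
    the output activation is inverse-scaled to milliseconds.  A charge state
    different from the model's training charge triggers a warning, since a
    separate model is trained per charge state.
    """
    if model.feature_params is None or model.target_scaler is None:
        raise ConfigurationError("model is missing feature normalization or target scaling state")
    trained_charge = model.metadata.get("charge")
    if trained_charge is not None:
        off = sorted({p.charge for p in peptides} - {trained_charge})
        if off:
            warnings.warn(
                f"model was trained on charge {trained_charge} but received charge(s) {off}",
                stacklevel=2,
            )
    M = featurize_dataset(peptides, pka=pka, mods=mods)
    Xn = apply_normalization(M, model.feature_params).values
    A2, _ = _forward_batch(model, Xn)
    return model.target_scaler.unscale(A2[0])
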
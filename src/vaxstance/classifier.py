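"""Two-layer fully connected stance classifier.

Architecture: input -> FC1 (ReLU, dropout during training) -> FC2 (ReLU) ->
sigmoid output.  Trained on binary cross-entropy with Adam; deterministic
given the seed.  Implemented directly in numpy so training is reproducible
bit-for-bit and has no framework dependency.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit


@dataclass(frozen=True)
class ModelConfig:
    hidden1: int = 256
    hidden2: int = 128
    dropout1: float = 0.1
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout1 < 1.0:
            raise ValueError("dropout1 must be in [0, 1)")
        if min(self.hidden1, self.hidden2, self.epochs, self.batch_size) < 1:
            raise ValueError("hidden sizes, epochs and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainedModel:
    weights: dict  # W1, b1, W2, b2, W3, b3
    config: ModelConfig
    block_spec: list | None = None
    losses: list = field(default_factory=list)

    @property
    def input_width(self) -> int:
        return self.weights["W1"].shape[0]


def _forward(weights: dict, X: np.ndarray):
    h1 = np.maximum(X @ weights["W1"] + weights["b1"], 0.0)
    h2 = np.maximum(h1 @ weights["W2"] + weights["b2"], 0.0)
    z = h2 @ weights["W3"] + weights["b3"]
    return h1, h2, z[:, 0]


def train(
    X: np.ndarray, y: np.ndarray, cfg: ModelConfig | None = None, block_spec=None
) -> TrainedModel:
    """Fit the classifier; raises on single-class labels or non-finite rows."""
    cfg = cfg or ModelConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")

    rng = np.random.default_rng([20, cfg.seed])
    d = X.shape[1]
    weights = {
        "W1": rng.standard_normal((d, cfg.hidden1)) * np.sqrt(2.0 / d),
        "b1": np.zeros(cfg.hidden1),
        "W2": rng.standard_normal((cfg.hidden1, cfg.hidden2)) * np.sqrt(2.0 / cfg.hidden1),
        "b2": np.zeros(cfg.hidden2),
        "W3": rng.standard_normal((cfg.hidden2, 1)) * np.sqrt(2.0 / cfg.hidden2),
        "b3": np.zeros(1),
    }
    mom = {k: np.zeros_like(v) for k, v in weights.items()}
    vel = {k: np.zeros_like(v) for k, v in weights.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(X)
    losses = []
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            B = len(idx)

            h1 = np.maximum(xb @ weights["W1"] + weights["b1"], 0.0)
            if cfg.dropout1 > 0:
                mask = (rng.random(h1.shape) >= cfg.dropout1) / (1.0 - cfg.dropout1)
                h1d = h1 * mask
            else:
                mask = None
                h1d = h1
            h2 = np.maximum(h1d @ weights["W2"] + weights["b2"], 0.0)
            z = (h2 @ weights["W3"] + weights["b3"])[:, 0]
            p = expit(z)
            epoch_loss += float(
                np.logaddexp(0.0, z).sum() - float(yb @ z)
            )  # BCE via log(1+e^z) - y z

            gz = (p - yb) / B
            gW3 = h2.T @ gz[:, None]
            gb3 = np.array([gz.sum()])
            gh2 = gz[:, None] * weights["W3"][:, 0][None, :]
            gh2[h2 <= 0] = 0.0
            gW2 = h1d.T @ gh2
            gb2 = gh2.sum(axis=0)
            gh1d = gh2 @ weights["W2"].T
            gh1 = gh1d * mask if mask is not None else gh1d
            gh1[h1 <= 0] = 0.0
            gW1 = xb.T @ gh1
            gb1 = gh1.sum(axis=0)

            grads = {"W1": gW1, "b1": gb1, "W2": gW2, "b2": gb2, "W3": gW3, "b3": gb3}
            step += 1
            for k in weights:
                mom[k] = beta1 * mom[k] + (1 - beta1) * grads[k]
                vel[k] = beta2 * vel[k] + (1 - beta2) * grads[k] ** 2
                mhat = mom[k] / (1 - beta1**step)
                vhat = vel[k] / (1 - beta2**step)
                weights[k] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        losses.append(epoch_loss / n)
    return TrainedModel(weights=weights, config=cfg, block_spec=block_spec, losses=losses)


def predict_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Scores in (0, 1), one per row; dropout disabled."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_width:
        raise ValueError(
            f"feature width {X.shape[1] if X.ndim == 2 else '?'} does not match "
            f"training width {model.input_width}"
        )
    _, _, z = _forward(model.weights, X)
    # keep scores in the open interval even when the sigmoid saturates
    return np.clip(expit(z), 1e-15, 1.0 - 1e-15)


def save_model(model: TrainedModel, path) -> None:
    """JSON header (shapes, config) with weights as exact-repr float lists."""
    payload = {
        "config": dataclasses.asdict(model.config),
        "block_spec": model.block_spec,
        "losses": model.losses,
        "weights": {k: v.tolist() for k, v in model.weights.items()},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    weights = {k: np.asarray(v, dtype=float) for k, v in payload["weights"].items()}
    weights["b3"] = np.atleast_1d(weights["b3"])
    return TrainedModel(
        weights=weights,
        config=ModelConfig(**payload["config"]),
        block_spec=payload.get("block_spec"),
        losses=payload.get("losses", []),
    )
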
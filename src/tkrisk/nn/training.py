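"""Epoch-wise training with early stopping, freezing and class weighting.

Training minimizes class-weighted softmax cross-entropy with Adam, assesses
validation loss and accuracy after every epoch, and stops once validation
loss has risen for ``patience`` consecutive epochs (patience 1 by default:
stop when it first begins to increase). The parameters from the
best-validation-loss epoch are restored before returning.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from tkrisk.nn import layers as L
from tkrisk.nn.densenet import DenseNet
from tkrisk.synthetic import SubjectRecord

__all__ = ["TrainConfig", "train_epochwise", "evaluate_model", "make_targets"]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 1e-3
    class_weights: tuple[float, float] = (0.5, 0.5)  # (w_tkr, w_control)
    frozen_layers: int = 0  # leading parameterized layers frozen; head exempt
    batch_size: int = 16
    max_epochs: int = 20
    patience: int = 1
    dropout_rate: Optional[float] = None  # None: keep the model's built-in rate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        w = self.class_weights
        if min(w) < 0 or abs(sum(w) - 1.0) > 1e-9:
            raise ValueError("class_weights must be nonnegative and sum to 1")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def make_targets(records: Sequence[SubjectRecord], target_label: str) -> np.ndarray:
    """Binary targets: 'tkr' -> case within 5 years; 'oa' -> KL >= 2."""
    if target_label == "tkr":
        return np.array([1 if r.label == "case" else 0 for r in records])
    if target_label == "oa":
        return np.array([1 if r.kl_grade >= 2 else 0 for r in records])
    raise ValueError(f"target_label must be 'oa' or 'tkr', got {target_label!r}")


def evaluate_model(
    model: DenseNet, X: np.ndarray, y: np.ndarray,
    class_weights: tuple[float, float] = (0.5, 0.5), batch_size: int = 32,
) -> dict[str, float]:
    """Loss, accuracy, sensitivity and specificity in inference mode."""
    losses, probs = [], []
    for start in range(0, len(y), batch_size):
        xb = X[start : start + batch_size]
        yb = y[start : start + batch_size]
        logits = model.forward(xb, train=False)
        loss, _ = L.weighted_cross_entropy(logits, yb, class_weights)
        losses.append(loss * len(yb))
        probs.append(L.softmax(logits)[:, 1])
    p = np.concatenate(probs)
    pred = (p >= 0.5).astype(int)
    out = {
        "loss": float(np.sum(losses) / len(y)),
        "accuracy": float((pred == y).mean()),
    }
    out["sensitivity"] = (
        float((pred[y == 1] == 1).mean()) if (y == 1).any() else np.nan
    )
    out["specificity"] = (
        float((pred[y == 0] == 0).mean()) if (y == 0).any() else np.nan
    )
    return out


def train_epochwise(
    model: DenseNet,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
) -> tuple[DenseNet, pd.DataFrame]:
    """Train in epochs with early stopping on validation loss.

    ``train_data`` / ``val_data`` are ``(volumes, binary_targets)`` pairs
    (use :func:`make_targets` to derive the OA-pretrain or TKR targets from
    records). Returns the model carrying the best-validation-loss
    parameters, plus a per-epoch history table.
    """
    X, y = train_data
    Xv, yv = val_data
    if len(y) == 0 or len(yv) == 0:
        raise ValueError("training and validation data must be nonempty")
    if np.unique(y).size < 2:
        raise ValueError("training data contains a single class")
    if config.dropout_rate is not None:
        model.set_dropout(config.dropout_rate)
    model.set_frozen(config.frozen_layers)
    opt = L.Adam(model.parameterized_modules(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = []
    best_state = model.state()
    best_loss = np.inf
    rises = 0
    prev_loss = np.inf
    for epoch in range(config.max_epochs):
        order = rng.permutation(len(y))
        epoch_loss = 0.0
        for start in range(0, len(y), config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.forward(X[idx], train=True)
            loss, grad = L.weighted_cross_entropy(
                logits, y[idx], config.class_weights
            )
            opt.zero_grad()
            model.backward(grad)
            opt.step()
            epoch_loss += loss * len(idx)
        val = evaluate_model(model, Xv, yv, config.class_weights)
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / len(y),
            "val_loss": val["loss"],
            "val_accuracy": val["accuracy"],
            "val_sensitivity": val["sensitivity"],
            "val_specificity": val["specificity"],
        })
        if val["loss"] < best_loss:
            best_loss = val["loss"]
            best_state = model.state()
        if val["loss"] > prev_loss:
            rises += 1
            if rises >= config.patience:
                break
        else:
            rises = 0
        prev_loss = val["loss"]
    model.load_state(best_state)
    return model, pd.DataFrame(history)
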
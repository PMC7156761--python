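"""Random hyperparameter search for fine-tuning.

Samples learning rate (log-uniform), dropout (uniform), TKR class weight
(uniform) and the freezing choice, trains each candidate on a seeded
subsample of the training/validation sets, and keeps the configuration with
the best unweighted mean of validation accuracy, sensitivity and
specificity (ties to the earlier iteration). 25 iterations by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from tkrisk.nn.densenet import DenseNet
from tkrisk.nn.training import TrainConfig, train_epochwise, evaluate_model

__all__ = ["SearchSpace", "random_search"]


@dataclass(frozen=True)
class SearchSpace:
    lr_range: tuple[float, float] = (1e-6, 1e-1)
    dropout_range: tuple[float, float] = (0.0, 0.5)
    w_tkr_range: tuple[float, float] = (0.5, 0.99)
    frozen_choices: tuple[str, ...] = ("last-1", "last-2", "all-but-head")
    n_iter: int = 25
    subset_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0.0 < self.subset_fraction <= 1.0:
            raise ValueError("subset_fraction must lie in (0, 1]")


def _frozen_count(choice: str, n_trunk_layers: int) -> int:
    """Map a freezing choice to a count of frozen leading trunk layers."""
    if choice == "all-but-head":
        return n_trunk_layers
    if choice.startswith("last-"):
        keep = int(choice.split("-")[1])
        return max(n_trunk_layers - keep, 0)
    raise ValueError(f"unknown freezing choice {choice!r}")


def _stratified_subsample(y: np.ndarray, fraction: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Seeded subsample keeping at least one sample of each class."""
    idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        k = max(1, int(round(fraction * members.size)))
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def random_search(
    space: SearchSpace,
    model: DenseNet,
    train_data: tuple[np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray],
    max_epochs: int = 5,
    batch_size: int = 16,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Return the best TrainConfig found plus the per-iteration report.

    Every iteration starts from a copy of ``model`` (typically the
    OA-pretrained network), so candidates are compared on equal footing.
    Fully reproducible from ``space.seed``.
    """
    X, y = train_data
    Xv, yv = val_data
    rng = np.random.default_rng(space.seed)
    n_trunk = len(model.parameterized_modules()) - 1
    rows = []
    best_score, best_config = -np.inf, None
    for it in range(space.n_iter):
        lr = float(np.exp(rng.uniform(*np.log(space.lr_range))))
        dropout = float(rng.uniform(*space.dropout_range))
        w_tkr = float(rng.uniform(*space.w_tkr_range))
        choice = str(rng.choice(list(space.frozen_choices)))
        config = TrainConfig(
            learning_rate=lr,
            class_weights=(w_tkr, 1.0 - w_tkr),
            frozen_layers=_frozen_count(choice, n_trunk),
            batch_size=batch_size,
            max_epochs=max_epochs,
            dropout_rate=dropout,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        sub_t = _stratified_subsample(y, space.subset_fraction, rng)
        sub_v = _stratified_subsample(yv, space.subset_fraction, rng)
        candidate = model.copy()
        candidate, _ = train_epochwise(
            candidate, (X[sub_t], y[sub_t]), (Xv[sub_v], yv[sub_v]), config
        )
        val = evaluate_model(candidate, Xv[sub_v], yv[sub_v], config.class_weights)
        score = float(np.mean([
            val["accuracy"], val["sensitivity"], val["specificity"]
        ]))
        rows.append({
            "iteration": it, "learning_rate": lr, "dropout": dropout,
            "w_tkr": w_tkr, "freezing": choice, "score": score,
            "val_accuracy": val["accuracy"],
            "val_sensitivity": val["sensitivity"],
            "val_specificity": val["specificity"],
        })
        if score > best_score:  # strict: ties keep the earlier iteration
            best_score, best_config = score, config
    return best_config, pd.DataFrame(rows)
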
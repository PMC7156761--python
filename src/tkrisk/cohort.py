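"""Cohort construction: labeling, splitting, balancing, imputation, screening.

Implements the tabular side of the pipeline: the 5-year case/control rule,
leakage-free patient-level 65/20/15 splitting, bootstrap oversampling of the
rare (TKR) class to 1:1, k-nearest-neighbor imputation of missing
non-imaging values, and random-forest minimum-depth feature screening.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import KNNImputer

from tkrisk.synthetic import SubjectRecord

__all__ = [
    "SplitConfig",
    "FeatureSelectConfig",
    "assign_label",
    "split_by_patient",
    "oversample_rare",
    "impute_knn",
    "select_features_min_depth",
]


@dataclass(frozen=True)
class SplitConfig:
    fractions: tuple[float, float, float] = (0.65, 0.20, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("split fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass(frozen=True)
class FeatureSelectConfig:
    n_trees: int = 100
    knn_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


def assign_label(
    visit_time: float, tkr_time: Optional[float], horizon: float = 5.0
) -> str:
    """Case iff a first TKR occurred within ``horizon`` years of the visit.

    The interval is closed: an event at exactly ``horizon`` years is a case.
    A visit recorded after the replacement is invalid.
    """
    if not np.isfinite(visit_time):
        raise ValueError("visit_time must be finite")
    if tkr_time is None or (isinstance(tkr_time, float) and np.isnan(tkr_time)):
        return "control"
    if not np.isfinite(tkr_time):
        raise ValueError("tkr_time must be finite or absent")
    if tkr_time < visit_time:
        raise ValueError(
            f"tkr_time {tkr_time} precedes visit_time {visit_time}: "
            "a visit after replacement is invalid"
        )
    return "case" if tkr_time - visit_time <= horizon else "control"


def split_by_patient(
    records: Sequence[SubjectRecord], config: SplitConfig = SplitConfig()
) -> list[SubjectRecord]:
    """Assign train/val/test at the patient level to prevent leakage.

    Each patient (not visit) is independently assigned with probabilities
    equal to the split fractions; all of a patient's visits share the
    assignment. Returns the same record objects with ``split`` set.
    """
    if not records:
        raise ValueError("cannot split an empty cohort")
    patients = sorted({r.patient_id for r in records})
    rng = np.random.default_rng(config.seed)
    choices = rng.choice(
        ["train", "val", "test"], size=len(patients), p=list(config.fractions)
    )
    assignment = dict(zip(patients, choices))
    for r in records:
        r.split = str(assignment[r.patient_id])
    return list(records)


def oversample_rare(
    train_records: Sequence[SubjectRecord], seed: int = 0
) -> list[SubjectRecord]:
    """Balance the training set 1:1 by bootstrap-resampling the rare class.

    Majority rows appear exactly once, in input order; they are followed by
    ``n_majority`` draws with replacement from the rare class. An already
    balanced input is returned unchanged.
    """
    labels = [r.label for r in train_records]
    n_case = labels.count("case")
    n_ctrl = labels.count("control")
    if n_case == 0 or n_ctrl == 0:
        raise ValueError("both classes must be present in the training split")
    if n_case == n_ctrl:
        return list(train_records)
    rare = "case" if n_case < n_ctrl else "control"
    rare_rows = [r for r in train_records if r.label == rare]
    major_rows = [r for r in train_records if r.label != rare]
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(rare_rows), size=len(major_rows))
    return major_rows + [rare_rows[i] for i in draws]


def impute_knn(table: pd.DataFrame, knn_k: int = 5) -> pd.DataFrame:
    """Fill missing values by the mean of the ``knn_k`` nearest rows.

    Distances are Euclidean on standardized columns, computed pairwise over
    mutually observed entries; observed cells are never altered. Requires at
    least ``knn_k`` rows without missing values.
    """
    if table.isna().all(axis=0).any():
        empty = table.columns[table.isna().all(axis=0)].tolist()
        raise ValueError(f"column(s) entirely missing: {empty}")
    complete = int((~table.isna().any(axis=1)).sum())
    if complete < knn_k:
        raise ValueError(
            f"need at least knn_k={knn_k} complete rows, found {complete}"
        )
    if not table.isna().any().any():
        return table.copy()
    values = table.to_numpy(dtype=float)
    mean = np.nanmean(values, axis=0)
    sd = np.nanstd(values, axis=0)
    sd[sd == 0] = 1.0
    standardized = (values - mean) / sd
    imputer = KNNImputer(n_neighbors=knn_k, weights="uniform")
    filled = imputer.fit_transform(standardized) * sd + mean
    out = table.copy()
    missing = table.isna().to_numpy()
    arr = out.to_numpy(dtype=float)
    arr[missing] = filled[missing]
    return pd.DataFrame(arr, index=table.index, columns=table.columns)


def _tree_min_depths(tree, n_features: int) -> np.ndarray:
    """Minimum depth at which each feature splits in one fitted tree.

    Root = 0; features never split on in this tree get inf.
    """
    depths = np.full(n_features, np.inf)
    left, right, feat = tree.children_left, tree.children_right, tree.feature
    stack = [(0, 0)]
    max_depth = 0
    while stack:
        node, depth = stack.pop()
        if left[node] == -1:  # leaf
            max_depth = max(max_depth, depth)
            continue
        f = feat[node]
        depths[f] = min(depths[f], depth)
        stack.append((left[node], depth + 1))
        stack.append((right[node], depth + 1))
    return depths


def forest_min_depths(forest, n_features: int) -> np.ndarray:
    """Minimal-depth score per feature: per-tree minimum depth of any split
    on the feature, averaged across trees.

    Within each tree, a feature never split on is penalized with one more
    than the deepest minimal depth observed in that tree, so the average is
    always defined. Lower
    scores mean the feature is chosen nearer the root, i.e. is more
    predictive. (Averaging across trees, rather than taking the forest-wide
    minimum, is what makes the score discriminative: in a large forest
    almost every feature ends up at the root of *some* tree.)
    """
    per_tree = np.array(
        [_tree_min_depths(est.tree_, n_features) for est in forest.estimators_]
    )
    for row in per_tree:
        finite = row[np.isfinite(row)]
        penalty = (finite.max() if finite.size else 0.0) + 1.0
        row[~np.isfinite(row)] = penalty
    return per_tree.mean(axis=0)


def select_features_min_depth(
    table: pd.DataFrame, labels, config: FeatureSelectConfig = FeatureSelectConfig()
) -> list[str]:
    """Screen features by minimal split depth in a random forest.

    A 100-tree forest is fit to predict the TKR label; each feature is
    scored by its average minimal depth (root = 0) across the trees, and
    features scoring strictly below the mean score of all features are
    retained.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least 2 features to screen")
    if table.isna().any().any():
        raise ValueError("table must be complete (impute first)")
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("labels must contain both classes")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.seed
    )
    forest.fit(table.to_numpy(dtype=float), y)
    scores = forest_min_depths(forest, table.shape[1])
    threshold = scores.mean()
    return [c for c, d in zip(table.columns, scores) if d < threshold]
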
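"""OA-stratified logistic-regression ensembling of image and clinical data.

The network's scalar TKR risk is prepended to the 27 non-imaging variables
to form a 28-feature vector. For each OA stratum (none / moderate / severe)
a random search over logistic-regression class weights (100 iterations,
w in U[0.5, 0.99]) produces candidate models; candidates are ranked by
Youden's index J = sensitivity + specificity - 1 on the stratum's
validation records, the top k are kept (k itself chosen to maximize the
mean of validation accuracy, AUC and J), and the stratum's prediction is
the average of the selected models' probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from tkrisk.stats import confusion_metrics, roc_auc
from tkrisk.synthetic import NONIMAGING_VARIABLES, SubjectRecord

__all__ = [
    "CANONICAL_VARIABLES",
    "LRCandidate",
    "StratumEnsemble",
    "IntegratedPipeline",
    "assemble_features",
    "lr_random_search",
    "select_top_k_youden",
    "choose_k",
    "predict_integrated",
    "fit_stratum_ensemble",
    "nonimaging_baseline",
]

#: Canonical feature order: the image risk scalar then the 27 variables.
CANONICAL_VARIABLES: tuple[str, ...] = ("image_risk",) + NONIMAGING_VARIABLES

STRATA = ("none", "moderate", "severe")


def assemble_features(record: SubjectRecord, risk: float) -> np.ndarray:
    """28-vector: [risk] followed by the 27 variables in canonical order.

    The record must be complete (post-imputation); a missing value is an
    error.
    """
    values = [float(risk)]
    for name in NONIMAGING_VARIABLES:
        if name not in record.nonimaging:
            raise ValueError(f"record missing non-imaging variable {name!r}")
        v = record.nonimaging[name]
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(
                f"variable {name!r} is unimputed (missing) for "
                f"{record.patient_id} at t={record.visit_time}"
            )
        values.append(float(v))
    return np.asarray(values)


@dataclass(eq=False)
class LRCandidate:
    """One fitted logistic model with its searched class-weight pair."""

    w_case: float
    scaler: StandardScaler
    model: LogisticRegression
    val_probs: np.ndarray

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(features)
        return self.model.predict_proba(self.scaler.transform(X))[:, 1]


@dataclass(eq=False)
class StratumEnsemble:
    stratum: str
    candidates: list[LRCandidate]
    selected: list[LRCandidate]
    k: int

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        if not self.selected:
            raise ValueError(f"ensemble for stratum {self.stratum!r} is unfitted")
        return np.mean(
            [c.predict_proba(features) for c in self.selected], axis=0
        )


def lr_random_search(
    features: np.ndarray,
    labels: np.ndarray,
    val_features: np.ndarray,
    n_iter: int = 100,
    seed: int = 0,
) -> list[LRCandidate]:
    """Fit ``n_iter`` class-weighted logistic models, w_case ~ U[0.5, 0.99].

    Features are standardized on the training split and the fit uses weak
    L2 regularization (C = 100), so the searched class weights — not the
    penalty — govern each candidate's operating point. Each candidate
    stores its validation probabilities for ranking.
    """
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    rng = np.random.default_rng(seed)
    scaler = StandardScaler().fit(features)
    Xs = scaler.transform(features)
    Xv = scaler.transform(val_features)
    candidates = []
    for _ in range(n_iter):
        w = float(rng.uniform(0.5, 0.99))
        model = LogisticRegression(
            class_weight={1: w, 0: 1.0 - w}, C=100.0, max_iter=5000
        )
        model.fit(Xs, y)
        candidates.append(
            LRCandidate(
                w_case=w,
                scaler=scaler,
                model=model,
                val_probs=model.predict_proba(Xv)[:, 1],
            )
        )
    return candidates


def _stratum_indices(records: Sequence[SubjectRecord], stratum: str) -> np.ndarray:
    return np.array([i for i, r in enumerate(records) if r.stratum == stratum])


def _youden(probs: np.ndarray, y: np.ndarray, threshold: float) -> float:
    pred = (probs >= threshold).astype(int)
    sens = (pred[y == 1] == 1).mean()
    spec = (pred[y == 0] == 0).mean()
    return float(sens + spec - 1.0)


def select_top_k_youden(
    candidates: Sequence[LRCandidate],
    val_records: Sequence[SubjectRecord],
    stratum: str,
    k: int,
    threshold: float = 0.5,
) -> StratumEnsemble:
    """Keep the k candidates with the highest Youden's index on the stratum.

    J is computed only on validation records of the given stratum at the
    classification threshold; ties are broken by candidate index.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    if k < 1 or k > len(candidates):
        raise ValueError(f"k must lie in 1..{len(candidates)}")
    idx = _stratum_indices(val_records, stratum)
    if idx.size == 0:
        raise ValueError(f"validation set has no records in stratum {stratum!r}")
    y = np.array([1 if val_records[i].label == "case" else 0 for i in idx])
    if y.min() == y.max():
        raise ValueError(
            f"validation stratum {stratum!r} contains a single class"
        )
    js = np.array([_youden(c.val_probs[idx], y, threshold) for c in candidates])
    order = np.lexsort((np.arange(len(candidates)), -js))
    selected = [candidates[i] for i in order[:k]]
    return StratumEnsemble(stratum=stratum, candidates=list(candidates),
                           selected=selected, k=k)


def choose_k(
    candidates: Sequence[LRCandidate],
    val_records: Sequence[SubjectRecord],
    stratum: str,
    k_max: int = 8,
    threshold: float = 0.5,
) -> int:
    """Pick the ensemble size k maximizing mean(val accuracy, AUC, J).

    Evaluates the averaged top-k ensemble for k = 1..k_max on the stratum's
    validation records; ties go to the smaller k.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    k_max = min(k_max, len(candidates))
    idx = _stratum_indices(val_records, stratum)
    if idx.size == 0:
        raise ValueError(f"validation set has no records in stratum {stratum!r}")
    y = np.array([1 if val_records[i].label == "case" else 0 for i in idx])
    best_k, best_score = 1, -np.inf
    for k in range(1, k_max + 1):
        ens = select_top_k_youden(candidates, val_records, stratum, k, threshold)
        probs = np.mean([c.val_probs[idx] for c in ens.selected], axis=0)
        m = confusion_metrics(probs, y, threshold)
        score = float(np.mean([m.accuracy, m.auc, m.youden_j]))
        if score > best_score:  # strict: ties keep the smaller k
            best_score, best_k = score, k
    return best_k


def fit_stratum_ensemble(
    candidates: Sequence[LRCandidate],
    val_records: Sequence[SubjectRecord],
    stratum: str,
    k: Optional[int] = None,
    k_max: int = 8,
    threshold: float = 0.5,
) -> StratumEnsemble:
    """Convenience: choose k (unless given) then select the top-k ensemble."""
    if k is None:
        k = choose_k(candidates, val_records, stratum, k_max, threshold)
    return select_top_k_youden(candidates, val_records, stratum, k, threshold)


@dataclass
class IntegratedPipeline:
    """Preprocessing + CNN + the three stratum ensembles + threshold."""

    preprocess_config: object
    cnn_model: object
    ensembles: dict[str, StratumEnsemble]
    threshold: float = 0.5

    def __post_init__(self) -> None:
        extra = set(self.ensembles) - set(STRATA)
        if extra:
            raise ValueError(f"unknown strata {sorted(extra)}")

    def ensemble_for(self, stratum: str) -> StratumEnsemble:
        if stratum not in self.ensembles:
            raise ValueError(f"no fitted ensemble for stratum {stratum!r}")
        return self.ensembles[stratum]


def predict_integrated(
    pipeline: IntegratedPipeline,
    record: SubjectRecord,
    risk: float,
) -> tuple[float, str]:
    """Route the record to its stratum's ensemble and classify.

    ``risk`` is the CNN's scalar output for the record's (preprocessed)
    volume. Returns (probability, 'case'/'control').
    """
    ens = pipeline.ensemble_for(record.stratum)
    features = assemble_features(record, risk)
    prob = float(ens.predict_proba(features)[0])
    return prob, "case" if prob >= pipeline.threshold else "control"


def nonimaging_baseline(
    features_27: np.ndarray, labels: np.ndarray
) -> tuple[StandardScaler, LogisticRegression]:
    """Unweighted single logistic model on the 27 non-imaging variables."""
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("labels contain a single class")
    scaler = StandardScaler().fit(features_27)
    model = LogisticRegression(C=100.0, max_iter=5000).fit(scaler.transform(features_27), y)
    return scaler, model
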
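"""ROC/AUC, fixed-specificity operating points, CV harness, stage stratification.

The AUC here is the tie-aware concordance probability: the chance that a
random case outscores a random control, with ties counted half.  Operating
points are fixed on the *training* score distribution — the threshold is the
smallest control order statistic guaranteeing the target specificity — and
transported unchanged to validation data, mimicking how a locked-down
diagnostic would be deployed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .exceptions import ConfigurationError
from .panels import Panel


def compute_auc(scores: Sequence[float], y: Sequence[int]) -> float:
    """Tie-aware concordance AUC.

    Equals ``(#{case > control} + 0.5 * #{ties}) / (n_case * n_control)``,
    computed via midranks in O(n log n).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    n_case = int((y == 1).sum())
    n_control = int((y == 0).sum())
    if n_case == 0 or n_control == 0:
        raise ConfigurationError("AUC needs at least one case and one control")
    ranks = rankdata(scores)  # midranks handle ties as half-concordant
    case_rank_sum = ranks[y == 1].sum()
    return float((case_rank_sum - n_case * (n_case + 1) / 2.0) / (n_case * n_control))


def threshold_at_specificity(
    control_scores: Sequence[float], target: float = 0.95
) -> float:
    """Score threshold achieving at least ``target`` specificity on controls.

    With the rule "classify case iff score > t", the returned t is the
    ``ceil(target * n)``-th smallest control score — the smallest control
    order statistic whose specificity ``#{controls <= t} / n`` reaches the
    target.
    """
    control_scores = np.asarray(control_scores, dtype=float)
    if control_scores.size == 0:
        raise ConfigurationError("cannot place a threshold without control scores")
    if not 0.0 < target <= 1.0:
        raise ConfigurationError(f"target specificity must be in (0, 1], got {target}")
    k = int(np.ceil(target * control_scores.size))
    return float(np.sort(control_scores)[k - 1])


def stage_stratified_sensitivity(
    scores: Sequence[float],
    y: Sequence[int],
    stages: Sequence[float],
    threshold: float,
) -> dict[int, float]:
    """Sensitivity within each tumor stage's cases at a fixed threshold.

    Stages with no cases are omitted; a case with a missing stage is an error.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    stages = np.asarray(stages, dtype=float)
    case = y == 1
    if np.any(np.isnan(stages[case])):
        raise ConfigurationError("every case must carry a stage")
    out: dict[int, float] = {}
    for s in sorted(np.unique(stages[case])):
        mask = case & (stages == s)
        out[int(s)] = float((scores[mask] > threshold).mean())
    return out


def evaluate_at_threshold(
    scores: Sequence[float],
    y: Sequence[int],
    threshold: float,
    stages: Sequence[float] | None = None,
) -> dict:
    """Sensitivity/specificity/accuracy (and per-stage sensitivity) at ``t``.

    A subject is called a case iff its score is strictly above the threshold;
    specificity is therefore the fraction of controls at or below it.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(threshold):
        raise ConfigurationError(f"threshold must be finite, got {threshold}")
    case, control = y == 1, y == 0
    called_case = scores > threshold
    out = {
        "sensitivity": float(called_case[case].mean()) if case.any() else float("nan"),
        "specificity": float((~called_case[control]).mean()) if control.any() else float("nan"),
        "accuracy": float((called_case == (y == 1)).mean()),
    }
    if stages is not None:
        out["stage_sensitivity"] = stage_stratified_sensitivity(
            scores, y, stages, threshold
        )
    return out


def cv_fold_indices(
    y: Sequence[int], k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold split indices, deterministic per seed."""
    y = np.asarray(y)
    if k < 2:
        raise ConfigurationError(f"cv folds must be >= 2, got {k}")
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ConfigurationError(
            f"smallest class has {counts.min()} subjects < {k} folds; lower k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validated_scores(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    folds: Sequence[tuple[np.ndarray, np.ndarray]],
    fold_seeds: Sequence[int] | None = None,
) -> np.ndarray:
    """Pooled out-of-fold scores: each subject scored by the model fitted on
    the folds that exclude it."""
    from sklearn.base import clone

    oof = np.full(len(y), np.nan)
    for i, (tr, te) in enumerate(folds):
        est = clone(estimator)
        if fold_seeds is not None:
            est.set_params(random_state=int(fold_seeds[i]))
        est.fit(X[tr], y[tr])
        oof[te] = est.score_samples(X[te])
    return oof


def cross_validated_auc(
    estimator,
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    pooling: str = "pooled",
) -> float:
    """Stratified k-fold cross-validated AUC.

    ``pooling='pooled'`` (default) computes one AUC over the pooled
    out-of-fold score vector; ``'per_fold'`` averages per-fold AUCs instead.
    Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = cv_fold_indices(y, k, seed)
    oof = cross_validated_scores(estimator, X, y, folds)
    if pooling == "pooled":
        return compute_auc(oof, y)
    if pooling == "per_fold":
        return float(np.mean([compute_auc(oof[te], y[te]) for _, te in folds]))
    raise ConfigurationError(f"pooling must be 'pooled' or 'per_fold', got {pooling!r}")


@dataclass(frozen=True)
class PerformanceRecord:
    """AUC and operating-point metrics for one (panel, algorithm, split)."""

    panel: Panel
    algorithm: str
    split: str  # train_cv | train_resub | validation
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    stage_sensitivity: Mapping[int, float] = field(default_factory=dict)

    def as_row(self) -> dict:
        from .panels import panel_key

        row = {
            "panel": panel_key(self.panel),
            "algorithm": self.algorithm,
            "split": self.split,
            "auc": self.auc,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }
        for s in (1, 2, 3, 4):
            row[f"stage{s}_sensitivity"] = self.stage_sensitivity.get(s, float("nan"))
        return row


def make_record(
    panel: Panel,
    algorithm: str,
    split: str,
    scores: np.ndarray,
    y: np.ndarray,
    threshold: float,
    stages: np.ndarray | None = None,
) -> PerformanceRecord:
    """Bundle AUC plus threshold metrics into a :class:`PerformanceRecord`."""
    metrics = evaluate_at_threshold(scores, y, threshold, stages)
    return PerformanceRecord(
        panel=panel,
        algorithm=algorithm,
        split=split,
        auc=compute_auc(scores, y),
        threshold=float(threshold),
        sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        accuracy=metrics["accuracy"],
        stage_sensitivity=metrics.get("stage_sensitivity", {}),
    )
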
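"""The panel-selection cascade and its audit ledger.

The cascade reproduces a four-step wrapper selection over the exhaustive
panel enumeration:

1. rank every panel by its mean training cross-validated AUC across the five
   classification algorithms and keep the top fraction (default 10%);
2. keep panels containing the mandatory clinical markers (default CEA and
   CA19-9, the tumor markers already used for PDAC);
3. keep panels whose train-CV versus validation AUC gap is small for every
   algorithm (stability across data splits);
4. of the survivors, pick the panel with the best worst-case validation AUC
   across the five algorithms (stability across algorithms), with ties broken
   by the smaller spread of validation AUCs, then fewer markers, then the
   canonical panel string.

Every stage's survivors, the parameters in force and the final panel's full
performance records are recorded in a :class:`SelectionLedger`, serializable
to deterministic JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .evaluate import (
    PerformanceRecord,
    cross_validated_scores,
    cv_fold_indices,
    make_record,
    threshold_at_specificity,
)
from .exceptions import ConfigurationError
from .models import ALGORITHMS, PanelClassifier, combine_glm_rf
from .panels import (
    FeatureMatrix,
    Panel,
    build_feature_matrix,
    canonicalize,
    enumerate_panels,
    panel_key,
)
from .preprocess import log_transform_markers, marker_columns, split_cohort, split_tables
from .seeding import derive_seed

#: records[panel_key][algorithm][split] -> PerformanceRecord
RecordMap = dict[str, dict[str, dict[str, PerformanceRecord]]]

_BASE_ALGORITHMS = ("GLM", "RIDGE", "SVM", "RF")


def evaluate_panel(
    panel: Panel,
    train: FeatureMatrix,
    validation: FeatureMatrix,
    *,
    cv_folds: int = 10,
    target_specificity: float = 0.95,
    seed: int = 0,
    model_params: Mapping | None = None,
) -> dict[str, dict[str, PerformanceRecord]]:
    """Fit and score all five algorithms for one panel.

    Produces, per algorithm, three records: ``train_cv`` (pooled out-of-fold
    scores of a stratified k-fold on the training set, threshold placed on the
    out-of-fold control scores), ``train_resub`` (resubstitution scores of the
    full-training fit, own threshold), and ``validation`` (validation scores
    of the full-training fit at the *transported* training threshold).

    GLM_RF is derived by averaging the GLM and RF score vectors — the two
    member fits are reused, not repeated.  Fold assignment is shared across
    algorithms within a panel so the combination is well defined out-of-fold.

    Fold assignment and per-fit seeds are shared across *panels* as well
    (seeds derive from the global seed, algorithm and fold only), the same
    paired design scikit-learn's model selection applies to candidate
    configurations: every panel is scored on identical folds with identical
    estimator randomness, so stochastic-fit noise cancels from panel
    comparisons instead of deciding near-ties by coin flip.  Results remain
    deterministic and independent of which other panels are evaluated.
    """
    params = dict(model_params or {})
    key = panel_key(panel)
    folds = cv_fold_indices(train.y, cv_folds, derive_seed(seed, "folds", cv_folds))

    oof: dict[str, np.ndarray] = {}
    resub: dict[str, np.ndarray] = {}
    val: dict[str, np.ndarray] = {}
    for alg in _BASE_ALGORITHMS:
        est = PanelClassifier(algorithm=alg, **params)
        fold_seeds = [derive_seed(seed, alg, i) for i in range(len(folds))]
        oof[alg] = cross_validated_scores(est, train.X, train.y, folds, fold_seeds)
        full = PanelClassifier(
            algorithm=alg, random_state=derive_seed(seed, alg, "full"), **params
        ).fit(train.X, train.y)
        resub[alg] = full.score_samples(train.X)
        val[alg] = full.score_samples(validation.X)
    for d in (oof, resub, val):
        d["GLM_RF"] = combine_glm_rf(d["GLM"], d["RF"])

    has_stage_train = not np.all(np.isnan(train.stages[train.y == 1]))
    has_stage_val = not np.all(np.isnan(validation.stages[validation.y == 1]))
    out: dict[str, dict[str, PerformanceRecord]] = {}
    for alg in ALGORITHMS:
        t_cv = threshold_at_specificity(oof[alg][train.y == 0], target_specificity)
        t_resub = threshold_at_specificity(resub[alg][train.y == 0], target_specificity)
        out[alg] = {
            "train_cv": make_record(
                panel, alg, "train_cv", oof[alg], train.y, t_cv,
                train.stages if has_stage_train else None,
            ),
            "train_resub": make_record(
                panel, alg, "train_resub", resub[alg], train.y, t_resub,
                train.stages if has_stage_train else None,
            ),
            "validation": make_record(
                panel, alg, "validation", val[alg], validation.y, t_resub,
                validation.stages if has_stage_val else None,
            ),
        }
    return out


def evaluate_panels(
    panels: Sequence[Panel],
    train: pd.DataFrame,
    validation: pd.DataFrame,
    *,
    covariates: bool = True,
    cv_folds: int = 10,
    target_specificity: float = 0.95,
    seed: int = 0,
    model_params: Mapping | None = None,
) -> RecordMap:
    """Evaluate every panel on already log-transformed train/validation tables."""
    records: RecordMap = {}
    for panel in panels:
        ftrain = build_feature_matrix(train, panel, covariates)
        fval = build_feature_matrix(validation, panel, covariates)
        records[panel_key(panel)] = evaluate_panel(
            panel,
            ftrain,
            fval,
            cv_folds=cv_folds,
            target_specificity=target_specificity,
            seed=seed,
            model_params=model_params,
        )
    return records


# -- cascade stages --------------------------------------------------------


def _mean_train_cv_auc(per_alg: Mapping[str, Mapping[str, PerformanceRecord]]) -> float:
    return float(np.mean([per_alg[a]["train_cv"].auc for a in ALGORITHMS]))


def rank_panels(records: RecordMap) -> list[str]:
    """Panels in descending mean train-CV AUC across the five algorithms.

    Ties favor fewer markers, then the canonical panel string.
    """
    for key, per_alg in records.items():
        missing = [a for a in ALGORITHMS if a not in per_alg]
        if missing:
            raise ConfigurationError(f"panel {key}: missing records for {missing}")
    return sorted(
        records,
        key=lambda k: (-_mean_train_cv_auc(records[k]), len(k.split("+")), k),
    )


def filter_top_fraction(ranked: Sequence[str], fraction: float) -> list[str]:
    """First ``ceil(fraction * N)`` panels of a ranked list."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError(f"fraction must be in (0, 1], got {fraction}")
    if not ranked:
        return []
    return list(ranked)[: ceil(fraction * len(ranked))]


def filter_mandatory(panels: Sequence[str], required: Sequence[str]) -> list[str]:
    """Panels containing every required marker, order preserved."""
    req = set(required)
    return [k for k in panels if req <= set(k.split("+"))]


def stability_filter(
    panels: Sequence[str], records: RecordMap, max_gap: float = 0.02
) -> list[str]:
    """Panels whose |train-CV AUC - validation AUC| <= ``max_gap`` for every
    one of the five algorithms."""
    kept = []
    for k in panels:
        gaps = [
            abs(records[k][a]["train_cv"].auc - records[k][a]["validation"].auc)
            for a in ALGORITHMS
        ]
        if max(gaps) <= max_gap:
            kept.append(k)
    return kept


def select_final(candidates: Sequence[str], records: RecordMap) -> str:
    """The candidate maximizing the minimum validation AUC across algorithms.

    Ties break by the smaller standard deviation of the five validation AUCs,
    then fewer markers, then the canonical string.
    """
    if not candidates:
        raise ConfigurationError(
            "no candidate panels survived the cascade; relax max_gap or "
            "increase top_fraction"
        )

    def sort_key(k: str):
        aucs = [records[k][a]["validation"].auc for a in ALGORITHMS]
        return (-min(aucs), float(np.std(aucs)), len(k.split("+")), k)

    return sorted(candidates, key=sort_key)[0]


@dataclass(frozen=True)
class SelectionLedger:
    """Full audit trail of the cascade, from all candidates to the final pick."""

    parameters: dict
    stage0: list  # [{"panel": key, "mean_train_cv_auc": float}, ...] ranked
    stage1: list[str]
    stage2: list[str]
    stage3: list[str]
    final: str
    final_records: list  # row dicts for the final panel, all algorithms/splits

    @property
    def counts(self) -> dict[str, int]:
        return {
            "stage0": len(self.stage0),
            "stage1": len(self.stage1),
            "stage2": len(self.stage2),
            "stage3": len(self.stage3),
        }

    @property
    def final_panel(self) -> Panel:
        return canonicalize(self.final.split("+"))

    def to_dict(self) -> dict:
        return {
            "parameters": self.parameters,
            "counts": self.counts,
            "stage0": self.stage0,
            "stage1": self.stage1,
            "stage2": self.stage2,
            "stage3": self.stage3,
            "final": self.final,
            "final_records": self.final_records,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary(self) -> str:
        lines = [
            "panel selection cascade",
            f"  candidates ranked        : {len(self.stage0)}",
            f"  top-fraction survivors   : {len(self.stage1)}",
            f"  mandatory-marker keepers : {len(self.stage2)}",
            f"  stability survivors      : {len(self.stage3)}",
            f"  final panel              : {self.final}",
        ]
        for row in self.final_records:
            if row["split"] == "validation":
                lines.append(
                    f"    {row['algorithm']:<7} validation AUC {row['auc']:.3f} "
                    f"sens {row['sensitivity']:.2f} spec {row['specificity']:.2f}"
                )
        return "\n".join(lines)


def run_cascade(
    records: RecordMap,
    *,
    top_fraction: float = 0.10,
    mandatory: Sequence[str] = ("CA19-9", "CEA"),
    max_gap: float = 0.02,
    extra_parameters: Mapping | None = None,
) -> SelectionLedger:
    """Apply the four cascade stages to a full record map."""
    ranked = rank_panels(records)
    stage0 = [
        {"panel": k, "mean_train_cv_auc": _mean_train_cv_auc(records[k])}
        for k in ranked
    ]
    stage1 = filter_top_fraction(ranked, top_fraction)
    stage2 = filter_mandatory(stage1, mandatory)
    stage3 = stability_filter(stage2, records, max_gap)
    final = select_final(stage3, records)
    final_records = [
        records[final][a][split].as_row()
        for a in ALGORITHMS
        for split in ("train_cv", "train_resub", "validation")
    ]
    parameters = {
        "top_fraction": top_fraction,
        "mandatory": sorted(mandatory),
        "max_gap": max_gap,
        **dict(extra_parameters or {}),
    }
    return SelectionLedger(
        parameters=parameters,
        stage0=stage0,
        stage1=stage1,
        stage2=stage2,
        stage3=stage3,
        final=final,
        final_records=final_records,
    )


class PanelSelector(BaseEstimator):
    """End-to-end panel discovery as a scikit-learn style estimator.

    ``fit`` takes a subject-level cohort table (marker concentrations plus
    ``age``, ``sex``, ``label`` and optionally ``subject_id``/``stage``
    columns), log-transforms the markers, draws a seeded label-stratified
    train/validation split, evaluates every non-empty marker subset under the
    five-algorithm suite with stratified k-fold CV, and runs the selection
    cascade.  Fitted attributes: ``panel_`` (the selected marker tuple),
    ``ledger_`` (the :class:`SelectionLedger`), ``records_`` (all
    performance records) and ``split_`` (the train/validation assignment).

    ``transform`` then projects any marker table onto the selected panel's
    columns, so the selector composes as a feature-selection step.
    """

    def __init__(
        self,
        markers: Sequence[str] | None = None,
        mandatory: Sequence[str] = ("CA19-9", "CEA"),
        train_fraction: float = 2.0 / 3.0,
        top_fraction: float = 0.10,
        max_gap: float = 0.02,
        cv_folds: int = 10,
        target_specificity: float = 0.95,
        covariates: bool = True,
        log_transform: bool = True,
        model_params: Mapping | None = None,
        max_markers: int = 16,
        random_state: int = 0,
    ):
        self.markers = markers
        self.mandatory = mandatory
        self.train_fraction = train_fraction
        self.top_fraction = top_fraction
        self.max_gap = max_gap
        self.cv_folds = cv_folds
        self.target_specificity = target_specificity
        self.covariates = covariates
        self.log_transform = log_transform
        self.model_params = model_params
        self.max_markers = max_markers
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "PanelSelector":
        table = X.copy()
        if y is not None:
            table["label"] = [
                "case" if v in (1, "1", "case", True) else "control"
                for v in np.asarray(y)
            ]
        if "label" not in table.columns:
            raise ConfigurationError("fit needs a 'label' column or a y vector")
        if "subject_id" not in table.columns:
            table.insert(0, "subject_id", [f"s{i:05d}" for i in range(len(table))])
        if "stage" not in table.columns:
            table["stage"] = pd.array([pd.NA] * len(table), dtype="Int64")

        candidates = list(self.markers) if self.markers is not None else marker_columns(table)
        missing_req = [m for m in self.mandatory if m not in candidates]
        if missing_req:
            raise ConfigurationError(
                f"mandatory markers not among candidates: {missing_req}"
            )
        if self.log_transform:
            table = log_transform_markers(table, candidates)

        self.split_ = split_cohort(table, self.train_fraction, self.random_state)
        train, validation = split_tables(table, self.split_)
        panels = enumerate_panels(candidates, self.max_markers)
        self.records_ = evaluate_panels(
            panels,
            train,
            validation,
            covariates=self.covariates,
            cv_folds=self.cv_folds,
            target_specificity=self.target_specificity,
            seed=self.random_state,
            model_params=self.model_params,
        )
        self.ledger_ = run_cascade(
            self.records_,
            top_fraction=self.top_fraction,
            mandatory=self.mandatory,
            max_gap=self.max_gap,
            extra_parameters={
                "markers": sorted(candidates),
                "train_fraction": self.train_fraction,
                "cv_folds": self.cv_folds,
                "target_specificity": self.target_specificity,
                "covariates": self.covariates,
                "log_transform": self.log_transform,
                "model_params": dict(self.model_params or {}),
                "seed": self.random_state,
            },
        )
        self.panel_ = self.ledger_.final_panel
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "panel_")
        return X[list(self.panel_)]


def select_panel(table: pd.DataFrame, **params) -> SelectionLedger:
    """Functional wrapper: run the full cascade on a cohort table."""
    return PanelSelector(**params).fit(table).ledger_
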
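"""Cohort CSV reading/validation, run configuration, and pipeline orchestration.

The cohort schema is one row per subject::

    subject_id, <marker names...>, age, sex, label, stage

with ``sex`` in {M, F}, ``label`` in {case, control}, marker concentrations
strictly positive, and ``stage`` (AJCC 1-4) present exactly for cases —
encoded as an empty field for controls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .cohort import CohortConfig, generate_cohort
from .exceptions import CohortValidationError, ConfigurationError
from .preprocess import marker_columns, rank_sum_screen
from .selection import PanelSelector, SelectionLedger

logger = logging.getLogger("seropanel")

_META_REQUIRED = ("subject_id", "age", "sex", "label")


def write_cohort(table: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV (missing stage -> empty field)."""
    table.to_csv(path, index=False)


def validate_cohort(table: pd.DataFrame) -> pd.DataFrame:
    """Validate the subject-level schema; errors name the offending cell."""
    for col in _META_REQUIRED:
        if col not in table.columns:
            raise CohortValidationError(f"missing required column {col!r}")
    if "stage" not in table.columns:
        table = table.copy()
        table["stage"] = pd.array([pd.NA] * len(table), dtype="Int64")
    markers = marker_columns(table)
    if not markers:
        raise CohortValidationError("no marker columns found")
    if len(table) == 0:
        raise CohortValidationError("cohort table has no rows")
    dup = table["subject_id"][table["subject_id"].duplicated()]
    if len(dup):
        raise CohortValidationError(f"duplicate subject_id {dup.iloc[0]!r}")
    bad_label = set(table["label"]) - {"case", "control"}
    if bad_label:
        raise CohortValidationError(f"label must be case/control, got {sorted(bad_label)}")
    bad_sex = set(table["sex"]) - {"M", "F"}
    if bad_sex:
        raise CohortValidationError(f"sex must be M/F, got {sorted(bad_sex)}")
    for m in markers:
        vals = pd.to_numeric(table[m], errors="coerce")
        bad = table.index[~(vals > 0)]
        if len(bad):
            i = bad[0]
            raise CohortValidationError(
                f"nonpositive or non-numeric value for marker {m!r} at subject "
                f"{table.loc[i, 'subject_id']!r}: {table.loc[i, m]!r}"
            )
    stage = pd.to_numeric(table["stage"], errors="coerce")
    is_case = table["label"] == "case"
    missing_stage = table.index[is_case & stage.isna()]
    if len(missing_stage):
        raise CohortValidationError(
            f"case {table.loc[missing_stage[0], 'subject_id']!r} has no stage"
        )
    spurious = table.index[~is_case & stage.notna()]
    if len(spurious):
        raise CohortValidationError(
            f"control {table.loc[spurious[0], 'subject_id']!r} carries a stage"
        )
    out_of_range = table.index[is_case & ~stage.isin([1, 2, 3, 4]) & stage.notna()]
    if len(out_of_range):
        raise CohortValidationError(
            f"case {table.loc[out_of_range[0], 'subject_id']!r} has stage "
            f"{table.loc[out_of_range[0], 'stage']!r} outside 1..4"
        )
    table = table.copy()
    table["stage"] = stage.astype("Int64")
    return table


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort CSV."""
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise CohortValidationError(f"{path}: empty file, expected cohort schema") from exc
    return validate_cohort(table)


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Either ``cohort_path`` (a CSV on disk) or ``cohort`` (a synthetic
    :class:`~seropanel.cohort.CohortConfig`) supplies the subjects.
    """

    cohort_path: str | None = None
    cohort: CohortConfig | None = None
    markers: tuple[str, ...] | None = None  # default: every marker column
    mandatory: tuple[str, ...] = ("CA19-9", "CEA")
    train_fraction: float = 2.0 / 3.0
    target_specificity: float = 0.95
    top_fraction: float = 0.10
    max_gap: float = 0.02
    cv_folds: int = 10
    screen_alpha: float = 0.01
    screen_exclude: bool = False  # drop non-significant markers before search
    covariates: bool = True
    model_params: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.cohort_path is None and self.cohort is None:
            raise ConfigurationError("config needs cohort_path or a synthetic cohort")
        for name in ("train_fraction", "top_fraction", "target_specificity"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ConfigurationError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ConfigurationError(f"cv_folds must be >= 2, got {self.cv_folds}")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a YAML or JSON run configuration mirroring the field names."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise ConfigurationError(f"{path}: expected a key-value mapping")
        return cls.from_mapping(data)

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        kwargs = dict(data)
        unknown = set(kwargs) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown run config key(s): {sorted(unknown)}")
        if kwargs.get("cohort") is not None:
            kwargs["cohort"] = CohortConfig.from_mapping(kwargs["cohort"])
        for key in ("markers", "mandatory"):
            if kwargs.get(key) is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def load_table(config: RunConfig) -> pd.DataFrame:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    return generate_cohort(config.cohort)


def run_pipeline(config: RunConfig) -> SelectionLedger:
    """Execute the full pipeline and (optionally) write all artifacts.

    Stages: load/generate cohort -> rank-sum screen (descriptive by default;
    ``screen_exclude`` makes it prune the candidate list) -> log transform +
    stratified split -> exhaustive panel evaluation under the five
    algorithms -> selection cascade.  When ``config.outdir`` is set, writes
    ``ledger.json``, ``performance.csv``, ``screen.csv``, ``split.csv``,
    ``cascade.csv``, ``summary.txt`` and a plain-text ``run.log`` there.
    """
    log_handler = None
    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        log_handler = logging.FileHandler(outdir / "run.log", mode="w")
        log_handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        logger.addHandler(log_handler)
        if logger.level in (logging.NOTSET, logging.WARNING):
            logger.setLevel(logging.INFO)
    try:
        return _run_pipeline(config)
    finally:
        if log_handler is not None:
            logger.removeHandler(log_handler)
            log_handler.close()


def _run_pipeline(config: RunConfig) -> SelectionLedger:
    table = load_table(config)
    markers = list(config.markers) if config.markers is not None else marker_columns(table)
    logger.info(
        "pipeline start: %d subjects, %d candidate markers, seed=%d, "
        "train_fraction=%.4f, top_fraction=%.3f, max_gap=%.3f, cv_folds=%d, "
        "target_specificity=%.3f, mandatory=%s, model_params=%s",
        len(table), len(markers), config.seed, config.train_fraction,
        config.top_fraction, config.max_gap, config.cv_folds,
        config.target_specificity, ",".join(config.mandatory), config.model_params,
    )

    screen = rank_sum_screen(table, config.screen_alpha, markers)
    logger.info(
        "screen: %d of %d markers significant at p < %g (%s)",
        int(screen["significant"].sum()), len(markers), config.screen_alpha,
        "exclusionary" if config.screen_exclude else "descriptive only",
    )
    if config.screen_exclude:
        kept = [m for m in markers if bool(screen.loc[m, "significant"])]
        missing = [m for m in config.mandatory if m not in kept]
        if missing:
            raise ConfigurationError(
                f"screen_exclude dropped mandatory marker(s) {missing}; "
                "lower screen_alpha or disable screen_exclude"
            )
        logger.info("screen_exclude: searching %d of %d markers", len(kept), len(markers))
        markers = kept

    selector = PanelSelector(
        markers=markers,
        mandatory=config.mandatory,
        train_fraction=config.train_fraction,
        top_fraction=config.top_fraction,
        max_gap=config.max_gap,
        cv_folds=config.cv_folds,
        target_specificity=config.target_specificity,
        covariates=config.covariates,
        model_params=config.model_params,
        random_state=config.seed,
    ).fit(table)
    ledger = selector.ledger_
    logger.info("cascade counts: %s; final panel: %s", ledger.counts, ledger.final)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "ledger.json").write_text(ledger.to_json() + "\n")
        rows = [
            rec.as_row()
            for per_alg in selector.records_.values()
            for per_split in per_alg.values()
            for rec in per_split.values()
        ]
        pd.DataFrame(rows).to_csv(outdir / "performance.csv", index=False)
        screen.reset_index().to_csv(outdir / "screen.csv", index=False)
        selector.split_.reset_index().to_csv(outdir / "split.csv", index=False)
        stage1, stage2, stage3 = map(set, (ledger.stage1, ledger.stage2, ledger.stage3))
        pd.DataFrame(
            {
                "panel": [e["panel"] for e in ledger.stage0],
                "mean_train_cv_auc": [e["mean_train_cv_auc"] for e in ledger.stage0],
                "stage1_top_fraction": [e["panel"] in stage1 for e in ledger.stage0],
                "stage2_mandatory": [e["panel"] in stage2 for e in ledger.stage0],
                "stage3_stable": [e["panel"] in stage3 for e in ledger.stage0],
                "final": [e["panel"] == ledger.final for e in ledger.stage0],
            }
        ).to_csv(outdir / "cascade.csv", index=False)
        (outdir / "summary.txt").write_text(ledger.summary() + "\n")
        logger.info("artifacts written to %s", outdir)
    return ledger
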
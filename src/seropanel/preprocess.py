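"""Preprocessing: log transform, age binning, stratified split, rank-sum screen.

The marker screen is descriptive by default: the exhaustive panel search runs
over *all* candidate markers, the screen merely reports which markers differ
between cases and controls at the chosen significance level.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import CohortValidationError, ConfigurationError

#: Left-closed decade bin edges for age categorization.
DEFAULT_AGE_EDGES: tuple[float, ...] = (40.0, 50.0, 60.0, 70.0)

#: Exact rank-sum p-values are used up to this per-group size (tie-free data).
EXACT_SCREEN_MAX_N = 8

META_COLUMNS = ("subject_id", "age", "sex", "label", "stage")


def marker_columns(table: pd.DataFrame) -> list[str]:
    """Columns of ``table`` that hold marker concentrations."""
    return [c for c in table.columns if c not in META_COLUMNS]


def log_transform_markers(
    table: pd.DataFrame, markers: Sequence[str] | None = None
) -> pd.DataFrame:
    """Replace each marker value by its natural logarithm.

    Covariates, labels and stage are untouched.  Nonpositive marker values are
    invalid concentrations and raise :class:`CohortValidationError` naming the
    subject and marker.
    """
    markers = list(markers) if markers is not None else marker_columns(table)
    out = table.copy()
    for m in markers:
        values = out[m].to_numpy(dtype=float)
        bad = np.flatnonzero(~(values > 0))
        if bad.size:
            subject = table["subject_id"].iloc[bad[0]] if "subject_id" in table else bad[0]
            raise CohortValidationError(
                f"nonpositive value for marker {m!r} at subject {subject!r}: "
                f"{values[bad[0]]!r}"
            )
        out[m] = np.log(values)
    return out


def age_bin_labels(edges: Sequence[float] = DEFAULT_AGE_EDGES) -> list[str]:
    """Ordered labels of the left-closed age bins defined by ``edges``."""
    edges = [int(e) if float(e).is_integer() else e for e in edges]
    labels = [f"<{edges[0]}"]
    labels += [f"{lo}-{hi - 1}" for lo, hi in zip(edges, edges[1:])]
    labels.append(f"{edges[-1]}+")
    return labels


def categorize_age(age, edges: Sequence[float] = DEFAULT_AGE_EDGES):
    """Map age in years to a decade-bin label (left-closed: 40 -> ``40-49``).

    Accepts a scalar or an array; negative ages are invalid.
    """
    arr = np.asarray(age, dtype=float)
    if np.any(arr < 0):
        raise CohortValidationError(f"negative age: {arr[arr < 0][:1]}")
    labels = np.asarray(age_bin_labels(edges))
    idx = np.digitize(arr, np.asarray(edges, dtype=float), right=False)
    result = labels[idx]
    return result.item() if np.isscalar(age) or arr.ndim == 0 else result


def split_cohort(
    table: pd.DataFrame, train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> pd.Series:
    """Randomly assign subjects to ``train``/``validation``, stratified by label.

    Within each label stratum exactly ``round(train_fraction * n)`` subjects
    (round half up) go to the training set; only the membership is random.
    Returns a Series mapping ``subject_id`` to the assignment.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    assignment = pd.Series(index=table["subject_id"], dtype=object, name="split")
    for label in sorted(table["label"].unique()):
        ids = table.loc[table["label"] == label, "subject_id"].to_numpy()
        n_train = int(np.floor(train_fraction * len(ids) + 0.5))
        perm = rng.permutation(len(ids))
        assignment.loc[ids[perm[:n_train]]] = "train"
        assignment.loc[ids[perm[n_train:]]] = "validation"
    return assignment


def split_tables(
    table: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Materialize the (train, validation) tables from a split assignment."""
    which = table["subject_id"].map(assignment)
    return (
        table.loc[which == "train"].reset_index(drop=True),
        table.loc[which == "validation"].reset_index(drop=True),
    )


def _marker_rank_sum(case: np.ndarray, control: np.ndarray) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (case vs control) with the exact null for
    small tie-free samples and the tie/continuity-corrected normal
    approximation otherwise."""
    pooled = np.concatenate([case, control])
    if np.all(pooled == pooled[0]):
        # Degenerate constant marker: no evidence either way.
        return float(len(case) * len(control)) / 2.0, 1.0
    tie_free = len(np.unique(pooled)) == pooled.size
    if min(case.size, control.size) <= EXACT_SCREEN_MAX_N and tie_free:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        case, control, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), min(float(res.pvalue), 1.0)


def rank_sum_screen(
    table: pd.DataFrame,
    alpha: float = 0.01,
    markers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Marker-wise two-sided Wilcoxon rank-sum (Mann-Whitney U) screen.

    Compares case versus control concentrations for every marker and flags
    those with p < ``alpha``.  Rank-based, hence invariant to the log
    transform.  Returns a DataFrame indexed by marker with columns ``U``,
    ``p_value`` and ``significant``.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    markers = list(markers) if markers is not None else marker_columns(table)
    is_case = (table["label"] == "case").to_numpy()
    if is_case.sum() == 0 or (~is_case).sum() == 0:
        raise CohortValidationError("rank-sum screen requires both cases and controls")
    rows = []
    for m in markers:
        values = table[m].to_numpy(dtype=float)
        u, p = _marker_rank_sum(values[is_case], values[~is_case])
        rows.append((m, u, p, p < alpha))
    out = pd.DataFrame(rows, columns=["marker", "U", "p_value", "significant"])
    return out.set_index("marker")
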
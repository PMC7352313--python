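"""Exhaustive marker-subset enumeration and per-panel feature assembly.

A *panel* is a non-empty subset of the candidate markers, represented
throughout as a sorted tuple of marker names; its canonical string form joins
the sorted names with ``+`` (e.g. ``ApoA1+ApoA2+CA125+CA19-9+CEA+TTR``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .preprocess import DEFAULT_AGE_EDGES, age_bin_labels, categorize_age

Panel = tuple[str, ...]

#: Enumeration is exponential; refuse absurd candidate lists by default.
DEFAULT_MAX_MARKERS = 16


def canonicalize(panel: Sequence[str]) -> Panel:
    """Sorted-tuple form of a marker subset."""
    members = tuple(sorted(panel))
    if not members:
        raise ConfigurationError("a panel must contain at least one marker")
    if len(set(members)) != len(members):
        raise ConfigurationError(f"duplicate markers in panel: {panel}")
    return members


def panel_key(panel: Sequence[str]) -> str:
    """Canonical '+'-joined serialized form of a panel."""
    return "+".join(canonicalize(panel))


def parse_panel(key: str) -> Panel:
    """Inverse of :func:`panel_key`."""
    return canonicalize(key.split("+"))


def enumerate_panels(
    markers: Sequence[str], max_markers: int = DEFAULT_MAX_MARKERS
) -> list[Panel]:
    """All 2^n - 1 non-empty subsets of ``markers``.

    Order is deterministic — by size, then lexicographic within size — so
    downstream rankings break ties reproducibly.
    """
    ms = sorted(markers)
    if len(ms) != len(set(ms)):
        raise ConfigurationError(f"duplicate marker names: {sorted(markers)}")
    if not ms:
        raise ConfigurationError("marker list must be non-empty")
    if len(ms) > max_markers:
        raise ConfigurationError(
            f"{len(ms)} markers exceeds the enumeration cap of {max_markers} "
            f"(2^{len(ms)} - 1 subsets); raise max_markers explicitly if intended"
        )
    return [c for size in range(1, len(ms) + 1) for c in combinations(ms, size)]


@dataclass(frozen=True)
class FeatureMatrix:
    """Design matrix for one panel, aligned to the subject rows of its table.

    ``X`` holds the panel's log-marker columns followed by the encoded
    covariates (age bins one-hot with the youngest bin as reference, then a
    male indicator); ``y`` is 1 for cases, 0 for controls.
    """

    X: np.ndarray
    feature_names: tuple[str, ...]
    y: np.ndarray
    subject_ids: tuple[str, ...]
    stages: np.ndarray  # NaN where absent (controls)

    def __post_init__(self) -> None:
        assert self.X.shape == (len(self.y), len(self.feature_names))


def encode_covariates(
    table: pd.DataFrame, age_edges: Sequence[float] = DEFAULT_AGE_EDGES
) -> tuple[np.ndarray, list[str]]:
    """One-hot age bins (reference = youngest bin) plus a sex indicator."""
    labels = age_bin_labels(age_edges)
    bins = categorize_age(table["age"].to_numpy(dtype=float), age_edges)
    cols = [(f"age_{lab}", (bins == lab).astype(float)) for lab in labels[1:]]
    cols.append(("sex_M", (table["sex"].to_numpy() == "M").astype(float)))
    names = [n for n, _ in cols]
    return np.column_stack([v for _, v in cols]), names


def build_feature_matrix(
    table: pd.DataFrame,
    panel: Sequence[str],
    covariates: bool = True,
    age_edges: Sequence[float] = DEFAULT_AGE_EDGES,
) -> FeatureMatrix:
    """Assemble the design matrix for ``panel`` from a log-transformed table."""
    members = canonicalize(panel)
    missing = [m for m in members if m not in table.columns]
    if missing:
        raise ConfigurationError(f"panel markers not in table: {missing}")
    parts = [table[list(members)].to_numpy(dtype=float)]
    names: list[str] = list(members)
    if covariates:
        cov, cov_names = encode_covariates(table, age_edges)
        parts.append(cov)
        names += cov_names
    y = (table["label"].to_numpy() == "case").astype(int)
    stages = table["stage"].to_numpy(dtype=float, na_value=np.nan)
    return FeatureMatrix(
        X=np.hstack(parts),
        feature_names=tuple(names),
        y=y,
        subject_ids=tuple(table["subject_id"]),
        stages=stages,
    )
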
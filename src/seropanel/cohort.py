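"""Synthetic case-control cohort generation for serum-marker panel studies.

The generator emulates a PDAC-versus-healthy-control serum study: eleven
candidate protein markers measured on every subject, right-skewed
concentrations (log-normal), a location shift on the log scale in cases for
the informative markers, a deliberately null marker (the B2M analog), tumor
stage drawn for cases with stage-dependent effect strength, and age/sex
covariates with the case group older and slightly more male.

Because the ground-truth informative set is planted by construction
(:func:`planted_truth`), downstream screening and panel-selection stages have
a recoverable target, which real (undeposited) patient sera cannot provide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigurationError

#: The eleven candidate serum markers, in assay-report order.
DEFAULT_MARKERS: tuple[str, ...] = (
    "ApoA1",
    "CA125",
    "CA19-9",
    "CRP",
    "CYFRA21.1",
    "LRG1",
    "CEA",
    "ApoA2",
    "TTR",
    "B2M",
    "D-Dimer",
)

#: The marker whose case/control distributions coincide under the defaults.
NULL_MARKER = "B2M"

#: Case stage mix (AJCC 1-4) under the defaults.
DEFAULT_STAGE_PROBS: tuple[float, ...] = (0.294, 0.411, 0.167, 0.128)

#: Multiplier applied to each marker's log-scale shift, by stage. Monotone
#: nondecreasing so that later-stage cases carry stronger signal.
DEFAULT_STAGE_EFFECT_SCALE: tuple[float, ...] = (0.8, 0.9, 1.1, 1.2)


def _per_marker(
    values: Mapping[str, float] | float | None,
    markers: Sequence[str],
    default: float,
) -> dict[str, float]:
    """Normalize a per-marker field to a complete {marker: value} dict."""
    if values is None:
        return {m: default for m in markers}
    if isinstance(values, (int, float)):
        return {m: float(values) for m in markers}
    unknown = set(values) - set(markers)
    if unknown:
        raise ConfigurationError(f"unknown marker(s) in config: {sorted(unknown)}")
    return {m: float(values.get(m, default)) for m in markers}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Marker concentrations are log-normal: for marker *j* a control draws
    ``exp(Normal(control_log_mean[j], log_sd[j]))`` and a case of stage *s*
    draws ``exp(Normal(control_log_mean[j] + effect_shift[j] *
    stage_effect_scale[s-1], log_sd[j]))``.  ``effect_shift`` is therefore an
    additive log-scale location shift in units of the assay's log
    concentration; 0 marks a null marker.  Absolute units are unit-free
    (defaults 0 and 1) because every downstream step works on the log scale.

    Ages are normal, truncated below at ``age_min``; sex is Bernoulli(male
    fraction).  A single ``seed`` governs all draws in a fixed order.
    """

    n_case: int = 180
    n_control: int = 573
    marker_names: tuple[str, ...] = DEFAULT_MARKERS
    control_log_mean: Mapping[str, float] | float | None = None
    log_sd: Mapping[str, float] | float | None = None
    effect_shift: Mapping[str, float] | float | None = None
    stage_probs: tuple[float, ...] = DEFAULT_STAGE_PROBS
    stage_effect_scale: tuple[float, ...] = DEFAULT_STAGE_EFFECT_SCALE
    age_case_mean: float = 64.4
    age_case_sd: float = 9.8
    age_control_mean: float = 56.9
    age_control_sd: float = 8.8
    male_frac_case: float = 0.650
    male_frac_control: float = 0.583
    age_min: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if int(self.n_case) != self.n_case or int(self.n_control) != self.n_control:
            raise ConfigurationError("n_case and n_control must be integers")
        if self.n_case < 0 or self.n_control < 0:
            raise ConfigurationError(
                f"negative cohort size: n_case={self.n_case}, n_control={self.n_control}"
            )
        markers = tuple(self.marker_names)
        if len(markers) == 0 or len(set(markers)) != len(markers):
            raise ConfigurationError("marker_names must be non-empty and unique")
        object.__setattr__(self, "marker_names", markers)
        object.__setattr__(
            self, "control_log_mean", _per_marker(self.control_log_mean, markers, 0.0)
        )
        object.__setattr__(self, "log_sd", _per_marker(self.log_sd, markers, 1.0))
        default_shift = {m: 0.0 if m == NULL_MARKER else 1.0 for m in markers}
        if self.effect_shift is None:
            shifts = {m: default_shift.get(m, 1.0) for m in markers}
        else:
            shifts = _per_marker(self.effect_shift, markers, 0.0)
        object.__setattr__(self, "effect_shift", shifts)
        for m in markers:
            if self.log_sd[m] <= 0:
                raise ConfigurationError(f"log_sd must be > 0 (marker {m!r})")
        probs = tuple(float(p) for p in self.stage_probs)
        if len(probs) != 4 or any(p < 0 or p > 1 for p in probs):
            raise ConfigurationError("stage_probs must be 4 probabilities in [0, 1]")
        if abs(sum(probs) - 1.0) > 1e-9:
            raise ConfigurationError(f"stage_probs must sum to 1, got {sum(probs)}")
        object.__setattr__(self, "stage_probs", probs)
        scale = tuple(float(s) for s in self.stage_effect_scale)
        if len(scale) != 4:
            raise ConfigurationError("stage_effect_scale must have 4 entries")
        if any(b < a for a, b in zip(scale, scale[1:])):
            raise ConfigurationError("stage_effect_scale must be nondecreasing")
        object.__setattr__(self, "stage_effect_scale", scale)
        for name in ("age_case_sd", "age_control_sd"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("male_frac_case", "male_frac_control"):
            frac = getattr(self, name)
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "CohortConfig":
        """Build a config from a plain key-value mapping (YAML/JSON payload)."""
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown cohort config key(s): {sorted(unknown)}")
        kwargs = dict(data)
        for key in ("marker_names", "stage_probs", "stage_effect_scale"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _truncated_normal(
    rng: np.random.Generator, n: int, mean: float, sd: float, lower: float
) -> np.ndarray:
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Draw a subject-level cohort table from ``config``.

    Returns a DataFrame with columns ``subject_id, <markers...>, age, sex,
    label, stage``; cases first (stage 1-4), controls after (stage missing).
    Draw order is fixed — case stages, case ages, case sexes, control ages,
    control sexes, then per marker (in ``marker_names`` order) case values
    followed by control values — so an identical config, seed included,
    reproduces the table bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    n_case, n_control = int(config.n_case), int(config.n_control)

    stages = rng.choice(np.arange(1, 5), size=n_case, p=np.asarray(config.stage_probs))
    age_case = _truncated_normal(
        rng, n_case, config.age_case_mean, config.age_case_sd, config.age_min
    )
    sex_case = np.where(rng.random(n_case) < config.male_frac_case, "M", "F")
    age_control = _truncated_normal(
        rng, n_control, config.age_control_mean, config.age_control_sd, config.age_min
    )
    sex_control = np.where(rng.random(n_control) < config.male_frac_control, "M", "F")

    scale_by_stage = np.asarray(config.stage_effect_scale)[stages - 1] if n_case else np.empty(0)
    marker_cols: dict[str, np.ndarray] = {}
    for m in config.marker_names:
        mu, sd = config.control_log_mean[m], config.log_sd[m]
        case_log = rng.normal(mu + config.effect_shift[m] * scale_by_stage, sd, size=n_case)
        control_log = rng.normal(mu, sd, size=n_control)
        marker_cols[m] = np.exp(np.concatenate([case_log, control_log]))

    table = pd.DataFrame(
        {
            "subject_id": [f"case-{i + 1:04d}" for i in range(n_case)]
            + [f"ctrl-{i + 1:04d}" for i in range(n_control)],
            **marker_cols,
            "age": np.concatenate([age_case, age_control]),
            "sex": np.concatenate([sex_case, sex_control]),
            "label": ["case"] * n_case + ["control"] * n_control,
            "stage": pd.array(
                list(stages) + [pd.NA] * n_control, dtype="Int64"
            ),
        }
    )
    return table


def planted_truth(config: CohortConfig) -> tuple[str, ...]:
    """The markers with a nonzero case shift — the recovery target, sorted."""
    return tuple(sorted(m for m in config.marker_names if config.effect_shift[m] != 0.0))
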
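"""Confidence-interval-based cohort stratification.

Samples are stratified by two histology measurements: the mean diffuse
tau-PLA particle count (tau multimers) and the mean perikaryal AT8-IHC
particle count (tangles).  Positivity cut-offs are the upper limits of the
two-sided 99% confidence interval of the corresponding counts in reference
(Braak stage 0) samples,

    CI = xbar +/- t_{(1+c)/2, n-1} * (s / sqrt(n)),

with the AT8 cut-off rounded up to the nearest whole number.  A sample is
positive when its measurement strictly exceeds the cut-off, yielding
Double-Negative (PLA-/AT8-), Intermediate (PLA+/AT8-) and Double-Positive
(PLA+/AT8+) groups.  The remaining cell (PLA-/AT8+) does not occur in the
scheme's intended use and is flagged as Atypical rather than silently
binned.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupLabel",
    "SampleMeasurements",
    "GroupThresholds",
    "ci_upper_cutoff",
    "assign_group",
    "classify_cohort",
]


class GroupLabel(str, Enum):
    DOUBLE_NEGATIVE = "DOUBLE_NEGATIVE"
    INTERMEDIATE = "INTERMEDIATE"
    DOUBLE_POSITIVE = "DOUBLE_POSITIVE"
    ATYPICAL = "ATYPICAL"


@dataclass(frozen=True)
class SampleMeasurements:
    """One sample's histology summary used for stratification."""

    sample_id: str
    braak_stage: str
    pla_diffuse_mean: float
    at8_perikaryal_mean: float

    def __post_init__(self) -> None:
        if self.pla_diffuse_mean < 0 or self.at8_perikaryal_mean < 0:
            raise ValueError("mean particle counts must be non-negative")


@dataclass(frozen=True)
class GroupThresholds:
    """Positivity cut-offs (strict ``>``) for the two measurements."""

    pla_cutoff: float
    at8_cutoff: float
    confidence: float = 0.99
    reference_n: int = 0

    def __post_init__(self) -> None:
        if self.pla_cutoff < 0 or self.at8_cutoff < 0:
            raise ValueError("cut-offs must be non-negative")
        if not 0.0 < self.confidence < 1.0:
            raise ValueError("confidence must lie in (0, 1)")


def ci_upper_cutoff(
    reference_values: Sequence[float] | np.ndarray,
    confidence: float = 0.99,
    rounding: str = "none",
) -> float:
    """Upper limit of the two-sided t confidence interval of the mean.

    ``xbar + t * s / sqrt(n)`` with the sample SD ``s`` (n-1 denominator)
    and the two-sided t quantile at ``(1 + confidence) / 2`` on ``n - 1``
    degrees of freedom.  ``rounding="ceil"`` rounds the result up to the
    nearest whole number.  Requires at least two reference values.
    """
    values = np.asarray(reference_values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise ValueError("need at least two reference values (t undefined)")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    n = values.size
    t = stats.t.ppf((1.0 + confidence) / 2.0, df=n - 1)
    upper = float(values.mean() + t * values.std(ddof=1) / math.sqrt(n))
    if rounding == "ceil":
        return float(math.ceil(upper))
    if rounding != "none":
        raise ValueError(f"unknown rounding mode {rounding!r}")
    return upper


def assign_group(
    sample: SampleMeasurements, thresholds: GroupThresholds
) -> GroupLabel:
    """Map a sample's two positivity calls to its pathology group."""
    pla_pos = sample.pla_diffuse_mean > thresholds.pla_cutoff
    at8_pos = sample.at8_perikaryal_mean > thresholds.at8_cutoff
    if pla_pos and at8_pos:
        return GroupLabel.DOUBLE_POSITIVE
    if pla_pos:
        return GroupLabel.INTERMEDIATE
    if at8_pos:
        warnings.warn(
            f"sample {sample.sample_id!r} is AT8-positive but tau-PLA-negative; "
            f"labelling it ATYPICAL",
            stacklevel=2,
        )
        return GroupLabel.ATYPICAL
    return GroupLabel.DOUBLE_NEGATIVE


def _as_measurements(samples) -> list[SampleMeasurements]:
    if isinstance(samples, pd.DataFrame):
        return [
            SampleMeasurements(
                sample_id=str(r.sample_id),
                braak_stage=str(r.braak_stage),
                pla_diffuse_mean=float(r.pla_diffuse_mean),
                at8_perikaryal_mean=float(r.at8_perikaryal_mean),
            )
            for r in samples.itertuples()
        ]
    return list(samples)


def classify_cohort(
    samples: pd.DataFrame | Iterable[SampleMeasurements],
    thresholds: GroupThresholds | None = None,
    reference_stage: str = "0",
    confidence: float = 0.99,
) -> tuple[pd.DataFrame, GroupThresholds]:
    """Stratify a cohort, deriving cut-offs from its reference samples.

    When ``thresholds`` is not supplied, the tau-PLA cut-off (no rounding)
    and AT8 cut-off (rounded up to a whole number) are derived from the
    samples whose ``braak_stage`` equals ``reference_stage``; at least two
    such samples are required.  Returns the labelled table and the
    thresholds used.
    """
    measurements = _as_measurements(samples)
    if not measurements:
        raise ValueError("empty cohort")
    if thresholds is None:
        reference = [m for m in measurements if m.braak_stage == reference_stage]
        if len(reference) < 2:
            raise ValueError(
                f"found {len(reference)} sample(s) at reference Braak stage "
                f"{reference_stage!r}; need at least 2, or supply explicit "
                f"thresholds"
            )
        thresholds = GroupThresholds(
            pla_cutoff=ci_upper_cutoff(
                [m.pla_diffuse_mean for m in reference], confidence, rounding="none"
            ),
            at8_cutoff=ci_upper_cutoff(
                [m.at8_perikaryal_mean for m in reference], confidence, rounding="ceil"
            ),
            confidence=confidence,
            reference_n=len(reference),
        )
    rows = [
        {
            "sample_id": m.sample_id,
            "braak_stage": m.braak_stage,
            "pla_diffuse_mean": m.pla_diffuse_mean,
            "at8_perikaryal_mean": m.at8_perikaryal_mean,
            "group": assign_group(m, thresholds).value,
        }
        for m in measurements
    ]
    return pd.DataFrame(rows), thresholds
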
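"""Plate normalization, SD-unit scoring, and hit-calling decision cascades.

The screen's statistic is the per-well GFP high/low ratio.  Wells are scored
in SD units, ``z = (x - mean) / sd``, against a reference population — all
sample wells of the plate for the primary screen (on the linear ratio), or
the arm's pooled non-targeting control wells for the validation / counter /
1i screens (on the log2 ratio).  Positive scores mean more GFP-high cells,
i.e. delayed exit from naive pluripotency.

Hit calling is a threshold cascade over the two biological replicates:

* primary screen: average >= 2 SD with both replicates >= 1.5 SD (rule R2),
  or average >= 2.5 SD with one replicate >= 1.5 SD (R3), or average >= 1.9 SD
  with both replicates >= 1.9 SD (R4); a single valid replicate at |z| >= 2
  when its duplicate well was defective (R1).  The same cascade on negated
  scores calls accelerated-exit (down-direction) hits.
* validation screens: average score >= 1.25 SD above the non-targeting
  controls (V1); genes scoring >= 0.8 SD in one validation screen and
  >= 1.0 SD in the other are rescued into the high-confidence set (V2).
* counter (+2i) screen: V1 applied to the +2i arm flags reporter-stabilising
  artifacts.
* 1i screens: average score >= 1.5 SD above the controls (I1), per arm.

All thresholds are inclusive (>=) and configurable.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .cytometry import WellSummary
from .errors import InsufficientReferenceError, InvalidConfigError


class HitStatus(enum.Enum):
    POSITIVE_UP = "positive_up"
    POSITIVE_DOWN = "positive_down"
    NEGATIVE = "negative"
    NO_CALL = "no_call"


@dataclass(frozen=True)
class HitThresholds:
    """All hit-calling thresholds, in SD units (defaults as published)."""

    primary_avg: float = 2.0          # R2: average across both plates
    primary_both: float = 1.5         # R2: each replicate
    primary_high_avg: float = 2.5     # R3: average
    primary_high_single: float = 1.5  # R3: at least one replicate
    primary_alt: float = 1.9          # R4: average and both replicates
    primary_single: float = 2.0       # R1: lone valid replicate
    validation: float = 1.25          # V1
    rescue_low: float = 0.8           # V2: one screen
    rescue_high: float = 1.0          # V2: the other screen
    counter: float = 1.25             # artifact call in the +2i arm
    one_i: float = 1.5                # I1

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass(frozen=True)
class PlateStats:
    """Reference-population location/scale for one plate (or plate pair)."""

    reference: str  # all_sample_wells | nt_control_wells
    scale: str      # linear_ratio | log2_ratio
    mean: float
    sd: float
    n: int


@dataclass(frozen=True)
class HitDecision:
    gene_id: str
    arm: str
    status: HitStatus
    rule_fired: str | None = None
    scores: tuple[float | None, ...] = ()
    average: float | None = None

    def __post_init__(self) -> None:
        positive = self.status in (HitStatus.POSITIVE_UP, HitStatus.POSITIVE_DOWN)
        if positive != (self.rule_fired is not None):
            raise InvalidConfigError("rule_fired must be set iff the decision is positive")

    @property
    def is_positive(self) -> bool:
        return self.status in (HitStatus.POSITIVE_UP, HitStatus.POSITIVE_DOWN)


def _statistic(summary: WellSummary, scale: str) -> float:
    if scale == "linear_ratio":
        return summary.ratio_high_low
    if scale == "log2_ratio":
        return summary.log2_ratio
    raise InvalidConfigError(f"unknown scale {scale!r}")


def plate_statistics(
    reference_summaries: Sequence[WellSummary],
    reference: str = "all_sample_wells",
    scale: str = "linear_ratio",
) -> PlateStats:
    """Mean and sample SD of the well statistic over the reference population.

    Defective wells are excluded; at least 3 usable reference wells are
    required.
    """
    if reference not in ("all_sample_wells", "nt_control_wells"):
        raise InvalidConfigError(f"unknown reference population {reference!r}")
    values = [
        _statistic(s, scale) for s in reference_summaries if not s.defective
    ]
    if len(values) < 3:
        raise InsufficientReferenceError(
            f"only {len(values)} non-defective reference wells (need >= 3)"
        )
    arr = np.asarray(values, dtype=float)
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        raise InsufficientReferenceError("reference population has zero spread")
    return PlateStats(reference=reference, scale=scale, mean=float(arr.mean()), sd=sd, n=len(values))


def score_well(summary: WellSummary, stats: PlateStats) -> float:
    """SD-unit score of one well against its plate reference."""
    return (_statistic(summary, stats.scale) - stats.mean) / stats.sd


def _valid(scores: Iterable[float | None]) -> list[float]:
    return [s for s in scores if s is not None and math.isfinite(s)]


def _cascade_up(z1: float, z2: float, t: HitThresholds) -> str | None:
    """Up-direction replicate cascade; returns the rule that fires.

    R3 (the high-average rule) is labelled before R2 so that a pair strong
    enough for the relaxed single-replicate requirement is attributed to it;
    the recorded label never changes the decision, only its provenance.
    """
    avg = (z1 + z2) / 2.0
    lo, hi = min(z1, z2), max(z1, z2)
    if avg >= t.primary_high_avg and hi >= t.primary_high_single:
        return "R3"
    if avg >= t.primary_avg and lo >= t.primary_both:
        return "R2"
    if avg >= t.primary_alt and lo >= t.primary_alt:
        return "R4"
    return None


def call_primary(
    z1: float | None,
    z2: float | None,
    thresholds: HitThresholds | None = None,
    gene_id: str = "",
    arm: str = "primary_minus2i",
) -> HitDecision:
    """Primary-screen decision for one gene from its two replicate scores.

    ``None`` marks a defective replicate.  With one valid replicate only rule
    R1 (|z| >= 2) is consulted; with both defective the gene is not callable.
    """
    t = thresholds or HitThresholds()
    valid = _valid((z1, z2))
    scores = (z1, z2)
    if not valid:
        return HitDecision(gene_id, arm, HitStatus.NO_CALL, scores=scores)
    avg = float(np.mean(valid))
    if len(valid) == 1:
        z = valid[0]
        if z >= t.primary_single:
            return HitDecision(gene_id, arm, HitStatus.POSITIVE_UP, "R1", scores, avg)
        if -z >= t.primary_single:
            return HitDecision(gene_id, arm, HitStatus.POSITIVE_DOWN, "R1", scores, avg)
        return HitDecision(gene_id, arm, HitStatus.NEGATIVE, scores=scores, average=avg)
    rule = _cascade_up(z1, z2, t)
    if rule is not None:
        return HitDecision(gene_id, arm, HitStatus.POSITIVE_UP, rule, scores, avg)
    rule = _cascade_up(-z1, -z2, t)
    if rule is not None:
        return HitDecision(gene_id, arm, HitStatus.POSITIVE_DOWN, rule, scores, avg)
    return HitDecision(gene_id, arm, HitStatus.NEGATIVE, scores=scores, average=avg)


def call_validation(
    z1: float | None,
    z2: float | None,
    thresholds: HitThresholds | None = None,
    gene_id: str = "",
    arm: str = "validation_rex1_minus2i",
) -> HitDecision:
    """Validation-screen call: average score >= 1.25 SD above the controls (V1).

    The average is always recorded so the cross-screen rescue rule can use it.
    """
    t = thresholds or HitThresholds()
    valid = _valid((z1, z2))
    if not valid:
        return HitDecision(gene_id, arm, HitStatus.NO_CALL, scores=(z1, z2))
    avg = float(np.mean(valid))
    if avg >= t.validation:
        return HitDecision(gene_id, arm, HitStatus.POSITIVE_UP, "V1", (z1, z2), avg)
    return HitDecision(gene_id, arm, HitStatus.NEGATIVE, scores=(z1, z2), average=avg)


@dataclass(frozen=True)
class ValidationCombination:
    gene_id: str
    high_confidence: bool
    rule_fired: str | None
    incomplete: bool


def combine_validation(
    rex1: HitDecision, oct4: HitDecision, thresholds: HitThresholds | None = None
) -> ValidationCombination:
    """High-confidence call across the two validation screens.

    V1: positive in both screens.  V2 (rescue): average score >= 0.8 SD in
    one screen and >= 1.0 SD in the other, in either assignment.  A no-call
    in either screen makes the gene incomplete and never high-confidence.
    """
    t = thresholds or HitThresholds()
    gene = rex1.gene_id or oct4.gene_id
    if rex1.status is HitStatus.NO_CALL or oct4.status is HitStatus.NO_CALL:
        return ValidationCombination(gene, False, None, incomplete=True)
    if rex1.status is HitStatus.POSITIVE_UP and oct4.status is HitStatus.POSITIVE_UP:
        return ValidationCombination(gene, True, "V1", incomplete=False)
    a, b = rex1.average, oct4.average
    if min(a, b) >= t.rescue_low and max(a, b) >= t.rescue_high:
        return ValidationCombination(gene, True, "V2", incomplete=False)
    return ValidationCombination(gene, False, None, incomplete=False)


def call_counter(
    z1: float | None,
    z2: float | None,
    thresholds: HitThresholds | None = None,
    gene_id: str = "",
) -> bool:
    """Artifact flag from the +2i counter screen.

    A gene that still accumulates GFP with both inhibitors present stabilises
    the reporter independently of ERK/GSK3 signalling (e.g. proteasome
    subunits) and is flagged.  The validation rule (average >= 1.25 SD,
    inclusive) is applied to the +2i scores.
    """
    t = thresholds or HitThresholds()
    valid = _valid((z1, z2))
    if not valid:
        warnings.warn(
            f"gene {gene_id or '?'}: counter screen not callable; treating as non-artifact",
            stacklevel=2,
        )
        return False
    return bool(float(np.mean(valid)) >= t.counter)


def call_1i(
    z1: float | None,
    z2: float | None,
    thresholds: HitThresholds | None = None,
    gene_id: str = "",
    arm: str = "oneI_minusMEKi",
) -> HitDecision:
    """Single-withdrawal screen call: average >= 1.5 SD above controls (I1)."""
    t = thresholds or HitThresholds()
    valid = _valid((z1, z2))
    if not valid:
        return HitDecision(gene_id, arm, HitStatus.NO_CALL, scores=(z1, z2))
    avg = float(np.mean(valid))
    if avg >= t.one_i:
        return HitDecision(gene_id, arm, HitStatus.POSITIVE_UP, "I1", (z1, z2), avg)
    return HitDecision(gene_id, arm, HitStatus.NEGATIVE, scores=(z1, z2), average=avg)
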
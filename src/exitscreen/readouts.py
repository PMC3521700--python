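"""Downstream quantitative readout logic for screen hits.

Covers the secondary assays that characterise validated hits:

* RT-qPCR marker panels, normalized to the mean of three reference genes
  (gapdh, hmbs, tbp) and rescaled to the panel maximum (taken as 100);
* SD-multiple effect thresholds against negative-control siRNAs
  (2x SD for qPCR markers, 1.5x SD for phospho-ERK, 2x SD for Ras activity);
* quadrant classification of genes by joint pluripotency-marker /
  differentiation-marker behaviour;
* placement of each gene's point of action in the ERK cascade (upstream of
  Ras, between Ras and ERK, or downstream of ERK) from its knockdown effect
  on Ras activity and ERK phosphorylation;
* ERK activation kinetics comparison (delayed and/or reduced peak after
  release from 2i, or the premature/elevated phenotype of Dusp depletion).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    DegenerateControlsError,
    DegeneratePanelError,
    GridError,
    InvalidReferenceError,
    UndefinedRSquaredError,
)


def normalize_qpcr(
    raw: float | np.ndarray,
    refs: Sequence[float],
    method: str = "arithmetic",
) -> float | np.ndarray:
    """Relative expression normalized to the reference-gene panel.

    ``refs`` are the raw relative expressions of the reference genes (gapdh,
    hmbs, tbp); the aggregate is their arithmetic mean by default, with the
    geometric mean available as the common alternative.
    """
    refs = np.asarray(refs, dtype=float)
    if refs.size == 0 or np.any(refs <= 0):
        raise InvalidReferenceError(f"reference values must all be positive: {refs}")
    if method == "arithmetic":
        denom = refs.mean()
    elif method == "geometric":
        denom = float(sps.gmean(refs))
    else:
        raise InvalidReferenceError(f"unknown aggregation {method!r}")
    return raw / denom


def rescale_to_max(values: Sequence[float]) -> np.ndarray:
    """Express a marker panel relative to its maximum, taken as 100."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0 or arr.max() <= 0:
        raise DegeneratePanelError("panel has no positive value to rescale against")
    # divide first so the maximum maps to exactly 100.0
    return (arr / arr.max()) * 100.0


def threshold_call(
    values: Sequence[float],
    controls: Sequence[float],
    k: float,
    direction: str = "above",
) -> np.ndarray:
    """Flag values beyond ``mean(controls) +/- k * SD(controls)``.

    ``direction='above'`` flags values >= mean + k*SD (e.g. elevated rex1 at
    k=2); ``direction='below'`` flags values <= mean - k*SD (e.g. reduced
    phospho-ERK at k=1.5, reduced Ras activity at k=2).  Thresholds are
    inclusive.
    """
    ctrl = np.asarray(controls, dtype=float)
    if ctrl.size < 2:
        raise DegenerateControlsError("need >= 2 control values")
    sd = float(ctrl.std(ddof=1))
    if sd == 0.0:
        raise DegenerateControlsError("control values have zero spread")
    vals = np.asarray(values, dtype=float)
    if direction == "above":
        return vals >= ctrl.mean() + k * sd
    if direction == "below":
        return vals <= ctrl.mean() - k * sd
    raise DegenerateControlsError(f"unknown direction {direction!r}")


def classify_quadrant(
    rex1_up: bool,
    second_marker_effect: bool,
    second_marker_kind: str = "fgf5_reduced",
) -> int:
    """Quadrant of a gene in the pluripotency-vs-differentiation marker plane.

    Quadrant 1: elevated pluripotency marker and the second-marker effect
    (reduced fgf5, or elevated nanog); quadrant 2: elevated pluripotency
    marker only; quadrant 3: second-marker effect only; quadrant 4: neither.
    When the second marker is fgf5, the plot axis is its reciprocal, so
    "effect" means reduced expression.
    """
    if second_marker_kind not in ("fgf5_reduced", "nanog_up"):
        raise ValueError(f"unknown second marker {second_marker_kind!r}")
    if rex1_up and second_marker_effect:
        return 1
    if rex1_up:
        return 2
    if second_marker_effect:
        return 3
    return 4


class PathwayPosition(enum.Enum):
    UPSTREAM_OF_RAS = "upstream_of_ras"
    BETWEEN_RAS_AND_ERK = "between_ras_and_erk"
    DOWNSTREAM_OF_ERK = "downstream_of_erk"


@dataclass(frozen=True)
class PointOfAction:
    gene_id: str
    position: PathwayPosition


def assign_point_of_action(
    gene_id: str,
    erk_reduced: bool,
    ras_reduced: bool | None = None,
) -> PointOfAction:
    """Place a gene in the ERK cascade from its knockdown phenotype.

    A knockdown that reduces ERK activation acts upstream of ERK; among those,
    one that also reduces Ras activity acts upstream of Ras, otherwise between
    Ras and ERK.  Ras activity is only assayed for ERK-upstream genes, so
    ``ras_reduced`` must be provided iff ``erk_reduced`` is true (a value
    supplied otherwise is ignored with a warning).
    """
    if not erk_reduced:
        if ras_reduced is not None:
            warnings.warn(
                f"gene {gene_id}: Ras call ignored for a gene that does not "
                "reduce ERK activation",
                stacklevel=2,
            )
        return PointOfAction(gene_id, PathwayPosition.DOWNSTREAM_OF_ERK)
    if ras_reduced is None:
        raise ValueError(
            f"gene {gene_id}: Ras call required for an ERK-upstream gene"
        )
    if ras_reduced:
        return PointOfAction(gene_id, PathwayPosition.UPSTREAM_OF_RAS)
    return PointOfAction(gene_id, PathwayPosition.BETWEEN_RAS_AND_ERK)


def coefficient_of_determination(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation between two paired marker-effect vectors."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise UndefinedRSquaredError("need >= 3 paired values")
    if xa.std() == 0.0 or ya.std() == 0.0:
        raise UndefinedRSquaredError("zero variance in one of the vectors")
    r = float(np.corrcoef(xa, ya)[0, 1])
    return r * r


@dataclass(frozen=True)
class KineticsCall:
    """Comparison of ERK activation time courses: knockdown vs control."""

    gene_id: str
    peak_time_control: float
    peak_time_kd: float
    peak_amp_control: float
    peak_amp_kd: float
    delayed: bool
    reduced: bool
    premature: bool
    elevated: bool


def compare_kinetics(
    times: Sequence[float],
    control: Sequence[float],
    knockdown: Sequence[float],
    gene_id: str = "",
    amplitude_tolerance: float = 0.10,
    times_knockdown: Sequence[float] | None = None,
) -> KineticsCall:
    """Compare activation kinetics sampled on a shared time grid.

    ``delayed`` means the knockdown peak occurs at a later sampled time than
    the control peak; ``reduced`` means its amplitude falls short of the
    control peak by more than ``amplitude_tolerance`` (fractional).  The
    opposite phenotype — premature and/or higher-amplitude activation, as
    seen on Dusp depletion — is reported through the ``premature`` and
    ``elevated`` annotations with both main flags false.
    """
    t = np.asarray(times, dtype=float)
    if times_knockdown is not None and not np.array_equal(
        t, np.asarray(times_knockdown, dtype=float)
    ):
        raise GridError("control and knockdown series sampled on different grids")
    c = np.asarray(control, dtype=float)
    k = np.asarray(knockdown, dtype=float)
    if t.size < 3 or c.size != t.size or k.size != t.size:
        raise GridError("series must share a time grid of >= 3 points")
    ic, ik = int(np.argmax(c)), int(np.argmax(k))
    amp_c, amp_k = float(c[ic]), float(k[ik])
    return KineticsCall(
        gene_id=gene_id,
        peak_time_control=float(t[ic]),
        peak_time_kd=float(t[ik]),
        peak_amp_control=amp_c,
        peak_amp_kd=amp_k,
        delayed=t[ik] > t[ic],
        reduced=amp_k < amp_c * (1.0 - amplitude_tolerance),
        premature=t[ik] < t[ic],
        elevated=amp_k > amp_c * (1.0 + amplitude_tolerance),
    )


def simulate_biochem_panel(
    positions: dict[str, PathwayPosition],
    rng: np.random.Generator,
    n_controls: int = 8,
    control_mean: float = 70.0,
    control_sd: float = 5.0,
    effect_sds: float = 6.0,
) -> dict[str, dict[str, np.ndarray | float]]:
    """Synthetic pERK/Ras assay values consistent with planted pathway positions.

    Gaussian readouts around the control mean; genes planted upstream of a
    node draw that node's readout ``effect_sds`` control SDs below the mean.
    Used to exercise the point-of-action logic end to end.
    """
    perk_controls = rng.normal(control_mean, control_sd, n_controls)
    ras_controls = rng.normal(control_mean, control_sd, n_controls)
    drop = effect_sds * control_sd
    perk, ras = {}, {}
    for gene, pos in positions.items():
        erk_upstream = pos in (
            PathwayPosition.UPSTREAM_OF_RAS,
            PathwayPosition.BETWEEN_RAS_AND_ERK,
        )
        perk[gene] = rng.normal(
            control_mean - (drop if erk_upstream else 0.0), control_sd
        )
        ras[gene] = rng.normal(
            control_mean - (drop if pos is PathwayPosition.UPSTREAM_OF_RAS else 0.0),
            control_sd,
        )
    return {
        "perk": perk,
        "ras": ras,
        "perk_controls": perk_controls,
        "ras_controls": ras_controls,
    }


def recover_points_of_action(
    panel: dict,
    perk_k: float = 1.5,
    ras_k: float = 2.0,
) -> dict[str, PointOfAction]:
    """Run the published thresholds over a biochemical panel.

    ERK-upstream genes are those whose pERK/ERK ratio falls at least
    ``perk_k`` control SDs below the control mean; only those are then tested
    for reduced Ras activity at ``ras_k`` SDs.
    """
    genes = sorted(panel["perk"])
    perk_vals = [panel["perk"][g] for g in genes]
    erk_flags = threshold_call(perk_vals, panel["perk_controls"], perk_k, "below")
    out = {}
    for gene, erk_reduced in zip(genes, erk_flags):
        if erk_reduced:
            ras_flag = bool(
                threshold_call(
                    [panel["ras"][gene]], panel["ras_controls"], ras_k, "below"
                )[0]
            )
            out[gene] = assign_point_of_action(gene, True, ras_flag)
        else:
            out[gene] = assign_point_of_action(gene, False)
    return out
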
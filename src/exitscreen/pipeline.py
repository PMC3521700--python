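"""End-to-end orchestration: simulate -> gate -> score -> call -> stratify ->
position, with a reproducible manifest.

The stages communicate through plain CSV tables (the same schemas the CLI
subcommands read and write), so each stage can also be run on real cytometry
exports without the simulator.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .cytometry import (
    EventTable,
    GateConfig,
    WellSummary,
    apply_gates,
    control_gfp_threshold,
    pool_events,
    summarize_well,
)
from .readouts import (
    PathwayPosition,
    recover_points_of_action,
    simulate_biochem_panel,
)
from .screen_stats import (
    HitStatus,
    HitThresholds,
    call_1i,
    call_counter,
    call_primary,
    call_validation,
    combine_validation,
    plate_statistics,
    score_well,
)
from .simulate import (
    ARM_NAMES,
    ROLE_NT,
    ROLE_SAMPLE,
    SimulatedScreen,
    SimulationConfig,
    simulate_screen,
)
from .stratify import (
    BOTH_REQUIRED,
    ERK_ONLY,
    GSK_ONLY,
    SHARED_EITHER,
    PathwayPartition,
    counter_filter,
    stratify,
    write_report,
)

logger = logging.getLogger("exitscreen")

PRIMARY_ARM = "primary_minus2i"
VALIDATION_ARMS = ("validation_rex1_minus2i", "validation_oct4_minus2i")
COUNTER_ARM = "counter_plus2i"
ONE_I_ARMS = ("oneI_minusMEKi", "oneI_minusGSKi")

#: Planted effect class -> expected pathway category.
CLASS_TO_CATEGORY = {
    "erk_specific": ERK_ONLY,
    "gsk_specific": GSK_ONLY,
    "shared": SHARED_EITHER,
    "both_required": BOTH_REQUIRED,
}


@dataclass
class PipelineConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gates: GateConfig = field(default_factory=GateConfig)
    thresholds: HitThresholds = field(default_factory=HitThresholds)
    arms: tuple[str, ...] = ARM_NAMES


def summarize_plate(
    wells: Mapping[str, EventTable],
    nt_wells: list[str],
    gates: GateConfig,
) -> dict[str, WellSummary]:
    """Gate a plate's wells, anchor the GFP threshold on its pooled
    non-targeting controls, and summarize every well against it."""
    gated = {w: apply_gates(ev, gates) for w, ev in wells.items()}
    pooled = pool_events([gated[w] for w in nt_wells if gated[w].n_events > 0])
    threshold = control_gfp_threshold(pooled)
    return {
        w: summarize_well(
            g, threshold, gates.min_gated_events, n_total=wells[w].n_events
        )
        for w, g in gated.items()
    }


def summarize_screen(screen: SimulatedScreen, gates: GateConfig) -> pd.DataFrame:
    """Run gating + anchoring + per-well summaries over every simulated plate."""
    records = []
    for arm, rep, plate in screen.plate_keys():
        layout = screen.layouts[plate]
        wells = {
            well: events
            for well, _, _, events in screen.iter_plate_wells(arm, rep, plate)
        }
        summaries = summarize_plate(wells, layout.nt_wells, gates)
        for well, s in summaries.items():
            records.append(
                {
                    "arm": arm,
                    "replicate": rep,
                    "plate": plate,
                    "well": well,
                    "gene_id": screen.gene_at(plate, well),
                    "role": layout.role_of[well],
                    "n_total": s.n_total,
                    "n_gated": s.n_gated,
                    "n_high": s.n_high,
                    "n_low": s.n_low,
                    "ratio_high_low": s.ratio_high_low,
                    "log2_ratio": s.log2_ratio,
                    "defective": s.defective,
                }
            )
        logger.debug("summarized arm=%s rep=%d plate=%d", arm, rep, plate)
    return pd.DataFrame(records)


def _row_summary(row) -> WellSummary:
    return WellSummary(
        well=row.well,
        n_total=int(row.n_total),
        n_gated=int(row.n_gated),
        n_high=int(row.n_high),
        n_low=int(row.n_low),
        ratio_high_low=float(row.ratio_high_low),
        log2_ratio=float(row.log2_ratio),
        defective=bool(row.defective),
    )


def score_arm(summaries: pd.DataFrame, arm: str) -> pd.DataFrame:
    """SD-unit scores for every sample well of one arm.

    The primary screen is scored on the linear ratio against all sample wells
    of each plate; validation / counter / 1i arms on the log2 ratio against
    the arm's non-targeting control wells, pooled across all duplicate plates
    (the per-plate GFP anchoring has already absorbed plate-to-plate timing
    variation, and arm-wide pooling gives the control SD enough degrees of
    freedom to be stable).  Returns columns
    (gene_id, replicate, plate, well, score, defective).
    """
    sub = summaries[summaries.arm == arm]
    out = []
    if arm == PRIMARY_ARM:
        for (rep, plate), grp in sub.groupby(["replicate", "plate"]):
            samples = grp[grp.role == ROLE_SAMPLE]
            ref = [_row_summary(r) for r in samples.itertuples()]
            stats = plate_statistics(ref, "all_sample_wells", "linear_ratio")
            for r in samples.itertuples():
                s = _row_summary(r)
                out.append(
                    {
                        "gene_id": r.gene_id,
                        "replicate": rep,
                        "plate": plate,
                        "well": r.well,
                        "score": None if s.defective else score_well(s, stats),
                        "defective": s.defective,
                    }
                )
    else:
        controls = [
            _row_summary(r) for r in sub[sub.role == ROLE_NT].itertuples()
        ]
        stats = plate_statistics(controls, "nt_control_wells", "log2_ratio")
        samples = sub[sub.role == ROLE_SAMPLE]
        for r in samples.itertuples():
            s = _row_summary(r)
            out.append(
                {
                    "gene_id": r.gene_id,
                    "replicate": r.replicate,
                    "plate": r.plate,
                    "well": r.well,
                    "score": None if s.defective else score_well(s, stats),
                    "defective": s.defective,
                }
            )
    return pd.DataFrame(out)


def replicate_scores(scored: pd.DataFrame) -> dict[str, tuple[float | None, float | None]]:
    """Collapse a scored arm to gene -> (z_rep0, z_rep1)."""
    pairs: dict[str, list[float | None]] = {}
    n_reps = int(scored.replicate.max()) + 1 if len(scored) else 0
    for r in scored.itertuples():
        pairs.setdefault(r.gene_id, [None] * n_reps)[int(r.replicate)] = (
            None if r.score is None or pd.isna(r.score) else float(r.score)
        )
    return {g: tuple(v) for g, v in pairs.items()}


@dataclass
class ScreenCalls:
    """All per-gene decisions and derived gene sets for one full screen run."""

    arm_scores: dict[str, dict[str, tuple[float | None, ...]]]
    primary: dict[str, object]
    validation: dict[str, dict[str, object]]
    high_confidence: dict[str, object]
    artifact: dict[str, bool]
    one_i: dict[str, dict[str, object]]
    validated: frozenset[str]
    retained: frozenset[str]
    eliminated: frozenset[str]
    partition: PathwayPartition
    one_i_average_scores: dict[str, tuple[float, float]]


def call_screen(
    summaries: pd.DataFrame, thresholds: HitThresholds | None = None
) -> ScreenCalls:
    """Run every decision cascade over a summarized multi-arm screen."""
    t = thresholds or HitThresholds()
    arms = list(summaries.arm.unique())
    arm_scores = {
        arm: replicate_scores(score_arm(summaries, arm)) for arm in arms
    }

    genes = sorted(
        set().union(*(set(s) for s in arm_scores.values())) if arm_scores else set()
    )

    def pair(arm: str, g: str) -> tuple[float | None, float | None]:
        z = arm_scores.get(arm, {}).get(g, (None, None))
        return (z + (None, None))[:2]

    primary = {
        g: call_primary(*pair(PRIMARY_ARM, g), t, gene_id=g) for g in genes
    }
    validation = {
        arm: {
            g: call_validation(*pair(arm, g), t, gene_id=g, arm=arm) for g in genes
        }
        for arm in VALIDATION_ARMS
        if arm in arm_scores
    }
    if all(arm in validation for arm in VALIDATION_ARMS):
        high_conf = {
            g: combine_validation(
                validation[VALIDATION_ARMS[0]][g], validation[VALIDATION_ARMS[1]][g], t
            )
            for g in genes
        }
        validated = frozenset(g for g, c in high_conf.items() if c.high_confidence)
    else:
        # Without both validation arms, primary up-hits stand in for the
        # validated set so the downstream stages still run.
        high_conf = {}
        validated = frozenset(
            g for g, d in primary.items() if d.status is HitStatus.POSITIVE_UP
        )

    artifact = {
        g: call_counter(*pair(COUNTER_ARM, g), t, gene_id=g) for g in genes
    } if COUNTER_ARM in arm_scores else {g: False for g in genes}

    retained, eliminated = counter_filter(
        validated, {g for g, a in artifact.items() if a}
    )

    one_i = {
        arm: {g: call_1i(*pair(arm, g), t, gene_id=g, arm=arm) for g in genes}
        for arm in ONE_I_ARMS
        if arm in arm_scores
    }
    mek_pos = {
        g
        for g, d in one_i.get(ONE_I_ARMS[0], {}).items()
        if d.status is HitStatus.POSITIVE_UP
    } & set(retained)
    gsk_pos = {
        g
        for g, d in one_i.get(ONE_I_ARMS[1], {}).items()
        if d.status is HitStatus.POSITIVE_UP
    } & set(retained)
    partition = stratify(retained, mek_pos, gsk_pos)

    def avg(arm: str, g: str) -> float:
        d = one_i.get(arm, {}).get(g)
        return float("nan") if d is None or d.average is None else d.average

    one_i_avg = {
        g: (avg(ONE_I_ARMS[0], g), avg(ONE_I_ARMS[1], g)) for g in retained
    }

    return ScreenCalls(
        arm_scores=arm_scores,
        primary=primary,
        validation=validation,
        high_confidence=high_conf,
        artifact=artifact,
        one_i=one_i,
        validated=validated,
        retained=retained,
        eliminated=eliminated,
        partition=partition,
        one_i_average_scores=one_i_avg,
    )


def hit_table(calls: ScreenCalls) -> pd.DataFrame:
    """Long-format hit table: one row per gene per called arm."""
    rows = []
    decisions_by_arm: dict[str, dict] = {PRIMARY_ARM: calls.primary}
    decisions_by_arm.update(calls.validation)
    decisions_by_arm.update(calls.one_i)
    for arm, decisions in decisions_by_arm.items():
        for g, d in sorted(decisions.items()):
            z1, z2 = (d.scores + (None, None))[:2]
            hc = calls.high_confidence.get(g)
            rows.append(
                {
                    "gene_id": g,
                    "arm": arm,
                    "z1": z1,
                    "z2": z2,
                    "average": d.average,
                    "status": d.status.value,
                    "rule_fired": d.rule_fired,
                    "high_confidence": bool(hc.high_confidence) if hc else None,
                    "artifact": calls.artifact.get(g, False),
                }
            )
    return pd.DataFrame(rows)


def recovery_metrics(calls: ScreenCalls, truth) -> dict[str, float]:
    """Compare decisions against the simulator's truth table.

    Reports primary-screen sensitivity on planted delay-of-exit genes, the
    empirical false-positive rate among null genes, the counter screen's
    artifact removal fraction, and the accuracy of the four-way pathway
    stratification on the planted pathway-specific classes.
    """
    def frac(flags: list[bool]) -> float:
        return float(np.mean(flags)) if flags else float("nan")

    delay = truth.genes_of_class("delay_exit")
    nulls = truth.genes_of_class("null")
    artifacts = truth.genes_of_class("proteasome_artifact")

    sensitivity = frac(
        [calls.primary[g].status is HitStatus.POSITIVE_UP for g in sorted(delay)]
    )
    fpr = frac([calls.primary[g].is_positive for g in sorted(nulls)])
    removal = frac([calls.artifact.get(g, False) for g in sorted(artifacts)])

    strat_flags = []
    per_class: dict[str, float] = {}
    for cls, category in CLASS_TO_CATEGORY.items():
        genes = sorted(truth.genes_of_class(cls))
        flags = []
        for g in genes:
            try:
                flags.append(calls.partition.category_of(g) == category)
            except KeyError:
                flags.append(False)
        per_class[f"stratification_accuracy_{cls}"] = frac(flags)
        strat_flags.extend(flags)

    return {
        "primary_sensitivity": sensitivity,
        "null_false_positive_rate": fpr,
        "artifact_removal": removal,
        "stratification_accuracy": frac(strat_flags),
        **per_class,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
) -> dict:
    """Execute the full pipeline and write all stage outputs plus a manifest.

    Returns a summary dict (gene-set sizes, partition counts, recovery
    metrics against the simulator's truth table).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if seed is not None:
        sim = SimulationConfig(**{**sim.__dict__, "seed": seed})

    logger.info("simulating screen: %d genes, arms=%s", sim.n_genes, list(config.arms))
    screen, truth = simulate_screen(sim, list(config.arms))
    screen.plate_map_frame().to_csv(out / "plate_map.csv", index=False)
    truth.to_frame().to_csv(out / "truth_table.csv", index=False)

    logger.info("gating and summarizing %d plates", len(screen.plate_keys()))
    summaries = summarize_screen(screen, config.gates)
    summaries.to_csv(out / "well_summaries.csv", index=False)

    logger.info(
        "calling hits with thresholds %s", json.dumps(config.thresholds.as_dict())
    )
    calls = call_screen(summaries, config.thresholds)
    hit_table(calls).to_csv(out / "hit_table.csv", index=False)
    write_report(calls.partition, calls.one_i_average_scores, out)

    # Point-of-action stage on a synthetic biochemical panel: ERK-linked
    # retained hits get planted positions, assayed, and recovered.
    rng = np.random.default_rng(np.random.SeedSequence(sim.seed, spawn_key=(7001,)))
    erk_linked = sorted(calls.partition.erk_only | calls.partition.shared_either)
    cycle = list(PathwayPosition)
    planted = {g: cycle[i % 3] for i, g in enumerate(erk_linked)}
    poa_rows = []
    if planted:
        panel = simulate_biochem_panel(planted, rng)
        recovered = recover_points_of_action(panel)
        poa_rows = [
            {
                "gene_id": g,
                "planted_position": planted[g].value,
                "position": recovered[g].position.value,
            }
            for g in erk_linked
        ]
    pd.DataFrame(
        poa_rows, columns=["gene_id", "planted_position", "position"]
    ).to_csv(out / "point_of_action.csv", index=False)

    metrics = recovery_metrics(calls, truth)
    result = {
        "n_genes": sim.n_genes,
        "n_plates": len(screen.layouts),
        "n_primary_up": sum(
            d.status is HitStatus.POSITIVE_UP for d in calls.primary.values()
        ),
        "n_primary_down": sum(
            d.status is HitStatus.POSITIVE_DOWN for d in calls.primary.values()
        ),
        "n_validated": len(calls.validated),
        "n_eliminated": len(calls.eliminated),
        "n_retained": len(calls.retained),
        "partition_counts": calls.partition.sizes(),
        "recovery": metrics,
    }
    (out / "run_summary.json").write_text(json.dumps(result, indent=2))

    manifest = {
        "software_version": __version__,
        "seed": sim.seed,
        "config": {
            "simulation": {
                **{
                    k: v
                    for k, v in sim.__dict__.items()
                    if not isinstance(v, (dict, tuple)) or k == "defective_event_range"
                },
                "gfp_mixture": sim.gfp_mixture.__dict__,
                "class_fractions": dict(sim.class_fractions),
                "class_magnitudes": dict(sim.class_magnitudes),
            },
            "gates": {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in config.gates.__dict__.items()
            },
            "thresholds": config.thresholds.as_dict(),
            "arms": list(config.arms),
        },
        "outputs": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".json") and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline complete: %s", json.dumps({k: v for k, v in result.items() if k != "recovery"}, default=str))
    return result
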
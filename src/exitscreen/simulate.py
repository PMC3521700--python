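"""Synthetic genome-scale RNAi screen generator.

Emulates the cytometry readout of a destabilised-GFP pluripotency-reporter
screen: mouse ES cells held in the naive state by two kinase inhibitors (a MEK
inhibitor and a GSK3 inhibitor, "2i") are released from self-renewal by
inhibitor withdrawal, and each 96-well plate of siRNA knockdowns is read out
by flow cytometry as a bimodal GFP intensity distribution.  The fraction of
cells that have converted to the GFP-low (differentiated) state at harvest is
the simulated phenotype; per-gene knockdown effects act as shifts on the logit
of that conversion fraction, so a gene required for exit from pluripotency has
a negative shift (cells retained in the GFP-high state).

Six screen arms are modelled: the primary and two validation screens with both
inhibitors withdrawn (-2i), a counter screen with both inhibitors still
present (+2i) that exposes reporter-stabilising artifacts such as proteasome
knockdowns, and two single-withdrawal ("1i") screens that attribute each hit
to the ERK pathway, the GSK3 pathway, either, or both.

Every well draws from its own random substream keyed by
``(seed, arm, replicate, plate, well)``, so any single well can be regenerated
without simulating the rest of the screen and iteration order is irrelevant.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cytometry import EventTable
from .errors import InvalidConfigError, MissingArmError

MEKI = "MEKi"
GSKI = "GSKi"

#: Canonical arm order; index is part of every RNG substream key.
ARM_NAMES = (
    "primary_minus2i",
    "validation_rex1_minus2i",
    "validation_oct4_minus2i",
    "counter_plus2i",
    "oneI_minusMEKi",
    "oneI_minusGSKi",
)

EFFECT_CLASSES = (
    "null",
    "delay_exit",
    "accelerate_exit",
    "proteasome_artifact",
    "erk_specific",
    "gsk_specific",
    "shared",
    "both_required",
)

ROLE_SAMPLE = "sample"
ROLE_NT = "nt_control"
ROLE_GSK3B = "gsk3b_control"
ROLE_FGF4 = "fgf4_control"

_ROWS = "ABCDEFGH"


@dataclass(frozen=True)
class ScreenArm:
    """One arm of the screen: an inhibitor condition and a harvest time.

    ``baseline_low_fraction`` is the probability that a cell transfected with
    a null siRNA has converted to the GFP-low state by harvest.  The -2i arms
    are harvested when control wells sit near 50/50 (the anchoring condition
    of the assay); the +2i counter arm barely converts at all; the 1i arms
    convert with delayed kinetics because one inhibitor remains.
    """

    name: str
    harvest_time_hr: float
    inhibitors_present: frozenset[str]
    baseline_low_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_low_fraction <= 1.0:
            raise InvalidConfigError(
                f"baseline_low_fraction must be in [0,1], got {self.baseline_low_fraction}"
            )
        if self.harvest_time_hr <= 0:
            raise InvalidConfigError("harvest_time_hr must be positive")
        bad = self.inhibitors_present - {MEKI, GSKI}
        if bad:
            raise InvalidConfigError(f"unknown inhibitors: {sorted(bad)}")
        if self.name == "counter_plus2i":
            if self.inhibitors_present != {MEKI, GSKI}:
                raise InvalidConfigError("counter_plus2i must keep both inhibitors")
            if self.baseline_low_fraction > 0.1:
                raise InvalidConfigError(
                    "counter_plus2i baseline_low_fraction must be near 0"
                )

    @property
    def mek_withdrawn(self) -> bool:
        return MEKI not in self.inhibitors_present

    @property
    def gsk_withdrawn(self) -> bool:
        return GSKI not in self.inhibitors_present


def standard_arms() -> dict[str, ScreenArm]:
    """The six arms of the published screen design with default baselines.

    Rex1-reporter arms harvest at 28 h, the Oct4-reporter validation arm at
    72 h.  Baselines: 0.5 for the -2i arms (controls anchored at a high/low
    ratio of 1), 0.35 for the slower single-withdrawal arms, 0.02 for +2i.
    """
    both = frozenset()
    return {
        "primary_minus2i": ScreenArm("primary_minus2i", 28, both, 0.5),
        "validation_rex1_minus2i": ScreenArm("validation_rex1_minus2i", 28, both, 0.5),
        "validation_oct4_minus2i": ScreenArm("validation_oct4_minus2i", 72, both, 0.5),
        "counter_plus2i": ScreenArm(
            "counter_plus2i", 28, frozenset({MEKI, GSKI}), 0.05
        ),
        "oneI_minusMEKi": ScreenArm("oneI_minusMEKi", 28, frozenset({GSKI}), 0.35),
        "oneI_minusGSKi": ScreenArm("oneI_minusGSKi", 28, frozenset({MEKI}), 0.35),
    }


def _arm_applies(effect_class: str, arm: ScreenArm) -> bool:
    """Does this effect class shift the conversion fraction in this arm?"""
    any_withdrawn = arm.mek_withdrawn or arm.gsk_withdrawn
    both_withdrawn = arm.mek_withdrawn and arm.gsk_withdrawn
    return {
        "null": False,
        "delay_exit": any_withdrawn,
        "accelerate_exit": any_withdrawn,
        "proteasome_artifact": True,
        "erk_specific": arm.mek_withdrawn,
        "gsk_specific": arm.gsk_withdrawn,
        "shared": any_withdrawn,
        "both_required": both_withdrawn,
    }[effect_class]


@dataclass(frozen=True)
class GeneEffect:
    """Planted knockdown effect: a logit shift per screen arm.

    Negative shifts delay loss of GFP (more GFP-high cells at harvest);
    positive shifts accelerate it.
    """

    gene_id: str
    effect_class: str
    logit_shift_per_arm: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise InvalidConfigError(f"unknown effect class {self.effect_class!r}")

    @classmethod
    def from_class(
        cls,
        gene_id: str,
        effect_class: str,
        magnitude: float | Mapping[str, float],
        arms: Mapping[str, ScreenArm],
    ) -> "GeneEffect":
        """Build the per-arm shift map from an effect class and a magnitude.

        ``magnitude`` is the absolute logit displacement in the arms where the
        class acts — a single number, or a per-arm mapping with a ``default``
        key.  The sign convention (delay = negative) is applied here.
        """

        def mag_in(arm_name: str) -> float:
            if isinstance(magnitude, Mapping):
                m = magnitude.get(arm_name, magnitude.get("default", 0.0))
            else:
                m = magnitude
            if m < 0:
                raise InvalidConfigError("magnitude must be non-negative")
            return m

        sign = +1.0 if effect_class == "accelerate_exit" else -1.0
        shifts = {
            name: (sign * mag_in(name) if _arm_applies(effect_class, arm) else 0.0)
            for name, arm in arms.items()
        }
        return cls(gene_id, effect_class, shifts)

    def shift_in(self, arm_name: str) -> float:
        try:
            return self.logit_shift_per_arm[arm_name]
        except KeyError as exc:
            raise MissingArmError(f"no shift configured for arm {arm_name!r}") from exc


@dataclass(frozen=True)
class GfpMixture:
    """Log-normal GFP intensity components (log10 scale), >= 1 decade apart."""

    low_log10_mean: float = 2.0
    high_log10_mean: float = 3.3
    log10_sd: float = 0.25

    def __post_init__(self) -> None:
        if self.high_log10_mean - self.low_log10_mean < 1.0:
            raise InvalidConfigError(
                "GFP components must be separated by at least one decade"
            )
        if self.log10_sd <= 0:
            raise InvalidConfigError("log10_sd must be positive")


# Fractions of the gene panel planted with each non-null effect class.  The
# mix mirrors a genome-wide screen in which a few percent of genes are true
# positives and reporter-stabilising artifacts (proteasome subunits etc.) are
# common enough to need a counter screen.
DEFAULT_CLASS_FRACTIONS: dict[str, float] = {
    "delay_exit": 0.010,
    "accelerate_exit": 0.005,
    "proteasome_artifact": 0.050,
    "erk_specific": 0.0075,
    "gsk_specific": 0.0075,
    "shared": 0.0075,
    "both_required": 0.0075,
}

# Absolute logit displacement per class in the arms where the class acts.
# An entry may be a single magnitude or a per-arm mapping with a "default"
# key.  The proteasome artifact is stronger in the +2i arm: reporter-protein
# stabilisation is unopposed when no differentiation programme is running.
DEFAULT_CLASS_MAGNITUDES: dict[str, float | dict[str, float]] = {
    # calibrated so a delay-of-exit knockdown displaces the primary-screen
    # well statistic by >= 4 plate SDs despite the SD inflation caused by
    # the planted hit mix itself
    "delay_exit": 1.9,
    "accelerate_exit": 1.2,
    "proteasome_artifact": {"default": 1.0, "counter_plus2i": 1.5},
    "erk_specific": 1.6,
    "gsk_specific": 1.6,
    "shared": 1.6,
    "both_required": 1.6,
}


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int = 860
    wells_per_plate: int = 96
    events_per_well: int = 10_000
    n_replicate_plates: int = 2
    n_nt_controls: int = 8
    gfp_mixture: GfpMixture = field(default_factory=GfpMixture)
    dead_fraction: float = 0.05
    plate_effect_sd: float = 0.15
    well_noise_sd: float = 0.10
    defective_well_rate: float = 0.01
    defective_event_range: tuple[int, int] = (100, 800)
    control_magnitude: float = 2.0
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FRACTIONS)
    )
    class_magnitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MAGNITUDES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidConfigError("n_genes must be >= 1")
        if self.events_per_well < 1:
            raise InvalidConfigError("events_per_well must be >= 1")
        if self.n_replicate_plates < 1:
            raise InvalidConfigError("n_replicate_plates must be >= 1")
        for name in ("dead_fraction", "defective_well_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0,1], got {v}")
        if self.samples_per_plate < 1:
            raise InvalidConfigError(
                "plate layout leaves no sample wells: too many controls"
            )
        if sum(self.class_fractions.values()) > 1.0:
            raise InvalidConfigError("class fractions sum to more than 1")

    @property
    def n_control_wells(self) -> int:
        return self.n_nt_controls + 2  # + gsk3b + fgf4

    @property
    def samples_per_plate(self) -> int:
        return self.wells_per_plate - self.n_control_wells


def _well_names(wells_per_plate: int) -> list[str]:
    n_cols = wells_per_plate // len(_ROWS)
    return [f"{r}{c:02d}" for r in _ROWS for c in range(1, n_cols + 1)]


@dataclass(frozen=True)
class PlateLayout:
    """Assignment of genes and controls to the wells of one plate."""

    plate_index: int
    role_of: Mapping[str, str]  # well -> role
    gene_of: Mapping[str, str]  # well -> gene_id (samples only)

    @property
    def sample_wells(self) -> list[str]:
        return [w for w, r in self.role_of.items() if r == ROLE_SAMPLE]

    @property
    def control_wells(self) -> list[str]:
        return [w for w, r in self.role_of.items() if r != ROLE_SAMPLE]

    @property
    def nt_wells(self) -> list[str]:
        return [w for w, r in self.role_of.items() if r == ROLE_NT]


def control_positions(config: SimulationConfig) -> dict[str, str]:
    """Fixed control layout: gsk3b at A01, fgf4 at B01, non-targeting down
    column 12 (overflowing into column 11 for non-standard layouts)."""
    n_cols = config.wells_per_plate // len(_ROWS)
    positions = {"A01": ROLE_GSK3B, "B01": ROLE_FGF4}
    nt_slots = [f"{r}{c:02d}" for c in (n_cols, n_cols - 1) for r in _ROWS]
    for well in nt_slots[: config.n_nt_controls]:
        positions[well] = ROLE_NT
    return positions


def plan_plates(config: SimulationConfig) -> list[PlateLayout]:
    """Lay out genes row-major across plates, each with fixed control wells."""
    controls = control_positions(config)
    names = _well_names(config.wells_per_plate)
    sample_slots = [w for w in names if w not in controls]
    genes = [f"gene{i:05d}" for i in range(1, config.n_genes + 1)]
    n_plates = math.ceil(config.n_genes / len(sample_slots))
    layouts = []
    it = iter(genes)
    for p in range(n_plates):
        gene_of = {}
        role_of = dict(controls)
        for well in sample_slots:
            gene = next(it, None)
            if gene is None:
                break
            gene_of[well] = gene
            role_of[well] = ROLE_SAMPLE
        layouts.append(PlateLayout(p, role_of, gene_of))
    return layouts


@dataclass
class TruthTable:
    """Ground truth of a simulated screen, for recovery benchmarking."""

    effects: dict[str, GeneEffect]
    plate_effects: dict[tuple[str, int, int], float]  # (arm, replicate, plate)
    defective_wells: list[tuple[str, int, int, str]]  # (arm, replicate, plate, well)

    def genes_of_class(self, effect_class: str) -> set[str]:
        return {
            g
            for g, e in self.effects.items()
            if e.effect_class == effect_class and not g.startswith("ctrl:")
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene_id": g, "effect_class": e.effect_class, **{
                f"shift_{a}": s for a, s in e.logit_shift_per_arm.items()
            }}
            for g, e in sorted(self.effects.items())
        ]
        return pd.DataFrame(rows)


def assign_effects(
    config: SimulationConfig, arms: Mapping[str, ScreenArm]
) -> dict[str, GeneEffect]:
    """Deterministically assign effect classes to the gene panel.

    Class counts are ``round(fraction * n_genes)``; which genes get which
    class is decided by a seeded shuffle so plates carry a random mix.
    The built-in positive controls (gsk3b -> GSK3-pathway effect, fgf4 ->
    ERK-pathway effect, since FGF4 is the autocrine driver of ERK signalling)
    are included under ``ctrl:`` ids.
    """
    genes = [f"gene{i:05d}" for i in range(1, config.n_genes + 1)]
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(999,)))
    order = list(rng.permutation(genes))
    effects: dict[str, GeneEffect] = {}
    pos = 0
    for cls in EFFECT_CLASSES:
        if cls == "null":
            continue
        count = round(config.class_fractions.get(cls, 0.0) * config.n_genes)
        mag = config.class_magnitudes.get(cls, 0.0)
        for g in order[pos : pos + count]:
            effects[g] = GeneEffect.from_class(g, cls, mag, arms)
        pos += count
    for g in order[pos:]:
        effects[g] = GeneEffect.from_class(g, "null", 0.0, arms)
    effects["ctrl:gsk3b"] = GeneEffect.from_class(
        "ctrl:gsk3b", "gsk_specific", config.control_magnitude, arms
    )
    effects["ctrl:fgf4"] = GeneEffect.from_class(
        "ctrl:fgf4", "erk_specific", config.control_magnitude, arms
    )
    effects["ctrl:nt"] = GeneEffect.from_class("ctrl:nt", "null", 0.0, arms)
    return effects


_ROLE_GENE = {ROLE_NT: "ctrl:nt", ROLE_GSK3B: "ctrl:gsk3b", ROLE_FGF4: "ctrl:fgf4"}


def simulate_well(
    effect: GeneEffect,
    arm: ScreenArm,
    plate_shift: float,
    n_events: int,
    rng: np.random.Generator,
    config: SimulationConfig,
    well: str = "",
) -> EventTable:
    """Draw one well of cytometry events.

    Each event independently: a dead flag ~ Bernoulli(dead_fraction); forward
    and side scatter from truncated Gaussians; a GFP intensity drawn from the
    low log-normal component with probability
    ``logistic(logit(baseline) + shift + plate_shift)`` and from the high
    component otherwise; and a viability-dye intensity whose distribution
    depends on the dead flag.
    """
    if n_events < 1:
        raise InvalidConfigError("n_events must be >= 1")
    shift = effect.shift_in(arm.name)
    p_low = float(expit(logit(arm.baseline_low_fraction) + shift + plate_shift))

    dead = rng.random(n_events) < config.dead_fraction
    is_low = rng.random(n_events) < p_low
    mix = config.gfp_mixture
    log10_gfp = rng.normal(
        np.where(is_low, mix.low_log10_mean, mix.high_log10_mean), mix.log10_sd
    )
    gfp = np.power(10.0, log10_gfp)
    fsc = np.clip(rng.normal(50_000, 8_000, n_events), 1.0, None)
    ssc = np.clip(rng.normal(30_000, 6_000, n_events), 1.0, None)
    viability = np.power(
        10.0, rng.normal(np.where(dead, 3.7, 2.3), 0.15)
    )
    return EventTable(well=well, fsc=fsc, ssc=ssc, gfp=gfp, viability=viability)


class SimulatedScreen:
    """Lazy handle on a simulated screen dataset.

    Event tables are regenerated on demand from per-well substreams, so a
    genome-scale screen never has to be held in memory at once.
    """

    def __init__(
        self,
        config: SimulationConfig,
        arms: Mapping[str, ScreenArm],
        layouts: list[PlateLayout],
        truth: TruthTable,
    ):
        self.config = config
        self.arms = dict(arms)
        self.layouts = layouts
        self.truth = truth
        self._arm_index = {name: ARM_NAMES.index(name) for name in self.arms}
        self._well_index = {
            w: i for i, w in enumerate(_well_names(config.wells_per_plate))
        }

    # -- substream plumbing -------------------------------------------------
    def _well_rng(self, arm: str, rep: int, plate: int, well: str) -> np.random.Generator:
        widx = self._well_index[well]
        seq = np.random.SeedSequence(
            self.config.seed, spawn_key=(self._arm_index[arm], rep, plate, widx)
        )
        return np.random.default_rng(seq)

    def _well_fate(
        self, rng: np.random.Generator
    ) -> tuple[bool, int]:
        """First draws of a well substream: (defective?, event count)."""
        cfg = self.config
        defective = rng.random() < cfg.defective_well_rate
        if defective:
            lo, hi = cfg.defective_event_range
            return True, int(rng.integers(lo, hi + 1))
        return False, cfg.events_per_well

    def gene_at(self, plate: int, well: str) -> str:
        layout = self.layouts[plate]
        role = layout.role_of.get(well)
        if role == ROLE_SAMPLE:
            return layout.gene_of[well]
        return _ROLE_GENE[role]

    def well_events(self, arm: str, rep: int, plate: int, well: str) -> EventTable:
        if arm not in self.arms:
            raise MissingArmError(f"arm {arm!r} not simulated")
        rng = self._well_rng(arm, rep, plate, well)
        _, n_events = self._well_fate(rng)
        well_noise = rng.normal(0.0, self.config.well_noise_sd)
        plate_shift = self.truth.plate_effects[(arm, rep, plate)] + well_noise
        effect = self.truth.effects[self.gene_at(plate, well)]
        return simulate_well(
            effect, self.arms[arm], plate_shift, n_events, rng, self.config, well=well
        )

    def iter_plate_wells(
        self, arm: str, rep: int, plate: int
    ) -> Iterator[tuple[str, str, str, EventTable]]:
        """Yield (well, role, gene_id, events) for one physical plate."""
        layout = self.layouts[plate]
        for well in sorted(layout.role_of):
            role = layout.role_of[well]
            yield well, role, self.gene_at(plate, well), self.well_events(
                arm, rep, plate, well
            )

    def plate_keys(self) -> list[tuple[str, int, int]]:
        return [
            (arm, rep, plate)
            for arm in self.arms
            for rep in range(self.config.n_replicate_plates)
            for plate in range(len(self.layouts))
        ]

    def materialize(self) -> dict[tuple[str, int, int], dict[str, pd.DataFrame]]:
        """Full in-memory dataset; only for small configurations."""
        return {
            key: {w: ev for w, _, _, ev in self.iter_plate_wells(*key)}
            for key in self.plate_keys()
        }

    # -- exports ------------------------------------------------------------
    def plate_map_frame(self) -> pd.DataFrame:
        rows = []
        for layout in self.layouts:
            for well in sorted(layout.role_of):
                rows.append(
                    {
                        "plate": layout.plate_index,
                        "well": well,
                        "gene_id": self.gene_at(layout.plate_index, well),
                        "role": layout.role_of[well],
                    }
                )
        return pd.DataFrame(rows)

    def write_csv(self, outdir: str | Path) -> None:
        """Export plate map, truth table, and per-plate event CSVs."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.plate_map_frame().to_csv(out / "plate_map.csv", index=False)
        self.truth.to_frame().to_csv(out / "truth_table.csv", index=False)
        for arm, rep, plate in self.plate_keys():
            frames = []
            for well, _, _, events in self.iter_plate_wells(arm, rep, plate):
                frame = events.to_frame()
                frame.insert(0, "well", well)
                frames.append(frame)
            pd.concat(frames).to_csv(
                out / f"events_{arm}_r{rep}_p{plate:03d}.csv", index=False
            )


def simulate_screen(
    config: SimulationConfig,
    arms: Mapping[str, ScreenArm] | list[str] | None = None,
) -> tuple[SimulatedScreen, TruthTable]:
    """Simulate a multi-arm screen; returns a lazy dataset and its truth table.

    ``arms`` may be a mapping of configured :class:`ScreenArm` objects or a
    list of standard arm names; by default all six standard arms are run.
    """
    std = standard_arms()
    if arms is None:
        arm_map = std
    elif isinstance(arms, Mapping):
        arm_map = dict(arms)
    else:
        try:
            arm_map = {name: std[name] for name in arms}
        except KeyError as exc:
            raise MissingArmError(f"unknown standard arm {exc}") from exc
    for name in arm_map:
        if name not in ARM_NAMES:
            raise MissingArmError(f"arm {name!r} has no substream index")

    layouts = plan_plates(config)
    effects = assign_effects(config, arm_map)

    plate_effects: dict[tuple[str, int, int], float] = {}
    for arm in arm_map:
        aidx = ARM_NAMES.index(arm)
        for rep, plate in itertools.product(
            range(config.n_replicate_plates), range(len(layouts))
        ):
            seq = np.random.SeedSequence(config.seed, spawn_key=(aidx, rep, plate))
            plate_effects[(arm, rep, plate)] = float(
                np.random.default_rng(seq).normal(0.0, config.plate_effect_sd)
            )

    truth = TruthTable(effects=effects, plate_effects=plate_effects, defective_wells=[])
    screen = SimulatedScreen(config, arm_map, layouts, truth)

    # Defect flags are the first draw of each well substream, so they can be
    # enumerated cheaply without generating events.
    for arm, rep, plate in screen.plate_keys():
        for well in sorted(layouts[plate].role_of):
            rng = screen._well_rng(arm, rep, plate, well)
            defective, _ = screen._well_fate(rng)
            if defective:
                truth.defective_wells.append((arm, rep, plate, well))

    return screen, truth
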
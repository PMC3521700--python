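"""Event-level flow-cytometry processing for reporter screens.

Implements the per-well readout of the assay: scatter gating to the intact
single-cell population, exclusion of dead cells on a viability dye channel
(Sytox-style far-red stain), a plate-wise GFP threshold anchored on the pooled
non-targeting control wells (so the control high/low ratio is 1 by
construction), and the per-well GFP high/low ratio statistic that all
downstream hit calling consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import fcsio
from .errors import (
    ChannelMappingError,
    InsufficientControlsError,
    InvalidConfigError,
)

#: Logical channels and the aliases accepted for each when reading files.
CHANNEL_ALIASES: dict[str, tuple[str, ...]] = {
    "fsc": ("fsc", "fsc-a", "fsc-h", "forward_scatter", "fs"),
    "ssc": ("ssc", "ssc-a", "ssc-h", "side_scatter", "ss"),
    "gfp": ("gfp", "fitc-a", "fitc", "gfp-a", "fl1-a", "green"),
    "viability": ("viability", "sytox", "sytox-red", "apc-a", "fl4-a", "red"),
}


@dataclass
class EventTable:
    """Per-cell events for one well: scatter, GFP, and viability-dye channels."""

    well: str
    fsc: np.ndarray
    ssc: np.ndarray
    gfp: np.ndarray
    viability: np.ndarray
    gated: bool = False

    def __post_init__(self) -> None:
        n = len(self.fsc)
        for name in ("fsc", "ssc", "gfp", "viability"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if len(arr) != n:
                raise InvalidConfigError("channel arrays must share one length")
            if arr.size and (not np.all(np.isfinite(arr)) or arr.min() < 0):
                raise InvalidConfigError(f"channel {name} has non-finite or negative values")

    @property
    def n_events(self) -> int:
        return len(self.gfp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fsc": self.fsc, "ssc": self.ssc, "gfp": self.gfp, "viability": self.viability}
        )

    @classmethod
    def from_frame(cls, well: str, frame: pd.DataFrame, gated: bool = False) -> "EventTable":
        cols = _resolve_channels(frame.columns)
        return cls(
            well=well,
            fsc=frame[cols["fsc"]].to_numpy(float),
            ssc=frame[cols["ssc"]].to_numpy(float),
            gfp=frame[cols["gfp"]].to_numpy(float),
            viability=frame[cols["viability"]].to_numpy(float),
            gated=gated,
        )


@dataclass(frozen=True)
class GateConfig:
    """Scatter and viability gates.

    ``scatter_quantiles`` defines a central quantile box per scatter channel,
    computed on the well's own events; absolute bounds override it when given.
    Events with viability dye above ``viability_threshold`` are dead.
    """

    scatter_quantiles: tuple[float, float] = (0.05, 0.95)
    fsc_bounds: tuple[float, float] | None = None
    ssc_bounds: tuple[float, float] | None = None
    viability_threshold: float = 1000.0
    min_gated_events: int = 1000

    def __post_init__(self) -> None:
        lo, hi = self.scatter_quantiles
        if not (0.0 <= lo < hi <= 1.0):
            raise InvalidConfigError("scatter quantiles must satisfy 0 <= lo < hi <= 1")
        if self.min_gated_events < 1:
            raise InvalidConfigError("min_gated_events must be >= 1")


@dataclass(frozen=True)
class WellSummary:
    """Gated counts and the GFP high/low ratio statistic for one well."""

    well: str
    n_total: int
    n_gated: int
    n_high: int
    n_low: int
    ratio_high_low: float
    log2_ratio: float
    defective: bool


def _resolve_channels(columns: Iterable[str]) -> dict[str, str]:
    lowered = {str(c).strip().lower(): str(c) for c in columns}
    mapping = {}
    for logical, aliases in CHANNEL_ALIASES.items():
        hit = next((lowered[a] for a in aliases if a in lowered), None)
        if hit is None:
            raise ChannelMappingError(
                f"no column for channel {logical!r} among {sorted(lowered)}"
            )
        mapping[logical] = hit
    return mapping


def read_events(
    path: str | Path,
    format: str = "csv",
    well: str | None = None,
) -> EventTable:
    """Read one well's events from a CSV event table or an FCS 3.0/3.1 file.

    Channel names are resolved through :data:`CHANNEL_ALIASES`; the well id
    defaults to the file stem (or the ``$WELLID`` keyword for FCS input).
    """
    path = Path(path)
    if format == "csv":
        frame = pd.read_csv(path)
        return EventTable.from_frame(well or path.stem, frame)
    if format == "fcs":
        channels, keywords = fcsio.read_fcs(path)
        cols = _resolve_channels(channels)
        wid = well or keywords.get("$WELLID") or path.stem
        return EventTable(
            well=wid,
            fsc=channels[cols["fsc"]],
            ssc=channels[cols["ssc"]],
            gfp=channels[cols["gfp"]],
            viability=channels[cols["viability"]],
        )
    raise InvalidConfigError(f"unknown event format {format!r}")


def write_events_fcs(path: str | Path, events: EventTable) -> None:
    """Write an EventTable as a minimal FCS 3.1 file (float32 channels)."""
    fcsio.write_fcs(
        path,
        {"FSC-A": events.fsc, "SSC-A": events.ssc, "FITC-A": events.gfp, "APC-A": events.viability},
        extra_keywords={"$WELLID": events.well},
    )


def apply_gates(events: EventTable, gates: GateConfig) -> EventTable:
    """Retain intact, live events: inside the scatter box and below the
    viability-dye threshold.

    Gating an already-gated table is the identity (gates are applied once).
    An empty result is returned with a warning; the well will be flagged
    defective at summary time.
    """
    if events.gated:
        return events
    if events.n_events == 0:
        raise InvalidConfigError("cannot gate an empty event table")

    keep = np.ones(events.n_events, dtype=bool)
    lo_q, hi_q = gates.scatter_quantiles
    for name, bounds in (("fsc", gates.fsc_bounds), ("ssc", gates.ssc_bounds)):
        values = getattr(events, name)
        if bounds is None:
            lo, hi = np.quantile(values, [lo_q, hi_q])
        else:
            lo, hi = bounds
        keep &= (values >= lo) & (values <= hi)
    keep &= events.viability <= gates.viability_threshold

    gated = EventTable(
        well=events.well,
        fsc=events.fsc[keep],
        ssc=events.ssc[keep],
        gfp=events.gfp[keep],
        viability=events.viability[keep],
        gated=True,
    )
    if gated.n_events == 0:
        warnings.warn(
            f"well {events.well}: all events removed by gating", stacklevel=2
        )
    return gated


def pool_events(tables: Sequence[EventTable]) -> EventTable:
    """Concatenate gated event tables (e.g. a plate's non-targeting wells)."""
    if not tables:
        raise InsufficientControlsError("no control wells to pool")
    return EventTable(
        well="pooled",
        fsc=np.concatenate([t.fsc for t in tables]),
        ssc=np.concatenate([t.ssc for t in tables]),
        gfp=np.concatenate([t.gfp for t in tables]),
        viability=np.concatenate([t.viability for t in tables]),
        gated=all(t.gated for t in tables),
    )


def control_gfp_threshold(control_events: EventTable, min_events: int = 100) -> float:
    """GFP threshold anchored on pooled non-targeting control events.

    The median splits the pooled controls 50/50, so the control high/low
    ratio is 1 by construction — the anchoring step that absorbs plate-to-
    plate variation in the timing of pluripotency loss.
    """
    if control_events.n_events < min_events:
        raise InsufficientControlsError(
            f"only {control_events.n_events} pooled control events (< {min_events})"
        )
    return float(np.median(control_events.gfp))


def summarize_well(
    events: EventTable,
    threshold: float,
    min_gated_events: int = 1000,
    pseudocount: float = 0.5,
    n_total: int | None = None,
) -> WellSummary:
    """Count GFP-high and GFP-low events against the plate threshold.

    Events exactly at the threshold count as low (deterministic tie-break,
    conservative toward GFP-high hit calls).  The ratio carries a pseudocount
    on both counts so wells with an empty side stay finite.
    """
    if not np.isfinite(threshold):
        raise InvalidConfigError("threshold must be finite")
    n_gated = events.n_events
    n_high = int(np.count_nonzero(events.gfp > threshold))
    n_low = n_gated - n_high
    ratio = (n_high + pseudocount) / (n_low + pseudocount)
    return WellSummary(
        well=events.well,
        n_total=n_total if n_total is not None else n_gated,
        n_gated=n_gated,
        n_high=n_high,
        n_low=n_low,
        ratio_high_low=ratio,
        log2_ratio=float(np.log2(ratio)),
        defective=n_gated < min_gated_events,
    )


def summaries_to_frame(rows: Iterable[tuple[Mapping, WellSummary]]) -> pd.DataFrame:
    """Flatten (metadata, WellSummary) pairs into the summary CSV schema."""
    records = []
    for meta, s in rows:
        records.append(
            {
                **meta,
                "well": s.well,
                "n_total": s.n_total,
                "n_gated": s.n_gated,
                "n_high": s.n_high,
                "n_low": s.n_low,
                "ratio_high_low": s.ratio_high_low,
                "log2_ratio": s.log2_ratio,
                "defective": s.defective,
            }
        )
    return pd.DataFrame(records)
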
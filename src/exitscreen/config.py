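"""Structured YAML configuration for pipeline runs.

Every hit-calling threshold is a named key with the published value as its
default; a config file only needs the keys it overrides.  Unknown keys are
violations, so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .cytometry import GateConfig
from .errors import InvalidConfigError
from .pipeline import PipelineConfig
from .screen_stats import HitThresholds
from .simulate import ARM_NAMES, GfpMixture, SimulationConfig


def _known_keys(cls) -> set[str]:
    return {f.name for f in fields(cls)}


def _build(cls, data: dict, violations: list[str], prefix: str):
    known = _known_keys(cls)
    for key in data:
        if key not in known:
            violations.append(f"{prefix}{key}: unknown key")
    kwargs = {k: v for k, v in data.items() if k in known}
    if cls is SimulationConfig and isinstance(kwargs.get("gfp_mixture"), dict):
        kwargs["gfp_mixture"] = GfpMixture(**kwargs["gfp_mixture"])
    for tuple_key in ("defective_event_range", "scatter_quantiles", "fsc_bounds", "ssc_bounds"):
        if isinstance(kwargs.get(tuple_key), list):
            kwargs[tuple_key] = tuple(kwargs[tuple_key])
    try:
        return cls(**kwargs)
    except (InvalidConfigError, TypeError, ValueError) as exc:
        violations.append(f"{prefix}{exc}")
        return cls()


def load_config(path: str | Path | None) -> tuple[PipelineConfig, list[str]]:
    """Parse a YAML config; return the pipeline config and any violations.

    A missing or empty file yields the full default configuration.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        parsed = yaml.safe_load(text)
        if parsed is None:
            parsed = {}
        if not isinstance(parsed, dict):
            raise InvalidConfigError(f"{path}: top level must be a mapping")
        data = parsed

    violations: list[str] = []
    top_known = {"simulation", "gates", "thresholds", "arms", "seed"}
    for key in data:
        if key not in top_known:
            violations.append(f"{key}: unknown key")

    sim_data = dict(data.get("simulation") or {})
    if "seed" in data:
        sim_data.setdefault("seed", int(data["seed"]))
    sim = _build(SimulationConfig, sim_data, violations, "simulation.")
    gates = _build(GateConfig, dict(data.get("gates") or {}), violations, "gates.")
    thresholds = _build(
        HitThresholds, dict(data.get("thresholds") or {}), violations, "thresholds."
    )

    arms = tuple(data.get("arms") or ARM_NAMES)
    for arm in arms:
        if arm not in ARM_NAMES:
            violations.append(f"arms: unknown arm {arm!r}")

    return PipelineConfig(simulation=sim, gates=gates, thresholds=thresholds, arms=arms), violations


def validate_config(path: str | Path | None) -> list[str]:
    """Return the list of violations for a config file (empty = valid)."""
    try:
        _, violations = load_config(path)
    except yaml.YAMLError as exc:
        return [f"parse error: {exc}"]
    return violations
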
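"""Run configuration: YAML loading, parameter overrides, provenance logging.

A run configuration ties together input paths, the column mapping used to
adapt external CSV headers to the canonical schema, overrides of the
isotope-system defaults, Monte-Carlo settings and output locations.  Every
parameter default and override is logged so the provenance of a run is
auditable from its log alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .params import McConfig, ParameterSet

log = logging.getLogger("otofmr")


@dataclass
class RunConfig:
    """Validated configuration for the pipeline commands."""

    records_path: str | None = None
    column_map: dict = field(default_factory=dict)
    parameter_overrides: dict = field(default_factory=dict)
    mc: McConfig = field(default_factory=McConfig)
    age_groups: list | None = None
    unknown_origin_water: float | None = None
    output_dir: str = "."
    log_level: str = "INFO"

    def parameter_set(self) -> ParameterSet:
        ps = ParameterSet().with_overrides(**self.parameter_overrides)
        return ps


def load_config(path) -> RunConfig:
    """Load a YAML run configuration, type-checking overrides against defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    mc_raw = raw.pop("mc", {}) or {}
    known_mc = {f.name for f in dataclasses.fields(McConfig)}
    bad = set(mc_raw) - known_mc
    if bad:
        raise ValueError(f"unknown mc config keys: {sorted(bad)}")
    mc = McConfig(**mc_raw)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    cfg = RunConfig(mc=mc, **raw)
    # overrides are validated (names and types) eagerly
    cfg.parameter_set()
    return cfg


def log_provenance(cfg: RunConfig) -> None:
    """Log every parameter central value and width, marking overrides."""
    ps = cfg.parameter_set()
    defaults = ParameterSet()
    for group_name, obj, ref in (
        ("thermometry", ps.thermometry, defaults.thermometry),
        ("carbon", ps.carbon, defaults.carbon),
    ):
        for f in dataclasses.fields(obj):
            val = getattr(obj, f.name)
            dflt = getattr(ref, f.name)
            tag = " (override)" if val != dflt else ""
            log.info("param %s.%s = %s%s", group_name, f.name, val, tag)
    log.info(
        "mc n_replicates=%d seed=%d ci_level=%s width_to_sd=%s",
        cfg.mc.n_replicates,
        cfg.mc.seed,
        cfg.mc.ci_level,
        cfg.mc.width_to_sd,
    )


def ensure_outdir(cfg: RunConfig) -> Path:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out
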
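"""Run configuration: presets, YAML loading, validation.

A ``RunConfig`` fully resolves one simulation/sweep/fit invocation.  The three
named presets are immutable:

* ``neutral_60_10`` — both species fecundity 60/10, all alphas 1.0.
* ``non_neutral_60_10`` — same fecundities, stabilized hierarchy alphas.
* ``vulpia_table1`` — the empirical *Vulpia* pair with environment-specific
  parameters, k = 0.5, T = 500, 100 replicates; the scenario strategy applies
  to species j.

Unknown keys are rejected so typos fail loudly rather than silently falling
back to defaults.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import CompetitionMatrix
from .errors import ConfigError
from .experiments import DEFAULT_K_GRID, SweepConfig
from .maternal_effects import STRATEGY_NAMES, SpeciesParams, strategy
from .presets import (
    NEUTRAL_ALPHA,
    NON_NEUTRAL_ALPHA,
    PRESET_NAMES,
    VULPIA_ALPHA,
    VULPIA_I,
    VULPIA_J,
    species_60_10,
)

__all__ = ["RunConfig", "load_config", "PRESET_NAMES"]


@dataclass(frozen=True)
class RunConfig:
    """A fully resolved run: species, competition, environment and bookkeeping."""

    preset: str = "neutral_60_10"
    strategy_i: str = "none"
    strategy_j: str = "none"
    s: float = 1.25
    k: float = 0.5
    k_grid: tuple = DEFAULT_K_GRID
    T: int = 500
    replicates: int = 500
    extinction_threshold: float = 1.0
    p_init: float = 0.5
    intro_time: int = 2
    intro_abundance: float = 2.0
    base_seed: int = 0
    outdir: str = "."

    def __post_init__(self) -> None:
        if self.preset not in PRESET_NAMES:
            raise ConfigError(f"preset: unknown preset {self.preset!r}; choose from {PRESET_NAMES}")
        for name in ("strategy_i", "strategy_j"):
            if getattr(self, name) not in STRATEGY_NAMES:
                raise ConfigError(f"{name}: must be one of {STRATEGY_NAMES}")
        for name in ("k", "p_init"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and 0 <= v <= 1):
                raise ConfigError(f"{name}: must be a probability in [0, 1], got {v!r}")
        for kk in self.k_grid:
            if not (math.isfinite(kk) and 0 <= kk <= 1):
                raise ConfigError(f"k_grid: entry {kk!r} is not a probability")
        if self.T < self.intro_time + 1:
            raise ConfigError("T: horizon must exceed intro_time")
        if self.intro_time < 2:
            raise ConfigError("intro_time: must be >= 2 (a maternal environment must exist)")
        if self.replicates < 1:
            raise ConfigError("replicates: must be >= 1")
        if self.s <= 0 or not math.isfinite(self.s):
            raise ConfigError("s: trait multiplier must be positive and finite")
        if self.extinction_threshold < 0:
            raise ConfigError("extinction_threshold: must be >= 0")
        if self.intro_abundance <= 0:
            raise ConfigError("intro_abundance: must be positive")

    # -- resolution helpers -------------------------------------------------

    def species(self) -> tuple[SpeciesParams, SpeciesParams]:
        si, sj = strategy(self.strategy_i, self.s), strategy(self.strategy_j, self.s)
        if self.preset == "vulpia_table1":
            return VULPIA_I.with_strategy(si), VULPIA_J.with_strategy(sj)
        return species_60_10("i", si), species_60_10("j", sj)

    def alphas(self) -> CompetitionMatrix:
        return {
            "neutral_60_10": NEUTRAL_ALPHA,
            "non_neutral_60_10": NON_NEUTRAL_ALPHA,
            "vulpia_table1": VULPIA_ALPHA,
        }[self.preset]

    def sweep_config(self) -> SweepConfig:
        species_i, species_j = self.species()
        return SweepConfig(
            species_i=species_i,
            species_j=species_j,
            alphas=self.alphas(),
            k_grid=tuple(self.k_grid),
            replicates=self.replicates,
            T=self.T,
            base_seed=self.base_seed,
            p_init=self.p_init,
            intro_time=self.intro_time,
            intro_abundance=self.intro_abundance,
            extinction_threshold=self.extinction_threshold,
        )

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["k_grid"] = list(self.k_grid)
        return d


_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}

_PRESET_OVERRIDES = {
    "neutral_60_10": {},
    "non_neutral_60_10": {},
    "vulpia_table1": {"k": 0.5, "T": 500, "replicates": 100},
}


def load_config(path=None, **overrides) -> RunConfig:
    """Build a validated RunConfig from a YAML file and/or keyword overrides.

    The file (if given) is a flat mapping of RunConfig fields; explicit
    keyword overrides win over file values, which win over preset defaults.
    Unknown keys raise ``ConfigError``.
    """
    values: dict = {}
    if path is not None:
        with open(Path(path)) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(values) - _FIELDS
    if unknown:
        raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")

    preset = values.get("preset", "neutral_60_10")
    merged = dict(_PRESET_OVERRIDES.get(preset, {}))
    merged.update(values)
    if "k_grid" in merged:
        merged["k_grid"] = tuple(merged["k_grid"])
    return RunConfig(**merged)
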
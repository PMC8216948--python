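"""Replicated competition experiments across autocorrelation levels.

Each replicate draws an independent environment sequence (seeded as
``base_seed + replicate``), simulates the pair, and classifies the outcome by
which species remain at the end.  A sweep repeats this across a grid of
persistence probabilities k, and a pairing grid repeats the sweep across
strategy pairings.  Proportions are exact multinomial fractions of the
replicate count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dynamics import OUTCOMES, CompetitionMatrix, classify_outcome, simulate
from .environment import generate_environment, _check_probability
from .errors import ParameterError
from .maternal_effects import MaternalStrategy, SpeciesParams, none, strategy
from .presets import species_60_10

__all__ = ["SweepConfig", "run_replicates", "k_sweep", "pairing_grid", "tidy_outcomes"]

DEFAULT_K_GRID = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))


@dataclass(frozen=True)
class SweepConfig:
    """Settings shared by every replicate of a sweep."""

    species_i: SpeciesParams = field(default_factory=lambda: species_60_10("i"))
    species_j: SpeciesParams = field(default_factory=lambda: species_60_10("j"))
    alphas: CompetitionMatrix = field(default_factory=CompetitionMatrix.neutral)
    k_grid: tuple = DEFAULT_K_GRID
    replicates: int = 500
    T: int = 500
    base_seed: int = 0
    p_init: float = 0.5
    intro_time: int = 2
    intro_abundance: float = 2.0
    extinction_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        for k in self.k_grid:
            _check_probability("k", k)

    def with_strategies(self, strat_i: MaternalStrategy, strat_j: MaternalStrategy) -> "SweepConfig":
        return replace(
            self,
            species_i=self.species_i.with_strategy(strat_i),
            species_j=self.species_j.with_strategy(strat_j),
        )


def run_replicates(config: SweepConfig, k: float) -> dict:
    """Run ``config.replicates`` independent simulations at one k.

    Returns a dict with the outcome proportions (exact fractions of the
    replicate count), the pairing label, and the replicate count.
    """
    k = _check_probability("k", k)
    counts = dict.fromkeys(OUTCOMES, 0)
    for rep in range(config.replicates):
        env = generate_environment(config.T, k, config.p_init, seed=config.base_seed + rep)
        traj = simulate(
            config.species_i,
            config.species_j,
            config.alphas,
            env,
            intro_time=config.intro_time,
            intro_abundance=config.intro_abundance,
            extinction_threshold=config.extinction_threshold,
        )
        counts[classify_outcome(traj)] += 1
    n = config.replicates
    row = {"k": k, "pairing": _pairing_label(config)}
    row.update({o: counts[o] / n for o in OUTCOMES})
    row["n_replicates"] = n
    return row


def k_sweep(config: SweepConfig) -> pd.DataFrame:
    """One outcome-proportion row per k in ``config.k_grid``."""
    return pd.DataFrame([run_replicates(config, k) for k in config.k_grid])


def pairing_grid(
    config: SweepConfig,
    strategies: tuple[str, ...] = ("none", "silver_spoon", "matching"),
    s: float = 1.25,
    ordered: bool | None = None,
) -> pd.DataFrame:
    """Run a k-sweep for every strategy pairing.

    With role-symmetric parameters (identical species, symmetric alphas) the
    six unordered pairings suffice; otherwise species roles matter and all
    ordered assignments are enumerated.  ``ordered=None`` chooses
    automatically.
    """
    if ordered is None:
        ordered = not _roles_symmetric(config)
    combos = (
        itertools.product(strategies, repeat=2)
        if ordered
        else itertools.combinations_with_replacement(strategies, 2)
    )
    frames = []
    for name_i, name_j in combos:
        cfg = config.with_strategies(strategy(name_i, s), strategy(name_j, s))
        frames.append(k_sweep(cfg))
    return pd.concat(frames, ignore_index=True)


def tidy_outcomes(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format (k, pairing, outcome, proportion, n_replicates) view."""
    return table.melt(
        id_vars=["k", "pairing", "n_replicates"],
        value_vars=list(OUTCOMES),
        var_name="outcome",
        value_name="proportion",
    )[["k", "pairing", "outcome", "proportion", "n_replicates"]]


def _pairing_label(config: SweepConfig) -> str:
    return f"{config.species_i.strategy.name}_vs_{config.species_j.strategy.name}"


def _roles_symmetric(config: SweepConfig) -> bool:
    a = config.alphas
    same_alpha = a.aii == a.ajj and a.aij == a.aji
    si, sj = config.species_i, config.species_j
    same_species = (si.lambda_good, si.lambda_bad) == (sj.lambda_good, sj.lambda_bad)
    return same_alpha and same_species
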
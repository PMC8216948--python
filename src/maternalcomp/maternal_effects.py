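"""Maternal-effect reaction norms and realized fecundity.

A maternal environmental effect makes an offspring's demographic performance
depend on the environment its mother experienced, not only on its own.  Here
the effect acts multiplicatively on fecundity:

    lambda_i(t) = lambda_(i,o) * s ** M(m, o)

where ``lambda_(i,o)`` is the species' baseline fecundity in the offspring
environment ``o`` (the current year), ``s`` is the phenotypic effect size, and
the exponent ``M(m, o)`` encodes the reaction norm over maternal environment
``m`` (previous year) and offspring environment ``o``:

* ``none`` — M = 0 everywhere; the past has no effect.
* ``silver_spoon`` — offspring of good-year mothers are enhanced in every
  environment (M = +1 when m is good, -1 when m is bad).
* ``matching`` — offspring do best when their environment matches their
  mother's (M = +1 when m == o, -1 otherwise; crossing reaction norms).

The default effect size ``s = 1.25`` is a 25% enhancement whose exact inverse
(0.8) is a 20% reduction, so benefit and penalty multipliers are reciprocal
and a matched enhancement/penalty pair cancels geometrically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from .environment import BAD, GOOD, Env
from .errors import ParameterError

__all__ = [
    "MaternalStrategy",
    "SpeciesParams",
    "none",
    "silver_spoon",
    "matching",
    "strategy",
    "STRATEGY_NAMES",
    "maternal_multiplier",
    "realized_fecundity",
]

_CELLS = ((GOOD, GOOD), (GOOD, BAD), (BAD, GOOD), (BAD, BAD))


@dataclass(frozen=True)
class MaternalStrategy:
    """A reaction norm: effect size ``s`` plus exponent table ``M``.

    ``M`` maps (maternal env, offspring env) to an exponent, conventionally in
    {-1, 0, +1}; arbitrary real exponents are accepted for user-defined norms.
    """

    name: str
    s: float = 1.25
    M: Mapping[tuple[Env, Env], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.s) and self.s > 0):
            raise ParameterError(f"trait multiplier s must be positive and finite, got {self.s!r}")
        table = dict(self.M)
        missing = [c for c in _CELLS if c not in table]
        if missing:
            raise ParameterError(f"M table missing cells: {missing}")
        object.__setattr__(self, "M", table)

    def multiplier(self, env_m: Env, env_o: Env) -> float:
        """The fecundity factor ``s ** M(m, o)``; exactly 1 when M = 0."""
        m = self.M[(Env(env_m), Env(env_o))]
        if m == 0:
            return 1.0
        return self.s ** m


def none() -> MaternalStrategy:
    """No maternal effect: fecundity depends on the current year only."""
    return MaternalStrategy("none", s=1.25, M={c: 0 for c in _CELLS})


def silver_spoon(s: float = 1.25) -> MaternalStrategy:
    """Good maternal years enhance offspring everywhere; bad ones penalize."""
    return MaternalStrategy(
        "silver_spoon",
        s=s,
        M={(GOOD, GOOD): 1, (GOOD, BAD): 1, (BAD, GOOD): -1, (BAD, BAD): -1},
    )


def matching(s: float = 1.25) -> MaternalStrategy:
    """Anticipatory effect: offspring are enhanced when their environment
    matches the maternal one and penalized when it does not."""
    return MaternalStrategy(
        "matching",
        s=s,
        M={(GOOD, GOOD): 1, (BAD, BAD): 1, (GOOD, BAD): -1, (BAD, GOOD): -1},
    )


STRATEGY_NAMES = ("none", "silver_spoon", "matching")


def strategy(name: str, s: float = 1.25) -> MaternalStrategy:
    """Look up one of the named preset strategies."""
    factories = {"none": none, "silver_spoon": silver_spoon, "matching": matching}
    try:
        factory = factories[name]
    except KeyError:
        raise ParameterError(f"unknown strategy {name!r}; choose from {STRATEGY_NAMES}") from None
    return none() if name == "none" else factory(s)


@dataclass(frozen=True)
class SpeciesParams:
    """Per-environment baseline fecundities plus a maternal-effect strategy.

    No ordering is enforced between the two fecundities: "good"/"bad" are
    nominal labels, and an empirically parameterized species may have its
    higher fecundity in the "bad" state.
    """

    label: str
    lambda_good: float
    lambda_bad: float
    strategy: MaternalStrategy = field(default_factory=none)

    def __post_init__(self) -> None:
        for nm, lam in (("lambda_good", self.lambda_good), ("lambda_bad", self.lambda_bad)):
            if not (math.isfinite(lam) and lam > 0):
                raise ParameterError(f"{nm} must be positive and finite, got {lam!r}")

    def baseline_fecundity(self, env_o: Env) -> float:
        return self.lambda_good if Env(env_o) is GOOD else self.lambda_bad

    def with_strategy(self, strat: MaternalStrategy) -> "SpeciesParams":
        return SpeciesParams(self.label, self.lambda_good, self.lambda_bad, strat)


def maternal_multiplier(strat: MaternalStrategy, env_m: Env, env_o: Env) -> float:
    """The factor ``s ** M(env_m, env_o)`` applied to baseline fecundity."""
    return strat.multiplier(env_m, env_o)


def realized_fecundity(species: SpeciesParams, env_m: Env, env_o: Env) -> float:
    """Fecundity after the maternal effect: ``lambda(i, o) * s ** M(m, o)``."""
    return species.baseline_fecundity(env_o) * species.strategy.multiplier(env_m, env_o)
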
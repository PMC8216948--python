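"""Binary good/bad environment sequences with Markovian persistence.

The environment in each generation is one of two nominal states, *good* or
*bad*.  Temporal structure is a two-state symmetric Markov chain controlled by
a single persistence probability ``k``: each year the environment remains in
its current state with probability ``k`` and switches with probability
``1 - k``.  ``k = 1`` gives constant conditions, ``k = 0`` strict alternation,
and ``k = 0.5`` an i.i.d. coin flip.  Because the chain is symmetric, the
long-run marginal frequency of good years is 0.5 for every ``k < 1``; only the
first state is a free draw (good with probability ``p_init``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import ParameterError

__all__ = [
    "Env",
    "GOOD",
    "BAD",
    "EnvSequence",
    "generate_environment",
    "stay_fraction",
]


class Env(str, Enum):
    """One of the two nominal environment states.

    "bad" conventionally denotes the environment in which a species has the
    lower baseline fecundity, but the mapping is per-experiment and purely
    nominal (e.g. the *Vulpia octoflora* parameterization has its higher
    fecundity in the "bad" state).
    """

    GOOD = "G"
    BAD = "B"

    def __invert__(self) -> "Env":
        return Env.BAD if self is Env.GOOD else Env.GOOD


GOOD = Env.GOOD
BAD = Env.BAD

#: integer codes used in the packed representation (1 = good, 0 = bad)
_CODE = {Env.GOOD: 1, Env.BAD: 0}
_FROM_CODE = {1: Env.GOOD, 0: Env.BAD}


def _check_probability(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


@dataclass(frozen=True)
class EnvSequence:
    """An ordered sequence of environment states plus its generating parameters.

    Parameters
    ----------
    states
        int8 array with 1 = good, 0 = bad, length ``T >= 2``.
    k
        Persistence probability used to generate the sequence.
    p_init
        Probability that the first state was drawn good.
    seed
        Seed of the generating RNG, or None for externally supplied sequences.
    """

    states: np.ndarray
    k: float
    p_init: float = 0.5
    seed: int | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.states, dtype=np.int8)
        if arr.ndim != 1 or arr.size < 2:
            raise ParameterError("an environment sequence needs length T >= 2")
        if not np.isin(arr, (0, 1)).all():
            raise ParameterError("environment states must be coded 0 (bad) or 1 (good)")
        object.__setattr__(self, "states", arr)
        _check_probability("k", self.k)
        _check_probability("p_init", self.p_init)

    def __len__(self) -> int:
        return int(self.states.size)

    def __getitem__(self, index: int) -> Env:
        return _FROM_CODE[int(self.states[index])]

    def __iter__(self):
        return (_FROM_CODE[int(c)] for c in self.states)

    def labels(self) -> np.ndarray:
        """Return the sequence as an array of 'G'/'B' single-character labels."""
        return np.where(self.states == 1, "G", "B")

    def signs(self) -> str:
        """Return the sequence as a '+'/'-' string (good = '+'), a compact
        annotation style for plots and logs."""
        return "".join("+" if c else "-" for c in self.states)

    @classmethod
    def from_labels(cls, labels, k: float = float("nan"), p_init: float = 0.5) -> "EnvSequence":
        """Build a sequence from 'G'/'B' labels (e.g. a CSV env column).

        ``k`` is unknown for external data; it is stored as given (NaN allowed
        only through this constructor, which bypasses the probability check by
        substituting the empirical stay fraction when k is not finite).
        """
        codes = np.asarray([1 if str(l).upper() in ("G", "+", "GOOD", "1") else 0 for l in labels], dtype=np.int8)
        if not math.isfinite(k):
            k = float((codes[1:] == codes[:-1]).mean()) if codes.size > 1 else 0.5
        return cls(states=codes, k=k, p_init=p_init)


def generate_environment(T: int, k: float, p_init: float = 0.5, seed: int | None = None) -> EnvSequence:
    """Draw a length-``T`` environment sequence from the symmetric Markov chain.

    The first state is good with probability ``p_init``; each subsequent state
    equals its predecessor with probability ``k`` and switches otherwise.
    Identical ``(T, k, p_init, seed)`` yield an identical sequence.
    """
    if not isinstance(T, (int, np.integer)) or T < 2:
        raise ParameterError(f"T must be an integer >= 2, got {T!r}")
    k = _check_probability("k", k)
    p_init = _check_probability("p_init", p_init)
    rng = np.random.default_rng(seed)
    first = 1 if rng.random() < p_init else 0
    switches = (rng.random(T - 1) >= k).astype(np.int8)
    # state_t = first XOR (number of switches so far, mod 2)
    states = np.empty(T, dtype=np.int8)
    states[0] = first
    states[1:] = (first + np.cumsum(switches)) % 2
    return EnvSequence(states=states, k=k, p_init=p_init, seed=seed)


def stay_fraction(env: EnvSequence) -> float:
    """Fraction of the T-1 transitions in which the environment did not switch.

    Converges to ``k`` as T grows; useful as a diagnostic of the generator.
    """
    states = np.asarray(env.states if isinstance(env, EnvSequence) else env, dtype=np.int8)
    if states.size < 2:
        raise ParameterError("stay_fraction needs a sequence of length >= 2")
    return float((states[1:] == states[:-1]).mean())
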
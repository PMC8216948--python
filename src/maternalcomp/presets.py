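"""Named, immutable parameter presets.

``neutral_60_10`` / ``non_neutral_60_10``
    The theoretical species pairs: identical baseline fecundities of 60
    (good year) and 10 (bad year) for both species, with either all
    competition coefficients equal to 1 (neutral) or a stabilized hierarchy
    (aii=1.25, ajj=1.0, aij=1.0, aji=0.8).

``vulpia_table1``
    The empirically parameterized annual grasses *Vulpia microstachys*
    (species i) and *V. octoflora* (species j), with environment-specific
    fecundities and competition coefficients measured under wet ("good") and
    dry ("bad") conditions.  Note that *V. octoflora*'s fecundity is higher in
    the nominal "bad" state: the labels are nominal.
"""

from __future__ import annotations

from .dynamics import CompetitionMatrix
from .maternal_effects import SpeciesParams, none

__all__ = [
    "species_60_10",
    "NEUTRAL_ALPHA",
    "NON_NEUTRAL_ALPHA",
    "VULPIA_I",
    "VULPIA_J",
    "VULPIA_ALPHA",
    "VULPIA_ACTUALS",
    "PRESET_NAMES",
]


def species_60_10(label: str, strategy=None) -> SpeciesParams:
    """A theoretical-scenario species: fecundity 60 in good years, 10 in bad."""
    return SpeciesParams(label, 60.0, 10.0, strategy if strategy is not None else none())


NEUTRAL_ALPHA = CompetitionMatrix.neutral()
NON_NEUTRAL_ALPHA = CompetitionMatrix.non_neutral()

# Empirical Vulpia pair: (good, bad) per coefficient.
VULPIA_I = SpeciesParams("Vulpia microstachys", 236.0, 153.0, none())
VULPIA_J = SpeciesParams("Vulpia octoflora", 924.0, 1127.0, none())
VULPIA_ALPHA = CompetitionMatrix(
    aii=(0.099, 0.082),
    aij=(0.083, 0.002),
    aji=(0.302, 0.574),
    ajj=(0.456, 0.515),
)

#: generating ("actual") parameter values per species, keyed the way the
#: estimation module reports them
VULPIA_ACTUALS = {
    "i": {
        "lambda_good": 236.0,
        "lambda_bad": 153.0,
        "alpha_self_good": 0.099,
        "alpha_self_bad": 0.082,
        "alpha_cross_good": 0.083,
        "alpha_cross_bad": 0.002,
    },
    "j": {
        "lambda_good": 924.0,
        "lambda_bad": 1127.0,
        "alpha_self_good": 0.456,
        "alpha_self_bad": 0.515,
        "alpha_cross_good": 0.302,
        "alpha_cross_bad": 0.574,
    },
}

PRESET_NAMES = ("neutral_60_10", "non_neutral_60_10", "vulpia_table1")
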
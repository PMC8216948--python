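# maternalcomp

Tools for asking how **maternal environmental effects** — carry-over of the
mother's environment into offspring performance — change the outcome of
**two-species competition** in temporally structured environments, and how
badly they bias demographic parameters estimated from observational time
series when they are ignored.

The package is aimed at population and community ecologists studying
transgenerational plasticity, temporal coexistence mechanisms, and time-series
parameter inference for annual plants and other organisms with discrete,
non-overlapping generations.

## Model

Two species compete through a discrete-time Beverton–Holt map,

```
N_i(t+1) = N_i(t) λ_i(t) / (1 + α_ii N_i(t) + α_ij N_j(t))
```

(and symmetrically for species *j*), in a binary good/bad environment that
follows a two-state symmetric Markov chain with persistence probability *k*
(*k* = 1: constant conditions; *k* = 0: strict alternation; *k* = 0.5:
i.i.d. years). Maternal effects enter through the fecundity term,

```
λ_i(t) = λ_(i,o) · s^M(m, o)
```

where `λ_(i,o)` is the baseline fecundity in the offspring-year environment
*o*, *s* is the phenotypic effect size (default 1.25, whose inverse is a 20%
penalty), and the exponent table `M(m, o)` over maternal (*m*) and offspring
(*o*) environments encodes the reaction norm:

* **none** — `M ≡ 0`; the past year is irrelevant;
* **silver spoon** — offspring of good-year mothers are enhanced everywhere
  (`M = +1` for *m* = good, `−1` for *m* = bad);
* **environmental matching** — offspring do best when their year matches
  their mother's (`M = +1` iff *m* = *o*, else `−1`).

On top of the simulator sit (i) replicated outcome sweeps across *k* and
strategy pairings, classifying each run as `only_i` / `only_j` / `both`, and
(ii) an estimation module that fits the *lag-free* model (environment-specific
λ and α per species, no maternal term) to simulated time series of an
empirically parameterized *Vulpia microstachys* / *V. octoflora* pair by
nonlinear least squares, quantifying the resulting parameter bias and loss of
explained variation. The fitter is a scikit-learn estimator
(`LagFreeBevertonHolt`), so it composes with sklearn tooling.

## Worked example

```python
from maternalcomp import (SweepConfig, run_replicates, run_estimation_experiment,
                          silver_spoon, none)
from maternalcomp.presets import NEUTRAL_ALPHA, species_60_10

# competitive outcomes: silver spoon vs no effect, constant environments (k=1)
config = SweepConfig(
    species_i=species_60_10("i", none()),
    species_j=species_60_10("j", silver_spoon()),
    alphas=NEUTRAL_ALPHA, replicates=500, T=500, base_seed=777,
)
row = run_replicates(config, k=1.0)
print(round(row["only_j"], 3), round(row["only_i"], 3))
# 0.524 0.476

# estimation bias when species j's silver spoon is omitted from the fit
res = run_estimation_experiment("silver_spoon", base_seed=7, replicates=100)
print(round(res.estimate("j", "alpha_self_good"), 3), round(res.r2("j"), 3))
# 0.258 0.873
```

The first pair of numbers says that with constant conditions the silver-spoon
species wins essentially the half of replicates whose environment is
constantly good (52.4% here, binomial noise around 1/2) and loses the
constantly-bad half — the maternal effect decides the winner even though the
species are otherwise identical. The second pair says that fitting the
memoryless model to data containing a silver-spoon effect underestimates
*V. octoflora*'s good-year intraspecific competition coefficient (0.258
vs the generating value 0.456) and explains only 87.3% of the variation in
next-generation abundances, even though the data are fully deterministic.

A command-line interface exposes the same workflows:

```bash
maternalcomp simulate --preset neutral_60_10 --strategy-j matching --k 0.5 --seed 7
maternalcomp sweep --preset neutral_60_10 --pairings all --replicates 500
maternalcomp fit trajectory.csv --focal both
maternalcomp table1 --seed 11
```

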
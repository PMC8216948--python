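# Methods

## Model and assumptions

Two annual-plant-like species compete through the discrete-time
Beverton–Holt map

    N_i(t+1) = N_i(t) λ_i(t) / (1 + α_ii N_i(t) + α_ij N_j(t)),

with the symmetric update for species j. Generations are discrete and
non-overlapping; there is no seed bank, so abundance counts germinated
individuals. The map is compensatory (no overcompensatory cycles), both
species are updated synchronously from the time-t state, and a zero abundance
is absorbing. Competition coefficients may take different values in good and
bad years (the empirical *Vulpia* parameterization does; the theoretical
presets do not).

Fecundity carries the maternal effect:

    λ_i(t) = λ_(i,o) · s^M(m, o),

where o is the environment of year t (the offspring year), m the environment
of year t−1 (the maternal year), s the phenotypic effect size and M an
exponent table over (m, o). Maternal effects reach back exactly one
generation — no grandparental accumulation — and act only on fecundity, not
on the competition coefficients. The three named reaction norms are `none`
(M ≡ 0), `silver_spoon` (M = +1 when m is good, −1 when m is bad) and
`matching` (M = +1 when m = o, else −1). Arbitrary user-defined M tables are
accepted; the presets are data, not code paths.

The environment is a two-state symmetric Markov chain: each year the state
persists with probability k and switches with probability 1 − k. Only the
first state is a free draw (good with probability `p_init`, default 0.5), so
the marginal frequency of good years is 0.5 for every k < 1. The chain is
the only source of randomness in the system; conditional on the environment
sequence, the dynamics are fully deterministic.

One structural note worth recording: with s an exact enhancement/penalty
inverse pair (s, s⁻¹), a silver-spoon species under strict alternation
realizes fecundities 48 and 12.5 (baseline 60/10), whose product 600 equals
the no-effect product 10 × 60 — the geometric mean growth rates are exactly
equalized, which is why alternating environments neutralize the silver
spoon's advantage.

## Parameters, units, defaults

| parameter | meaning | default | why |
|---|---|---|---|
| `lambda_good`, `lambda_bad` | baseline per-capita fecundity (offspring/individual) | 60 / 10 (theoretical pairs) | the canonical 6× good:bad contrast of the study conditions |
| `s` | maternal trait multiplier (dimensionless) | 1.25 (= 0.8⁻¹) | a moderate ±20–25% effect within the range reported for plants and animals; benefit and penalty exactly reciprocal |
| `k` | P(environment persists) | swept 0–1 in 0.1 steps; 0.5 for estimation | covers alternation through constancy; 0.5 is the zero-autocorrelation midpoint |
| `alphas` | competition coefficients (per capita) | neutral: all 1.0; non-neutral: α_ii=1.25, α_jj=1.0, α_ij=1.0, α_ji=0.8 | neutral pair has no coexistence mechanism; non-neutral pair combines stabilization with a hierarchy favoring j |
| `T` | horizon (generations) | 500 | long enough for slow (algebraic) exclusion under the non-neutral preset to complete; configurable, 100 also meaningful for plotting |
| `replicates` | environment draws per condition | 500 (sweeps), 100 (estimation) | resolves outcome proportions to ~2 percentage points |
| `intro_time`, `intro_abundance` | introduction of both species | t = 2, 2 individuals | a maternal environment must exist at introduction, hence t ≥ 2 |
| `extinction_threshold` | abundance below which a species is removed | 1.0 | fewer than one (discrete) individual; see below |

The *Vulpia microstachys* (species i) / *V. octoflora* (species j) preset
carries environment-specific empirical values (λ_i = 236/153, λ_j = 924/1127,
and per-environment α); note λ_j is *higher* in the nominal "bad" state —
the good/bad labels are nominal and per-experiment.

## Numerical choices

**Extinction threshold.** The deterministic map never reaches exactly zero,
so competitive exclusion is operationalized by zeroing abundances below a
threshold after each update. The default of 1.0 reads as "fewer than one
individual". Losing species decline geometrically in the scenarios treated
here, so classifications are insensitive to the threshold across
[10⁻⁶, 1]; the one regime where the threshold matters is the non-neutral
hierarchy without maternal effects, where the inferior competitor declines
only algebraically (~1/t) and needs several hundred generations to cross
1.0 — one reason the default horizon is 500 rather than 100.

**Update order.** Both updates add the self-competition term before the
cross term, which makes relabelling the species (with a transposed α matrix)
swap the output series bit-exactly — a property the tests assert.

**Seeding.** Replicate r of an experiment uses environment seed
`base_seed + r`; identical configurations reproduce byte-identical results.

**Outcome classification.** `only_i` / `only_j` / `both` by which final
abundances are positive. `neither` is permitted defensively and warns; it
does not occur under the presets.

## The lag-free fit and why it pools replicates

The estimation experiment fits, per focal species, the memoryless model

    N(t+1) = N(t) λ(e_t) / (1 + a_self(e_t) N(t) + a_cross(e_t) N_other(t))

with a good/bad dummy on every parameter (6 per species), by bounded
trust-region nonlinear least squares on raw next-generation abundance.
The response choice matters: fitting N(t+1) yields R² ≈ 0.87 under an
omitted silver spoon, whereas fitting per-capita growth weights transitions
differently and yields R² ≈ 0.95 — the raw abundance response is the one
used and documented here. R² is
1 − SSE/SST per species. Starting values are the largest observed
per-capita growth per environment for λ and 0.1 for every α, with jittered
restarts on solver failure.

At the *Vulpia* parameter values, abundances sit in the thousands, so away
from the introduction transient the "1 +" in the denominator is negligible
and each environment block of parameters is identified only up to a common
scale factor. A single 500-step replicate therefore puts the misspecified
fit on a nearly flat scaling ridge — R's `nls` reports a singular gradient
on such data, and trust-region solvers wander to extreme values with
essentially unchanged SSE. The experiment consequently **pools all
replicates into one regression per species**: each replicate contributes its
low-abundance introduction rows, which anchor the absolute scale, and the
pooled optimum is well defined and independent of starting values (verified:
identical optima from generic and from generating-value starts). Regression
rows keep only transitions where both species are present, with the
environment dummy being the state of the transition's starting year; rows
with a missing environment stratum raise an identifiability error rather
than returning garbage.

With no maternal effect in the data the pooled fit recovers all twelve
generating parameters to machine precision with R² = 1 — the control that
validates the pipeline. With a maternal effect on species j, species i's
fit remains exact (its model is correctly specified), while species j's
estimates are biased: everything underestimated under a silver spoon;
good-year parameters underestimated and bad-year parameters overestimated
under matching; 13–17% of variation left unexplained.

Because each 100-replicate experiment's pooled estimate still varies with
the environment draws (sd ≈ 6% on λ̂_j(g)), the acceptance script reports
the mean over five independent 100-replicate experiments; each individual
experiment keeps the study conditions (T = 500, k = 0.5, 100 replicates).

## What the generator emulates — and what it does not

The synthetic environments are binary, symmetric and first-order Markov:
they emulate interannual quality fluctuations with tunable persistence, not
continuous climate variables, trends, seasonality, spatial heterogeneity or
asymmetric good/bad frequencies. The dynamics contain no demographic or
observation noise, so a passing suite demonstrates properties of the
deterministic model under idealized forcing — it does not show that the
estimation biases would have the same magnitude in noisy field data, where
sampling error would add to (and partially mask) the lag-induced
misspecification. Neutral coexistence ("both persist") is likewise an
artifact of determinism: any demographic stochasticity would eventually
break ties at random.

## Known limitations and open choices

* Grandparental/cumulative effects, seed banks, evolution of the maternal
  strategies, and >2 species are out of scope by design.
* Summary estimates from replicated experiments can in principle be computed
  as per-replicate fits averaged afterwards or as one pooled fit;
  per-replicate fitting is numerically ill-posed here (see above), so the
  pooled design is the one implemented. `fit_bh_model` still accepts any
  single-replicate table for well-posed cases.
* The horizon T is an explicit parameter; 500 generations is the default
  used throughout (long enough for slow exclusions to resolve), and shorter
  runs such as T = 100 remain useful for visualizing dynamics.
* The fecundity equation with s = 1.25 gives 12.5 for a 10-baseline year
  with an enhancing maternal exponent, and 12.5 — not any intermediate
  value — is what makes the geometric-mean equalization above exact; the
  worked values 75 / 48 / 12.5 / 8 follow directly from λ(i,o) · s^M.
* Maternal effects act multiplicatively on fecundity only; effects on
  competition coefficients or survival are not modeled.
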
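# Methods

## Model

`lenage` treats a sampled fish population as a set of annual cohorts
born in a single yearly pulse at calendar time `t_b` (a fraction of the
year).  At sampling time `t` within the year, the cohort of age class
`a ∈ {0..3}` has elapsed age

    age = (t − t_b) + a        (+1 if t < t_b; a cohort's class
                                increments at its birthday)

and mean total length given by a von Bertalanffy growth function
(VBGF).  Two growth forms are supported:

- **Traditional**: `L(t) = L∞(1 − e^(−K(t−t₀)))`.
- **Seasonal (Somers form)**:
  `L(t) = L∞(1 − e^(−[K(t−t₀) + S(t) − S(t₀)]))`,
  `S(t) = (CK/2π)·sin(2π(t − t_s))`.
  The instantaneous rate is proportional to `1 + C·cos(2π(t − t_s))`,
  so growth is slowest at `t_w = t_s + 0.5` (the *winter point*) and
  stops entirely there when `C = 1`.  With `t₀ = 0` the oscillation
  integrates to zero over whole years, so seasonal and traditional
  lengths agree at integer ages.

Printed forms of the seasonal VBGF circulate with inconsistent phase
and period conventions; this package standardizes on the form above,
which places the slowest growth at `t_s + 0.5` and is the one under
which the worked values in the tests hold together.

Individual lengths within a cohort are modelled as
`N(L̄_{a,t}, σ_a²)` — `σ_a` absorbs both individual growth variability
and the spread of true birth dates around the pulse.  Expected counts
in length bin `i` of month `t`:

    n_{a,i,t} = N_t · P_{a,t} · [Φ((L_upper−L̄)/σ_a) − Φ((L_lower−L̄)/σ_a)]
    N_{i,t}   = Σ_a n_{a,i,t}

Bins are half-open `[lower, upper)`, 10 mm wide, 46 bins covering
[0, 460) mm by default.  No truncation at 0 mm is applied: at realistic
dispersions (σ ≈ 25–40 mm against means ≥ 30 mm) the sub-zero mass is
negligible.

### Time frames

Model age is measured from birth (`t₀ = 0`; the birth date `t_b` plays
the cohort-origin role, so a separate `t₀` is redundant and is fixed).
`t_s` lives in the age frame; the calendar winter date is
`(t_s + 0.5 + t_b) mod 1`.  Calendar arithmetic uses a fixed 365-day
year with `year_fraction = (day_of_year − 1)/365`; rendering uses
`round()`, which keeps two-decimal year fractions within a day or two
of their nominal dates.

## Estimation

Four candidate structures form a 2×2 set: seasonal vs traditional
growth × shared vs age-specific σ.  `L∞` is fixed at the maximum
observed length by default (freeing it is supported but poorly
identified when old fish are scarce — unconstrained fits drift past
800 mm on data of this shape, a well-known `K`–`L∞` trade-off).

The likelihood kernel is selectable:

- **multinomial** (default): per month, bin counts are a multinomial
  draw from the normalized predicted composition;
  `−lnL = −Σ_t Σ_i n_{i,t} ln p̂_{i,t}`.
- **poisson**: independent Poisson cells,
  `Σ (μ − n ln μ)`.
- **concentrated_normal**: least squares on counts with the error
  variance concentrated out, `(n_cells/2)·ln(SSE/n_cells)`.

Under the multinomial kernel the per-month proportions-at-age enter
only through a convex per-month subproblem (a finite-mixture weight
MLE).  They are therefore *profiled out* by an inner EM pass, run
vectorized across months; the outer optimizer (bounded L-BFGS-B,
seeded multi-start, default 25 starts) searches only the ≤ 8 growth and
dispersion parameters.  The outer gradient uses the envelope theorem:
at the inner optimum, the gradient of the profiled objective equals the
partial gradient with the mixes held fixed, evaluated by central
differences of the cheap fixed-mix objective.  Two numerical details
matter:

- the EM update is multiplicative and cannot revive a weight that has
  reached exactly zero, so warm starts between evaluations are floored
  at 1e-3 and renormalized (harmless, because each subproblem is
  convex and has a unique optimum);
- `t_s` and `t_b` are periodic, so their search interval extends to
  (−1, 2) with reduction mod 1, preventing optima from pinning to an
  artificial [0, 1) boundary.

Bin probabilities are floored at 1e-12 so an observed count in a
zero-prediction bin penalizes rather than crashes the fit.  Bounds:
`K ∈ (0, 3]`, `C ∈ [0, 1]`, `σ_a ∈ [1, 100]` mm.  For the Poisson and
concentrated-normal kernels the proportions join the outer vector
through an anchored softmax.

Parameter counting for information criteria follows the original
spreadsheet convention: proportions count as 4 ages × 6 months = 24
even though only 3 per month are free on the simplex, giving
K = 32/29/30/27 for the four candidates.  The AICc effective sample
size defaults to the number of histogram cells (46 × 6 = 276), the
convention recovered from the published table arithmetic; the total
fish count is an alternative a caller can pass explicitly.

## Synthetic data

`canonical_scenario()` reproduces the study conditions: six sampling
months (April 2014 – January 2015, mid-month sampling dates, n = 850,
33, 1102, 53, 41, 58), seasonal growth (L∞ = 448, K = 0.47, C = 0.61,
t_s = 0.21, t_b = 0.41), at-age dispersions (26.29, 27.48, 24.13,
40.30) mm, and the published monthly age proportions.  Lengths are
drawn from the model's own normal-mixture assumptions, redrawn below
1 mm, and rounded to the nearest millimetre (field measurement
precision).  Exact sampling dates within months are not published;
mid-month is assumed and configurable.

What the generator does *not* emulate: diver size-selectivity (off by
default; a logistic retention curve is available for robustness
experiments), spread of birth dates (optional normal jitter, default
off), interannual growth variation, and mortality/abundance dynamics.
Passing tests on synthetic data therefore demonstrate correctness of
the estimator under the model's own assumptions, not robustness to the
ways real sampling violates them.

## What the diagnostics show

Parameter recovery at study-scale sample sizes (20 replicates of the
canonical scenario, checked in the acceptance tests): `K` and `t_b` are
recovered with median absolute relative errors of roughly 1% and 3%.
`C` is the weakly identified parameter — its information comes almost
entirely from the two large months (April, August), and its
replicate-to-replicate spread is large (median error ≈ 12%, above the
10% working threshold), although the estimator is consistent: at 100×
sample sizes `C` returns to within ~2% of truth.

A structural near-degeneracy also surfaces in a minority of
realizations: because the monthly proportions-at-age are free, the
likelihood has an alternative basin in which the birth date locks onto
the largest month's sampling date and every cohort is relabelled one
age class up.  When sampling noise favours that basin the recovered
`(K, C, t_b)` are systematically shifted and the seasonal signal is
diluted.  The randomized grid-search diagnostic exists precisely to
flag such multimodality, and multi-start fitting is the default.
Model selection is more stable than `C` itself: the generating
seasonal/variable-σ structure wins an AICc weight > 0.9 in ~85% of
replicates.

The published −lnL scale for this analysis is not reproduced by the
multinomial kernel (which yields values in the thousands at n = 2137);
the likelihood form behind the published table is unstated, which is
why the kernel is selectable and the concentrated-normal option exists
(its magnitude is plausible for the published values).  Information-
criteria *differences* and weights, which drive selection, do not
depend on kernel-specific additive constants within a kernel.

## Otolith reconciliation

Annuli are assumed deposited at the winter point.  A fish with one
annulus is `A = t_w + 1 − t_b` years old at deposition (1.30 yr for the
study parameters); each additional annulus adds a year, and the time
from the most recent calendar winter to the capture date supplies the
fractional remainder.  Fish whose two independent readers disagreed are
excluded and counted, never silently dropped.  Age classes derived from
reconciled ages use `floor(age)`, with the class incrementing at the
birthday inclusive.

## Limitations

- Four age classes are assumed present; older fish would be absorbed
  into the oldest class and inflate `σ_3`.
- Proportions-at-age are relative to the *sampled* population; with
  unknown, time-varying selectivity they do not support abundance or
  mortality inference.
- The mid-month sampling-date assumption introduces up to ±0.04 yr of
  chronology error if true collection dates were near month edges.
- Standard errors for parameters are not produced (matching the scope
  of the diagnostics: sensitivity clamps and start-point robustness
  rather than asymptotic CIs).
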
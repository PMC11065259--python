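# Methods

## Scope and data model

The package estimates HIV-serodifferent couples (SDCs) among adults aged
15–49 in TB-affected households — households where at least one member has
TB — for Ethiopia, Kenya, South Africa and Uganda, under two parallel
definitions of the index population: people with **incident** TB and people
with **prevalent** TB. Every country input is tabulated over the same eight
strata (male/female × 15–24, 25–34, 35–44, 45–49) and shipped as plain CSV
fixtures (`src/tbsdc/data/table1.csv`) plus a YAML manifest naming each
country's TB-HIV pathway and scalar parameters. Proportions are stored as
values in [0, 1]; age bands are categorical labels, never parsed as numeric
ranges; percent rendering happens only in reports.

The incident-scenario counts of people with both TB and HIV are not
published at the stratum level; `tbhiv_incident_synthetic.csv` carries a
**synthetic reconstruction**: the per-country total is back-solved from the
published HIV-positive household totals minus the computed contact
component, distributed across strata proportionally to TB counts × national
HIV prevalence. They make the incidence scenario runnable end-to-end; no
test of record depends on their stratum-level detail.

## The serodifference curve

`P_SDC` is the proportion of SDCs among all people living with HIV who are
in stable partnerships. Across national surveys it declines with population
prevalence `P`: the higher the prevalence, the likelier the partner of a
person with HIV is also positive. The package models this with one
homogeneity parameter `α ∈ (0, 1)` and supports two readings of the curve:

- **exponent** (default): `P_SDC = (P(1-P))^(αP)`. Maps (0,1) into (0,1),
  tends to 1 as `P → 0`, is strictly decreasing in `P` and in `α`, and is
  identifiable from survey points across the realistic prevalence range
  (0.5%–30%).
- **ratio**: `P_SDC = (P(1-P))^α / P`, clamped to [0, 1]. The raw value
  exceeds 1 for all `P` below ≈ 0.25 whenever `α < 0.98`, so over the
  realistic range the clamped curve degenerates to the constant 1 and `α`
  cannot be recovered from data. It is retained for comparison and
  sensitivity analysis only; the clamp and the raw values are tested
  against 30-digit arbitrary-precision oracles.

The model function is pluggable (`form=` argument throughout), so further
readings can be added without touching the fitters.

### Fitting

Two-stage grid-search least squares: stage 1 scans nine α values 0.1–0.9
(step 0.1); stage 2 scans nine values spanning the stage-1 winner ± 0.08 at
step 0.02 (0.72–0.88 when stage 1 selects 0.8). Ties break toward the
smaller α. Fewer than two distinct prevalences raise an identifiability
error.

Uncertainty comes from a Metropolis random walk on α: likelihood of
independent Gaussian residuals whose variance is the sample residual
variance at the initial value (`SSE/(n−1)`, held fixed along the chain — the
unbiased estimator was chosen as the standard default), uniform prior on
(0, 1), Gaussian proposals (default sd 0.01) rejected outside (0, 1);
defaults chain length 10,000, burn-in 1,000, seed 20240502. The posterior
mean and the 2.5/97.5-percentile interval are taken over post-burn-in
samples; identical seeds reproduce chains bit-exactly; a whole-chain
acceptance rate of 0 or 1 flags the result as degenerate.

**Calibration caveat.** On synthetic survey points (19 points, log-uniform
prevalences on 0.5%–30%, Gaussian noise) the least-squares estimator of α
carries a small upward finite-sample bias of order σ² — roughly +0.01 at
noise sd 0.03 (part intrinsic nonlinear-LS bias, part the truncation of
noisy P_SDC at 1 near the low-prevalence end). In simulation the 95%
posterior interval covers the generating α in about 90% of replicates
rather than the nominal 95%; censored-likelihood and
variance-marginalized variants were evaluated and do not materially change
this, so the plain Gaussian likelihood is kept. Posterior intervals near
the boundary of the observable prevalence range should be read accordingly.

The reference α used by the pipeline when no freshly fitted curve is
supplied is 0.829.

### Back-calculation and the published couple counts

The pipeline evaluates the curve at household prevalence to convert
HIV-positive partnered individuals into SDCs. No simple reading of the
curve reproduces the published per-country couple counts from the published
household prevalences, so the model also accepts an externally supplied
couple count (`n_sdc="published"` uses the packaged published estimates,
with their uncertainty intervals); this isolates the one unresolved step
from everything downstream and is the default for reporting. The modeled
path (`n_sdc=None`) remains fully functional, including posterior draws of
α resampled from the MCMC chain.

## Prevalence-ratio meta-analysis

Each household-contact study contributes a log prevalence ratio
`ln((cases/n)/ref_prevalence)` with delta-method variance `(1−p̂)/cases`
(plus a binomial comparator term when a comparator sample size is given); a
0.5 continuity correction on cases and denominator handles zero or
all-positive studies. Studies are pooled with DerSimonian–Laird τ²
(truncated at zero) and inverse-variance weights `1/(vᵢ+τ²)`. The default
95% interval is Hartung–Knapp (weighted residual variance, t quantile on
k−1 df); simulation at k = 6 heterogeneous studies shows plain DL–Wald
intervals covering only ~83% while HKSJ restores ~93–96%, which is why HKSJ
is the default and `interval="wald"` is the classic alternative. With one
study the pool is the identity with a Wald interval.

The pipeline itself consumes the pooled ratios as published (Kenya 4.12,
95% UI 1.50–11.31; Uganda 1.86, 1.54–2.23; South Africa 1.11, 0.75–1.64);
Ethiopia had no eligible studies and defaults to 1.0 (a back-calculation
from the published totals is consistent with ≈1), exposed as a
configuration knob. The pooling code is exercised on synthetic study sets.

## Household pipeline conventions

- Partnership proportions apply identically to HIV-positive and
  HIV-negative people within a stratum.
- Couples = partnered individuals / 2, real-valued; fractional couples are
  carried internally and rounded only on report (half away from zero).
- Contact HIV counts are capped at the stratum's contact count, and TB-HIV
  counts at the stratum's TB count, so no stratum implies >100% prevalence.
- The proportion of couples that are serodifferent uses couples
  (partnered/2) as denominator, matching the published values.
- Zero-prevalence strata are legal; P_SDC is evaluated only where anyone
  lives with HIV.

With the packaged tables, the pipeline reproduces the published
adults-in-households totals exactly (Uganda prevalence 616,268) or within
rounding (Kenya incidence 508,405 vs 508,403), and the prevalence-pathway
HIV-positive totals within 0.1% (Uganda 88,348 vs 88,312; Kenya 153,933 vs
154,026). South Africa's prevalence scenario is a known exception: the
published HIV-positive total (424,211) is ~12% above what the published
inputs yield (~374,880), suggesting an unpublished pathway detail; the
package reports what its inputs imply.

## PrEP impact

With uptake u = 0.97, effectiveness f = 0.95 and incidence i = 4.75 per 100
person-years among HIV-negative partners not on PrEP (all from a large SDC
demonstration study), and eligibility e (the fraction of couples whose
positive partner is not virally suppressed; 25/50/75/100% scenarios):

- without PrEP: `e·n·i`
- with PrEP: `e·(n·u·i·(1−f) + n·(1−u)·i)`
- averted: `e·n·i·u·f`

Eligibility multiplies both counterfactual arms — a suppressed partner
transmits in neither — which makes the scenario columns exact fractions of
the 100% column. Expected infections are real-valued; rounding happens only
in reports.

## Monte Carlo propagation

Every uncertain input is expanded into a fixed number of aligned draws
(default 1,000) and the entire pipeline runs element-wise on the draw axis;
summaries report the mean and the 2.5/97.5 empirical percentiles (linear
interpolation between order statistics, numpy's default rule, verified
against an independent sort-and-interpolate oracle).

Conventions:

- Counts and ratios draw lognormal; proportions draw truncated normal
  (resampling out-of-support values). An interval (L, U) converts to a
  standard error as (U−L)/3.92 on the sampling scale (log scale for
  lognormal).
- Lognormal draws are **mean-anchored** (`mu = ln(mean) − s²/2`) so draw
  means reproduce the deterministic pipeline; median anchoring is available.
- Where the published tables give no spread, defaults are: count cells ±20%
  relative 95% interval (lognormal), survey proportions ±10%, partnership
  proportions ±5% (truncated normal). All defaults live in
  `MonteCarloSpreads` and can be zeroed (`MonteCarloSpreads.zero()`), which
  collapses every summary onto the deterministic output exactly.
- Draws across distinct parameters are independent; cells of one parameter
  block share a draw index but are sampled independently, each from a
  substream derived from the master seed and a stable label hash, so adding
  a parameter never shifts another parameter's stream.
- A 1-draw run is defined as the point pipeline (no sampling), so
  `draws=1` equals the deterministic fit exactly.

With the published couple counts as inputs, 1,000-draw means agree with the
deterministic averted-acquisition values to within ~1%.

## Synthetic data

The statistical machinery was developed against survey microdata that is
not redistributable, so generators provide stand-ins:

- **Survey points**: prevalences log-uniform on (0.005, 0.30) — mirroring
  the skew of sub-Saharan national prevalences — with curve values plus
  Gaussian noise truncated to [0, 1].
- **Couple tables**: both partners marginally positive at the requested
  prevalence; a single multiplicative assortativity factor inflates the
  concordant-positive cell with the off-diagonals rebalanced to preserve
  margins; counts are multinomial. Closed-form cell probabilities serve as
  the oracle.
- **Study sets**: per-study log prevalence ratios Normal(ln PR, τ),
  binomial case counts, implied prevalences capped at 1 (and flagged).

All generators are bit-reproducible under a fixed seed. What they do not
emulate: DHS sampling weights, clustering and nonresponse; secular trends
across survey years; subnational prevalence variation; household-size
structure. Passing tests therefore demonstrate the correctness of the
estimation machinery under the stated sampling models, not the fidelity of
those models to any particular country's survey system.

## Reported sizes and runtimes

Test and acceptance runs use 250–1,000 draws, Metropolis chains of
2,000–10,000 iterations, and 19-point survey fits — the same sizes as the
reference analysis except where a smaller chain suffices for a determinism
check. The full suite runs in well under a minute on a single core.

## Known limitations

- The serodifference back-calculation does not reproduce the published
  couple counts under any simple reading of the curve equation; reporting
  defaults to the published counts (see above).
- South Africa's prevalence-scenario HIV-positive total is not recoverable
  from the published inputs (~12% gap).
- Ethiopia's household-contact prevalence ratio is an assumption (1.0),
  not an estimate.
- The α posterior shows ~90% empirical coverage at nominal 95% on noisy
  synthetic fits (finite-sample bias; see Calibration caveat).
- Couples are assumed monogamous and stable; non-couple household HIV
  exposures are out of scope, so the PrEP-eligible population is a lower
  bound.
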
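# Methods

`rootworm` models the emergence dynamics of the western corn rootworm
(WCR, *Diabrotica virgifera virgifera*), a univoltine maize pest, from
weekly pheromone-trap counts. This note records the model, the numerical
and design choices, what the synthetic data do and do not emulate, and
the known limitations.

## Observation model

Let `y_itk` be the count for trap `i`, week `t`, year `k` over a 19-week
monitoring season (early June to early October). Counts are conditionally
Poisson,

    y_itk | mu_itk ~ Poisson(mu_itk),

with the intensity tied not to calendar time but to a phenological clock:
cumulative growing degree days (GDD). Daily GDD is
`max((Tmax+Tmin)/2 - Tbase, 0)` with `Tbase = 10 °C`, accumulated from
1 April; `z_t` is the cumulative sum at the t-th weekly reading date.
An alternative "half-range" daily formula `max((Tmax-Tmin)/2 - Tbase, 0)`
is available behind `dialect="as_printed"` for comparison experiments; it
is not a degree-day measure in the usual sense and is never the default.

Cumulative emergence follows a Gompertz sigmoid
`f(z) = alpha * exp(-beta * exp(-gamma z))`, so the weekly intensity is
its derivative:

    log mu = log alpha + log beta + log gamma - gamma z - beta exp(-gamma z).

This is unimodal in `z` with peak emergence at the inflection
`z* = log(beta)/gamma`, where `mu = alpha * gamma / e`. `alpha` is the
saturation level (expected cumulative catch), `beta` a relative starting
value (lower = earlier first emergence), `gamma` a growth-rate
coefficient (lower = more protracted emergence).

### Scale conventions

The Gompertz family is invariant under `(gamma, z) -> (gamma/c, c z)`, so
the units of `z` are a free choice that only relocates `gamma`. Default:
`z` is cumulative GDD divided by the dataset mean of the season-end
cumulative GDD, so `z` spans roughly [0, 1] across the season and
`gamma` is O(1-10). The factor is recorded in `ModelData.z_scale` and in
every run manifest. Raw degree days (`z_scale=1`) are equally supported.

Trap coordinates enter the saturation regression in centred 100-km units
(`ModelSpec.coord_unit_km`), keeping the spatial polynomial terms of
comparable magnitude to the climate covariates over a ~200 km region.
Climate covariates are used in raw units (°C, mm) without standardisation;
only coordinates are centred.

## Hierarchy and priors

Each trap-year has its own triple, positive by construction because the
normal hierarchy is placed on the log scale:

    log alpha_ik ~ N(a0 + w' X_alpha_ik, 1/tau_alpha)
    log beta_ik  ~ N(b0,                 1/tau_beta)
    log gamma_ik ~ N(g0 + u' X_gamma_ik, 1/tau_gamma)

`X_alpha`: mean winter temperature (1 Jan-31 Mar), winter precipitation
sum, year index, maize share of municipal agricultural area (%), and the
centred coordinates x, y with xy, x², y². `X_gamma`: mean spring
temperature (1 Apr-30 Jun). The log-scale placement makes every
regression coefficient a multiplicative effect: a one-unit covariate
increase scales the natural-scale parameter by `exp(c)`, reported as
`100*(exp(c)-1)` percent.

Priors: every intercept and coefficient `~ N(0, precision 0.01)`
(variance 100, the BUGS precision convention — a genuinely diffuse
choice); each precision `tau ~ Gamma(0.01, 0.01)`.

## Blank/zero recoding

Raw sheets record blanks and zeroes interchangeably. Traps with no
positive count over the season are excluded; for the rest each
blank-or-zero slot is classified, in order, first match wins:

1. before the first positive count -> zero (early season);
2. between two positive neighbours -> missing if either neighbour >= 10,
   else zero;
3. no positive neighbour -> zero (sequential zeroes are real);
4. a **blank** adjacent to exactly one positive neighbour -> missing.

Rules 1-3 apply to blanks and recorded zeroes alike; rule 4 applies to
blanks only, so an explicitly recorded zero next to a positive stays an
observed zero. "Neighbour" means the immediately adjacent weeks; at the
season edges the single existing neighbour decides between rules 3 and 4,
which also resolves end-of-season blanks (missing next to a positive,
zero otherwise). Runs of two or more blanks between positives fall
through to rule 4 because neighbourhood is strictly adjacent. The
accounting report stores counts and recomputes all percentages from them;
rule percentages use the denominator `retained traps x 19`.

MISSING slots are handed to the sampler as latent quantities: they
contribute no likelihood and are redrawn each sweep from `Poisson(mu)` at
the current parameters (posterior-predictive imputation), so imputed
values never inform the parameters — the nuisance-parameter treatment.

## Sampler

No probabilistic-programming backend is used; the sampler is
Metropolis-within-Gibbs written against the model's conditional
structure:

* **Coefficient blocks** (`a0,w`), (`b0`), (`g0,u`): exact conjugate
  normal draws given the latent log-parameters and precisions.
* **Precisions**: exact conjugate Gamma draws.
* **Latent triples** (log alpha, log beta, log gamma) per trap-year:
  random-walk Metropolis, vectorized across trap-years (conditionally
  independent given the hyperparameters). The first half of burn-in uses
  component-wise proposals with per-trap scales adapted toward 44%
  acceptance; from mid burn-in onward all three components are proposed
  jointly along the running per-trap 3x3 sample covariance (scaled
  `2.38/sqrt(3)`, global per-trap scalar adapted toward 28% acceptance).
  The joint phase is what handles the strong within-trap-year
  (log beta, log gamma) posterior correlation; component-wise updates
  alone leave `beta` with effective sample sizes in the tens. Adaptation
  freezes at the end of burn-in. Three latent sweeps run per Gibbs
  iteration (`MCMCSettings.n_latent_sweeps`).
* **Initialisation**: `log alpha` from `log(total catch + 1)` per
  trap-year plus jitter, `log beta`/`log gamma` near the hierarchy
  centre, coefficients from least squares on the initial latents.
* Non-finite proposal log-densities are treated as `-inf` (rejection),
  never exceptions; imputation intensities are capped at `exp(27)` to
  keep the Poisson sampler in range.

Default protocol: 20000 iterations, 10000 burn-in, thinning 5, i.e.
2000 retained draws per chain; 4 chains by default (the original analysis
does not state a chain count). Chain `c` is seeded with the sequence
`(seed, c)`, making every fit a pure function of data and settings.

Convergence: split R-hat and bulk ESS (via arviz) for every top-level
scalar, with a warning above R-hat 1.01; trace inspection remains
advisable but the thresholds make the check machine-verifiable.

## Synthetic studies

The generator is a first-class module that produces exactly the structure
the model assumes, plus the recording pathologies the recoder must undo:

* traps uniform over a 200x200 km region, maize share `100*Beta(2,5)`;
* daily weather per station (nearest-station assignment) as an annual
  sinusoid (mean 9.5 °C, amplitude 10.5 °C, coldest mid-January) with
  station offsets, year offsets and daily noise; tmin/tmax are the daily
  mean -/+ half a non-negative diurnal range, so `tmin <= tmax` holds by
  construction; precipitation is a wet-day Bernoulli times an exponential
  amount;
* latent triples drawn from the log-scale hierarchy, counts from the
  Poisson-Gompertz intensity at the weekly `z`;
* blanks injected on top of the true counts: a true zero becomes an empty
  cell with probability 0.5 (the blank/zero interchangeability), a
  positive count is lost with probability 0.05. The uncorrupted counts
  are retained, so recoding can be scored cell-by-cell.

Default size: 100 traps x 3 years, 6 stations — a deliberate desk-scale
reduction of the original network (thousands of traps over 12 years)
chosen so a full simulate-fit-report cycle takes seconds, with replicate
studies in minutes.

**Generative constants.** All covariate slopes and precisions default to
the published posterior means (winter temperature 0.143, precipitation
-3.72e-6, year 0.106, maize 1.4e-4, spatial terms; spring temperature
0.0454; tau 0.149/0.672/2.890), as does the saturation intercept
(a0 = 2.03). The `beta`/`gamma` intercepts cannot be transplanted: the
published values are tied to an unstated `z` unit, and under this
package's z convention they would place peak emergence before the season
starts, contradicting the observed pattern of near-zero counts in the
first and last weeks. They are instead anchored at `b0 = 4.5`,
`g0 = 1.55`, putting the median inflection at `z* ~ 0.5` (mid-season,
around week 8) with a sharp enough pulse that early and late weeks are
quiet for a typical trap.

What the generator does **not** emulate: real geography and climate
normals, spatial autocorrelation beyond the covariate surface,
overdispersion relative to Poisson, trap-level recording idiosyncrasies,
and non-random trap placement. Passing tests therefore demonstrate the
correctness of the machinery under the model's own assumptions, not the
adequacy of the model for any particular real network.

## Verification experiments

* **Parameter recovery**: 20 replicates of simulate-and-refit at 100
  traps x 3 years with a reduced protocol (4000/2000/thin 2, 2 chains).
  Each of the three scientifically central slopes (winter temperature on
  alpha, year trend on alpha, spring temperature on gamma) must fall in
  its 95% credible interval in at least 90% of replicates with split
  R-hat < 1.05. These fits use the **full** simulated network, not the
  retained subset: conditioning on "at least one catch" truncates the
  latent hierarchy and measurably attenuates the spring-temperature slope
  (regressing even the *true* latent log-gamma on spring temperature
  drops from ~0.04 to ~0.01 after filtering), a selection effect the
  model — like the original — does not correct; a hurdle extension
  would, and is out of scope. The pipeline commands keep the filter,
  because that is how monitoring data arrive.
* **Posterior-predictive band**: for each retained draw a full replicate
  study is simulated — new trap-year parameters from the fitted
  hierarchy, new Poisson counts — and the average cumulative curve
  accumulated. The equal-tailed 95% envelope over replicates must contain
  the observed average curve at >= 90% of weeks; the band is wide because
  it carries the (heavy-tailed) population heterogeneity of the traps,
  not merely count noise. A "conditional" mode keeping each draw's own
  latents is available for residual-style checks.
* **Recoding**: exhaustive agreement with an independent transcription of
  the rules over all length-7 blank/zero/small/large patterns, plus
  cell-level audit against synthetic ground truth.

## Numerical and edge-case choices

* Equal-tailed 95% intervals (not HPD), matching classic BUGS summaries.
* An empty dataset is legal: the sampler then draws from the priors
  (used to verify the prior-sampling identity).
* `diagnose` requires at least 4 retained draws per chain; fewer is an
  explicit error, not a silent pass.
* Recoding is idempotent; re-running on recoded output changes nothing.
* Weather tables are validated (`tmin <= tmax`, no duplicate or gapped
  dates, non-negative precipitation) before any phenology computation;
  leap years are handled by calendar arithmetic (91- vs 90-day winters).
* Blank cells in CSV output are genuinely empty fields — never "NA",
  never 0 — because the recoder's whole task is to distinguish them.

## Known limitations

* Retention-filter selection bias (above) is inherited from the study
  design; intercept-level parameters (`a0`, `tau_alpha`) absorb most of
  it in filtered fits.
* The weekly intensity is the pointwise derivative `f'(z_t)`, not the
  exact between-reading increment `f(z_t) - f(z_{t-1})`; both are
  implemented (`weekly_mean_from_curve`) and agree when `z` steps are
  small relative to the pulse width, but very sharp pulses (large gamma)
  can fall between weekly readings.
* No spatial residual correlation, no hurdle component for all-zero
  traps, no model comparison machinery.
* Poisson observation noise only; field counts are often overdispersed.
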
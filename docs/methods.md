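# Methods

## Model and assumptions

`rubrwatch` couples two conjugate Bayesian models and propagates both
through one Monte-Carlo simulation so that every prediction of the combined
UBR rate is paired with a prediction of the total sample size.

**Accrual.** Enrollment is a renewal process with i.i.d. exponential
waiting times of mean θ (study time-units per subject). This implies a
constant underlying accrual rate: no ramp-up, seasonality, or site-level
heterogeneity. The prior is θ ~ IG(k, V) with k = nP, V = TP. We use the
shape–scale parameterization, density ∝ θ^−(A+1) e^(−B/θ) (equivalently
1/θ ~ Gamma(shape A, rate B), posterior mean of θ is B/(A−1) for A > 1);
implementers' defaults differ, so this contract is fixed here and in the
docstrings. The interpretation of the prior is "P·n pseudo-subjects
observed over P·T pseudo-time": at P = 1 the prior carries as much weight
as a fully enrolled trial, at P = 0 it vanishes. After m enrollments over
t_m the posterior is IG(k + m, V + t_m).

Monitoring looks use the data up to the m-th enrollment time t_m; a look
strictly between enrollments does not contribute the censored in-progress
waiting time. This loses a small amount of information when accrual is slow
relative to the look spacing but keeps the update in closed form and works
from exactly what aggregated reports contain.

**Predictive sample size.** For each draw j, θ_j ~ IG(A, B), then the
number of additional enrollments in the remaining budget L = max(0, T − t_m)
is drawn. The default draws Poisson(L/θ_j) directly; a "sequential" method
counts exponential waiting times whose partial sums stay within L. The two
are distributionally identical (Poisson-process/renewal equivalence) and
the suite tests this with a two-sample chi-square at α = 0.001. Marginally
the additional count is negative binomial, NB(size = A, p = B/(B + L)),
mean L·A/B — the closed-form oracle for the sampler. Predicted totals
n_j^p = m + count are deliberately **not** capped at the design target: a
trial can over-enroll, and truncation would bias the meeting probability.
If t_m ≥ T the budget is clamped to zero and every draw equals m.

**UBR categories.** Each category is an independent binomial on aggregated
counts; the conjugate Beta(p₀nP, (1−p₀)nP) prior shares the single global
confidence P with the accrual prior (no per-category confidence knob). One
rate p_j^u is drawn per accrual draw j — not one per prediction — so
parameter uncertainty propagates into the predictive spread. With a fixed
remaining size the future count is exactly beta-binomial, the second
closed-form oracle.

A boundary-elicited prior (p₀ ∈ {0, 1} with P > 0) or a flat prior with
all-or-none observed counts makes the posterior improper; the package
raises rather than silently regularizing, with the suggestion to nudge p₀
into (0, 1), because silent regularization would change the elicited prior.

**Combined rUBR.** rUBR_j^p = Σ_u S^u_{n_j^p} / n_j^p, and the final
observed value is rUBR_f = Σ_u n_f^u / n_f. Summing proportions
double-counts subjects in several categories; with heavy overlap draws can
exceed 1. They are reported with an `OverlapWarning` and never clamped —
that is the honest consequence of working from aggregated counts. The
synthetic generator's "paired" overlap mode exists to demonstrate the bias.

**Meeting probabilities and summaries.** P(meet) is the proportion of draws
at or above the target (ties count as meeting; the ≥ convention is fixed
and documented because published descriptions leave equality ambiguous).
Interim tables report the median as the default point estimate (the
predictive sample-size distribution is right-skewed), the mean alongside,
and equal-tailed 2.5/97.5-percentile 95% credible intervals. Display
rounding is integers for sample sizes and three decimals for rates; full
precision is kept internally.

## Tunable parameters

| parameter | meaning | units | default |
|---|---|---|---|
| `n_target` | planned sample size | subjects | — |
| `horizon_T` | recruitment window | study units (e.g. months) | — |
| `confidence_P` | prior weight, 1–10 elicitation ÷ 10 | [0, 1] | — (0.1–0.5 typical) |
| `p0` per category | prior expected category rate | [0, 1] | — |
| `rubr_target` | combined-rate target for P(meet) | [0, 1] | none |
| `draws` (s) | Monte-Carlo draws per prediction | — | 10,000 |
| `seed` | RNG seed | — | none |

The core is unit-agnostic: t_m and T must simply share a unit. Calendar
dates are converted at the I/O layer (days, or months = days / 30.4375).

## Randomness and numerics

One seeded `numpy.random.Generator` drives each prediction call. Draw
order: the θ vector, then the count vector, then for each category in
design order the rate vector followed by the binomial vector. A fixed seed
therefore reproduces a prediction bit-for-bit; multi-look runs spawn
per-look seeds from a `SeedSequence`, so tables and reports are also
deterministic. Negative remaining budgets are clamped to zero. The m = 0
division guard in the rUBR computation only matters in the degenerate
no-data, no-budget case.

## Synthetic-data generator

`generate_trial` emulates precisely the generative assumptions of the
models: exponential inter-arrivals at a fixed θ_true and independent
Bernoulli category flags at fixed p_true, stopping at whichever of the
subject cap or the horizon binds first. It does **not** emulate ramp-up or
seasonal accrual, site heterogeneity, time-varying category mix, or
informative missingness — so passing calibration and recovery tests shows
the implementation is correct under its own assumptions, not that those
assumptions hold for any particular real trial. An `adore_like` fixture
reproduces only the published *shape* of a large completed trial (target
1355 over 48 months, confidence 0.3, about 1100 enrollments over about 45
months, category rates near 302/1100 and 244/1100, ten looks every three
months after 300 enrollments); no subject-level data from any real trial
are used or approximated beyond those summary figures.

## Verification choices and problem sizes

* Sampler-vs-oracle agreement uses chi-square goodness of fit at α = 0.001
  on 50,000 draws, with expected-count pooling of sparse tail cells.
* Flat-prior recovery: 100 replicates at m = 2,000 (θ) and m = 1,000 (p),
  requiring < 5% average relative error; credible-interval coverage for p
  uses 1,000 replicates at m = 500 within ±3 points of nominal.
* Predictive calibration: 500 trials simulated from the model's own priors
  under the adore-like design, one look at T/2, 1,000 draws per prediction;
  95% intervals for the realized final sample size and final rUBR must
  cover at 95% ± 3 points. These sizes give Monte-Carlo standard errors
  comfortably inside the stated tolerances while keeping the suite fast.
* The ten-look workflow check requires consecutive 95% interval widths to
  be non-increasing up to 5% Monte-Carlo slack with the final width below
  half the first, at a fixed seed.

## Known limitations

* Aggregated counts cannot resolve cross-category overlap; the combined
  rUBR is biased upward by exactly the overlapped mass. With unaggregated
  subject-level membership data a joint (e.g. multinomial or overlap-aware)
  model would be preferable; that analysis is out of scope here.
* The constant-rate exponential assumption makes early-trial predictions
  optimistic when accrual ramps up slowly.
* The confidence P is held constant across looks; re-elicitation at later
  interims (or accelerated/hedging confidence schemes) is not supported.
* Categories share the single global P; per-category prior weights are not
  exposed.
* Decision rules (stopping, recruitment redirection) are out of scope: the
  output is monitoring information, not a decision procedure.
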
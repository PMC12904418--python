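# Methods

This note records the model, the algorithmic choices, and the known
limitations of the package, in the order data flows through it.

## In-bed detection from wrist step counts

Consumer watches do not export bed times, so nightly in-bed intervals are
reconstructed from the step counter. Step records are apportioned to a
regular epoch grid (default 10 min) proportionally to temporal overlap;
epochs never covered by any record are *missing*, not zero — a zero-step
record is evidence of stillness, absence of records is absence of
evidence. Within a nightly search window (default 20:00–12:00 next day,
clock time in the configured study timezone, default Europe/Brussels) each
epoch is classified inactive (steps < 5 per 10 min, or a recording gap —
a watch on a nightstand produces gaps, and long gaps overnight are treated
as inactivity) or active. The in-bed interval is the longest run of
inactive epochs in the window, where:

- interior active bursts strictly shorter than the exit-confirmation
  length (default 3 epochs = 30 min) and within the WASO cap (default 3
  epochs) are absorbed as wake-after-sleep-onset;
- a burst of ≥ 3 consecutive active epochs confirms a bed exit and
  terminates the run (exit confirmation wins the tie at exactly 3);
- runs shorter than 3 h are discarded; ties go to the earliest run; at
  most one interval per night; a window with no coverage at all yields a
  flagged missing night.

All thresholds live in `DetectorParams` and are config/CLI exposed. They
are conventional actigraphy values, not fitted quantities; the property
suite proves the implementation equivalent to a brute-force enumeration of
candidate runs under the same rules, so threshold changes cannot silently
change semantics. Raising the low-step threshold weakly grows the
inactive set and therefore never shortens a detected interval.

A night is assigned to the calendar date on which the search window opens
(the evening's date). Daytime total smartphone use of day *d*, in-bed use
during the night starting on evening *d*, and the sleep episode inside
that night thus share day index *d*, which makes the same-day causal
ordering TSU → SUiB → sleep temporally coherent.

## Panel variables

Sleep stage seconds are summed per night (awake episodes excluded;
overlapping same-stage records merged first so duplicated export rows
cannot double-count); total sleep = REM + core + deep. TSU is the coded
daily total. SUiB prorates each clock hour's usage seconds by the hour's
overlap with the in-bed interval — usage is only known per hour, so
uniformity within the hour is the only available assumption. SUiB is
capped at TSU, set to 0 on detected nights with no overlapping usage, and
missing when either the night or the day's screen-time source is missing.
Participants missing ≥ 7 of 14 days of sleep *or* screen time are
excluded.

## Decomposition, standardization and imputation

Each variable splits into a between component (person mean over observed
days, centered at the grand mean) and a within component (daily deviation
from the person mean), with lag-1 copies; lagged between predictors use
the person mean of the lagged series (days 1..T−1), which is distinct
from the current-series mean. Within columns are standardized by their
pooled within-person SD. Between *predictors* are standardized by the SD
of person means.

Between *coefficients* are reported per total day-level SD of the
outcome. This is deliberate: with observed overlapping person means the
lagged and current means share 12 of 13 days of within noise, so a
between-SD-standardized stability is pinned near 12/13 ≈ 0.92 regardless
of trait variance — it cannot measure habit strength at all. On the
total-SD scale the stability estimand is
(v + c)/√((v + ψ)(1 + v)) for trait variance v and overlap terms c, ψ,
which ranges from ≈ 0.26 (no stable traits) toward 1 and maps
monotonically to the intra-class correlation. Reported stabilities of
0.5–0.8 then correspond to plausible ICCs (≈ 0.25 for sleep, ≈ 0.65 for
total use).

Missing cells are imputed by chained equations (scikit-learn's iterative
imputer, posterior sampling on) with the same-day other variables,
observed-day person means and day-of-week indicators as predictors;
observed cells are never modified, values are bounded to [0, max + 3 SD],
and the stage-sum identity is restored on imputed rows. m = 5 completed
panels are decomposed with centering anchored on observed-day person
means. Because the imputation model carries no lag terms, imputed cells
dilute lag-1 coefficients slightly (≈ 5–10% at the default 5% cell
missingness); this is visible in the calibration experiments and accepted
as the cost of a simple, spec-stable imputation model.

## The two-level DSEM

Per outcome, one regression with the within columns at their specified
timing (autoregressive and cross-lagged paths at t−1; TSU→SUiB and both
smartphone variables → sleep outcomes same-day, in the recursive order
TSU → SUiB → sleep), the matching between columns, a person random
intercept, and Gaussian residuals. Same-day paths form an acyclic
recursive system, so equation-by-equation estimation is consistent.
Residuals are independent across outcomes given the random intercepts; a
residual correlation structure is a known omission, documented rather
than modelled.

Estimation is a blocked Gibbs sampler: joint conjugate normal updates for
the coefficient vector, per-person normal updates for the random
intercepts, and inverse-gamma updates for both variances using the
scale-mixture representation of the half-Student-t(3, 0, 2.5) priors.
Coefficients get normal(0, 10) priors — effectively flat on the
standardized scale, but proper ("uninformative" instantiated as
weakly-informative; truly flat priors only hurt sampling). Defaults are 2
chains × 5,000 iterations with the first half as warmup. Convergence is
judged by split rank-normalized R-hat (< 1.01), computed per imputation
and reported as the worst value per path; non-convergence flags the
result rather than raising. Draws from the m imputations are pooled by
concatenation — the Bayesian analogue of combining completed-data
analyses — and a path is "significant" when the pooled 2.5–97.5
percentile interval excludes zero.

### Small-T centering bias and its correction

Centering at *observed* person means over a short series induces the
classic dynamic-panel (Nickell) bias: the centered lag correlates
negatively with the innovation, shifting autoregressive estimates by
about −(1 + β)/(T − 1) ≈ −0.07 at T = 14 — larger than the credible
intervals at this study scale. Latent-mean centering (the textbook
remedy) is out of scope, so the estimator corrects itself by parametric
bootstrap: person constants cancel exactly under person-mean centering,
so the bias depends only on the within dynamics; the fitted standardized
within VAR is simulated (40 replicates, innovations scaled to unit
stationary variance), the identical centering + standardization +
regression mirror is applied, and the mean shift per within column is
subtracted from the posterior draws. The correction is applied uniformly
to every within path (default on, `debias=False` to disable); between
columns are untouched. The 20-study coverage experiment in the acceptance
suite verifies that corrected 95% intervals cover generating values at
roughly nominal rates.

### Diagnostics

Posterior-predictive p for each outcome's mean (fraction of replicated
datasets whose mean exceeds the observed mean; ≈ 0.5 is ideal), VIF per
within design column, and PSIS-LOO with pointwise log-likelihoods summed
across outcomes per person-day; model comparison aligns observation sets
on (participant, day) and reports the ELPD difference with its SE.

## The synthetic generator

The generator is the model's exact mirror plus a measurement layer:

- **Between level**: independent per-variable traits with variance v_k
  (diagonal by design — reported cross-variable between paths are ≈ 0);
  `calibrate_between` tunes v_k by Monte-Carlo search (large-n simulated
  panels, inverting the rational stability map refit each round) until
  the observed-scale stability matches targets within ±0.03. Targets ≥ 1
  are infeasible; targets below the shared-noise floor (≈ 0.26) raise
  with the measured floor.
- **Within level**: structural VAR(1) with the reported standardized
  coefficients as lag/current matrices, solved in recursive order, with
  innovation variances fixed-pointed so every within component has unit
  stationary variance — which is precisely what makes the generating
  coefficients standardized betas.
- **Measurement**: latent values map to seconds through a softplus with
  per-variable softness (one anchor SD) whose location/scale are
  moment-matched by Gauss–Hermite quadrature to the study descriptives;
  for in-bed use the matching accounts for the SUiB ≤ TSU cap via
  bivariate quadrature. The softplus respects non-negativity without the
  truncation that would bias recovery; for strongly skewed variables
  (SUiB: mean 0.54 h < SD 0.73 h) the person-varying local slopes still
  dilute paths where that variable is a *predictor* by roughly 10–25%.
  That attenuation is a property of fitting linear models to skewed
  non-negative measurements — the real analysis shares it — and is left
  visible rather than compensated.
- **Missingness**: 5% MCAR at source level (watch block and screenshot
  block drop independently; SUiB needs both). The study this emulates
  reported imputation and heavy-missingness exclusions but no cell rate;
  5% is a realistic choice for retained participants, fixed once.
- **Raw streams**: a panel can be rendered to step XML, sleep XML and an
  hourly usage CSV — 10-minute-aligned intervals, zero/absent steps in
  bed and active records outside, stage records partitioning total sleep
  in short cycles, in-bed usage placed in fully-contained clock hours
  (boundary hours get proration-compensated amounts), daytime usage only
  in hours fully outside every interval. The round trip through
  detection and panel construction recovers each variable to a few
  seconds per day (tolerance 300 s/day); missing nights are rendered as
  watch-off gaps and come back as missing.

What the generator does *not* emulate: circadian texture beyond the
day/night activity contrast, zero-inflated usage marginals, weekday
structure in the outcomes, informative missingness, device clock drift,
or DST transitions. Passing recovery tests therefore show that the
estimator recovers the assumed data-generating process at study scale —
not that the model is correct for any particular real dataset.

## Problem sizes used in the shipped experiments

Recovery experiments run at the published scale (68 participants × 14
days, m = 5, 2 × 5,000 iterations); between-level calibration uses
3,000-participant panels per Monte-Carlo round; the coverage experiment
uses 20 replicate studies of 34 participants with complete data and
shorter chains; descriptive-anchor checks use 10,000 participants. A
single recovery study is one draw of a finite experiment: pooled
posterior means wobble around generating values with SD ≈ 0.03–0.04, so
individual paths occasionally land outside narrow reference bands even
when the estimator is calibrated.

## Known limitations

- Observed-mean (not latent) centering; the bootstrap correction removes
  the first-order small-T bias but not finite-T variance effects.
- No residual correlations across outcomes and no random slopes.
- Between-level regressions use observed person means as predictors;
  their shared-noise component is handled by the reporting scale, not by
  a latent model.
- The usage-hour proration assumes uniform usage within the clock hour.
- Sleep staging is taken as given from the device export; the detector
  infers only in-bed boundaries, not sleep/wake within them.
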
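# Methods

This note documents the statistical procedures the package implements, the
assumptions behind them, the synthetic-data generator that stands in for
participant data, and the numerical and design choices made where
conventions differ across published pipelines.

## Reaction-time cleaning

Trials are discarded per participant × timepoint × trial-type cell by
three rules applied in fixed order, each trial keeping the first
applicable reason:

1. **error** — incorrect probe response;
2. **absolute bounds** — RT < 200 ms or > 2000 ms (exclusive bounds:
   exactly 200/2000 ms survives);
3. **SD outlier** — |RT − m| > 2·s, where m and s are the mean and sample
   (n−1) SD of the trials surviving rules 1–2 in that cell, computed in a
   single, non-iterative pass.

A participant is excluded when strictly more than 20% of any of the four
cells (pre/post × congruent/incongruent) is discarded; error trials count
in both numerator and denominator. Published descriptions of this cleaning
recipe rarely state whether the SD statistics include error or
out-of-bounds trials, or whether the rule iterates; the defaults above are
the most common deterministic reading, and both SD-statistic conventions
are exposed as config switches (`sd_after_absolute`, `errors_in_sd_stats`).
Single-pass rather than recursive trimming keeps the rule order-free and
idempotent.

Degenerate cells are handled explicitly: s = 0 discards nothing; a cell
with < 2 trials surviving rules 1–2 skips the SD rule; a cell left empty
makes the bias index undefined for that participant/timepoint (NaN and a
logged warning, not an error).

## Bias scoring

`BI = mean RT(incongruent) − mean RT(congruent)` on retained trials only,
in ms. Positive = attention toward the threatening face. The index is
antisymmetric in the trial-type labels and invariant to adding a constant
to every RT; both properties are tested.

## Split-half reliability

For each of `n_splits` (default 5000) random splits, every participant's
congruent trials and incongruent trials are halved independently
(stratified, so each half contains both trial types; an odd trial is
assigned to a random half per split), a bias index is computed per half,
and the Pearson correlation between half-1 and half-2 indices across
participants is recorded. The per-split correlations are averaged first
and then Spearman–Brown corrected, `r_full = 2r̄/(1+r̄)`
(`correction_order="average_then_correct"`; the correct-then-average
convention is available since split-half tools differ). Negative split
correlations stay in the average — truncating them would bias the
estimate upward.

**Trimming must happen inside each half.** The 2-SD outlier rule couples
every trial to its cell-mates. If a cell is trimmed once and the retained
trials are then split, both halves inherit the cell's sampling
fluctuation — the trimmed mean tracks the untrimmed sample mean while the
within-half variability reflects only the reduced post-trim spread — and
the half–half correlation is inflated far above zero (≈ 0.25–0.40 after
correction in simulation) even when the bias has **no** true
between-person variance. The estimator therefore honours the error and
absolute-bounds discards upstream (they are per-trial criteria,
independent of the cell) but re-applies the SD rule within each random
half, which restores exact independence of the halves under the null.
The split-the-cleaned-trials variant remains available as
`sd_trim_within_half=False` for comparison with pipelines that use it.

Sampling properties worth knowing: with ~45 retained trials per cell and
200 participants, the estimate carries a cohort-level sampling SD of
roughly 0.1 — averaging more splits does not reduce it, only more
participants or replicate cohorts do. The package's null-calibration
checks therefore average replicate cohorts.

## SE_M, S_diff, and Jacobson–Truax classification

`SE_M = sd_baseline·√(1−r)` with the pooled pre-training SD over retained
participants; `S_diff = √(2·SE_M²)`. r ≥ 1 degenerates to SE_M = 0 with a
warning. Classification at each follow-up against baseline:

| reliable change (|Δ| ≥ 1.96·S_diff) | below cutoff (score < M₀ − 1.96·SD₀) | label |
|---|---|---|
| decrease | yes | recovered |
| decrease | no | improved |
| none | yes | non-reliably recovered |
| none | no | unchanged |
| increase | either | deteriorated |

The reliable-change threshold is inclusive (≥) and the cutoff strict (<);
both are measure-zero boundaries for continuous scores, but the choice is
fixed and documented because integer questionnaire totals can land exactly
on a threshold. A reliable deterioration takes precedence over
below-cutoff status. Only criterion A is implemented; criteria B/C require
a functional-population distribution this design does not use. Missing
follow-ups drop out of that timepoint's denominator; participants without
a baseline are excluded with a warning.

Under a no-change cohort with correctly specified S_diff, the fraction
classified as reliably changed is 2·(1−Φ(1.96)) ≈ 5%; this calibration is
exercised with 10 000 simulated participants.

## Baseline comparisons from printed summaries

One-way ANOVA needs only per-group (n, M, SD), because
SS_between = Σ nᵢ(mᵢ−m̄)² and SS_within = Σ (nᵢ−1)sᵢ² are sufficient; the
summary-statistics route is tested to 1e-9 against raw-data ANOVA. Welch's
ANOVA uses weights nᵢ/sᵢ² with Welch–Satterthwaite denominator df, for
measures whose variances Levene's test flags as heterogeneous. Categorical
rows use Pearson's chi-square without continuity correction (the tables
are 2×4; Yates is a 2×2 convention). Tukey–Kramer post-hocs use the
studentized-range distribution with the unequal-n standard error
√(MSW/2·(1/nᵢ+1/nⱼ)); with two groups this reduces exactly to the pooled
t-test. Because printed summaries are rounded to two decimals, recomputed
statistics are compared at ±0.02.

## 2×4 repeated-measures ANOVA

The pre/post bias analysis is a mixed between-within ANOVA (four groups
between, two timepoints within), computed via pingouin's `mixed_anova` and
cross-checked in the tests against a brute-force sums-of-squares oracle.
With two within levels, sphericity holds trivially. Participants missing
either timepoint are dropped listwise with a log message.

## Longitudinal linear mixed model

For questionnaire totals y_it at assessments t = 0..3 (pre, post, 1-week,
3-month), with condition c (disgust = 0, neutral = 1) and stimuli s
(2D = 0, 3D = 1) dummy-coded:

```
y_it = β₀ + β₁t + β₂c + β₃s + β₄tc + β₅ts + β₆cs + β₇tcs
       + u₀ᵢ + u₁ᵢt + ε_it,    (u₀ᵢ,u₁ᵢ) ~ N(0, Σ),  ε ~ N(0, σ²)
```

fit by **maximum likelihood** (statsmodels MixedLM) so AIC and
likelihood-ratio comparisons across fixed-effect structures are valid;
REML is available for variance reporting but refuses AIC comparison.
Coding time 0..3 makes β₁ the change per successive assessment. Reduced
models (`time_only`, `main_effects`, `null`) support model comparison;
the pipeline's null reference is a genuine intercept-only model (random
intercept, no slope), so the pseudo-r² credits the full model for both
the mean time trend and slope heterogeneity.

Denominator df follow the **containment** convention: terms varying within
participants (anything involving time) are tested on
n_obs − n_participants − (#within terms) df, purely between-participant
terms on n_participants − (#between terms); a residual-df option exists,
and Satterthwaite-style df are deliberately not emulated. AIC is
−2·logLik + 2k with k = fixed effects + random-covariance parameters +
residual variance. If the ML estimate of Σ is boundary-singular
(correlation ±1 or a zero variance), the model is refit with uncorrelated
intercept and slope and the fallback recorded in the result's notes.

Nagelkerke's pseudo-r²: R²_CS = 1 − exp(2(L₀−L₁)/n),
R²_N = R²_CS / (1 − exp(2L₀/n)). n defaults to the number of score
observations entering the fit (configurable to participants; the
literature is not consistent). A full model with lower likelihood than
the null clamps to 0 with a warning.

## Synthetic-data generator

The generator emulates a 100-participant, four-arm trial: allocation
pseudorandomised in blocks of 4, 8 or 12 (each block balanced across the
four groups, sequence truncated at the target n, so group imbalance is
bounded by the last block's residual); 100 dot-probe trials per timepoint,
types balanced 50/50; four questionnaire assessments with 9%/7% missing
follow-ups.

**RTs.** Each participant draws a Gaussian-component mean
mu_i ~ N(600, 80²) ms and a latent bias b_i ~ N(group mean, 12²) ms shared
by both timepoints; trial RTs are ex-Gaussian — centre ± b_i/2 (congruent
−, incongruent +) plus N(0, 150²) plus Exp(150) — so the expected bias
index equals b_i exactly and symmetric cleaning cannot bias it. Errors
occur at 5%, and 2% of trials are replaced by uniform draws from
(2100, 5000) ms, above the absolute bound so contamination is filterable.
These defaults were chosen to land the *observed* pre-training bias SD
near 45 ms with split-half reliability in the 0.05–0.2 regime
characteristic of dot-probe bias indices; no RT distribution is published
for the design emulated here, so the ex-Gaussian (the standard
psychometric RT model) with round parameter values is an
arbitrary-but-plausible anchor, not an estimate.

**Scores.** Totals follow the mixed model above with defaults
β₀ = 67.56, β₁ = −4.57 (and the published small group terms), random SDs
tau₀ = 20, tau₁ = 5 (correlation −0.3), residual σ = 7, rounded and
clipped to the instrument range [0, 144]. tau₁ = 5 points/assessment makes
the random slope identifiable at n = 100 (smaller values drive the ML
covariance to the boundary) and matches a cohort where a third of
participants clear a ~14-point reliable-change band while half stay
unchanged. When item-level data are requested, each total is decomposed
into 48 item scores in {0..3} by largest-remainder allocation under
random gamma weights (dispersion parameter, default 1.0, giving
alpha ≈ 0.9); the decomposition conserves the total exactly. This is a
conservation device, not an item-response model — alpha values from it
are calibration checks only.

**What the generator does not emulate:** training effects on bias (the
design's point estimate of interest is null by construction), practice or
fatigue trends within a session, RT autocorrelation, item-level trait
structure, and informative missingness (follow-ups are missing completely
at random). Passing tests therefore demonstrate that the *machinery* is
calibrated and correct under the assumed data structure, not that any
substantive effect exists in real data.

## Problem sizes and determinism

Test and acceptance runs use 100–200 participant cohorts, 1000–5000
splits, 200 model-recovery refits and a 10 000-participant classification
null — sizes at which every Monte-Carlo check's sampling error is well
inside its tolerance while a full run stays around a minute. All
randomness flows from explicit seeds (numpy Generator); the pipeline
records a config hash and per-file SHA-256 digests, and re-running a
config reproduces identical digests.

## Known limitations

- Containment df are an approximation; packages using Satterthwaite or
  Kenward–Roger will print different t-test df for the same fit.
- The split-half engine assumes trials within a cell are exchangeable;
  sequential effects (fatigue, practice) would make first/second-half
  splits systematically different from random splits.
- Summary-statistics ANOVA inherits the rounding of its inputs; ±0.02 on
  the F statistic is the attainable agreement from 2-decimal tables.
- `MixedLM` occasionally reports non-convergence on near-boundary
  variance structures; results carry a `converged` flag and notes rather
  than silently failing.
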
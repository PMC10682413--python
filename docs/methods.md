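# Methods

This note documents the models, numerical choices, and synthetic-data
assumptions behind `pfcnet`. It covers what each stage computes, which
design decisions were genuinely open, and what the synthetic validation
does and does not demonstrate about real data.

## Study design being emulated

Three groups of male mice — unirradiated controls (n = 10 for
neurochemistry), an acute exposure group (n = 10), and a chronic
fractionated exposure group (n = 8; 49.9 cGy over 4 weeks × 6 days/week =
2.08 cGy/day) — are characterized on a within-session economic demand task
(n = 8/group), 15 sessions of a titrating vigilance task (n = 8/group),
and a K+-stimulation microdialysis session in the prefrontal cortex. The
perfusate steps through 4 (baseline), 30, 60, and 120 mM K+, 80 min per
block, one dialysate sample every 20 min — four samples per block, sixteen
per subject, for each of DA, 5-HT, NE, Glu, and GABA.

Time is indexed so the last baseline sample is t = 0; the downstream time
courses use that point plus the twelve post-baseline samples (13 points).
This convention is inferred from the shape of the reported time-course
ANOVA (error df 325 with 28 subjects implies 13 time points), since four
baseline samples are collected but only one baseline point is carried into
the analysis.

## Synthetic-cohort generator

Each subject × neurotransmitter series is

```
conc(t) = basal_mean × fold_vs_control × R(t) × exp(s·u − s²/2) × exp(z_t − v/2)
```

* `R(t)` — deterministic K+-response multiplier. Per block, a gamma-shaped
  kernel `shape(τ) = (τ/L)^(dL) · exp(dL·(1 − τ/L))` rises to its peak
  exactly at latency `L` (min) and decays like `exp(−dτ)`; its amplitude is
  the peak as percent of basal (100 = flat/abolished, 53 = a dip).
  Kernels from successive blocks superpose additively on the running
  percent-basal baseline, so slow responses bleed into later blocks.
* `u` — per-subject, per-NT standard-normal random effect with SD `s`
  (`subject_sd`, default 0.1 log units).
* `z_t` — a 5-dimensional lag-1 vector autoregression over the five
  neurotransmitters' log-deviations, `z_t = C_g z_{t−1} + ε_t`, with
  innovation SD `sqrt(log(1 + noise_cv²))` (default `noise_cv` 0.3) and a
  50-step burn-in so the first sample is already stationary. `C_g` is the
  group coupling matrix (spectral radius < 1 enforced).

Both lognormal factors are re-centered by half their (stationary) log
variance, so every factor has mean one: long-run sample means converge to
`basal_mean`, replicate CV equals `noise_cv` when the coupling is zero, and
group-mean fold-changes are unbiased.

Default group profiles encode the study's printed neurochemical features:
basal folds vs control DA 2.71 (acute) / 2.14 (chronic), 5-HT 1.75 / 1.96,
NE 1.60 (chronic); a control DA peak of 394% basal at the first 30 mM
sample; control GABA 515% and chronic GABA 957% late excursions at 120 mM;
a control Glu dip to 53% during 60 mM; and abolished (flat) DA responses in
both exposed groups. One printed value is deliberately not reproduced: a
chronic-DA cumulative fold of 1.69 at 120 mM is arithmetically incompatible
with a flat chronic DA response at basal fold 2.14 together with a ~293%
control peak (any rise-decay kernel forces the ratio below ~1.45); the
generator keeps the abolished response, which is the design's central DA
feature.

Default couplings: control is autocorrelated (diag 0.5) with one strong
symmetric Glu–GABA block (0.48 — strong enough that the across-subject
correlation of cumulative levels clears the r ≥ 0.5, p < 0.05 edge rule at
n = 10 in ~100% of seeds); acute adds symmetric monoamine coupling (0.22);
chronic zeroes DA's own lag and slaves DA to a correlated GABA/NE drive
(GABA→DA 1.32, NE→DA 1.28, GABA↔NE 0.45) with a weak residual Glu–GABA
link (0.15). The chronic coefficients were chosen by power pilots so that
an 8-subject group of 16-sample series yields median Granger p < 0.05 for
the two true drives in ≳90% of cohorts while the indirect Glu→DA route
stays quiet — deliberately strong coupling, because pairwise lag tests on
16 points have little power.

Demand generation draws Poisson counts around the exponential demand
model (k = 2 log units) with per-subject lognormal heterogeneity (SD 0.15)
on Q0 and α. Default means (Q0 50→150, α 4.5e-4→8.5e-5 across milk 0/5/20/
50%) give curves that retain ~90% of Q0 at the cheapest price and collapse
to single-digit counts at the most expensive — shapes under which the
5-point fit identifies both parameters. Vigilance agents have a latent
mean RT `asymptote + (initial − asymptote)·exp(−s/τ)` (controls 2.5 s
asymptote, τ = 3 sessions; exposed 3.5 s, τ = 5 — a ~1 s late-session
separation), lognormal trial RTs (CV 0.25), and a 5% per-trial lapse
probability; lapses respond after any finite limit and are
indistinguishable from slow misses, which is all the task itself can see.

What the generator does *not* emulate: pharmacokinetics of K+ diffusion or
probe recovery, metabolite chemistry, non-stationary drift within blocks,
heavy-tailed or autocorrelated behavioral noise, and any dose-rate physics.
Passing recovery tests therefore demonstrates that the estimators recover
the structure this generator plants at the study's n — not that the
biological effects themselves are identifiable from 16-point series in
general.

## Demand fitting

Fitting minimizes residuals of `log10(Q_obs + 0.1)` against
`log10(Q_model + 0.1)`; applying the 0.1 offset to both sides keeps zero
consumption representable and makes noiseless model data exactly
recoverable. Internally the search runs in log-parameter space (Q0 and α
differ by five orders of magnitude and share a mild ridge) with multistart
(α ∈ {1e-4…1e-1}, Q0 ∈ {max Q, 5·max Q}) and tolerances 1e-14. `k` is
either a fixed positive constant or "shared": one k estimated for the whole
dataset by profiling the pooled SS over k (coarse 32-point scan, then
bounded refinement — the profile need not be unimodal). Per-curve k is
deliberately not offered; with five points it is not identifiable apart
from α. Covariances treat k as fixed, so SEs condition on the shared range
constant, and DF = n_points − 2 accordingly. All-zero curves are rejected
(`rejected_zero`), as the model cannot represent them.

## Vigilance engine

Limits move on an exact ±0.25 s lattice (0.25 is a negative power of two,
so float arithmetic is exact), floored at 0.25 s, no ceiling; the final
limit of a session seeds the next. The titrated reaction time averages hit
RTs with the full limit on misses over all 48 trials. ITIs and stimulus
locations are sampled uniformly and logged but do not enter the metric.

## Statistics conventions

* Two-way ANOVAs (demand parameters, vigilance, time courses) are
  fixed-effects OLS ANOVAs with subjects as replicates, matching the
  reported error df (84, 315, 325); type-II sums of squares, which
  coincide with type-I on balanced designs; unbalanced input is computed
  and flagged. Constant data short-circuits to F = 0 with a
  `zero_variance` flag rather than 0/0.
* Group contrasts on cumulative levels use the classic pooled-variance
  unpaired two-tailed t (Welch available, off by default); two identical
  zero-variance groups return t = 0, p = 1 by convention.
* Tukey HSD is the only post-hoc; no correction is applied across
  neurotransmitters or pairs.
* Correlation p-values use the exact t transform with n − 2 df. The edge
  rule applies to signed r (strong negative correlations never form
  edges), and box-plot summaries use signed r; both were open questions
  resolved in favor of the literal threshold statement.

## iRF and iRF-LOOP

Round 1 is a plain `RandomForestRegressor` (so one-iteration iRF is
definitionally equivalent to a random forest, which the tests exploit as
an oracle). Later rounds implement importance-weighted feature selection
at per-tree granularity: each tree draws a bootstrap sample and a feature
subset of p draws with replacement with probabilities proportional to the
previous round's importances (plus a 1e-6 floor so features can re-enter),
and impurity importances are averaged over trees and renormalized. The
weighted-sampling contract, not scikit-learn's internals, is the normative
part. Defaults: 500 trees, 5 iterations, both config-exposed; the
repeated-seed recovery studies use 150 trees × 2 iterations, which pilots
showed lose almost no recovery rate at a fraction of the cost.

LOOP rows are per-sample records (4 per subject per K+ block, i.e. 32–40
rows per model) rather than per-subject aggregates: an 80/20 split of 8–10
subjects would be vacuous, while 32–40 rows make the held-out R² (recorded
as metadata, never an edge filter) meaningful. Importances per target are
normalized to sum 1 over the four source NTs, thresholded at 0.2 for
edges; signs come from the univariate OLS slope of target on source over
the block's rows (zero slope or constant source flags sign 0). Difference
networks take |importance_A − importance_B| per directed edge over
retained edges, 0 for absent ones.

## Granger causality

The SSR-based F statistic on nested OLS models, per lag m = 1..3:
`F = ((SSR_r − SSR_u)/m) / (SSR_u/(T_eff − 2m − 1))`, `T_eff = T − m`,
p from `F(m, T_eff − 2m − 1)` (verified against the standard VAR toolkit
implementation). With T = 16 and m = 3 the denominator df is 6, which is
as far as these series can be pushed; the minimum-length guard
`T ≥ 3·max_lag + 2` refuses anything shorter. Per-pair aggregation is the
minimum p over lags 1..3 (the common reading of a "max-lag" parameter); a
"lag-3 only" mode ships as an alternative. The tested series is the full
16-sample session in time order, levels uncorrected and untransformed.
Identical series raise a collinearity error; a perfectly interpolating
unrestricted model reports p = 0. Group decisions use the median of
per-subject aggregated p-values against α = 0.05. Note the min-over-lags
rule makes the per-pair null rejection rate ~0.1 rather than 0.05; the
type-I calibration study therefore pins the single-lag test, which is the
calibrated primitive.

## Pipeline

`run_pipeline` executes simulate → neurochem → {corrnet, irfnet, granger}
with demand and vigilance as independent branches; a failing stage halts
its dependents only. Every run writes a manifest (version, seed,
thresholds, per-stage status, output list). All randomness descends from
the single run seed through `SeedSequence`, so a rerun is byte-identical.
CSV schemas are validated on read with row-level error messages; group
labels are restricted to {control, acute, chronic} and neurotransmitter
labels to {DA, 5HT, NE, Glu, GABA} (serotonin loses its hyphen in files to
avoid parsing hazards).

## Validation studies and problem sizes

`pfcnet.studies` holds the repeated-seed experiments used by the test
suite and `scripts/acceptance.py`: demand parameter recovery (200 cohorts
of 8 subjects × 4 concentrations, Poisson noise, k fixed at the generating
value; median relative errors ~8% for Q0 and ~9–16% for α), Granger type-I
calibration (2,000 white-noise pairs, T = 40, lag 1) and power (500 seeds
of `B_t = A_{t−1}` + 1e-3 noise), and designed-coupling recovery for the
three network layers (100 seeds each). The coupling-recovery scenarios
generate with flat response kernels so the stochastic lag-1 channel is
isolated from the deterministic population kernels, which at 16 samples
would otherwise dominate the within-subject variance; this is a statement
about the recovery experiment's design, not a preprocessing step users
must apply. The end-to-end determinism check runs the full default cohort
with 60 trees × 2 iterations and fixed k = 2 to keep two complete pipeline
executions inside a few minutes.

## Known limitations

* Pairwise Granger tests on 16-point series have low power and no
  correction for the indirect-path confound; the negative-control check
  (Glu→DA) guards the designed scenario only.
* The iRF importance threshold of 0.2 sits just below the uniform
  importance (0.25) of a 4-source model, so targets with no real signal
  frequently carry near-uniform importances that hover around the
  threshold; difference networks inherit that instability.
* Repeated-measures structure is modeled with subjects as replicates
  (matching the reported df), not with a subject random effect; p-values
  for time-course effects are anti-conservative under within-subject
  correlation.
* The shared-k profile fit is quasi-global (coarse scan + local
  refinement), not certified global.
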
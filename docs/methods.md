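# Methods

`refcurve` estimates continuous, age-dependent reference intervals (RIs) and
percentile charts directly from routine laboratory measurements — a mixture
of non-pathological and pathological samples — without any manual selection
of healthy subjects or hand-tuning of smoothing parameters. This note
describes the statistical procedure, the choices that were genuinely open,
and what the synthetic-data experiments do and do not demonstrate.

## The four-step procedure

**Step 1 — overlapping age groups.** Conceptually one group per day of
life. The base width of the group at center day *c* is `max(1, 0.01·c)`
days (a half-day floor on the half-width), so temporal resolution is daily
through infancy and grows 1% of age thereafter. Consecutive base ranges are
tiled edge-to-edge, which thins the 6570 daily candidates (ages 0–18 y at
365 d/y) to roughly 500 groups; the exact count depends only on the width
rule and integer rounding, not on the data. Each group is then expanded
symmetrically — one day at a time, lower bound first, spilling to the other
side at the data's age boundary — until it contains at least `n_min = 1000`
samples. Samples are counted *after* per-subject deduplication: within a
group each subject keeps only the measurement whose age is closest to the
group center (ties: the younger sample), so `n_min` counts distinct
subjects. The minimal range under this schedule is found by exponential
search plus bisection on the step count, which is equivalent to stepping
one day at a time because the member count is monotone in the step count.

**Step 2 — indirect non-pathological model per group.** Each group's value
distribution is modeled as `np_fraction` × a one-parameter Box–Cox
transformed normal (skewness λ, location μ > 0, scale σ > 0, support (0,∞),
density renormalized by the positive-support mass `C = Φ(1/(σ|λ|))`). The
fit is a deterministic three-level grid search (coarse → twice refined)
over (λ, μ, σ, np_fraction) minimizing a histogram cost: squared count
discrepancies (normalized by `max(observed, 1)`) inside the *central
concentration region*, plus a one-sided penalty (weight 4) wherever the
model predicts more counts than observed outside that region, which keeps
the model inside the data rather than stretched over pathological tails.
The central region is the contiguous run of histogram bins around the mode
whose smoothed counts (5-bin moving average) stay above 10% of the modal
count. Binning is Freedman–Diaconis with a floor of 30 and cap of 300 bins.
Grid ranges: λ ∈ [−1, 1.5] (7 points), μ over the 10th–90th percentile of
the central region (13 points), σ log-spaced around the in-region log-SD
(11 points), np_fraction ∈ [0.5, 1] (11 points); each refinement recenters
with half-range 1.5 grid steps. This is a deliberately simple scheme in the
spirit of published indirect methods; the function boundary is plain so a
different indirect estimator can be swapped in. The shifted (two-parameter)
Box–Cox form is not implemented.

**Step 3 — probability weights.** For each group, the weight of a
concentration is

    P(conc) = min(1, max(0, D_np(conc) / D_total(conc)))

with `D_np = np_fraction · f_BCN` from step 2 and `D_total` a Gaussian KDE
(Silverman bandwidth) of the group's deduplicated values. The ratio is
evaluated on a 512-point grid spanning the group's data range, smoothed
along concentration with a Gaussian kernel of 2 grid steps (edge-replicated
convolution), clipped to [0, 1], and linearly interpolated to each
measurement. The ratio is defined as 0 where the KDE underflows to zero.
Because groups overlap, each measurement takes its single weight from the
group whose center is nearest its age (ties: younger center); groups whose
indirect fit failed propagate no weights and their measurements fall to the
next-nearest fitted group. Finally each weight is divided by the number of
samples its subject contributes to the whole dataset, which removes the
leverage of repeatedly sampled (often sicker) subjects. The absolute
scaling of `D_np` by the estimated non-pathological fraction is this
package's choice; the ratio needs an absolutely scaled numerator and the
mixture fraction is the natural scale.

**Step 4 — weighted GAMLSS.** The response follows a Box–Cox family —
BCCG (the LMS model), BCPE or BCT (kurtosis parameter τ) — whose parameters
are smooth curves over transformed age `u = log(age_days + 1)`. The log
transform concentrates resolution in the first weeks and months of life
where dynamics are fastest. Each curve is a cubic B-spline with 20 equally
spaced interior knots and a second-order difference penalty; μ, σ, τ use
log links, λ the identity. The fit maximizes

    Σᵢ wᵢ · log f(yᵢ | θ(uᵢ)) − ½ Σₖ penₖ ‖D cₖ‖²

jointly over all coefficient blocks by L-BFGS-B with eta-space central-
difference scores (step 1e-4) aggregated through the design matrix; up to
two jittered restarts (seeded) on failure. Because ages are integer days,
all age-dependent quantities are evaluated on the unique-age grid and
gathered, which makes the likelihood cost essentially independent of how
many measurements share an age. The τ predictor is clipped to ±8 on the
log scale (τ ≤ ~3000): beyond that the kurtosis families are numerically
their normal-kernel limits and the likelihood ridge is flat.

Smoothing strengths are selected per curve — one pass, in parameter order,
warm-started — over a 7-point logarithmic grid (10⁻²…10⁴) by minimizing

    BIC = −2 · (weighted log-likelihood) + (total effective df) · log(Σᵢ wᵢ)

with per-curve effective df `tr[(BᵀHB + pen·DᵀD)⁻¹ BᵀHB]`, where `H`
aggregates the weighted negative second derivatives of the log density with
respect to the linear predictor. The same BIC selects among the families;
ties break to fewer effective df, then BCCG < BCPE < BCT. The BCCG fit is
performed first and warm-starts the four-parameter families (τ starts at 2
for BCPE, 10 for BCT); those families keep the smoothing strengths selected
for the three shared curves and run the grid selection only for the τ
curve — the shared curves describe the same functions, and re-running
their selection per family triples the cost for no measurable change in
the selected model. `n_eff = Σ wᵢ` in the BIC is a definition this
package fixes: classical BIC is undefined under fractional weights.
Multiplying all weights by a constant c is equivalent to dividing all
penalties by c; with penalties scaled accordingly the fitted curves are
unchanged (tested), so only the weight *profile* matters, as it should.

Percentiles follow by inverting the family CDF at θ(u(age)); z-scores are
`Φ⁻¹(F(y | θ(u(age))))`, so the model's own 2.5th/97.5th percentiles map to
z = ∓1.96 by construction, and results at different ages become directly
comparable. Prediction outside the fitted age range raises an error —
spline extrapolation is never silent.

**Confidence bands.** Measurement-level resampling with replacement
(B = 100 by default); each replicate reruns steps 1–3 in full (subject
sample counts for the repeated-measurement correction are recomputed inside
the replicate) and refits step 4 for the family selected on the full data,
reusing its per-curve smoothing strengths and warm-starting from its
coefficients — a model-conditional bootstrap, which keeps B pipeline
executions tractable and is the standard practice when the band is meant to
describe the selected model. Replicate RNG streams derive from
`(seed, replicate_index)`, so runs are reproducible and order-insensitive;
failed replicates are dropped and counted (more than 50% failures aborts).
Per (age, percentile) cell the band is the central 95% of replicate values
(linear interpolation between order statistics); where the bootstrap
distribution is asymmetric enough to leave the point estimate outside, the
band is expanded to include it. Subject-level (clustered) resampling is
available as a design alternative but measurement-level is the default.

## Synthetic data: what it emulates, what it does not

`synthetic_data` draws datasets with known truth: closed-form parameter
curves λ*(a), μ*(a), σ*(a) for the clean component; a pathological
admixture (default 10%, capped at 40%) drawn from the same family with
μ × 1.8 and σ × 1.5 (one-sided high contamination, the typical pathological
pattern); ages from a 70/30 mixture of log-uniform and uniform over
[0, 6570] days, reproducing the strong neonatal overrepresentation of
routine pediatric data; and repeated samples per subject (60% singletons,
up to 5 samples, repeats clustered near the subject's base age). Three
scenarios are styled after pediatric analytes — `alp_like` (right-skewed,
infancy peak near day 100, pubertal peak near 13 y), `crea_like` (neonatal
fall, slow rise), `hb_like` (brief post-natal rise, fall to ~day 50,
pubertal step). The shapes are qualitative; the parameters are this
package's own and are not estimates of any real population.

Passing recovery tests on these scenarios shows the pipeline can undo a
known one-sided contamination and recover smooth truth curves through all
four stages. It does not show robustness to two-sided or age-correlated
pathology, analyzer changes or drift, preanalytical artifacts, mixed
in-/outpatient case-mix shifts, or contamination that mimics the
non-pathological shape — none of which the generator produces.

## Numerical choices and degenerate inputs

- Box–Cox z-transform uses the log-limit for |λ| < 1e-12; quantile
  inversion accounts for the positive-support constant, so cdf∘quantile is
  the identity to ~1e-8 across families.
- Histogram/grid fits and group construction are fully deterministic; the
  only randomness anywhere is the seeded optimizer jitter and the seeded
  bootstrap/generator streams.
- Groups with fewer than 100 members (underpowered) or zero variance raise
  a fitting error; in the pipeline such groups are skipped and logged, and
  their measurements fall to the nearest fitted group.
- A dataset smaller than `n_min` makes every group span all data, with a
  warning — the pipeline still runs but the "continuous" model is then
  effectively one group.
- Constant-age datasets collapse the spline basis to a single constant per
  curve and reproduce the one-dimensional maximum-likelihood fit.
- Initialization: μ-curve from a penalized LSQ fit to binned weighted
  medians, σ-curve from binned weighted quartile spreads on the log scale,
  λ flat at 1 (0 if the weighted skewness exceeds 2).
- Percentile tables are written with 12 significant digits and round-trip
  below 1e-9 relative error; model JSON serialization reloads to
  bit-identical predictions.

## Scale of the shipped experiments

The test suite's recovery study uses the `alp_like` scenario at n = 50,000
with 10% contamination and checks the median within 5% and the outer
percentiles within 10% on a 50-point age grid; the bootstrap study uses
n = 10,000 with B = 20 replicates; the coverage study uses n = 2,000 with
B = 50 and six outer Monte-Carlo repetitions of a fit-only bootstrap with
penalties scaled by n (coverage of the true median curve in [0.85, 1.0]
pooled over cells). The family-selection study draws from BCT(τ = 4) at
n = 6,000 with fixed smoothing and requires BCT to win the BIC comparison
in at least five of six seeded replicates. These problem sizes are the
package's chosen test scale; the pipeline itself has no size ceiling beyond
memory and patience (fitting scales roughly linearly in n for steps 1–3 and
with the number of distinct ages for step 4).

## Known limitations

- The indirect step is a simplified histogram-grid scheme, not a
  reimplementation of any published tool; with heavy (> 20–30%) or
  two-sided contamination its central-region heuristic can misplace the
  bulk.
- Only age is modeled; sex strata are run as fully separate pipelines, and
  no other covariates (gestational age, device, site) are supported.
- The bootstrap conditions on the selected family and smoothing strengths,
  so the bands do not carry model-selection uncertainty.
- No unit conversion or analyzer harmonization: inputs must already be on
  one measurement scale.
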
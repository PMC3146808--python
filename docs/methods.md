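# Methods

## The signature model

A pathway signature is a three-stage pipeline trained on a two-class
perturbation experiment with expression matrix `X` (probes × samples,
linear MAS5-like intensities) and binary labels `y` (0 = control,
1 = oncogene-perturbed).

**Probe selection.** Probes are scored by the pooled-variance two-sample
*t* statistic on log₂ data. The pooled SD receives an additive floor of
10⁻⁶ so a zero-variance probe yields a large but finite statistic rather
than NaN; ties are broken by probe ID so selection is deterministic.
Control probes (IDs with the `AFFX` prefix) are never eligible — they are
hybridization/degradation controls, not biology.

**Metagene factorization.** The selected log₂ sub-matrix is centered per
probe (means and SDs retained for test-sample normalization; the SD floor
is 10⁻⁸) and decomposed by a truncated SVD `X̃ = U D Vᵀ` of rank *k*
(default 3; *k* must not exceed the numerical rank, judged at
10⁻¹⁰ · d₁). Each column of `U` is sign-fixed so its largest-magnitude
element is positive, making the basis reproducible across linear-algebra
backends. Training factor scores are the rows of `D Vᵀ = Uᵀ X̃`.

**Bayesian probit regression.** Labels are regressed on factor scores
with the probit link under independent `Normal(0, prior_sd²)` priors
(default `prior_sd = 10`) on the intercept and coefficients. The
posterior is sampled with the Albert–Chib construction: latent
`zᵢ ~ N(α + βᵀfᵢ, 1)` truncated to `(0, ∞)` for label 1 and `(−∞, 0]`
for label 0, then a conjugate multivariate-normal coefficient draw.
Truncated-normal draws use survival-function inversion so they remain
exact arbitrarily far into the tails.

Two-class training data of the strength produced by engineered
overexpression is linearly separable in factor space, and the plain
Albert–Chib chain then mixes extremely slowly: the slope coefficient
random-walks across the likelihood plateau and the intercept drifts on a
timescale of thousands of sweeps. Each sweep therefore adds two marginal
data-augmentation moves, each an exact Gibbs step along a group orbit of
the prior-marginalized law of the latents `z ~ N(0, Σ)`,
`Σ = I + prior_sd² X Xᵀ`, restricted by the sign constraints:

* a **scale move** — `g² ~ S/χ²ₙ` with `S = zᵀΣ⁻¹z` under the Haar
  working prior, then `z ← z/g`;
* a **translation move** along the intercept direction — `z ← z + t·1`
  with `t` drawn from its normal conditional under `N(0, Σ)`, truncated
  to the interval in which no latent changes sign.

Both moves leave the exact posterior invariant; correctness is verified
against a two-dimensional quadrature of the exact posterior on a toy
problem (the quadrature grid must extend to ±60 — with a `N(0,10²)` prior
and separable data the posterior inherits the prior's tail and a ±20 grid
visibly truncates it). Defaults are 11,000 sweeps with 1,000 discarded as
burn-in; a Geweke diagnostic with autocorrelation-robust (batch-means)
standard errors warns — never fails — on suspicious chains. Because the
separable-direction coefficient still has a long autocorrelation time,
occasional flags on healthy chains are expected and are logged as QC
warnings.

**Prediction.** An investigational sample is normalized, projected
(`f = Uᵀ x̃`), and its activity probability is the posterior mean of
`Φ(α + βᵀ(f − f̄))` over the retained draws, with the 2.5/97.5 percentile
credible interval. Two normalization modes exist:

* `standardize` — per-probe log₂ z-score against the training statistics
  mapped back onto the training spread (algebraically: deviation from the
  training probe means). Appropriate when test arrays share the training
  arrays' intensity scale.
* `quantile` — the sample's signature-probe values are rank-mapped onto
  the pooled training distribution before centering and projection. This
  makes the projection invariant to any monotone distortion of the test
  sample and is the right choice for degraded or rescaled material.

Two design choices matter here. First, the probit is fit on training
factors **processed under the same normalization used at prediction
time**: rank-mapping is not an isometry of factor space (it shrinks
whichever class has the wider per-sample marginal), so a probit trained
on raw SVD factors would be miscalibrated for quantile-normalized test
samples. Second, the fit factors are centered at their grand mean
(`f̄`, stored in the signature) before regression — ordinary covariate
centering, which makes the zero-centered intercept prior symmetric with
respect to the two classes. For `standardize` mode the grand mean is
identically zero and both choices are no-ops.

Signatures serialize to a single versioned JSON document containing the
probe list, basis, posterior draws, training statistics and normalization
mode. A free-text protocol tag travels with the signature; predicting
samples tagged with a different protocol warns.

**Validation.** `leave_one_out` rebuilds the signature from scratch
(probe selection, SVD, probit refit) with each training sample held out
in turn and reports the held-out probability.

## The synthetic study

The generator reproduces the structure of a matched fresh-frozen/FFPE
pathway-prediction study with known ground truth. All randomness derives
from named substreams of a single universe seed, so training sets,
xenografts and patient lesions drawn from one configuration share probe
baselines and signature memberships, and every generator is a pure
function of its configuration.

**Biology.** Each probe has a log₂ baseline `~ N(7, 1)`. Each pathway
owns a disjoint set of signature probes (default 150); when the pathway
is active, half shift up and half shift down by `effect_size` (default
2.0 log₂) — an oncogenic program both induces and represses
transcription, and balanced signs are also what makes rank-based
normalization informative. Cell lines carry line-specific offsets
(`line_effect_sd = 0.15`), patients patient-specific offsets
(`patient_effect_sd = 0.4`), tumors replicate-level noise
(`replicate_noise_sd = 0.3`). Training sets default to 8 controls vs.
8 (RAS) or 6 (MYC) perturbed replicates; xenografts to 5 lines × 5
animals with both pathway states always represented across lines;
patients to 6, each with 3 fresh lesions plus 1 FFPE lesion derived from
the first lesion's underlying profile. The fresh-frozen profile is the
reference measurement of a tumor's underlying biology; a re-amplified
fresh-frozen copy re-draws only assay noise
(`reamplification_noise_sd = 0.15`), and the FFPE half degrades the same
underlying profile, so switching every degradation component off makes
the FFPE matrix equal its fresh partner exactly.

**Degradation model.** Applied in linear scale (additively in log₂), in
order:

1. *Fold-change compression* (`signal_compression = 0.6`): each sample's
   log₂ deviations from its own mean shrink — fragmented templates
   amplify with a flattened dynamic range. The distortion is linear per
   sample, hence removed by rank-based normalization.
2. *Probe-level attenuation*: one draw per probe from
   `N(1.5, 1²)` truncated at 0 (degradation never increases signal),
   shared across the batch — susceptibility is a property of the
   transcript/probe, which is why FFPE samples share a loss pattern and
   cluster together.
3. *Per-sample severity* (`sample_severity_sd = 0.25`, log₂): a lognormal
   multiplier on the attenuation pattern that also shifts the dropout
   log-odds (coefficient 1.5). Archival blocks differ in fixation time
   and age; severity reproduces the severalfold spread of percent-present
   and scaling factors seen within one real FFPE batch.
4. *Measurement noise* (`extra_noise_sd = 0.5` per cell).
5. *Detection-floor dropout*: each sample drops its severity-adjusted
   fraction (base `dropout_rate = 0.35`) of probes to background
   (`background_level = 30`, times a small lognormal jitter). Which
   probes drop is driven mostly by how weak the degraded signal is, plus
   a shared probe-level susceptibility and a little per-cell randomness —
   dropout is censoring at the detection floor, not uniform erasure.
6. *3′ bias*: two housekeeping control pairs (β-actin- and GAPDH-like)
   are always present; the members of a pair share one transcript-level
   attenuation draw and the 5′ member loses an extra
   `five_prime_extra_attenuation = 3.0` log₂, so the 3′/5′ ratio is
   centered on 2³ = 8 in geometric mean. Control probes never drop out
   (housekeeping transcripts stay detectable even in degraded RNA, which
   is what makes the ratio measurable).

**Calibration.** The degradation and line-effect parameters were
calibrated jointly — once, against the batch-level QC behavior of real
FFPE arrays (percent present far below fresh tissue with a severalfold
within-batch spread; all 3′/5′ ratios elevated; scaling factors several
times the fresh values) and against the whole-genome structure of matched
designs (re-amplified fresh pairs clearly more similar than unmatched;
fresh/FFPE matched pairs no more similar than unmatched; clustering
driven by preservation type). They are not tuned per analysis.

**What the generator does not emulate.** Probe-position-resolved
degradation, batch effects beyond the fresh/FFPE contrast, missing
values, cross-hybridization, graded (non-binary) pathway activity, and
any probe-level (PM/MM) structure. Passing tests on this generator show
the pipeline behaves correctly under the stated statistical model of
degradation; they cannot certify performance on real arrays, whose
degradation is sequence- and position-dependent.

## QC metrics

Percent present is the fraction of probes above a plain intensity
threshold (default 2× the degradation background, i.e. 60) — the
probe-pair Wilcoxon detection call needs PM/MM data that summarized
matrices do not carry, and the simple threshold preserves the metric's
comparative meaning. The scaling factor is `target / trimmed mean`
(target 500, symmetric 2% trim — the MAS5 convention). The distribution
summary is `log₂(percentile / scaling factor)` at the 5th, 25th, 50th,
75th and 95th percentiles, with linear interpolation between order
statistics; it is invariant under joint rescaling of sample and scaling
factor. Average background is an instrument-level quantity that cannot be
recomputed from summarized intensities and is not reported.

## Concordance analyses

Whole-genome Pearson correlations are computed on log₂ intensities over
all shared probes; matched coefficients are the declared pairs, unmatched
all remaining cross combinations (including same-line non-pairs).
The SD filter keeps the highest-SD probes (default 1000) of the log₂
matrix and then mean-centers genes and arrays in one pass (genes first,
then arrays); because centered values are no longer positive the result
is a plain data frame, not an expression matrix. Hierarchical clustering
uses the uncentered-correlation similarity `Σxy/√(Σx²Σy²)` and average
linkage (UPGMA, via scipy) on `1 − similarity` clipped to [0, 2], with
samples processed in lexicographic ID order for deterministic ties; merge
heights are monotone under average linkage. PCA scores come from the SVD
of the probe-centered log₂ matrix. Patient concordance compares each
patient's single FFPE probability with all fresh-lesion probabilities:
concordant iff the *minimum* absolute difference is ≤ 0.3 ("at least one
lesion agrees"); the mean difference is reported alongside because the
two summaries can disagree, and the rate is rounded to the nearest
integer percent (5/6 → 83%).

## Pipeline

`run_all` derives one sub-seed per stage by hashing the master seed with
the stage name (CRC-32, kept below 2³¹), so stages can be re-run
independently and a repeated run writes byte-identical artifacts.
The pipeline's generator default is the full U133A-2.0-sized probe
complement (22,277 probes plus the 4 controls): whole-genome correlation
and clustering depend on what fraction of the genome the signatures
occupy, and the scaled-down 2,000-probe default of the generator class —
convenient for unit tests — over-represents a 150-probe signature by an
order of magnitude in those analyses. Signature defaults for
investigational samples use quantile normalization, since the degraded
material is exactly the case rank normalization exists for. Logs
(stage timing, parameter echo, Geweke flags) go to standard error;
artifacts and the summary JSON contain no timestamps.

## Known limitations

* Detection-floor censoring biases surviving-cell class means: with
  default dropout, FFPE class separation on signature probes retains most
  — not all — of its compression-scaled value. This mirrors real
  detection censoring and is why predictions, not per-probe contrasts,
  are the unit of validation.
* Quantile normalization shrinks the factor scores of the class with the
  wider marginal; training-side normalization and factor centering
  compensate, but heavily degraded samples still land closer to the
  decision boundary than fresh ones, with correspondingly wider credible
  intervals.
* The probit's slope on separable training data is prior-limited; the
  posterior probability of a mid-range sample is sensitive to `prior_sd`.
* The concordance rule's minimum-difference definition is generous when a
  patient has many lesions; the mean difference is reported for that
  reason.
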
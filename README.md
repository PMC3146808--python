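# pathsig

Gene-expression signatures of oncogenic pathway activity (RAS, MYC) for
degraded, archival tumor material — with the QC and concordance machinery
needed to decide whether formalin-fixed, paraffin-embedded (FFPE) profiles
yield the same pathway calls as matched fresh-frozen tissue.

## Who this is for

Translational genomics groups who want to apply perturbation-trained
pathway signatures to archival FFPE tumor blocks. Whole-genome expression
from FFPE RNA is badly degraded — low percent-present calls, inflated
3′/5′ control ratios, large scaling factors, and whole-genome correlations
between matched fresh/FFPE halves of the *same tumor* no better than
between unrelated samples. The question this package operationalizes is
whether a *targeted, probabilistic* signature survives that degradation.

## The model

A signature is trained on a two-class perturbation experiment (control
replicates vs. cells overexpressing the oncogene):

1. **Probe selection.** Probes are ranked by the absolute pooled-variance
   two-sample *t* statistic on log₂ intensities; the top *N* (default 150,
   configurable to the 200/350/500 used in practice) form the signature.
2. **Metagene factors.** The selected log₂ sub-matrix is per-probe
   centered and factored by a truncated SVD, `X = U D Vᵀ`. The first *k*
   (default 3) left singular vectors are the metagenes; factor scores
   `f = Uᵀx̃` summarize any normalized sample.
3. **Bayesian probit regression.** Class labels follow
   `P(y = 1 | f) = Φ(α + βᵀf)` with independent `N(0, 10²)` priors on α
   and β. The posterior is sampled by the Albert–Chib latent-variable
   Gibbs sampler, accelerated with two marginal data-augmentation moves
   (a working rescaling of the latent vector and a sign-preserving
   intercept translation) that fix the slow mixing the plain chain
   suffers on linearly separable training data.

Prediction projects a normalized investigational sample onto the
metagenes and averages `Φ(α + βᵀf)` over the posterior draws: a posterior
probability of pathway activity with a credible interval. Two test
normalizations are provided — `standardize` (deviation from training probe
means; for same-platform, same-protocol samples) and `quantile`
(rank-mapping onto the pooled training distribution; invariant to any
monotone distortion, the right choice for degraded material).

A synthetic-data module emulates the full study with known ground truth:
training sets (8 GFP controls vs. 8 RAS / 6 MYC replicates), 5 melanoma
cell lines × 5 mice of paired fresh-frozen/FFPE xenografts, and 6
patients with several fresh lesions plus one FFPE lesion each, under a
parametric FFPE degradation model (fold-change compression, probe-level
attenuation, per-sample severity, detection-floor dropout, 3′-biased
control-probe loss).

## Worked example

Run the whole synthetic study — simulate, QC, signature building,
prediction, concordance — with one command:

```
$ pathsig run-all --seed 1 --outdir out/
RAS: FF/FFPE prediction r = 0.920 (p = 8.22e-11); patient concordance 83%
MYC: FF/FFPE prediction r = 0.975 (p = 1.97e-16); patient concordance 83%
```

The two lines summarize the punchline: predicted pathway probabilities of
matched fresh-frozen and FFPE xenograft halves correlate strongly (Pearson
r across the 25 pairs, with the two-sided p-value from the t
distribution), and for 5 of 6 synthetic patients the FFPE lesion's
probability lies within 0.3 of at least one fresh lesion (83%,
rounded to the nearest integer percent).

`out/summary.json` holds the machine-readable results. The whole-genome
block shows the contrast that motivates signature-level analysis: for
fresh-frozen pairs re-amplified by a second protocol, matched correlations
(mean 0.990) clearly exceed unmatched ones (0.885); for fresh/FFPE pairs
they collapse (0.465 vs. 0.416), and hierarchical clustering of the
SD-filtered data splits by preservation type rather than by tumor.
Per-sample QC tables (`out/qc_*.tsv`) report percent present, MAS5-style
scaling factor, β-actin- and GAPDH-like 3′/5′ ratios, and scaled log₂
percentile summaries:

```
sample_id   percent_present  scaling_factor  ratio_AFFX_ACTB_3_AFFX_ACTB_5 ...
FFPE_L1R1   28.05            9.63            8.00
FFPE_L1R2   38.00            8.19            9.84
```

Subcommands `simulate`, `qc`, `build-signature`, `predict` and
`concordance` expose each stage separately; `--config` accepts a YAML file
mirroring the generator, degradation and signature settings, and every
command is deterministic given `--seed`.

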
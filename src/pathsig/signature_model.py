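"""Pathway-activity signatures: metagene factors + Bayesian probit regression.

A signature is built from a two-class training set in three steps:

1. **Probe selection** — probes are ranked by the absolute pooled-variance
   two-sample t statistic on log2 intensities and the top ``n_probes`` kept.
2. **Metagene factorization** — the selected log2 sub-matrix is per-probe
   centered and decomposed by a truncated SVD, X = U D V'.  The first
   ``k`` left singular vectors define the metagenes; the factor scores
   D V' (equivalently U'X) summarize each sample.
3. **Bayesian probit regression** — class labels are regressed on the
   factor scores with a probit link, P(y=1 | f) = Phi(alpha + beta'f),
   under independent Normal(0, prior_sd^2) priors.  The posterior is
   sampled with the Albert–Chib latent-variable Gibbs sampler: truncated
   normal latent draws given coefficients, conjugate normal coefficient
   draws given latents.

Prediction projects a new, normalized sample onto the metagene basis and
averages Phi(alpha + beta'f) over the posterior draws, yielding a posterior
probability of pathway activity with a credible interval.

Two test-normalization modes are provided.  ``standardize`` expresses the
sample's signature probes as deviations from the training probe means
(z-scores mapped back onto the training spread) before projection; it is
appropriate when test arrays share the training arrays' intensity scale.
``quantile`` first maps the sample's signature-probe values, by rank, onto
the pooled training distribution, making the projection invariant to any
monotone distortion of the test sample — the right choice for degraded or
rescaled material such as FFPE extracts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import rankdata

from .core_data import ExpressionMatrix, TrainingDesign

__all__ = [
    "MetageneBasis",
    "ProbitPosterior",
    "Signature",
    "PathwayPrediction",
    "select_signature_probes",
    "compute_metagenes",
    "fit_probit",
    "build_signature",
    "project_samples",
    "predict",
    "leave_one_out",
    "signature_to_json",
    "signature_from_json",
    "save_signature",
    "load_signature",
]

_VARIANCE_FLOOR = 1e-6  # added to the pooled SD so zero-variance probes rank finite
_SD_FLOOR = 1e-8
_FORMAT_TAG = "pathsig.signature/1"
_CONTROL_PREFIX = "AFFX"  # hybridization/degradation controls, never signature members


@dataclass
class MetageneBasis:
    """Truncated SVD of the selected, centered training sub-matrix."""

    probe_subset: list[str]
    loadings: np.ndarray        # probes x k, orthonormal columns
    singular_values: np.ndarray  # k
    k: int
    training_factors: np.ndarray  # k x n_train (rows of D V')


@dataclass
class ProbitPosterior:
    """Post-burn-in Gibbs draws of (alpha, beta_1..beta_k)."""

    draws: np.ndarray  # M x (k+1), intercept first
    burn_in: int
    seed: int
    prior_sd: float


@dataclass
class Signature:
    pathway_name: str
    n_probes: int
    basis: MetageneBasis
    posterior: ProbitPosterior
    train_probe_means: np.ndarray
    train_probe_sds: np.ndarray
    train_pooled_sorted: np.ndarray  # sorted pooled training log2 values (quantile mode)
    #: normalization the probit was trained under; predictions default to it.
    #: Train and test samples must pass through the same normalization, so
    #: the regression is fit on training factors projected in this mode.
    normalization: str = "standardize"
    #: mean of the training factors under the fitting normalization;
    #: subtracted before the probit so the zero-centered coefficient prior
    #: is symmetric to both classes (covariate centering; identically zero
    #: for standardize mode)
    factor_center: Optional[np.ndarray] = None
    protocol: Optional[str] = None


@dataclass
class PathwayPrediction:
    sample_id: str
    probability: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# probe selection


def select_signature_probes(
    train: ExpressionMatrix, design: TrainingDesign, n_probes: int
) -> list[str]:
    """Top ``n_probes`` probes by |pooled-variance two-sample t| on log2 data.

    Ties are broken by probe ID.  Control probes (``AFFX`` prefix) are never
    selected.  Zero-variance probes get a small variance floor instead of NaN.
    """
    candidates = [p for p in train.probe_ids if not p.startswith(_CONTROL_PREFIX)]
    if n_probes > len(candidates):
        raise ValueError(
            f"n_probes={n_probes} exceeds {len(candidates)} selectable probes"
        )
    if len(design.control_ids) < 2 or len(design.perturbed_ids) < 2:
        raise ValueError("both classes need >= 2 samples")

    sub = train.subset_probes(candidates)
    log2 = np.log2(sub.values)
    col = {s: j for j, s in enumerate(train.sample_ids)}
    i0 = [col[s] for s in design.control_ids]
    i1 = [col[s] for s in design.perturbed_ids]
    x0, x1 = log2[:, i0], log2[:, i1]
    n0, n1 = len(i0), len(i1)
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    ss = x0.var(axis=1, ddof=1) * (n0 - 1) + x1.var(axis=1, ddof=1) * (n1 - 1)
    pooled_sd = np.sqrt(ss / (n0 + n1 - 2)) + _VARIANCE_FLOOR
    t = (m1 - m0) / (pooled_sd * np.sqrt(1.0 / n0 + 1.0 / n1))

    order = sorted(range(len(candidates)), key=lambda i: (-abs(t[i]), candidates[i]))
    return [candidates[i] for i in order[:n_probes]]


# ---------------------------------------------------------------------------
# metagenes


def compute_metagenes(
    centered: np.ndarray, probe_subset: Sequence[str], k: int
) -> MetageneBasis:
    """Rank-``k`` truncated SVD of a per-probe-centered log2 matrix.

    The sign of each loading column is fixed so its largest-magnitude
    element is positive, making the basis reproducible across linear-algebra
    backends.
    """
    centered = np.asarray(centered, dtype=float)
    if centered.shape[0] != len(probe_subset):
        raise ValueError("probe_subset length does not match matrix rows")
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size and s[0] > 0 else 0
    if k < 1 or k > rank:
        raise ValueError(f"k={k} exceeds effective rank {rank}")
    u, s, vt = u[:, :k], s[:k], vt[:k]
    for j in range(k):
        if u[np.argmax(np.abs(u[:, j])), j] < 0:
            u[:, j] = -u[:, j]
            vt[j] = -vt[j]
    factors = s[:, None] * vt  # k x n, equals U' X
    return MetageneBasis(list(probe_subset), u, s, k, factors)


# ---------------------------------------------------------------------------
# Albert–Chib Gibbs sampler


def _truncnorm_draw(mu: np.ndarray, positive: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Inverse-CDF draw of z ~ N(mu,1) truncated to (0,inf) where ``positive``
    else (-inf,0], numerically stable far into the tails."""
    t = np.empty_like(mu)
    # lower truncation at 0: survival-function inversion keeps precision
    pos = positive
    p_pos = np.maximum((1.0 - u[pos]) * ndtr(mu[pos]), 1e-300)
    t[pos] = -ndtri(p_pos)
    neg = ~positive
    p_neg = np.maximum(u[neg] * ndtr(-mu[neg]), 1e-300)
    t[neg] = ndtri(p_neg)
    return mu + t


def _truncnorm_scalar(mean: float, sd: float, lo: float, hi: float, u: float) -> float:
    """One draw from N(mean, sd^2) truncated to (lo, hi), tail-stable."""
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    if a > 0:  # work in the upper tail via symmetry
        return -_truncnorm_scalar(-mean, sd, -hi, -lo, 1.0 - u)
    pa, pb = ndtr(a), ndtr(b)
    p = max(pa + u * (pb - pa), 1e-300)
    return mean + sd * float(ndtri(min(p, 1.0 - 1e-16)))


def fit_probit(
    factors: np.ndarray,
    labels: np.ndarray,
    prior_sd: float = 10.0,
    n_iter: int = 11_000,
    burn_in: int = 1_000,
    seed: int = 0,
) -> ProbitPosterior:
    """Gibbs sampler for Bayesian probit regression of labels on factors.

    ``factors`` is k x n; the design matrix is [1, f'] per sample.  Latent
    variables z_i ~ N(alpha + beta'f_i, 1) are truncated to (0,inf) for
    label 1 and (-inf,0] for label 0; coefficients are redrawn from their
    conjugate normal full conditional under a Normal(0, prior_sd^2 I) prior.
    Two marginal data-augmentation moves (a working rescaling of the
    latent vector and a sign-preserving translation along the intercept
    direction, each drawn from its conditional under the marginal law of
    the latents) leave the posterior unchanged but break the slow random
    walks the plain chain suffers when the classes are linearly separable —
    the usual situation for a signature trained on strong perturbations.
    A Geweke diagnostic on each coefficient emits a warning (never a
    failure) when the chain looks unconverged.
    """
    factors = np.atleast_2d(np.asarray(factors, dtype=float))
    y = np.asarray(labels)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    n = y.size
    if factors.shape[1] != n:
        raise ValueError("factors and labels disagree on sample count")
    if n < 4 or y.sum() == 0 or y.sum() == n:
        raise ValueError("need >= 4 samples with both classes present")
    if burn_in >= n_iter:
        raise ValueError("burn_in must be < n_iter")

    X = np.column_stack([np.ones(n), factors.T])  # n x (k+1)
    d = X.shape[1]
    precision = X.T @ X + np.eye(d) / prior_sd**2
    V = np.linalg.inv(precision)
    L = np.linalg.cholesky(V)
    XtV = V @ X.T  # maps z -> posterior mean of coefficients
    # Sigma^-1 = I - X V X' is the precision of the prior-marginalized
    # latents; these quantities drive the augmentation moves
    u_vec = np.ones(n) - X @ (XtV @ np.ones(n))  # Sigma^-1 1
    q_scalar = float(u_vec.sum())  # 1' Sigma^-1 1

    rng = np.random.default_rng(int(seed) % (2**31))
    positive = y == 1
    beta = np.zeros(d)
    draws = np.empty((n_iter - burn_in, d))
    for it in range(n_iter):
        mu = X @ beta
        z = _truncnorm_draw(mu, positive, rng.random(n))
        # scale move: draw a working scale for z under the Haar working
        # prior (g^2 ~ S/chi^2_n with S the prior-marginalized residual)
        s = float(z @ z - z @ X @ XtV @ z)
        g2 = s / rng.chisquare(n)
        z = z / np.sqrt(g2)
        # translation move along the intercept direction, truncated so no
        # latent changes sign (a Gibbs step along the translation orbit of
        # the marginal law of z)
        t_mean = -float(u_vec @ z) / q_scalar
        t_sd = 1.0 / np.sqrt(q_scalar)
        lo = -z[positive].min() if positive.any() else -np.inf
        hi = -z[~positive].max() if (~positive).any() else np.inf
        z = z + _truncnorm_scalar(t_mean, t_sd, lo, hi, float(rng.random()))
        beta = XtV @ z + L @ rng.standard_normal(d)
        if it >= burn_in:
            draws[it - burn_in] = beta

    _geweke_warning(draws)
    return ProbitPosterior(draws, burn_in, int(seed), float(prior_sd))


def _batch_se(x: np.ndarray, n_batches: int = 20) -> np.ndarray:
    """Autocorrelation-robust MC standard error of the chain mean."""
    m = (x.shape[0] // n_batches) * n_batches
    bm = x[:m].reshape(n_batches, -1, *x.shape[1:]).mean(axis=1)
    return bm.std(axis=0, ddof=1) / np.sqrt(n_batches)


def _geweke_warning(draws: np.ndarray, z_threshold: float = 3.0) -> None:
    m = draws.shape[0]
    a = draws[: max(m // 10, 20)]
    b = draws[m // 2 :]
    se = np.sqrt(_batch_se(a, 10) ** 2 + _batch_se(b, 10) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(a.mean(axis=0) - b.mean(axis=0)) / np.where(se > 0, se, np.inf)
    if np.any(z > z_threshold):
        warnings.warn(
            f"Geweke diagnostic flags possible non-convergence (max |z|={z.max():.1f})",
            RuntimeWarning,
            stacklevel=3,
        )


# ---------------------------------------------------------------------------
# signature assembly / prediction


def build_signature(
    train: ExpressionMatrix,
    design: TrainingDesign,
    n_probes: int = 150,
    k: int = 3,
    prior_sd: float = 10.0,
    n_iter: int = 11_000,
    burn_in: int = 1_000,
    seed: int = 0,
    normalization: str = "standardize",
    protocol: Optional[str] = None,
) -> Signature:
    """Probe selection -> log2 -> per-probe centering -> SVD -> probit fit.

    The probit is fit on the training factors projected under the same
    ``normalization`` that will be applied to investigational samples (for
    ``standardize`` these are exactly the SVD factor scores D V').
    """
    probes = select_signature_probes(train, design, n_probes)
    ordered = train.subset_probes(probes).subset_samples(design.sample_ids)
    log2 = np.log2(ordered.values)
    means = log2.mean(axis=1)
    sds = np.maximum(log2.std(axis=1, ddof=1), _SD_FLOOR)
    basis = compute_metagenes(log2 - means[:, None], probes, k)
    sig = Signature(
        pathway_name=design.pathway_name,
        n_probes=n_probes,
        basis=basis,
        posterior=ProbitPosterior(np.zeros((1, k + 1)), 0, seed, prior_sd),
        train_probe_means=means,
        train_probe_sds=sds,
        train_pooled_sorted=np.sort(log2, axis=None),
        normalization=normalization,
        protocol=protocol,
    )
    fit_factors = project_samples(sig, ordered, normalization)
    sig.factor_center = fit_factors.mean(axis=1)
    sig.posterior = fit_probit(
        fit_factors - sig.factor_center[:, None],
        design.labels, prior_sd, n_iter, burn_in, seed,
    )
    return sig


def project_samples(
    sig: Signature, x: ExpressionMatrix, mode: str = "standardize"
) -> np.ndarray:
    """Factor scores (k x n) for each sample of ``x``.

    ``standardize``: log2, per-probe z-score against the training statistics
    mapped back onto the training spread (net effect: deviation from the
    training probe means), then project onto the loadings.
    ``quantile``: map each sample's signature-probe values, by rank, onto
    the pooled training distribution first — invariant to monotone
    distortions of the test sample.
    """
    missing = set(sig.basis.probe_subset) - set(x.probe_ids)
    if missing:
        raise KeyError(f"sample matrix is missing signature probes: {sorted(missing)[:10]}")
    sub = x.subset_probes(sig.basis.probe_subset)
    log2 = np.log2(sub.values)
    p = log2.shape[0]
    if mode == "standardize":
        z = (log2 - sig.train_probe_means[:, None]) / sig.train_probe_sds[:, None]
        tilde = z * sig.train_probe_sds[:, None]
    elif mode == "quantile":
        tilde = np.empty_like(log2)
        for j in range(log2.shape[1]):
            q = (rankdata(log2[:, j], method="average") - 0.5) / p
            mapped = np.quantile(sig.train_pooled_sorted, q, method="linear")
            tilde[:, j] = mapped - sig.train_probe_means
        return sig.basis.loadings.T @ tilde
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return sig.basis.loadings.T @ tilde


def predict(
    sig: Signature,
    x: ExpressionMatrix,
    mode: Optional[str] = None,
    protocol: Optional[str] = None,
) -> pd.DataFrame:
    """Posterior probability of pathway activity per sample of ``x``.

    ``mode`` defaults to the normalization the signature was trained under
    (overriding it mismatches the probit's factor space and warns).
    Returns a DataFrame indexed by sample with columns ``probability``
    (posterior mean of Phi(alpha + beta'f)), ``ci_low`` and ``ci_high``
    (2.5/97.5 posterior percentiles).
    """
    if protocol is not None and sig.protocol is not None and protocol != sig.protocol:
        warnings.warn(
            f"signature was trained on protocol {sig.protocol!r} but is applied "
            f"to {protocol!r} samples",
            RuntimeWarning,
            stacklevel=2,
        )
    if mode is None:
        mode = sig.normalization
    elif mode != sig.normalization:
        warnings.warn(
            f"predicting with {mode!r} normalization but the signature was "
            f"trained under {sig.normalization!r}",
            RuntimeWarning,
            stacklevel=2,
        )
    f = project_samples(sig, x, mode)
    if sig.factor_center is not None:
        f = f - sig.factor_center[:, None]
    design = np.vstack([np.ones(f.shape[1]), f])  # (k+1) x n
    eta = sig.posterior.draws @ design  # M x n
    phi = ndtr(eta)
    prob = phi.mean(axis=0)
    lo, hi = np.percentile(phi, [2.5, 97.5], axis=0)
    prob = np.clip(prob, lo, hi)
    return pd.DataFrame(
        {"probability": prob, "ci_low": lo, "ci_high": hi},
        index=pd.Index(x.sample_ids, name="sample_id"),
    )


def leave_one_out(
    train: ExpressionMatrix,
    design: TrainingDesign,
    n_probes: int = 150,
    k: int = 3,
    prior_sd: float = 10.0,
    n_iter: int = 11_000,
    burn_in: int = 1_000,
    seed: int = 0,
    normalization: str = "standardize",
) -> pd.Series:
    """Leave-one-out probabilities: each training sample predicted by a
    signature rebuilt (probe selection, SVD and probit refit) without it."""
    if len(design.sample_ids) < 5:
        raise ValueError("need at least 5 training samples for leave-one-out")
    out = {}
    for held in design.sample_ids:
        ctrl = [s for s in design.control_ids if s != held]
        pert = [s for s in design.perturbed_ids if s != held]
        fold_design = TrainingDesign(design.pathway_name, ctrl, pert)
        fold_train = train.subset_samples(fold_design.sample_ids)
        sig = build_signature(
            fold_train, fold_design, n_probes, k, prior_sd, n_iter, burn_in, seed,
            normalization=normalization,
        )
        pred = predict(sig, train.subset_samples([held]))
        out[held] = float(pred["probability"].iloc[0])
    return pd.Series(out, name="loo_probability")


# ---------------------------------------------------------------------------
# serialization


def signature_to_json(sig: Signature) -> str:
    doc = {
        "format": _FORMAT_TAG,
        "pathway_name": sig.pathway_name,
        "n_probes": sig.n_probes,
        "normalization": sig.normalization,
        "protocol": sig.protocol,
        "basis": {
            "probe_subset": sig.basis.probe_subset,
            "loadings": sig.basis.loadings.tolist(),
            "singular_values": sig.basis.singular_values.tolist(),
            "k": sig.basis.k,
            "training_factors": sig.basis.training_factors.tolist(),
        },
        "posterior": {
            "draws": sig.posterior.draws.tolist(),
            "burn_in": sig.posterior.burn_in,
            "seed": sig.posterior.seed,
            "prior_sd": sig.posterior.prior_sd,
        },
        "factor_center": None if sig.factor_center is None else sig.factor_center.tolist(),
        "train_probe_means": sig.train_probe_means.tolist(),
        "train_probe_sds": sig.train_probe_sds.tolist(),
        "train_pooled_sorted": sig.train_pooled_sorted.tolist(),
    }
    return json.dumps(doc)


def signature_from_json(text: str) -> Signature:
    doc = json.loads(text)
    if doc.get("format") != _FORMAT_TAG:
        raise ValueError(f"unrecognized signature format {doc.get('format')!r}")
    basis = MetageneBasis(
        probe_subset=list(doc["basis"]["probe_subset"]),
        loadings=np.array(doc["basis"]["loadings"]),
        singular_values=np.array(doc["basis"]["singular_values"]),
        k=int(doc["basis"]["k"]),
        training_factors=np.array(doc["basis"]["training_factors"]),
    )
    posterior = ProbitPosterior(
        draws=np.array(doc["posterior"]["draws"]),
        burn_in=int(doc["posterior"]["burn_in"]),
        seed=int(doc["posterior"]["seed"]),
        prior_sd=float(doc["posterior"]["prior_sd"]),
    )
    return Signature(
        pathway_name=doc["pathway_name"],
        n_probes=int(doc["n_probes"]),
        basis=basis,
        posterior=posterior,
        train_probe_means=np.array(doc["train_probe_means"]),
        train_probe_sds=np.array(doc["train_probe_sds"]),
        train_pooled_sorted=np.array(doc["train_pooled_sorted"]),
        normalization=doc.get("normalization", "standardize"),
        factor_center=(
            None if doc.get("factor_center") is None else np.array(doc["factor_center"])
        ),
        protocol=doc.get("protocol"),
    )


def save_signature(sig: Signature, path: str | Path) -> None:
    Path(path).write_text(signature_to_json(sig))


def load_signature(path: str | Path) -> Signature:
    return signature_from_json(Path(path).read_text())
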
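"""Comparison machinery for matched sample sets.

Covers the whole-genome and prediction-level comparisons used to judge
whether archival (FFPE) material carries the same information as matched
fresh-frozen tissue: matched vs. unmatched Pearson correlations, SD-filtered
mean-centered hierarchical clustering with the uncentered-correlation
metric and average linkage, PCA, probability scatter correlation with a
p-value, and the per-patient concordance rule (FFPE prediction within a
threshold of at least one fresh lesion's prediction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from .core_data import ExpressionMatrix

__all__ = [
    "ConcordanceResult",
    "PatientConcordance",
    "DendrogramNode",
    "pearson_with_pvalue",
    "matched_unmatched",
    "sd_filter_and_center",
    "hierarchical_cluster",
    "pca_scores",
    "patient_concordance",
]

MatrixLike = Union[ExpressionMatrix, pd.DataFrame]


@dataclass
class ConcordanceResult:
    """Matched and unmatched whole-genome correlation coefficients."""

    matched_r: pd.Series    # indexed by pair_id
    unmatched_r: pd.Series  # indexed by (sample_a, sample_b)

    @property
    def matched_mean(self) -> float:
        return float(self.matched_r.mean())

    @property
    def matched_range(self) -> tuple[float, float]:
        return float(self.matched_r.min()), float(self.matched_r.max())

    @property
    def unmatched_mean(self) -> float:
        return float(self.unmatched_r.mean())

    @property
    def unmatched_range(self) -> tuple[float, float]:
        return float(self.unmatched_r.min()), float(self.unmatched_r.max())


@dataclass
class PatientConcordance:
    """Per-patient FF/FFPE prediction agreement under the min-difference rule."""

    table: pd.DataFrame  # per patient: min_abs_diff, mean_abs_diff, concordant
    threshold: float

    @property
    def concordance_rate(self) -> int:
        """Percent of concordant patients, rounded to the nearest integer."""
        return int(round(100.0 * self.table["concordant"].mean()))

    @property
    def average_difference(self) -> float:
        return float(self.table["mean_abs_diff"].mean())

    @property
    def difference_range(self) -> tuple[float, float]:
        col = self.table["mean_abs_diff"]
        return float(col.min()), float(col.max())


@dataclass
class DendrogramNode:
    """Binary dendrogram; ``height`` is 1 - similarity at the merge."""

    height: float
    children: Optional[tuple["DendrogramNode", "DendrogramNode"]] = None
    leaf_id: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf_id is not None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.leaf_id]
        return self.children[0].leaves() + self.children[1].leaves()

    def to_newick(self) -> str:
        def fmt(node: DendrogramNode, parent_height: float) -> str:
            length = max(parent_height - node.height, 0.0)
            if node.is_leaf:
                return f"{node.leaf_id}:{length:.6g}"
            left = fmt(node.children[0], node.height)
            right = fmt(node.children[1], node.height)
            return f"({left},{right}):{length:.6g}"

        if self.is_leaf:
            return f"{self.leaf_id};"
        left = fmt(self.children[0], self.height)
        right = fmt(self.children[1], self.height)
        return f"({left},{right});"


def pearson_with_pvalue(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r and the two-sided p-value from the t distribution with
    n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("vectors must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def matched_unmatched(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    pairing: Mapping[str, tuple[str, str]],
    log_scale: bool = True,
) -> ConcordanceResult:
    """Pearson correlations over all shared probes: within declared pairs
    versus every other cross combination.

    ``pairing`` maps pair_id -> (sample in a, sample in b).  Correlations
    are computed on log2 intensities (the scale of every visualization in
    this field) unless ``log_scale`` is False.
    """
    if set(a.probe_ids) != set(b.probe_ids) or a.probe_ids != b.probe_ids:
        raise ValueError("matrices must be probe-aligned (use align_matrices)")
    for pid, (sa, sb) in pairing.items():
        if sa not in a.sample_ids or sb not in b.sample_ids:
            raise ValueError(f"pair {pid!r} references unknown samples ({sa!r}, {sb!r})")

    va = np.log2(a.values) if log_scale else a.values
    vb = np.log2(b.values) if log_scale else b.values
    na, nb = a.n_samples, b.n_samples
    za = (va - va.mean(axis=0)) / va.std(axis=0)
    zb = (vb - vb.mean(axis=0)) / vb.std(axis=0)
    corr = za.T @ zb / va.shape[0]  # na x nb Pearson matrix

    ia = {s: i for i, s in enumerate(a.sample_ids)}
    ib = {s: i for i, s in enumerate(b.sample_ids)}
    matched_cells = {(ia[sa], ib[sb]): pid for pid, (sa, sb) in pairing.items()}

    matched = pd.Series(
        {pid: corr[i, j] for (i, j), pid in matched_cells.items()}, name="matched_r"
    ).sort_index()
    unmatched = {}
    for i in range(na):
        for j in range(nb):
            if (i, j) not in matched_cells:
                unmatched[(a.sample_ids[i], b.sample_ids[j])] = corr[i, j]
    return ConcordanceResult(matched, pd.Series(unmatched, name="unmatched_r").sort_index())


def sd_filter_and_center(x: ExpressionMatrix, n_keep: int = 1000) -> pd.DataFrame:
    """Keep the ``n_keep`` highest-SD probes of the log2 matrix, then mean
    center genes and arrays in a single pass (genes first, then arrays).

    Returns a centered log2 DataFrame (no longer strictly positive, so not
    an :class:`ExpressionMatrix`).
    """
    if n_keep > x.n_probes:
        raise ValueError(f"n_keep={n_keep} exceeds {x.n_probes} probes")
    log2 = x.log2()
    sd = log2.std(axis=1, ddof=1)
    order = sorted(x.probe_ids, key=lambda p: (-sd[p], p))
    kept = log2.loc[order[:n_keep]]
    centered = kept.sub(kept.mean(axis=1), axis=0)
    return centered.sub(centered.mean(axis=0), axis=1)


def _uncentered_corr_matrix(v: np.ndarray) -> np.ndarray:
    norms = np.sqrt((v**2).sum(axis=0))
    if np.any(norms == 0):
        raise ValueError("all-zero sample vector")
    unit = v / norms
    return unit.T @ unit


def hierarchical_cluster(x: MatrixLike) -> DendrogramNode:
    """Average-linkage (UPGMA) clustering of samples under the uncentered
    correlation similarity; merge height is 1 - similarity.

    Samples are processed in lexicographic ID order so ties resolve
    deterministically.
    """
    df = x.to_frame() if isinstance(x, ExpressionMatrix) else x
    df = df[sorted(df.columns)]
    if df.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sim = _uncentered_corr_matrix(df.to_numpy(dtype=float))
    dist = np.clip(1.0 - sim, 0.0, 2.0)
    condensed = dist[np.triu_indices_from(dist, k=1)]
    Z = hierarchy.linkage(condensed, method="average")

    nodes: list[DendrogramNode] = [
        DendrogramNode(0.0, leaf_id=s) for s in df.columns
    ]
    for left, right, height, _ in Z:
        nodes.append(
            DendrogramNode(float(height), children=(nodes[int(left)], nodes[int(right)]))
        )
    return nodes[-1]


def pca_scores(
    x: MatrixLike, n_components: int = 2, log_scale: bool = True
) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores and variance-explained fractions from the SVD of the
    probe-centered (log2) matrix."""
    df = x.to_frame() if isinstance(x, ExpressionMatrix) else x
    v = df.to_numpy(dtype=float)
    if log_scale and isinstance(x, ExpressionMatrix):
        v = np.log2(v)
    if n_components > min(v.shape):
        raise ValueError("n_components exceeds matrix dimensions")
    centered = v - v.mean(axis=1, keepdims=True)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    total = float((s**2).sum())
    frac = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    scores = pd.DataFrame(
        (s[:n_components, None] * vt[:n_components]).T,
        index=df.columns,
        columns=[f"PC{i+1}" for i in range(n_components)],
    )
    return scores, frac


def patient_concordance(
    predictions_ff: Mapping[str, Sequence[float]],
    predictions_ffpe: Mapping[str, float],
    threshold: float = 0.3,
) -> PatientConcordance:
    """Per-patient agreement between the FFPE prediction and the fresh
    lesions' predictions.

    A patient is concordant when the FFPE probability is within
    ``threshold`` of **at least one** fresh-frozen lesion (the minimum
    absolute difference rule); the mean absolute difference is reported
    alongside.  The summary rate is rounded to the nearest integer percent.
    """
    rows = {}
    for patient, ffpe_p in predictions_ffpe.items():
        lesions = np.asarray(list(predictions_ff.get(patient, [])), dtype=float)
        if lesions.size == 0:
            raise ValueError(f"patient {patient!r} has no fresh-frozen lesion predictions")
        diffs = np.abs(lesions - float(ffpe_p))
        rows[patient] = {
            "min_abs_diff": float(diffs.min()),
            "mean_abs_diff": float(diffs.mean()),
            "concordant": bool(diffs.min() <= threshold),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient"
    return PatientConcordance(table.sort_index(), float(threshold))
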
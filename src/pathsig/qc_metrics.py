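"""Array-quality metrics for linear-scale expression profiles.

Per-sample metrics mirror the standard Affymetrix quality report: percent
present (fraction of probes above a detection threshold), MAS5-style scaling
factor (target over trimmed mean), 3'/5' control-probe ratios, and the
scaled log2 percentile summary used for signal-distribution box plots.

The detection call is a plain intensity threshold rather than the
probe-pair Wilcoxon test, since only summarized probe-set intensities are
in scope; the metric keeps its comparative meaning (degraded arrays call
fewer probes present).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core_data import ExpressionMatrix

__all__ = [
    "QCReport",
    "percent_present",
    "scaling_factor",
    "three_five_ratio",
    "distribution_summary",
    "qc_report",
    "DEFAULT_SCALING_TARGET",
    "DEFAULT_TRIM",
    "PERCENTILES",
]

DEFAULT_SCALING_TARGET = 500.0
DEFAULT_TRIM = 0.02
PERCENTILES = (5, 25, 50, 75, 95)


@dataclass
class QCReport:
    """Per-sample QC table plus the control pairs it was computed with."""

    table: pd.DataFrame  # one row per sample
    threshold: float
    scaling_target: float
    control_pairs: tuple[tuple[str, str], ...]


def percent_present(x: ExpressionMatrix, threshold: float) -> pd.Series:
    """Percent of probes with intensity strictly above ``threshold``, per sample."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    frac = (x.values > threshold).mean(axis=0) * 100.0
    return pd.Series(frac, index=x.sample_ids, name="percent_present")


def scaling_factor(
    sample: np.ndarray,
    target: float = DEFAULT_SCALING_TARGET,
    trim: float = DEFAULT_TRIM,
) -> float:
    """MAS5-style scaling factor: ``target`` / symmetric-trimmed mean.

    The lowest and highest ``trim`` fractions of intensities are discarded
    before averaging (defaults: 2% each side, target 500).
    """
    v = np.asarray(sample, dtype=float)
    if not 0 <= trim < 0.5:
        raise ValueError("trim must be in [0, 0.5)")
    if target <= 0:
        raise ValueError("target must be > 0")
    if v.size < 10:
        raise ValueError("need at least 10 intensities")
    k = int(np.floor(trim * v.size))
    v = np.sort(v)
    trimmed = v[k : v.size - k] if k > 0 else v
    if trimmed.size == 0:
        raise ValueError("no intensities left after trimming")
    return float(target / trimmed.mean())


def three_five_ratio(
    x: ExpressionMatrix, pair: tuple[str, str]
) -> pd.Series:
    """Per-sample ratio of the 3' control probe over its 5' partner."""
    p3, p5 = pair
    probe_index = {p: i for i, p in enumerate(x.probe_ids)}
    for p in pair:
        if p not in probe_index:
            raise KeyError(f"control probe {p!r} not in matrix")
    ratio = x.values[probe_index[p3]] / x.values[probe_index[p5]]
    return pd.Series(ratio, index=x.sample_ids, name=f"ratio_{p3}_{p5}")


def distribution_summary(
    sample: np.ndarray,
    scaling_factor: float,
    percentiles: Sequence[float] = PERCENTILES,
) -> np.ndarray:
    """log2(percentile / scaling factor) at the 5/25/50/75/95th percentiles.

    Percentiles use linear interpolation between order statistics.  Jointly
    rescaling the sample and the scaling factor leaves the summary unchanged.
    """
    if scaling_factor <= 0:
        raise ValueError("scaling_factor must be > 0")
    q = np.percentile(np.asarray(sample, dtype=float), percentiles, method="linear")
    return np.log2(q / scaling_factor)


def qc_report(
    x: ExpressionMatrix,
    control_pairs: Sequence[tuple[str, str]],
    threshold: float,
    scaling_target: float = DEFAULT_SCALING_TARGET,
    trim: float = DEFAULT_TRIM,
) -> QCReport:
    """Full QC table: one row per sample, Table-style column semantics."""
    pp = percent_present(x, threshold)
    rows = {}
    sf = np.array([scaling_factor(x.values[:, j], scaling_target, trim) for j in range(x.n_samples)])
    rows["percent_present"] = pp.to_numpy()
    rows["scaling_factor"] = sf
    for pair in control_pairs:
        rows[f"ratio_{pair[0]}_{pair[1]}"] = three_five_ratio(x, pair).to_numpy()
    summaries = np.array(
        [distribution_summary(x.values[:, j], sf[j]) for j in range(x.n_samples)]
    )
    for i, p in enumerate(PERCENTILES):
        rows[f"log2_scaled_p{p}"] = summaries[:, i]
    table = pd.DataFrame(rows, index=pd.Index(x.sample_ids, name="sample_id"))
    return QCReport(table, threshold, scaling_target, tuple(tuple(p) for p in control_pairs))
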
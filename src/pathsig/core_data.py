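"""Shared data containers and text I/O for probe-level expression data.

Expression values live on the linear (MAS5-like) intensity scale, probes in
rows and samples in columns.  Log2 transforms are applied transiently inside
the analyses that need them; nothing here ever stores logged data.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "TrainingDesign",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "align_matrices",
]

PRESERVATIONS = ("fresh_frozen", "ffpe", "cell_line")


def _first_duplicate(items: Sequence[str]) -> Optional[str]:
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass
class ExpressionMatrix:
    """Probes x samples matrix of strictly positive linear-scale intensities."""

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        dup = _first_duplicate(self.probe_ids)
        if dup is not None:
            raise ValueError(f"duplicate probe ID: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise ValueError(f"duplicate sample ID: {dup!r}")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite intensity at probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if np.any(self.values <= 0):
            i, j = np.argwhere(self.values <= 0)[0]
            raise ValueError(
                f"non-positive intensity {self.values[i, j]!r} at probe "
                f"{self.probe_ids[i]!r}, sample {self.sample_ids[j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def log2(self) -> pd.DataFrame:
        """Transient log2 view used by the analyses (never stored)."""
        return pd.DataFrame(
            np.log2(self.values), index=self.probe_ids, columns=self.sample_ids
        )

    def subset_probes(self, probes: Sequence[str]) -> "ExpressionMatrix":
        idx = {p: i for i, p in enumerate(self.probe_ids)}
        missing = [p for p in probes if p not in idx]
        if missing:
            raise KeyError(f"probes not in matrix: {missing[:10]}")
        rows = [idx[p] for p in probes]
        return ExpressionMatrix(list(probes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in idx]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        cols = [idx[s] for s in samples]
        return ExpressionMatrix(list(self.probe_ids), list(samples), self.values[:, cols])

    def sample_vector(self, sample_id: str) -> np.ndarray:
        try:
            j = self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"sample {sample_id!r} not in matrix") from None
        return self.values[:, j]


@dataclass
class SampleAnnotation:
    """Per-sample metadata: class label, grouping, FF/FFPE pairing."""

    sample_id: str
    class_label: Optional[int] = None
    group_id: Optional[str] = None
    pair_id: Optional[str] = None
    preservation: str = "cell_line"

    def __post_init__(self) -> None:
        if self.class_label is not None and self.class_label not in (0, 1):
            raise ValueError(f"class_label must be 0/1, got {self.class_label!r}")
        if self.preservation not in PRESERVATIONS:
            raise ValueError(
                f"preservation must be one of {PRESERVATIONS}, got {self.preservation!r}"
            )


def validate_pairing(annotations: Sequence[SampleAnnotation]) -> dict[str, tuple[str, str]]:
    """Resolve pair_ids to (fresh_frozen, ffpe) sample tuples, or raise."""
    pairs: dict[str, dict[str, str]] = {}
    for ann in annotations:
        if ann.pair_id is None:
            continue
        slot = pairs.setdefault(ann.pair_id, {})
        if ann.preservation not in ("fresh_frozen", "ffpe"):
            raise ValueError(
                f"pair member {ann.sample_id!r} has preservation {ann.preservation!r}"
            )
        if ann.preservation in slot:
            raise ValueError(
                f"pair {ann.pair_id!r} has two {ann.preservation} members"
            )
        slot[ann.preservation] = ann.sample_id
    out = {}
    for pid, slot in pairs.items():
        if set(slot) != {"fresh_frozen", "ffpe"}:
            raise ValueError(f"pair {pid!r} is incomplete: has {sorted(slot)}")
        out[pid] = (slot["fresh_frozen"], slot["ffpe"])
    return out


@dataclass
class TrainingDesign:
    """Two-class training layout for one pathway: controls vs perturbed."""

    pathway_name: str
    control_ids: list[str] = field(default_factory=list)
    perturbed_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.control_ids or not self.perturbed_ids:
            raise ValueError("both control and perturbed classes must be non-empty")
        overlap = set(self.control_ids) & set(self.perturbed_ids)
        if overlap:
            raise ValueError(f"samples in both classes: {sorted(overlap)[:5]}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.control_ids) + list(self.perturbed_ids)

    @property
    def labels(self) -> np.ndarray:
        return np.array([0] * len(self.control_ids) + [1] * len(self.perturbed_ids))


# ---------------------------------------------------------------------------
# text I/O


def read_expression_matrix(path: str | Path | io.IOBase) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column probe IDs, header sample IDs).

    Rejects duplicate IDs and non-positive or non-numeric cells with a message
    naming the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    dup = _first_duplicate(list(df.index))
    if dup is not None:
        raise ValueError(f"duplicate probe ID in file: {dup!r}")
    dup = _first_duplicate(list(df.columns))
    if dup is not None:
        raise ValueError(f"duplicate sample ID in file: {dup!r}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            probe = df.index[bad.to_numpy().argmax()]
            raise ValueError(
                f"non-numeric or missing value at probe {probe!r}, sample {col!r}"
            )
        df[col] = converted
    return ExpressionMatrix.from_frame(df)


def write_expression_matrix(x: ExpressionMatrix, path: str | Path) -> None:
    """Write TSV at full double precision (shortest round-trip repr)."""
    df = x.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t")


_ANNOT_COLS = ["sample_id", "class_label", "group_id", "pair_id", "preservation"]


def read_annotations(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        out.append(
            SampleAnnotation(
                sample_id=row["sample_id"],
                class_label=int(row["class_label"]) if row["class_label"] != "" else None,
                group_id=row["group_id"] or None,
                pair_id=row["pair_id"] or None,
                preservation=row["preservation"],
            )
        )
    validate_pairing(out)
    return out


def write_annotations(annotations: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for ann in annotations:
        rows.append(
            {
                "sample_id": ann.sample_id,
                "class_label": "" if ann.class_label is None else str(ann.class_label),
                "group_id": ann.group_id or "",
                "pair_id": ann.pair_id or "",
                "preservation": ann.preservation,
            }
        )
    pd.DataFrame(rows, columns=_ANNOT_COLS).to_csv(path, sep="\t", index=False)


def align_matrices(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict both matrices to their common probes, in a's probe order."""
    in_b = set(b.probe_ids)
    common = [p for p in a.probe_ids if p in in_b]
    if len(common) < 2:
        raise ValueError(
            f"matrices share only {len(common)} probe(s); need at least 2"
        )
    return a.subset_probes(common), b.subset_probes(common)
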
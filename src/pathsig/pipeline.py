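"""End-to-end orchestration: simulate -> QC -> signatures -> predict -> concordance.

A single :class:`RunConfig` (optionally loaded from YAML) drives the whole
synthetic study.  Every stage's randomness is seeded from the master seed by
hashing the stage name, so stages are independently reproducible and a rerun
with the same config writes byte-identical artifacts.
"""

from __future__ import annotations

import json
import sys
import time
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import concordance_analysis as ca
from . import qc_metrics as qc
from . import signature_model as sm
from . import synthetic_data as sd
from .core_data import (
    ExpressionMatrix,
    validate_pairing,
    write_annotations,
    write_expression_matrix,
)

__all__ = [
    "SignatureSettings",
    "RunConfig",
    "derive_seed",
    "load_run_config",
    "run_all",
]


def derive_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (< 2**31)."""
    return zlib.crc32(f"{master_seed}:{stage}".encode()) % (2**31)


@dataclass
class SignatureSettings:
    n_probes: int = 150
    k: int = 3
    prior_sd: float = 10.0
    n_iter: int = 11_000
    burn_in: int = 1_000
    #: normalization for investigational (non-training) samples; quantile is
    #: the default because degraded material needs rank-based normalization
    normalization: str = "quantile"


def _default_generator() -> sd.GeneratorConfig:
    # full U133A-2.0-sized probe complement, so whole-genome correlation and
    # clustering reflect platform-realistic signal proportions
    return sd.GeneratorConfig(n_probes=22_277)


@dataclass
class RunConfig:
    generator: sd.GeneratorConfig = field(default_factory=_default_generator)
    degradation: sd.DegradationConfig = field(default_factory=sd.DegradationConfig)
    signature: dict[str, SignatureSettings] = field(
        default_factory=lambda: {p: SignatureSettings() for p in sd.DEFAULT_PATHWAYS}
    )
    concordance_threshold: float = 0.3
    sd_filter: int = 1000
    present_threshold: Optional[float] = None  # default: 2 x degradation background
    master_seed: int = 0

    def resolved_present_threshold(self) -> float:
        if self.present_threshold is not None:
            return float(self.present_threshold)
        return 2.0 * self.degradation.background_level


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML document mirroring the dataclass fields."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig()
    if "generator" in doc:
        cfg.generator = sd.GeneratorConfig(**doc["generator"])
    if "degradation" in doc:
        cfg.degradation = sd.DegradationConfig(**doc["degradation"])
    if "signature" in doc:
        cfg.signature = {
            pathway: SignatureSettings(**settings)
            for pathway, settings in doc["signature"].items()
        }
    for key in ("concordance_threshold", "sd_filter", "present_threshold", "master_seed"):
        if key in doc:
            setattr(cfg, key, doc[key])
    return cfg


def _log(stage: str, message: str) -> None:
    ts = time.strftime("%H:%M:%S")
    print(f"[{ts}] {stage}: {message}", file=sys.stderr)


def _qc_ranges(report: qc.QCReport) -> dict:
    out = {}
    for col in report.table.columns:
        out[col] = [float(report.table[col].min()), float(report.table[col].max())]
    return out


def _round(x: float, digits: int = 10) -> float:
    return float(round(float(x), digits))


def run_all(config: RunConfig, outdir: str | Path) -> dict:
    """Run the full synthetic study and write all artifacts under ``outdir``.

    Returns the machine-readable summary (also written to ``summary.json``):
    whole-genome matched/unmatched correlations, per-pathway FF/FFPE
    prediction correlations with p-values, patient concordance rates, and
    per-batch QC ranges.  Identical configs produce byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        gen = sd.GeneratorConfig(**{**asdict(config.generator),
                                    "seed": derive_seed(config.master_seed, "generator")})
        degr = sd.DegradationConfig(**{**asdict(config.degradation),
                                       "seed": derive_seed(config.master_seed, "degradation")})
        threshold = config.resolved_present_threshold()
        summary: dict = {
            "format": "pathsig.summary/1",
            "master_seed": config.master_seed,
            "present_threshold": threshold,
        }

        stage = "simulate"
        _log(stage, f"generating synthetic study (seed {gen.seed})")
        training = {}
        for pathway in config.signature:
            training[pathway] = sd.generate_training_set(gen, pathway)
        xeno = sd.generate_xenograft_pairs(gen, degr)
        patients = sd.generate_patient_lesions(gen, degr)

        for pathway, (matrix, design, _) in training.items():
            write_expression_matrix(matrix, outdir / f"training_{pathway}.tsv")
        write_expression_matrix(xeno.ff, outdir / "xenograft_ff.tsv")
        write_expression_matrix(xeno.ffpe, outdir / "xenograft_ffpe.tsv")
        write_expression_matrix(xeno.ff_reamplified, outdir / "xenograft_ff_reamplified.tsv")
        write_expression_matrix(patients.ff, outdir / "patient_ff.tsv")
        write_expression_matrix(patients.ffpe, outdir / "patient_ffpe.tsv")
        write_annotations(xeno.annotations, outdir / "xenograft_annotations.tsv")
        write_annotations(patients.annotations, outdir / "patient_annotations.tsv")
        truth_rows = []
        merged_truth = xeno.truth.merge(patients.truth)
        for pathway, acts in sorted(merged_truth.activity.items()):
            for sample, val in sorted(acts.items()):
                truth_rows.append({"sample_id": sample, "pathway": pathway, "activity": val})
        pd.DataFrame(truth_rows).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)

        stage = "qc"
        _log(stage, "computing QC reports")
        qc_summary = {}
        batches = {
            "xenograft_ff": xeno.ff,
            "xenograft_ffpe": xeno.ffpe,
            "patient_ff": patients.ff,
            "patient_ffpe": patients.ffpe,
        }
        for pathway, (matrix, _, _) in training.items():
            batches[f"training_{pathway}"] = matrix
        for name, matrix in sorted(batches.items()):
            report = qc.qc_report(matrix, sd.CONTROL_PAIRS, threshold)
            report.table.to_csv(outdir / f"qc_{name}.tsv", sep="\t", float_format="%.10g")
            qc_summary[name] = _qc_ranges(report)
        summary["qc_ranges"] = qc_summary

        stage = "signatures"
        signatures = {}
        for pathway, settings in config.signature.items():
            matrix, design, _ = training[pathway]
            _log(stage, f"building {pathway} signature ({settings.n_probes} probes, k={settings.k})")
            sig = sm.build_signature(
                matrix,
                design,
                n_probes=settings.n_probes,
                k=settings.k,
                prior_sd=settings.prior_sd,
                n_iter=settings.n_iter,
                burn_in=settings.burn_in,
                seed=derive_seed(config.master_seed, f"mcmc:{pathway}"),
                normalization=settings.normalization,
            )
            sm.save_signature(sig, outdir / f"signature_{pathway}.json")
            signatures[pathway] = (sig, settings)

        stage = "predict"
        _log(stage, "predicting pathway activity")
        predictions: dict[str, dict[str, pd.DataFrame]] = {}
        for pathway, (sig, settings) in signatures.items():
            preds = {
                "xenograft_ff": sm.predict(sig, xeno.ff),
                "xenograft_ffpe": sm.predict(sig, xeno.ffpe),
                "patient_ff": sm.predict(sig, patients.ff),
                "patient_ffpe": sm.predict(sig, patients.ffpe),
            }
            predictions[pathway] = preds
            for name, df in sorted(preds.items()):
                df.to_csv(
                    outdir / f"predictions_{pathway}_{name}.tsv",
                    sep="\t",
                    float_format="%.10g",
                )

        stage = "concordance"
        _log(stage, "whole-genome and prediction concordance")
        identity_pairs = {
            s: (s, f"{s}_re") for s in xeno.ff.sample_ids
        }
        reamp = ca.matched_unmatched(xeno.ff, xeno.ff_reamplified, identity_pairs)
        xeno_pairs = validate_pairing(xeno.annotations)
        ff_ffpe = ca.matched_unmatched(xeno.ff, xeno.ffpe, xeno_pairs)
        summary["whole_genome"] = {
            "ff_vs_reamplified": {
                "matched_mean": _round(reamp.matched_mean),
                "matched_range": [_round(v) for v in reamp.matched_range],
                "unmatched_mean": _round(reamp.unmatched_mean),
                "unmatched_range": [_round(v) for v in reamp.unmatched_range],
            },
            "ff_vs_ffpe": {
                "matched_mean": _round(ff_ffpe.matched_mean),
                "matched_range": [_round(v) for v in ff_ffpe.matched_range],
                "unmatched_mean": _round(ff_ffpe.unmatched_mean),
                "unmatched_range": [_round(v) for v in ff_ffpe.unmatched_range],
            },
        }
        pd.concat(
            [reamp.matched_r.rename("r"), ff_ffpe.matched_r.rename("r")],
            keys=["ff_vs_reamplified", "ff_vs_ffpe"],
        ).to_csv(outdir / "matched_correlations.tsv", sep="\t", float_format="%.10g")

        combined = ExpressionMatrix(
            list(xeno.ff.probe_ids),
            list(xeno.ff.sample_ids) + list(xeno.ffpe.sample_ids),
            np.hstack([xeno.ff.values, xeno.ffpe.values]),
        )
        filtered = ca.sd_filter_and_center(combined, min(config.sd_filter, combined.n_probes))
        tree = ca.hierarchical_cluster(filtered)
        (outdir / "xenograft_dendrogram.nwk").write_text(tree.to_newick() + "\n")
        left, right = (set(c.leaves()) for c in tree.children)
        ff_set = set(xeno.ff.sample_ids)
        summary["clustering"] = {
            "root_split_matches_preservation": bool(
                left == ff_set or right == ff_set
            )
        }
        scores, frac = ca.pca_scores(combined, n_components=2)
        scores.to_csv(outdir / "xenograft_pca_scores.tsv", sep="\t", float_format="%.10g")
        summary["pca_variance_fractions"] = [_round(v) for v in frac]

        pred_summary = {}
        patient_summary = {}
        patient_pairs = validate_pairing(patients.annotations)
        for pathway, preds in predictions.items():
            ff_p = preds["xenograft_ff"]["probability"]
            ffpe_p = preds["xenograft_ffpe"]["probability"]
            paired = [(ff_p[sa], ffpe_p[sb]) for sa, sb in xeno_pairs.values()]
            r, p = ca.pearson_with_pvalue(*zip(*paired))
            pred_summary[pathway] = {"ff_ffpe_r": _round(r), "ff_ffpe_p": float(p)}

            by_patient: dict[str, list[float]] = {}
            for ann in patients.annotations:
                if ann.preservation == "fresh_frozen":
                    by_patient.setdefault(ann.group_id, []).append(
                        float(preds["patient_ff"]["probability"][ann.sample_id])
                    )
            ffpe_by_patient = {}
            for ann in patients.annotations:
                if ann.preservation == "ffpe":
                    ffpe_by_patient[ann.group_id] = float(
                        preds["patient_ffpe"]["probability"][ann.sample_id]
                    )
            pc = ca.patient_concordance(
                by_patient, ffpe_by_patient, config.concordance_threshold
            )
            pc.table.to_csv(
                outdir / f"patient_concordance_{pathway}.tsv",
                sep="\t",
                float_format="%.10g",
            )
            patient_summary[pathway] = {
                "rate_percent": pc.concordance_rate,
                "average_difference": _round(pc.average_difference),
                "difference_range": [_round(v) for v in pc.difference_range],
            }
        summary["predictions"] = pred_summary
        summary["patient_concordance"] = patient_summary

        stage = "summary"
        text = json.dumps(summary, sort_keys=True, indent=2)
        (outdir / "summary.json").write_text(text + "\n")
        _log(stage, f"wrote {outdir / 'summary.json'}")
        return summary
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
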
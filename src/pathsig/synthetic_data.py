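"""Synthetic expression data with known pathway ground truth.

Emulates the three study designs the pipeline is exercised on:

* two-class training sets — control replicates vs. oncogene-perturbed
  replicates (defaults: 8 GFP controls vs. 8 RAS / 6 MYC),
* paired fresh-frozen / FFPE xenografts — 5 cell lines x 5 replicates,
  each tumor split into a fresh-frozen half and an FFPE half sharing the
  same underlying biology,
* patient lesion sets — several lesions per patient sharing one latent
  pathway status, plus one FFPE lesion per patient.

Expression is generated additively in log2 space (probe baseline + pathway
effect + line/patient effect + replicate noise + assay noise) and exported
on the linear scale.  FFPE degradation is multiplicative in linear scale:
probe-specific random attenuation shared across samples of a batch, extra
per-measurement noise, and random dropout to background.  Two 3'/5' control
probe pairs (beta-actin- and GAPDH-like) are always included; the 5' member
of each pair receives additional attenuation, emulating the 3'-bias of
reverse transcription on fragmented RNA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core_data import ExpressionMatrix, SampleAnnotation, TrainingDesign

__all__ = [
    "GeneratorConfig",
    "DegradationConfig",
    "GroundTruth",
    "XenograftPairs",
    "PatientLesions",
    "CONTROL_PAIRS",
    "DEFAULT_PATHWAYS",
    "generate_training_set",
    "generate_xenograft_pairs",
    "apply_ffpe_degradation",
    "generate_patient_lesions",
]

#: 3'/5' control probe pairs always present in generated matrices,
#: as (3' probe, 5' probe).  Modeled on the AFFX beta-actin / GAPDH controls.
CONTROL_PAIRS: tuple[tuple[str, str], ...] = (
    ("AFFX_ACTB_3", "AFFX_ACTB_5"),
    ("AFFX_GAPDH_3", "AFFX_GAPDH_5"),
)

# High-abundance housekeeping baselines (log2).  3' slightly above 5' so
# intact-RNA ratios sit in the 1-2 range typical of good arrays.
_CONTROL_BASELINES = {
    "AFFX_ACTB_3": 10.0,
    "AFFX_ACTB_5": 9.5,
    "AFFX_GAPDH_3": 9.8,
    "AFFX_GAPDH_5": 9.6,
}

DEFAULT_PATHWAYS: tuple[str, ...] = ("RAS", "MYC")

# Default perturbed-replicate counts per pathway (controls default to 8).
_DEFAULT_PERTURBED = {"RAS": 8, "MYC": 6}

# log2 SD of the positive jitter applied to dropped-out probes around the
# background level.
_DROPOUT_JITTER_SD = 0.25

# How strongly per-sample degradation severity shifts the dropout log-odds.
_DROPOUT_SEVERITY_COEF = 1.5

# Weights of the dropout-propensity score.  Dropout is censoring at the
# detection floor, so it is driven mostly by how weak the degraded signal is
# (intensity), plus a probe-level susceptibility shared across samples
# (fragmentation is a property of the transcript/probe position) and a
# little per-cell randomness.
_DROPOUT_W_INTENSITY = 0.8
_DROPOUT_W_PROBE = 0.5
_DROPOUT_W_CELL = 0.33


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic biology/assay model.

    All noise terms are SDs in log2 units.  ``seed`` fixes the whole
    generated universe: probe baselines, signature memberships, and every
    sample drawn from the same config are reproducible.
    """

    n_probes: int = 2000
    n_signature_probes_per_pathway: int = 150
    effect_size: float = 2.0
    base_log2_mean: float = 7.0
    base_log2_sd: float = 1.0
    replicate_noise_sd: float = 0.3
    reamplification_noise_sd: float = 0.15
    #: SD of cell-line-specific expression offsets.  Lines from one tissue
    #: differ modestly relative to probe-to-probe baseline spread; the value
    #: is calibrated so whole-genome structure collapses under default
    #: degradation while remaining detectable in fresh-frozen data.
    line_effect_sd: float = 0.15
    #: SD of patient-specific offsets (distinct tumors differ more than
    #: replicate xenografts of one line).
    patient_effect_sd: float = 0.4
    seed: int = 0

    def validate(self, n_pathways: int = len(DEFAULT_PATHWAYS)) -> None:
        if self.n_probes < 10:
            raise ValueError("n_probes must be >= 10")
        if self.n_signature_probes_per_pathway < 1:
            raise ValueError("n_signature_probes_per_pathway must be >= 1")
        if self.n_signature_probes_per_pathway * n_pathways > self.n_probes:
            raise ValueError(
                "signature probes across pathways exceed n_probes "
                f"({self.n_signature_probes_per_pathway} x {n_pathways} > {self.n_probes})"
            )
        for name in (
            "base_log2_sd",
            "replicate_noise_sd",
            "reamplification_noise_sd",
            "line_effect_sd",
            "patient_effect_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class DegradationConfig:
    """Parametric FFPE degradation model (all attenuations in log2 units)."""

    attenuation_log2_mean: float = 1.5
    attenuation_log2_sd: float = 1.0
    dropout_rate: float = 0.35
    background_level: float = 30.0
    extra_noise_sd: float = 0.5
    five_prime_extra_attenuation: float = 3.0
    #: log2 SD of per-sample degradation severity.  Archival blocks differ in
    #: fixation time and age, so one batch spans a wide quality range; each
    #: sample's severity multiplies its probe-level attenuation and shifts its
    #: dropout odds.  Calibrated so one simulated FFPE batch spans the
    #: severalfold percent-present and scaling-factor ranges typical of real
    #: FFPE array batches.
    sample_severity_sd: float = 0.25
    #: fraction of log2 fold-change retained after amplification of degraded
    #: RNA (1.0 = none lost).  Fragmented templates compress fold-changes —
    #: a monotone, per-sample-linear distortion in log2 space — which is why
    #: rank-based test normalization is needed for archival material.
    signal_compression: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError("dropout_rate must be in [0, 1]")
        if self.background_level <= 0:
            raise ValueError("background_level must be > 0")
        if self.attenuation_log2_sd < 0 or self.extra_noise_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.sample_severity_sd < 0:
            raise ValueError("sample_severity_sd must be >= 0")
        if not 0.0 < self.signal_compression <= 1.0:
            raise ValueError("signal_compression must be in (0, 1]")


@dataclass
class GroundTruth:
    """Latent truth of a generated dataset.

    ``activity[pathway][sample_id]`` is the binary pathway status;
    ``signature_probes[pathway]`` lists the probes carrying that pathway's
    expression program.
    """

    activity: dict[str, dict[str, int]] = field(default_factory=dict)
    signature_probes: dict[str, list[str]] = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(
            {p: dict(v) for p, v in self.activity.items()},
            {p: list(v) for p, v in self.signature_probes.items()},
        )
        for p, v in other.activity.items():
            out.activity.setdefault(p, {}).update(v)
        for p, v in other.signature_probes.items():
            out.signature_probes[p] = list(v)
        return out


@dataclass
class XenograftPairs:
    """Matched fresh-frozen / FFPE xenograft profiles plus a second
    fresh-frozen assay replicate (re-amplification of the same RNA)."""

    ff: ExpressionMatrix
    ffpe: ExpressionMatrix
    ff_reamplified: ExpressionMatrix
    annotations: list[SampleAnnotation]
    truth: GroundTruth
    dropout_mask: np.ndarray  # probes x ffpe-samples, True where dropped


@dataclass
class PatientLesions:
    ff: ExpressionMatrix
    ffpe: ExpressionMatrix
    annotations: list[SampleAnnotation]
    truth: GroundTruth


# ---------------------------------------------------------------------------
# universe helpers (deterministic functions of GeneratorConfig.seed)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), int(stream)])


def _probe_ids(config: GeneratorConfig) -> list[str]:
    width = max(5, len(str(config.n_probes)))
    ids = [f"P{i:0{width}d}" for i in range(config.n_probes)]
    for p3, p5 in CONTROL_PAIRS:
        ids.extend([p3, p5])
    return ids


def _probe_baselines(config: GeneratorConfig) -> np.ndarray:
    """log2 baseline per probe (regular probes random, controls fixed)."""
    rng = _rng(config.seed, 1)
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, config.n_probes)
    ctrl = [_CONTROL_BASELINES[p] for pair in CONTROL_PAIRS for p in pair]
    return np.concatenate([base, np.array(ctrl)])


def _pathway_index(pathway: str) -> int:
    if pathway in DEFAULT_PATHWAYS:
        return DEFAULT_PATHWAYS.index(pathway)
    # stable slot for ad-hoc pathway names, after the default ones
    import zlib

    return len(DEFAULT_PATHWAYS) + zlib.crc32(pathway.encode()) % 97


def signature_probe_ids(config: GeneratorConfig, pathway: str) -> list[str]:
    """The probes carrying ``pathway``'s program (disjoint across pathways)."""
    m = config.n_signature_probes_per_pathway
    idx = _pathway_index(pathway)
    if (idx + 1) * m > config.n_probes:
        raise ValueError(
            f"pathway slot {idx} needs {(idx + 1) * m} probes, have {config.n_probes}"
        )
    order = _rng(config.seed, 2).permutation(config.n_probes)
    width = max(5, len(str(config.n_probes)))
    return [f"P{i:0{width}d}" for i in sorted(order[idx * m : (idx + 1) * m])]


def _effect_vector(config: GeneratorConfig, pathway: str) -> np.ndarray:
    """Per-probe log2 shift applied when ``pathway`` is active.

    An oncogenic program both induces and represses transcription, so half
    the signature probes shift up by ``effect_size`` and half shift down
    (balanced signs, assigned reproducibly from the universe seed).
    """
    ids = _probe_ids(config)
    members = signature_probe_ids(config, pathway)
    m = len(members)
    signs = np.ones(m)
    signs[m // 2 :] = -1.0
    signs = _rng(config.seed, 1000 + _pathway_index(pathway)).permutation(signs)
    shift = {p: config.effect_size * s for p, s in zip(members, signs)}
    return np.array([shift.get(p, 0.0) for p in ids])


def _replicate_profiles(
    baseline_log2: np.ndarray,
    activities: Sequence[dict[str, int]],
    effects: dict[str, np.ndarray],
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stack per-sample log2 profiles: baseline + active effects + noise."""
    cols = []
    for act in activities:
        mu = baseline_log2.copy()
        for pathway, on in act.items():
            if on:
                mu = mu + effects[pathway]
        cols.append(mu + rng.normal(0.0, noise_sd, baseline_log2.size))
    return np.column_stack(cols)


# ---------------------------------------------------------------------------
# generators


def generate_training_set(
    config: GeneratorConfig,
    pathway: str,
    n_control: int = 8,
    n_perturbed: Optional[int] = None,
) -> tuple[ExpressionMatrix, TrainingDesign, GroundTruth]:
    """Two-class training set: control replicates vs. pathway-perturbed ones.

    Defaults follow the study design: 8 controls, 8 perturbed for RAS and
    6 for MYC.  Perturbed samples have the pathway's signature probes
    shifted by ``effect_size`` log2 units.
    """
    config.validate()
    if n_perturbed is None:
        n_perturbed = _DEFAULT_PERTURBED.get(pathway, 8)
    if n_control < 2 or n_perturbed < 2:
        raise ValueError("need at least 2 replicates per class")

    ids = _probe_ids(config)
    baseline = _probe_baselines(config)
    effects = {pathway: _effect_vector(config, pathway)}
    rng = _rng(config.seed, 2000 + _pathway_index(pathway))

    control_ids = [f"TRN_{pathway}_CTRL_{i+1}" for i in range(n_control)]
    perturbed_ids = [f"TRN_{pathway}_{pathway}_{i+1}" for i in range(n_perturbed)]
    activities = [{pathway: 0}] * n_control + [{pathway: 1}] * n_perturbed
    log2 = _replicate_profiles(baseline, activities, effects, config.replicate_noise_sd, rng)

    matrix = ExpressionMatrix(ids, control_ids + perturbed_ids, 2.0**log2)
    design = TrainingDesign(pathway, control_ids, perturbed_ids)
    truth = GroundTruth(
        activity={pathway: {s: a[pathway] for s, a in zip(matrix.sample_ids, activities)}},
        signature_probes={pathway: signature_probe_ids(config, pathway)},
    )
    return matrix, design, truth


def _balanced_assignment(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random binary vector with both classes present (as balanced as n allows)."""
    v = np.zeros(n, dtype=int)
    v[: n // 2 + n % 2] = 1
    return rng.permutation(v) if n > 1 else np.ones(1, dtype=int)


def apply_ffpe_degradation(
    x: ExpressionMatrix,
    degr: DegradationConfig,
    control_pairs: Sequence[tuple[str, str]] = CONTROL_PAIRS,
    return_mask: bool = False,
):
    """Degrade a linear-scale matrix the way formalin fixation degrades RNA.

    First, per-sample fold-change compression shrinks each profile's log2
    deviations from its own mean by ``signal_compression`` — fragmented
    templates amplify with a flattened dynamic range.  Then, per probe, a
    random attenuation (log2 loss, truncated at 0) is drawn once
    and applied to every sample — degradation susceptibility is a property of
    the probe, so FFPE profiles share a batch-wide loss pattern.  Per sample,
    a severity multiplier (lognormal around 1) scales that loss and shifts
    the dropout odds, emulating block-to-block differences in fixation.  Per
    cell, extra Gaussian log2 noise is added, and with a severity-adjusted
    probability around ``dropout_rate`` the signal collapses to background
    (times a small positive jitter).

    The two members of a 3'/5' control pair share one transcript-level
    attenuation draw; the 5' member additionally loses
    ``five_prime_extra_attenuation`` log2 units.  Control probes never drop
    out (housekeeping transcripts stay detectable even in degraded RNA —
    that is what makes the 3'/5' ratio measurable).
    """
    degr.validate()
    rng = np.random.default_rng([int(degr.seed) % (2**31), 101])
    p, n = x.values.shape
    log2 = np.log2(x.values)

    # fold-change compression: per sample, deviations from the sample's own
    # mean log2 level shrink by signal_compression (linear in log2, so ranks
    # are preserved but absolute separations are not)
    if degr.signal_compression < 1.0:
        center = log2.mean(axis=0, keepdims=True)
        log2 = center + degr.signal_compression * (log2 - center)

    if degr.attenuation_log2_sd > 0:
        a = (0.0 - degr.attenuation_log2_mean) / degr.attenuation_log2_sd
        atten = stats.truncnorm.rvs(
            a,
            np.inf,
            loc=degr.attenuation_log2_mean,
            scale=degr.attenuation_log2_sd,
            size=p,
            random_state=rng,
        )
    else:
        atten = np.full(p, max(degr.attenuation_log2_mean, 0.0))

    probe_index = {pid: i for i, pid in enumerate(x.probe_ids)}
    control_rows: set[int] = set()
    five_prime_rows: list[int] = []
    for p3, p5 in control_pairs:
        if p3 not in probe_index or p5 not in probe_index:
            raise KeyError(f"control pair ({p3!r}, {p5!r}) not in matrix")
        i3, i5 = probe_index[p3], probe_index[p5]
        atten[i5] = atten[i3]  # shared transcript-level susceptibility
        five_prime_rows.append(i5)
        control_rows.update((i3, i5))

    severity = rng.normal(0.0, degr.sample_severity_sd, n)
    loss = np.outer(atten, 2.0**severity)  # probes x samples
    # 3'-bias of reverse transcription: fixed extra loss at the 5' end,
    # applied after severity scaling so the 3'/5' log-ratio stays centered
    # on five_prime_extra_attenuation.
    loss[five_prime_rows, :] += degr.five_prime_extra_attenuation

    out = log2 - loss + rng.normal(0.0, degr.extra_noise_sd, (p, n))

    if degr.dropout_rate in (0.0, 1.0):
        rate = np.full(n, degr.dropout_rate)
    else:
        logit = np.log(degr.dropout_rate / (1.0 - degr.dropout_rate))
        rate = 1.0 / (1.0 + np.exp(-(logit + _DROPOUT_SEVERITY_COEF * severity)))
    # dropout score: weakest degraded signals drop first, with a shared
    # probe-level susceptibility and some per-cell randomness; each sample
    # drops exactly its severity-adjusted fraction of probes
    probe_score = rng.standard_normal(p)
    cell_score = rng.standard_normal((p, n))
    with np.errstate(invalid="ignore"):
        z_int = (out - out.mean(axis=0)) / np.where(out.std(axis=0) > 0, out.std(axis=0), 1.0)
    score = (
        -_DROPOUT_W_INTENSITY * z_int
        + _DROPOUT_W_PROBE * probe_score[:, None]
        + _DROPOUT_W_CELL * cell_score
    )
    mask = np.zeros((p, n), dtype=bool)
    noncontrol = np.array([i not in control_rows for i in range(p)])
    for j in range(n):
        k = int(round(rate[j] * noncontrol.sum()))
        if k > 0:
            col = score[:, j].copy()
            col[~noncontrol] = -np.inf  # controls never drop
            cutoff = np.partition(col, p - k)[p - k]
            mask[:, j] = col >= cutoff
            # exact count even with ties
            if mask[:, j].sum() != k:
                order = np.argsort(-col, kind="stable")
                mask[:, j] = False
                mask[order[:k], j] = True
    if mask.any():
        jitter = rng.normal(0.0, _DROPOUT_JITTER_SD, int(mask.sum()))
        out[mask] = np.log2(degr.background_level) + jitter

    result = ExpressionMatrix(list(x.probe_ids), list(x.sample_ids), 2.0**out)
    if return_mask:
        return result, mask
    return result


def generate_xenograft_pairs(
    config: GeneratorConfig,
    degr: DegradationConfig,
    n_lines: int = 5,
    n_replicates: int = 5,
) -> XenograftPairs:
    """Paired fresh-frozen / FFPE xenografts: ``n_lines`` cell lines, each
    grown in ``n_replicates`` animals; every tumor split into an FF and an
    FFPE half sharing the same underlying profile.

    Each line carries a fixed latent status per pathway (both statuses
    always represented across lines) and a line-specific expression offset.
    A second fresh-frozen assay of the same RNA (``ff_reamplified``) is
    produced by re-drawing only the assay noise.
    """
    config.validate()
    degr.validate()
    if n_lines < 1 or n_replicates < 1:
        raise ValueError("n_lines and n_replicates must be >= 1")

    ids = _probe_ids(config)
    baseline = _probe_baselines(config)
    effects = {p: _effect_vector(config, p) for p in DEFAULT_PATHWAYS}
    n_total = config.n_probes + 2 * len(CONTROL_PAIRS)

    rng_act = _rng(config.seed, 20)
    line_activity = {
        p: _balanced_assignment(n_lines, rng_act) for p in DEFAULT_PATHWAYS
    }
    rng_line = _rng(config.seed, 21)
    line_eff = rng_line.normal(0.0, config.line_effect_sd, (n_lines, config.n_probes))
    line_eff = np.hstack([line_eff, np.zeros((n_lines, 2 * len(CONTROL_PAIRS)))])

    rng_rep = _rng(config.seed, 22)
    rng_re = _rng(config.seed, 24)

    underlying, ff_ids, ffpe_ids, pair_ids, groups, acts = [], [], [], [], [], []
    for li in range(n_lines):
        act = {p: int(line_activity[p][li]) for p in DEFAULT_PATHWAYS}
        for r in range(n_replicates):
            mu = baseline + line_eff[li]
            for p in DEFAULT_PATHWAYS:
                if act[p]:
                    mu = mu + effects[p]
            underlying.append(mu + rng_rep.normal(0.0, config.replicate_noise_sd, n_total))
            ff_ids.append(f"FF_L{li+1}R{r+1}")
            ffpe_ids.append(f"FFPE_L{li+1}R{r+1}")
            pair_ids.append(f"PAIR_L{li+1}R{r+1}")
            groups.append(f"LINE{li+1}")
            acts.append(act)
    U = np.column_stack(underlying)

    # the fresh-frozen profile is the reference measurement of the underlying
    # biology; the re-amplified copy re-draws only the assay noise
    ff = ExpressionMatrix(ids, ff_ids, 2.0**U)
    ff_re = ExpressionMatrix(
        list(ids),
        [f"{s}_re" for s in ff_ids],
        2.0 ** (U + rng_re.normal(0.0, config.reamplification_noise_sd, U.shape)),
    )
    ffpe_base = ExpressionMatrix(ids, ffpe_ids, 2.0**U)
    ffpe, mask = apply_ffpe_degradation(ffpe_base, degr, CONTROL_PAIRS, return_mask=True)

    annotations = []
    truth = GroundTruth(
        activity={p: {} for p in DEFAULT_PATHWAYS},
        signature_probes={p: signature_probe_ids(config, p) for p in DEFAULT_PATHWAYS},
    )
    for ffs, ffpes, pid, grp, act in zip(ff_ids, ffpe_ids, pair_ids, groups, acts):
        annotations.append(
            SampleAnnotation(ffs, None, grp, pid, "fresh_frozen")
        )
        annotations.append(SampleAnnotation(ffpes, None, grp, pid, "ffpe"))
        for p in DEFAULT_PATHWAYS:
            truth.activity[p][ffs] = act[p]
            truth.activity[p][ffpes] = act[p]

    return XenograftPairs(ff, ffpe, ff_re, annotations, truth, mask)


def generate_patient_lesions(
    config: GeneratorConfig,
    degr: DegradationConfig,
    n_patients: int = 6,
    lesions_per_patient: int = 3,
) -> PatientLesions:
    """Patient melanoma lesions: each patient contributes several fresh-frozen
    lesions plus one FFPE lesion, all sharing the patient's latent pathway
    status.  The FFPE lesion is derived from the first fresh lesion's
    underlying profile."""
    config.validate()
    degr.validate()
    if n_patients < 1 or lesions_per_patient < 1:
        raise ValueError("n_patients and lesions_per_patient must be >= 1")

    ids = _probe_ids(config)
    baseline = _probe_baselines(config)
    effects = {p: _effect_vector(config, p) for p in DEFAULT_PATHWAYS}
    n_total = config.n_probes + 2 * len(CONTROL_PAIRS)

    rng_act = _rng(config.seed, 30)
    pt_activity = {p: _balanced_assignment(n_patients, rng_act) for p in DEFAULT_PATHWAYS}
    rng_pt = _rng(config.seed, 31)
    pt_eff = rng_pt.normal(0.0, config.patient_effect_sd, (n_patients, config.n_probes))
    pt_eff = np.hstack([pt_eff, np.zeros((n_patients, 2 * len(CONTROL_PAIRS)))])

    rng_les = _rng(config.seed, 32)

    ff_cols, ff_ids, ffpe_under, ffpe_ids = [], [], [], []
    annotations = []
    truth = GroundTruth(
        activity={p: {} for p in DEFAULT_PATHWAYS},
        signature_probes={p: signature_probe_ids(config, p) for p in DEFAULT_PATHWAYS},
    )
    for pi in range(n_patients):
        act = {p: int(pt_activity[p][pi]) for p in DEFAULT_PATHWAYS}
        mu_pt = baseline + pt_eff[pi]
        for p in DEFAULT_PATHWAYS:
            if act[p]:
                mu_pt = mu_pt + effects[p]
        for li in range(lesions_per_patient):
            under = mu_pt + rng_les.normal(0.0, config.replicate_noise_sd, n_total)
            sid = f"PT{pi+1}_FF{li+1}"
            ff_cols.append(under)
            ff_ids.append(sid)
            pair = f"PAIR_PT{pi+1}" if li == 0 else None
            annotations.append(SampleAnnotation(sid, None, f"PT{pi+1}", pair, "fresh_frozen"))
            if li == 0:
                ffpe_under.append(under)
                fid = f"PT{pi+1}_FFPE"
                ffpe_ids.append(fid)
                annotations.append(SampleAnnotation(fid, None, f"PT{pi+1}", pair, "ffpe"))
            for p in DEFAULT_PATHWAYS:
                truth.activity[p][sid] = act[p]
        for p in DEFAULT_PATHWAYS:
            truth.activity[p][f"PT{pi+1}_FFPE"] = act[p]

    ff = ExpressionMatrix(ids, ff_ids, 2.0 ** np.column_stack(ff_cols))
    ffpe_base = ExpressionMatrix(ids, ffpe_ids, 2.0 ** np.column_stack(ffpe_under))
    ffpe = apply_ffpe_degradation(ffpe_base, degr, CONTROL_PAIRS)
    return PatientLesions(ff, ffpe, annotations, truth)
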
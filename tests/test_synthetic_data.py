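import numpy as np
import pytest
from scipy import stats

from pathsig.core_data import ExpressionMatrix, validate_pairing
from pathsig.synthetic_data import (
    CONTROL_PAIRS,
    DegradationConfig,
    GeneratorConfig,
    apply_ffpe_degradation,
    generate_patient_lesions,
    generate_training_set,
    generate_xenograft_pairs,
    signature_probe_ids,
)


class TestTrainingSets:
    @pytest.mark.parametrize("pathway,n_perturbed", [("RAS", 8), ("MYC", 6)])
    def test_replicate_counts_follow_study_design(self, small_config, pathway, n_perturbed):
        matrix, design, truth = generate_training_set(small_config, pathway)
        assert len(design.control_ids) == 8
        assert len(design.perturbed_ids) == n_perturbed
        assert matrix.n_samples == 8 + n_perturbed
        assert set(truth.activity[pathway]) == set(matrix.sample_ids)

    def test_signature_probes_shift_by_effect_size(self, small_config):
        matrix, design, truth = generate_training_set(small_config, "RAS")
        log2 = np.log2(matrix.values)
        idx = {p: i for i, p in enumerate(matrix.probe_ids)}
        cols = {s: j for j, s in enumerate(matrix.sample_ids)}
        c = [cols[s] for s in design.control_ids]
        p = [cols[s] for s in design.perturbed_ids]
        diffs = log2[:, p].mean(axis=1) - log2[:, c].mean(axis=1)
        sig_rows = [idx[pr] for pr in truth.signature_probes["RAS"]]
        # every signature probe shifts by +-effect_size (balanced signs)
        assert np.abs(np.abs(diffs[sig_rows]) - small_config.effect_size).max() < 0.5
        signs = np.sign(diffs[sig_rows])
        assert abs(signs.sum()) <= 2  # half up, half down
        other = [i for i in range(matrix.n_probes) if i not in set(sig_rows)]
        assert np.abs(diffs[other]).max() < 1.0

    def test_null_effect_gives_student_t_statistics(self, small_config):
        config = GeneratorConfig(
            n_probes=small_config.n_probes,
            n_signature_probes_per_pathway=small_config.n_signature_probes_per_pathway,
            effect_size=0.0,
            seed=4,
        )
        matrix, design, _ = generate_training_set(config, "RAS")
        log2 = np.log2(matrix.values[: config.n_probes])  # exclude controls
        t, _ = stats.ttest_ind(log2[:, 8:], log2[:, :8], axis=1)
        # two-sided KS against the t distribution with n0+n1-2 df
        ks = stats.kstest(t, stats.t(df=14).cdf)
        assert ks.pvalue > 0.01

    def test_same_seed_reproduces_identical_output(self, small_config):
        m1, _, _ = generate_training_set(small_config, "RAS")
        m2, _, _ = generate_training_set(small_config, "RAS")
        np.testing.assert_array_equal(m1.values, m2.values)

    def test_pathway_signature_sets_are_disjoint(self, small_config):
        ras = set(signature_probe_ids(small_config, "RAS"))
        myc = set(signature_probe_ids(small_config, "MYC"))
        assert not ras & myc

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_probes=100, n_signature_probes_per_pathway=60).validate()
        with pytest.raises(ValueError):
            GeneratorConfig(replicate_noise_sd=-1).validate()


class TestXenografts:
    def test_study_counts(self, small_config, degradation):
        x = generate_xenograft_pairs(small_config, degradation)
        assert x.ff.n_samples == 25 and x.ffpe.n_samples == 25
        assert len(validate_pairing(x.annotations)) == 25

    def test_identity_degradation_gives_equal_pair(self, small_config, identity_degradation):
        x = generate_xenograft_pairs(small_config, identity_degradation)
        np.testing.assert_allclose(x.ffpe.values, x.ff.values, rtol=1e-12)

    def test_within_line_correlation_exceeds_between_line(self, small_config, degradation):
        x = generate_xenograft_pairs(small_config, degradation)
        log2 = np.log2(x.ff.values)
        z = (log2 - log2.mean(0)) / log2.std(0)
        corr = z.T @ z / log2.shape[0]
        lines = [ann.group_id for ann in x.annotations if ann.preservation == "fresh_frozen"]
        within, between = [], []
        for i in range(25):
            for j in range(i + 1, 25):
                (within if lines[i] == lines[j] else between).append(corr[i, j])
        assert np.mean(within) > np.mean(between)

    def test_counts_validated(self, small_config, degradation):
        with pytest.raises(ValueError):
            generate_xenograft_pairs(small_config, degradation, n_lines=0)


class TestDegradation:
    def test_identity_config_is_noop(self, tiny_matrix, identity_degradation):
        base = ExpressionMatrix(
            tiny_matrix.probe_ids + [p for pair in CONTROL_PAIRS for p in pair],
            tiny_matrix.sample_ids,
            np.vstack([tiny_matrix.values, np.full((4, 2), 100.0)]),
        )
        out = apply_ffpe_degradation(base, identity_degradation)
        np.testing.assert_allclose(out.values, base.values, rtol=1e-12)

    def test_three_five_ratio_geometric_mean_is_two_to_extra_attenuation(self):
        # constant 10,000 matrix; >=10,000 Monte-Carlo ratio draws
        n = 5000
        ids = [p for pair in CONTROL_PAIRS for p in pair] + ["P1"]
        base = ExpressionMatrix(ids, [f"s{i}" for i in range(n)], np.full((5, n), 1e4))
        degr = DegradationConfig(seed=8)
        out = apply_ffpe_degradation(base, degr)
        log_ratios = []
        for p3, p5 in CONTROL_PAIRS:
            i3, i5 = ids.index(p3), ids.index(p5)
            log_ratios.append(np.log2(out.values[i3] / out.values[i5]))
        geo = 2.0 ** np.concatenate(log_ratios).mean()
        assert 2**degr.five_prime_extra_attenuation == 8
        assert 7.4 < geo < 8.6

    def test_output_strictly_positive(self, small_config, degradation):
        x = generate_xenograft_pairs(small_config, degradation)
        assert (x.ffpe.values > 0).all()

    @staticmethod
    def _signature_class_diffs(x, pathway="RAS"):
        idx = {p: i for i, p in enumerate(x.ff.probe_ids)}
        act = x.truth.activity[pathway]
        cols = np.array([act[s] for s in x.ff.sample_ids])
        rows = [idx[p] for p in x.truth.signature_probes[pathway]]
        lf = np.log2(x.ff.values)[rows]
        lp = np.log2(x.ffpe.values)[rows]
        drop = x.dropout_mask[rows]
        diffs_ff, diffs_fp = [], []
        for r in range(len(rows)):
            diffs_ff.append(abs(lf[r, cols == 1].mean() - lf[r, cols == 0].mean()))
            keep1 = (cols == 1) & ~drop[r]
            keep0 = (cols == 0) & ~drop[r]
            if keep1.sum() >= 2 and keep0.sum() >= 2:
                diffs_fp.append(abs(lp[r, keep1].mean() - lp[r, keep0].mean()))
        return np.array(diffs_ff), np.array(diffs_fp)

    def test_class_separation_scales_with_compression(self, default_config):
        """Without censoring, FFPE signature-probe class separation equals
        the fresh separation scaled by the fold-change compression."""
        degr = DegradationConfig(dropout_rate=0.0, seed=99)
        x = generate_xenograft_pairs(default_config, degr)
        diffs_ff, diffs_fp = self._signature_class_diffs(x)
        expected = degr.signal_compression * diffs_ff.mean()
        se = diffs_fp.std(ddof=1) / np.sqrt(diffs_fp.size)
        assert abs(diffs_fp.mean() - expected) < 3 * se + 0.05

    def test_class_separation_survives_censoring(self, default_config, degradation):
        """With full default degradation, detection censoring biases the
        surviving-cell means but most of the compressed separation remains."""
        x = generate_xenograft_pairs(default_config, degradation)
        diffs_ff, diffs_fp = self._signature_class_diffs(x)
        compressed = degradation.signal_compression * diffs_ff.mean()
        assert diffs_fp.mean() > 0.6 * compressed

    def test_percent_present_decreases_with_dropout_rate(self):
        from pathsig.qc_metrics import percent_present

        rng = np.random.default_rng(0)
        ids = [f"P{i}" for i in range(2000)] + [p for pair in CONTROL_PAIRS for p in pair]
        base = ExpressionMatrix(
            ids, [f"s{i}" for i in range(10)], 2.0 ** rng.normal(7, 1, (2004, 10))
        )
        for seed in range(20):
            means = []
            for rate in (0.0, 0.2, 0.4, 0.6, 0.8):
                degr = DegradationConfig(dropout_rate=rate, seed=seed)
                out = apply_ffpe_degradation(base, degr)
                means.append(percent_present(out, 60.0).mean())
            assert all(a > b for a, b in zip(means, means[1:]))


class TestPatients:
    def test_study_counts(self, small_config, degradation):
        pat = generate_patient_lesions(small_config, degradation)
        assert pat.ff.n_samples == 18 and pat.ffpe.n_samples == 6
        groups = {a.group_id for a in pat.annotations}
        assert len(groups) == 6
        assert len(validate_pairing(pat.annotations)) == 6

    def test_single_lesion_reduces_to_paired_design(self, small_config, degradation):
        pat = generate_patient_lesions(small_config, degradation, lesions_per_patient=1)
        assert pat.ff.n_samples == pat.ffpe.n_samples == 6
        assert len(validate_pairing(pat.annotations)) == 6

    def test_lesions_share_patient_truth(self, small_config, degradation):
        pat = generate_patient_lesions(small_config, degradation)
        for pathway, acts in pat.truth.activity.items():
            for pi in range(1, 7):
                vals = {acts[s] for s in acts if s.startswith(f"PT{pi}_")}
                assert len(vals) == 1

    def test_counts_validated(self, small_config, degradation):
        with pytest.raises(ValueError):
            generate_patient_lesions(small_config, degradation, n_patients=0)
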
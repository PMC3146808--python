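import numpy as np
import pytest

from pathsig.core_data import ExpressionMatrix, validate_pairing
from pathsig.concordance_analysis import (
    hierarchical_cluster,
    matched_unmatched,
    patient_concordance,
    pca_scores,
    pearson_with_pvalue,
    sd_filter_and_center,
)
from pathsig.synthetic_data import (
    DegradationConfig,
    GeneratorConfig,
    generate_xenograft_pairs,
)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        r, _ = pearson_with_pvalue(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_with_pvalue(x, -x)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_pvalue(np.ones(5), np.arange(5.0))

    def test_pvalue_consistent_with_permutation_oracle(self):
        rng = np.random.default_rng(42)
        n = 25
        x = rng.standard_normal(n)
        y = 0.8 * x + np.sqrt(1 - 0.64) * rng.standard_normal(n)
        r, p = pearson_with_pvalue(x, y)
        # 100,000-permutation null of |r|
        perms = np.argsort(rng.random((100_000, n)), axis=1)
        yp = y[perms]
        xc = x - x.mean()
        rs = (yp - y.mean()) @ xc / (np.sqrt(((yp - yp.mean(1, keepdims=True)) ** 2).sum(1)) * np.sqrt((xc**2).sum()))
        p_perm = (np.abs(rs) >= abs(r)).mean()
        resolution = 10.0 / 100_000
        if p >= resolution:
            assert p / 2 < max(p_perm, 1e-5) < p * 2
        else:
            # analytic p below what permutations can resolve: the oracle must agree it is tiny
            assert p_perm <= resolution

    def test_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            pearson_with_pvalue([1, 2], [3, 4])


class TestMatchedUnmatched:
    def _pair(self, n_probes=300, n=5, seed=0):
        rng = np.random.default_rng(seed)
        a = ExpressionMatrix(
            [f"P{i}" for i in range(n_probes)],
            [f"a{j}" for j in range(n)],
            2.0 ** rng.normal(7, 1, (n_probes, n)),
        )
        return a

    def test_self_pairing_gives_unit_matched(self):
        a = self._pair()
        b = ExpressionMatrix(a.probe_ids, [f"b{j}" for j in range(5)], a.values)
        pairing = {f"p{j}": (f"a{j}", f"b{j}") for j in range(5)}
        res = matched_unmatched(a, b, pairing)
        np.testing.assert_allclose(res.matched_r.to_numpy(), 1.0, atol=1e-12)

    def test_pair_counts(self, small_config, degradation):
        x = generate_xenograft_pairs(small_config, degradation)
        res = matched_unmatched(x.ff, x.ffpe, validate_pairing(x.annotations))
        assert len(res.matched_r) == 25
        assert len(res.unmatched_r) == 25 * 25 - 25

    def test_sample_order_permutation_preserves_coefficients(self):
        a = self._pair(seed=1)
        rng = np.random.default_rng(2)
        b = ExpressionMatrix(
            a.probe_ids, [f"b{j}" for j in range(5)],
            a.values * 2.0 ** rng.normal(0, 0.3, a.values.shape),
        )
        pairing = {f"p{j}": (f"a{j}", f"b{j}") for j in range(5)}
        res1 = matched_unmatched(a, b, pairing)
        perm = [3, 1, 4, 0, 2]
        a2 = a.subset_samples([f"a{j}" for j in perm])
        res2 = matched_unmatched(a2, b, pairing)
        np.testing.assert_allclose(
            np.sort(res1.matched_r), np.sort(res2.matched_r), atol=1e-12
        )
        np.testing.assert_allclose(
            np.sort(res1.unmatched_r), np.sort(res2.unmatched_r), atol=1e-12
        )

    def test_reamplified_pairs_beat_unmatched(self, small_config, degradation):
        x = generate_xenograft_pairs(small_config, degradation)
        pairing = {s: (s, f"{s}_re") for s in x.ff.sample_ids}
        res = matched_unmatched(x.ff, x.ff_reamplified, pairing)
        assert res.matched_mean > res.unmatched_mean

    def test_unresolvable_pair_rejected(self):
        a = self._pair()
        with pytest.raises(ValueError, match="unknown samples"):
            matched_unmatched(a, a, {"p": ("a0", "nope")})


class TestSDFilterAndCenter:
    def test_keep_all_only_centers(self, tiny_matrix):
        out = sd_filter_and_center(tiny_matrix, n_keep=3)
        assert out.shape == (3, 2)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)

    def test_column_means_zero_after_two_pass_centering(self):
        rng = np.random.default_rng(4)
        m = ExpressionMatrix(
            [f"P{i}" for i in range(50)], [f"s{j}" for j in range(6)],
            2.0 ** rng.normal(7, 1, (50, 6)),
        )
        out = sd_filter_and_center(m, 20)
        np.testing.assert_allclose(out.mean(axis=0), 0.0, atol=1e-10)

    def test_selects_high_sd_probes(self):
        rng = np.random.default_rng(5)
        n_hi, n_lo = 40, 160
        hi = 2.0 ** rng.normal(7, 2.0, (n_hi, 8))
        lo = 2.0 ** rng.normal(7, 0.1, (n_lo, 8))
        ids = [f"HI{i}" for i in range(n_hi)] + [f"LO{i}" for i in range(n_lo)]
        m = ExpressionMatrix(ids, [f"s{j}" for j in range(8)], np.vstack([hi, lo]))
        out = sd_filter_and_center(m, n_hi)
        # brute-force SD ranking oracle
        sds = np.log2(m.values).std(axis=1, ddof=1)
        expected = {ids[i] for i in np.argsort(-sds)[:n_hi]}
        assert set(out.index) == expected
        assert all(p.startswith("HI") for p in out.index)


class TestHierarchicalCluster:
    def test_identical_samples_merge_at_zero(self):
        m = ExpressionMatrix(["P1", "P2"], ["a", "b"], np.array([[2.0, 2.0], [3.0, 3.0]]))
        tree = hierarchical_cluster(m)
        assert tree.height == pytest.approx(0.0, abs=1e-12)

    def test_three_sample_toy_matches_hand_calculation(self):
        # u=(1,0), v=(1,1), w=(0.2,1):
        #   sim(u,v)=1/sqrt(2)=0.70711, sim(u,w)=0.2/sqrt(1.04)=0.19612,
        #   sim(v,w)=1.2/sqrt(2*1.04)=0.83205
        # first merge (v,w) at 1-0.83205=0.16795; u joins at
        # mean(0.29289, 0.80388)=0.54839
        import pandas as pd

        df = pd.DataFrame(
            {"u": [1.0, 0.0], "v": [1.0, 1.0], "w": [0.2, 1.0]}, index=["P1", "P2"]
        )
        tree = hierarchical_cluster(df)
        assert tree.height == pytest.approx(0.54839, abs=1e-4)
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert sorted(inner.leaves()) == ["v", "w"]
        assert inner.height == pytest.approx(0.16795, abs=1e-4)

    def test_merge_heights_monotone(self, small_config, degradation):
        x = generate_xenograft_pairs(small_config, degradation)
        tree = hierarchical_cluster(sd_filter_and_center(x.ff, 200))

        def check(node, parent):
            assert node.height <= parent + 1e-9
            if not node.is_leaf:
                for c in node.children:
                    check(c, node.height)

        check(tree, np.inf)

    def test_two_block_data_splits_at_root(self):
        rng = np.random.default_rng(6)
        block = rng.normal(0, 1, 30)
        cols = {}
        for j in range(4):
            cols[f"x{j}"] = block + rng.normal(0, 0.1, 30)
        for j in range(4):
            cols[f"y{j}"] = -block + rng.normal(0, 0.1, 30)
        import pandas as pd

        tree = hierarchical_cluster(pd.DataFrame(cols))
        left = set(tree.children[0].leaves())
        assert left in ({f"x{j}" for j in range(4)}, {f"y{j}" for j in range(4)})

    def test_all_zero_sample_rejected(self):
        import pandas as pd

        df = pd.DataFrame({"a": [0.0, 0.0], "b": [1.0, 2.0]})
        with pytest.raises(ValueError, match="all-zero"):
            hierarchical_cluster(df)

    def test_newick_output_parses(self, tiny_matrix):
        tree = hierarchical_cluster(tiny_matrix)
        text = tree.to_newick()
        assert text.endswith(";") and text.count("(") == text.count(")")


class TestPCA:
    def test_full_rank_fractions_sum_to_one_nonincreasing(self):
        rng = np.random.default_rng(7)
        m = ExpressionMatrix(
            [f"P{i}" for i in range(40)], [f"s{j}" for j in range(6)],
            2.0 ** rng.normal(7, 1, (40, 6)),
        )
        _, frac = pca_scores(m, n_components=6)
        assert frac[0] >= frac[-1]
        assert (np.diff(frac) <= 1e-12).all()
        assert frac.sum() == pytest.approx(1.0)

    def test_rank_one_first_component_explains_everything(self):
        u = np.linspace(1, 3, 30)[:, None]
        v = np.array([[1.0, 2, 3, 4]])
        m = ExpressionMatrix(
            [f"P{i}" for i in range(30)], list("abcd"), 2.0 ** (u @ v)
        )
        _, frac = pca_scores(m, n_components=2)
        assert frac[0] == pytest.approx(1.0)

    def test_duplicate_samples_receive_identical_scores(self):
        rng = np.random.default_rng(8)
        col = 2.0 ** rng.normal(7, 1, (30, 1))
        m = ExpressionMatrix(
            [f"P{i}" for i in range(30)], ["a", "b"], np.hstack([col, col])
        )
        scores, _ = pca_scores(m, n_components=1)
        np.testing.assert_allclose(scores.loc["a"], scores.loc["b"], atol=1e-8)


class TestPatientConcordance:
    def test_concordant_when_one_lesion_close(self):
        res = patient_concordance({"p": [0.10, 0.45]}, {"p": 0.50})
        row = res.table.loc["p"]
        assert row["min_abs_diff"] == pytest.approx(0.05)
        assert row["concordant"]

    def test_discordant_when_all_lesions_far(self):
        res = patient_concordance({"p": [0.20, 0.30]}, {"p": 0.90})
        row = res.table.loc["p"]
        assert row["min_abs_diff"] == pytest.approx(0.60)
        assert not row["concordant"]

    def test_five_of_six_rounds_to_83_percent(self):
        ff = {f"p{i}": [0.5] for i in range(6)}
        ffpe = {f"p{i}": 0.5 for i in range(5)}
        ffpe["p5"] = 0.95
        res = patient_concordance(ff, ffpe)
        assert res.concordance_rate == 83

    def test_patient_without_lesions_rejected(self):
        with pytest.raises(ValueError, match="no fresh-frozen"):
            patient_concordance({}, {"p": 0.5})
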
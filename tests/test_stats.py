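import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from treburden.exceptions import ConfigError, DegenerateDataError
from treburden.stats import (
    bh_adjust,
    burden_test,
    carrier_excess,
    compute_pcs,
    constraint_compare,
    normalize_irr,
    select_covariate_pcs,
    wilcoxon_rank_sum,
)

from oracles import rank_sum_exact_p


class TestNormalizeIrr:
    def test_equal_depths_identity(self):
        irr = pd.DataFrame(np.arange(12.0).reshape(3, 4), index=["a", "b", "c"])
        depths = pd.Series([30.0, 30.0, 30.0], index=["a", "b", "c"])
        pd.testing.assert_frame_equal(normalize_irr(irr, depths), irr)

    def test_double_depth_halves_counts(self):
        irr = pd.DataFrame([[10.0], [10.0], [10.0]], index=["a", "b", "c"])
        depths = pd.Series([30.0, 30.0, 60.0], index=["a", "b", "c"])
        out = normalize_irr(irr, depths)
        assert out.loc["c", 0] == pytest.approx(5.0)
        assert out.loc["a", 0] == pytest.approx(10.0)

    def test_invariant_to_common_depth_rescale(self):
        rng = np.random.default_rng(0)
        irr = pd.DataFrame(rng.poisson(5, (5, 3)).astype(float))
        depths = pd.Series(rng.uniform(20, 40, 5))
        pd.testing.assert_frame_equal(
            normalize_irr(irr, depths), normalize_irr(irr, depths * 7.5)
        )

    def test_zero_depth_rejected(self):
        irr = pd.DataFrame([[1.0], [1.0]])
        with pytest.raises(ConfigError):
            normalize_irr(irr, pd.Series([30.0, 0.0]))


class TestComputePcs:
    def test_rank_one_matrix_concentrates_variance(self):
        u = np.arange(10.0)[:, None]
        v = np.arange(6.0)[None, :]
        scores, evr = compute_pcs(pd.DataFrame(u @ v), k=3)
        assert evr[0] == pytest.approx(1.0, abs=1e-10)

    def test_scores_orthogonal(self):
        rng = np.random.default_rng(1)
        scores, _ = compute_pcs(pd.DataFrame(rng.normal(size=(30, 8))), k=5)
        gram = scores.to_numpy().T @ scores.to_numpy()
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8

    def test_agrees_with_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 10))
        scores, evr = compute_pcs(pd.DataFrame(X), k=4)
        Xc = X - X.mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Xc.T @ Xc))[::-1]
        np.testing.assert_allclose(
            (scores.to_numpy() ** 2).sum(axis=0), eigvals[:4], rtol=1e-8
        )

    def test_constant_matrix_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            scores, evr = compute_pcs(pd.DataFrame(np.ones((5, 4))), k=2)
        assert not scores.to_numpy().any()


class TestSelectCovariatePcs:
    def test_pc_equal_to_burden_is_selected(self):
        rng = np.random.default_rng(3)
        burden = pd.Series(rng.poisson(2, 50).astype(float))
        pcs = pd.DataFrame(
            {"PC1": rng.normal(size=50), "PC2": burden.to_numpy(), "PC3": rng.normal(size=50)}
        )
        assert 2 in select_covariate_pcs(pcs, burden)

    def test_override_list_wins(self):
        pcs = pd.DataFrame(np.random.default_rng(0).normal(size=(20, 9)),
                           columns=[f"PC{i}" for i in range(1, 10)])
        burden = pd.Series(np.zeros(20))
        assert select_covariate_pcs(pcs, burden, override=[2, 3, 8]) == [2, 3, 8]
        with pytest.raises(ConfigError):
            select_covariate_pcs(pcs, burden, override=[0])

    def test_null_selection_rate_near_alpha(self):
        rng = np.random.default_rng(4)
        picks = 0
        trials = 200
        for _ in range(trials):
            pcs = pd.DataFrame({"PC1": rng.normal(size=40)})
            burden = pd.Series(rng.normal(size=40))
            picks += len(select_covariate_pcs(pcs, burden, alpha=0.05))
        # binomial(200, 0.05): mean 10, sd ~3.1
        assert 1 <= picks <= 22


class TestBurdenTest:
    def test_reduces_to_contingency_odds_ratio(self):
        y = np.r_[np.ones(1000), np.zeros(1000)]
        b = np.r_[np.ones(50), np.zeros(950), np.ones(10), np.zeros(990)]
        res = burden_test(y, b)
        closed = (50 * 990) / (950 * 10)
        assert res.odds_ratio == pytest.approx(closed, abs=5e-4)
        assert res.ci_low < res.odds_ratio < res.ci_high
        assert not res.separation

    def test_complete_separation_triggers_firth(self):
        y = np.r_[np.ones(25), np.zeros(25)]
        b = y.copy()
        res = burden_test(y, b)
        assert res.separation
        assert np.isfinite(res.odds_ratio) and res.odds_ratio > 1

    def test_constant_burden_rejected(self):
        with pytest.raises(DegenerateDataError):
            burden_test([1, 0, 1, 0], [2.0, 2.0, 2.0, 2.0])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(300):
            y = rng.integers(0, 2, 120).astype(float)
            if y.min() == y.max():
                continue
            b = rng.poisson(1.0, 120).astype(float)
            if np.ptp(b) == 0:
                continue
            ps.append(burden_test(y, b).p)
        stat = sps.kstest(ps, "uniform").pvalue
        assert stat > 0.01

    def test_or_invariant_to_covariate_rescaling(self):
        rng = np.random.default_rng(6)
        y = rng.integers(0, 2, 300).astype(float)
        b = rng.poisson(1.0, 300).astype(float)
        cov = pd.DataFrame({"c1": rng.normal(size=300)})
        r1 = burden_test(y, b, cov)
        r2 = burden_test(y, b, cov * 1000.0 + 3.0)
        assert r1.odds_ratio == pytest.approx(r2.odds_ratio, rel=1e-6)


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.005, 0.04, 0.04, 0.5]),
            [0.02, 0.04 * 4 / 3, 0.04 * 4 / 3, 0.5],
            rtol=1e-12,
        )

    def test_equal_p_triplet(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]).tolist() == [0.2]

    def test_properties(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(1e-6, 1, 40)
        adj = bh_adjust(p)
        assert np.all(adj >= p) and np.all(adj <= 1)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_rejects_out_of_range(self):
        with pytest.raises(ConfigError):
            bh_adjust([0.0, 0.5])


class TestWilcoxon:
    def test_exact_small_sample(self):
        _, p = wilcoxon_rank_sum([1, 2], [3, 4], alternative="less")
        assert p == pytest.approx(1 / 6)

    def test_identical_multisets_two_sided(self):
        _, p = wilcoxon_rank_sum([1, 2, 3, 4, 5, 6, 7], [4, 5, 6, 7, 1, 2, 3])
        assert p > 0.9

    def test_approximation_close_to_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(5):
            x = np.round(rng.normal(0, 1, 10), 3)
            y = np.round(rng.normal(0.5, 1, 10), 3)
            _, p_approx = wilcoxon_rank_sum(x, y, alternative="less")
            p_exact = rank_sum_exact_p(x, y, alternative="less")
            assert abs(p_approx - p_exact) < 0.01


class TestCarrierExcess:
    def test_intercept_only_reduces_to_raw_fractions(self):
        counts = pd.Series([1, 1, 0, 0, 0, 1, 0, 0, 0, 0], dtype=float)
        labels = [1, 1, 1, 1, 1, 0, 0, 0, 0, 0]
        res = carrier_excess(counts, labels)
        assert res.proportion_cases == pytest.approx(0.4)
        assert res.proportion_controls == pytest.approx(0.2)
        assert res.excess == pytest.approx(0.2)

    def test_wilcoxon_consistency_with_residuals(self):
        rng = np.random.default_rng(9)
        counts = pd.Series(rng.poisson(0.3, 200).astype(float))
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        res = carrier_excess(counts, labels)
        resid = counts - counts.mean()
        _, p = wilcoxon_rank_sum(resid[:100], resid[100:])
        assert res.p == pytest.approx(p)

    def test_recovers_planted_seven_point_excess(self):
        """Planted ~11.35%/4.39% carrier design: estimated excess within
        +/-2 points of 6.96 averaged over 100 seeded cohorts."""
        n_loci = 50
        f_case = 1 - (1 - 0.1135) ** (1 / n_loci)
        f_ctrl = 1 - (1 - 0.0439) ** (1 / n_loci)
        excesses = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            case_counts = rng.binomial(n_loci, f_case, 1154)
            ctrl_counts = rng.binomial(n_loci, f_ctrl, 934)
            counts = pd.Series(np.r_[case_counts, ctrl_counts].astype(float))
            labels = np.r_[np.ones(1154, int), np.zeros(934, int)]
            excesses.append(carrier_excess(counts, labels).excess)
        assert np.mean(excesses) == pytest.approx(0.0696, abs=0.02)

    def test_case_status_cannot_be_a_covariate(self):
        counts = pd.Series([0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ConfigError):
            carrier_excess(counts, [1, 1, 0, 0], pd.DataFrame({"case": [1, 1, 0, 0]}))


class TestConstraintCompare:
    def test_exact_fully_separated_groups(self):
        scores = dict(zip("abcdef", [0.1, 0.2, 0.3, 1.0, 2.0, 3.0]))
        res = constraint_compare(["a", "b", "c"], ["d", "e", "f"], scores)
        assert res.p == pytest.approx(1 / 20)
        assert res.median_with < res.median_without

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(10)
        scores = {f"g{i}": float(s) for i, s in enumerate(rng.uniform(0, 2, 400))}
        genes = list(scores)
        res = constraint_compare(genes[:200], genes[200:], scores)
        assert 0.2 < res.p < 0.8

    def test_subset_restriction_filters_both_groups(self):
        scores = dict(zip("abcdef", [0.1, 0.2, 0.3, 1.0, 2.0, 3.0]))
        res = constraint_compare(
            ["a", "b", "c"], ["d", "e", "f"], scores, subset=["a", "d"]
        )
        assert res.n_with == 1 and res.n_without == 1

    def test_no_scored_genes_rejected(self):
        with pytest.raises(DegenerateDataError):
            constraint_compare(["x"], ["y"], {"z": 1.0})
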
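import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stratmeta.corr_meta import (
    StratumCorrelation,
    cohort_correlations,
    fisher_z,
    heterogeneity,
    inverse_fisher_z,
    pool_z,
    spearman_rho,
    stouffer_pool_corr,
)


def _sc(rho, n, cohort="c1", gene="G", stratum="LOW", p=0.01):
    return StratumCorrelation(
        cohort_id=cohort, gene=gene, stratum=stratum, rho=rho, n=n,
        z_prime=fisher_z(rho), weight=float(n - 3), p_two_tailed=p,
    )


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        rho, n, p = spearman_rho([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)

    def test_monotone_decreasing_is_minus_one(self):
        rho, n, p = spearman_rho([1, 2, 3, 4, 5], [5, 4, 3, 2, 1])
        assert rho == pytest.approx(-1.0)

    def test_rank_formula_example(self):
        # d^2 sums to 4: rho = 1 - 6*4/(5*24) = 0.8
        rho, n, p = spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8)
        assert n == 5

    def test_pairwise_deletion(self):
        rho, n, p = spearman_rho(
            [1, 2, np.nan, 4, 5, 6], [2, 1, 9, 3, np.nan, 5]
        )
        assert n == 4

    def test_too_few_pairs_flagged(self):
        assert spearman_rho([1, 2, 3], [3, 2, 1]) is None

    def test_zero_variance_flagged(self):
        assert spearman_rho([1, 1, 1, 1], [1, 2, 3, 4]) is None

    @given(
        st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
            min_size=5, max_size=30, unique_by=lambda t: t[0],
        )
    )
    def test_invariance_under_monotone_transform(self, pairs):
        from hypothesis import assume

        x = np.array([a for a, _ in pairs])
        y = np.array([b for _, b in pairs])
        tx = np.exp(x / 25)
        assume(len(np.unique(tx)) == len(x))  # transform must stay injective in floats
        base = spearman_rho(x, y)
        transformed = spearman_rho(tx, y)
        if base is None:
            assert transformed is None
        else:
            assert transformed[0] == pytest.approx(base[0], abs=1e-12)


class TestFisherTransform:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_half_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3))

    def test_odd_symmetry(self):
        assert fisher_z(-0.73) == pytest.approx(-fisher_z(0.73))

    @pytest.mark.parametrize("rho", [1.0, -1.0, 1.5])
    def test_unit_correlation_excluded(self, rho):
        with pytest.raises(ValueError, match="undefined variance"):
            fisher_z(rho)

    def test_round_trip_identity_on_grid(self):
        grid = np.linspace(-0.999, 0.999, 201)
        for r in grid:
            assert inverse_fisher_z(fisher_z(r)) == pytest.approx(r, abs=1e-12)


class TestPoolZ:
    def test_consensus(self):
        pooled = pool_z([_sc(0.4, 100), _sc(0.4, 50, cohort="c2")])
        assert pooled.pooled_rho == pytest.approx(0.4)

    def test_single_cohort_identity_and_ci(self):
        pooled = pool_z([_sc(0.3, 103)])
        assert pooled.pooled_rho == pytest.approx(0.3)
        se = 1 / np.sqrt(100)
        assert pooled.ci_low == pytest.approx(np.tanh(np.arctanh(0.3) - 1.96 * se))
        assert pooled.ci_high == pytest.approx(np.tanh(np.arctanh(0.3) + 1.96 * se))

    def test_two_cohort_weighted_mean(self):
        # (100*atanh(0.3) + 200*atanh(0.5)) / 300 = 0.46938 -> tanh = 0.43770
        pooled = pool_z([_sc(0.3, 103), _sc(0.5, 203, cohort="c2")])
        assert pooled.pooled_rho == pytest.approx(0.43770, abs=1e-4)

    @given(
        st.lists(
            st.tuples(st.floats(-0.95, 0.95), st.integers(10, 300)),
            min_size=1, max_size=6,
        )
    )
    def test_pooled_within_cohort_range(self, raw):
        corrs = [_sc(r, n, cohort=f"c{i}") for i, (r, n) in enumerate(raw)]
        pooled = pool_z(corrs)
        rhos = [c.rho for c in corrs]
        assert min(rhos) - 1e-9 <= pooled.pooled_rho <= max(rhos) + 1e-9

    def test_no_valid_cohorts_flagged(self):
        with pytest.raises(ValueError, match="no valid"):
            pool_z([])


class TestStoufferCorr:
    def test_single_cohort_identity(self):
        assert stouffer_pool_corr([_sc(0.4, 100, p=0.02)]) == pytest.approx(0.02)

    def test_opposite_signs_cancel(self):
        corrs = [_sc(0.4, 100, p=0.01), _sc(-0.4, 100, cohort="c2", p=0.01)]
        assert stouffer_pool_corr(corrs) == pytest.approx(1.0)

    def test_four_cohorts_closed_form(self):
        # Z = 2 * Phi^-1(0.995) = 5.1517 -> p = 2.58e-7
        corrs = [_sc(0.4, 100, cohort=f"c{i}", p=0.01) for i in range(4)]
        assert stouffer_pool_corr(corrs) == pytest.approx(2.58e-7, rel=0.01)


class TestHeterogeneity:
    def test_identical_effects_give_zero(self):
        q, q_p, i2 = heterogeneity([0.5, 0.5, 0.5], [10, 20, 30])
        assert q == pytest.approx(0.0)
        assert i2 == 0.0
        assert q_p == pytest.approx(1.0)

    def test_two_term_expansion(self):
        # z' = (0, 1), equal weights w: mean 0.5, Q = w*(0.25 + 0.25) = w/2
        w = 8.0
        q, q_p, i2 = heterogeneity([0.0, 1.0], [w, w])
        assert q == pytest.approx(w / 2)

    def test_df_is_k_minus_1(self):
        corrs = [_sc(r, 100, cohort=f"c{i}") for i, r in enumerate([0.1, 0.2, 0.3, 0.4])]
        pooled = pool_z(corrs)
        assert pooled.df == 3

    def test_fewer_than_two_studies_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity([0.5], [10])

    def test_matches_statsmodels(self, rng):
        z = rng.normal(0.3, 0.2, size=5)
        n = rng.integers(50, 200, size=5)
        q, q_p, i2 = heterogeneity(z, n - 3)

        from statsmodels.stats.meta_analysis import combine_effects

        res = combine_effects(z, 1.0 / (n - 3))
        assert q == pytest.approx(res.q)
        assert q_p == pytest.approx(res.test_homogeneity().pvalue)
        assert i2 == pytest.approx(100 * res.i2, rel=1e-6)


class TestCohortCorrelations:
    def test_pairwise_n_differs_between_genes(self, rng):
        n = 40
        marker = rng.normal(size=n)
        g1 = 0.5 * marker + rng.normal(size=n)
        g2 = rng.normal(size=n)
        g2[:10] = np.nan
        expr = pd.DataFrame(
            {"PROS1": marker, "G1": g1, "G2": g2},
            index=[f"S{i}" for i in range(n)],
        )
        labels = pd.Series(["LOW"] * n, index=expr.index)
        out = cohort_correlations("c", expr, labels, "PROS1", ["G1", "G2"])
        by_gene = {c.gene: c for c in out}
        assert by_gene["G1"].n == 40
        assert by_gene["G2"].n == 30
        assert by_gene["G2"].weight == 27

    def test_absent_gene_skipped(self, rng):
        expr = pd.DataFrame({"PROS1": rng.normal(size=10)}, index=[f"S{i}" for i in range(10)])
        labels = pd.Series(["LOW"] * 10, index=expr.index)
        out = cohort_correlations("c", expr, labels, "PROS1", ["MISSING"])
        assert out == []

    def test_perfect_correlation_excluded_from_pooling(self):
        x = np.arange(10.0)
        expr = pd.DataFrame({"PROS1": x, "G": 2 * x}, index=[f"S{i}" for i in range(10)])
        labels = pd.Series(["LOW"] * 10, index=expr.index)
        out = cohort_correlations("c", expr, labels, "PROS1", ["G"])
        assert out == []
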
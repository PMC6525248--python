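"""Gene-level tests: statistics, analytic p-values and their oracles."""

import numpy as np
import pytest
from scipy import stats

from gamut.association import (
    CumulativeScore,
    all_snp_pvalues,
    cumulative_score,
    gamut_test,
    gene_minp,
    kmr_permutation_pvalue,
    kmr_test,
    permutation_pvalue,
    snp_regression,
)
from gamut.kernels import (
    CovariateMatrix,
    DegenerateInputError,
    GenotypeMatrix,
    PhenotypeMatrix,
    WeightVector,
)

from conftest import make_null_dataset


class TestCumulativeScore:
    @pytest.mark.parametrize(
        "row,expected",
        [(np.zeros(21, dtype=int), 0), (np.full(21, 3), 63),
         (np.r_[1, 2, np.zeros(19, dtype=int)], 3)],
    )
    def test_rowwise_sums(self, row, expected):
        Y = PhenotypeMatrix(row.reshape(1, -1))
        assert cumulative_score(Y).score[0] == expected


class TestGamut:
    def test_constant_phenotype_gives_unit_p(self, small_dataset):
        _, G, w = small_dataset
        n = G.n_subjects
        rng = np.random.default_rng(0)
        y = rng.integers(0, 4, n)
        # items exactly linear in the covariate: residuals vanish
        C = CovariateMatrix(y.astype(float).reshape(-1, 1))
        Y = PhenotypeMatrix(np.column_stack([y, y]), n_levels=4)
        res = gamut_test(Y, G, w, C, mode="projection")
        assert res.p_value == 1.0
        assert "degenerate" in res.diagnostics

    def test_weight_rescaling_leaves_p_invariant(self, small_dataset):
        Y, G, w = small_dataset
        p1 = gamut_test(Y, G, w, mode="projection").p_value
        w2 = WeightVector(2.0 * w.w, scheme="external")
        p2 = gamut_test(Y, G, w2, mode="projection").p_value
        assert p2 == pytest.approx(p1, rel=1e-9)

    @pytest.mark.parametrize("mode", ["projection", "linear"])
    def test_analytic_agrees_with_permutation(self, mode):
        """Analytic p within 3 binomial SE of a 4,000-permutation p."""
        for seed in (11, 12, 13):
            Y, G, w = make_null_dataset(seed)
            res = gamut_test(Y, G, w, mode=mode)
            pp = permutation_pvalue(Y, G, w, mode=mode, n_perm=4000, seed=seed)
            se = np.sqrt(max(pp * (1 - pp), 1e-8) / 4000)
            assert abs(res.p_value - pp) < 3 * se

    def test_permutation_determinism_and_extreme_association(self):
        rng = np.random.default_rng(5)
        n = 120
        g = rng.binomial(2, 0.4, n).astype(float)
        Y = PhenotypeMatrix(np.column_stack([np.clip(g.astype(int), 0, 3)] * 2))
        G = GenotypeMatrix(g.reshape(-1, 1))
        p1 = permutation_pvalue(Y, G, n_perm=500, seed=9)
        p2 = permutation_pvalue(Y, G, n_perm=500, seed=9)
        assert p1 == p2
        assert p1 == pytest.approx(1.0 / 501.0)


class TestKmr:
    def test_single_snp_equals_score_test(self, small_dataset):
        """V=1 unweighted KMR reduces to the simple-regression score test."""
        Y, G, _ = small_dataset
        score = cumulative_score(Y)
        g = G.dosages[:, 0]
        G1 = GenotypeMatrix(g.reshape(-1, 1))
        res = kmr_test(score, G1, WeightVector.flat(1))
        y = score.score.astype(float)
        yc = y - y.mean()
        gc = g - g.mean()
        n = y.size
        sigma2 = yc @ yc / (n - 1)
        chi = (yc @ gc) ** 2 / (sigma2 * (gc @ gc))
        assert res.p_value == pytest.approx(stats.chi2.sf(chi, 1), abs=1e-6)

    def test_analytic_agrees_with_permutation(self):
        for seed in (21, 22):
            Y, G, w = make_null_dataset(seed)
            score = cumulative_score(Y)
            res = kmr_test(score, G, w)
            pp = kmr_permutation_pvalue(score, G, w, n_perm=4000, seed=seed)
            se = np.sqrt(max(pp * (1 - pp), 1e-8) / 4000)
            assert abs(res.p_value - pp) < 3 * se

    def test_constant_score_rejected(self, small_dataset):
        _, G, w = small_dataset
        with pytest.raises(DegenerateInputError):
            kmr_test(CumulativeScore(np.full(G.n_subjects, 5)), G, w)


class TestSnpRegression:
    def test_matches_hand_computed_ols(self):
        """Textbook 5-point fit: slope/intercept from the normal equations."""
        x = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        y = np.array([1.0, 3.0, 4.0, 2.0, 0.0])
        beta, se, p = snp_regression(CumulativeScore(y), x)
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        assert beta == pytest.approx(sxy / sxx)
        resid = y - (y.mean() + beta * (x - x.mean()))
        s2 = (resid @ resid) / 3
        assert se == pytest.approx(np.sqrt(s2 / sxx))

    def test_duplicating_rows_keeps_beta_shrinks_se(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.3, 40).astype(float)
        y = 2.0 + x + rng.standard_normal(40)
        b1, se1, _ = snp_regression(CumulativeScore(y), x)
        b2, se2, _ = snp_regression(CumulativeScore(np.r_[y, y]), np.r_[x, x])
        assert b2 == pytest.approx(b1)
        assert se2 < se1

    def test_orthogonal_snp_gives_null_beta(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        x = np.array([1.0, 1.0, 0.0, 0.0])
        beta, _, p = snp_regression(CumulativeScore(y), x)
        assert beta == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_vectorized_path_matches_per_snp(self, small_dataset):
        Y, G, _ = small_dataset
        rng = np.random.default_rng(2)
        C = CovariateMatrix(rng.standard_normal((G.n_subjects, 2)))
        score = cumulative_score(Y)
        fast = all_snp_pvalues(score, G, C)
        slow = [snp_regression(score, G.dosages[:, j], C)[2] for j in range(G.n_variants)]
        assert np.allclose(fast, slow, atol=1e-12)


class TestGeneMinp:
    def test_single_variant_returns_raw_p(self):
        G = GenotypeMatrix(np.array([0, 1, 2, 1, 0, 2.0]).reshape(-1, 1))
        assert gene_minp(np.array([0.037]), G) == pytest.approx(0.037)

    def test_independent_snps_match_sidak(self):
        rng = np.random.default_rng(8)
        G = GenotypeMatrix(rng.binomial(2, 0.4, (3000, 4)).astype(float))
        pmin = 0.02
        adj = gene_minp(np.array([pmin, 0.8, 0.5, 0.9]), G)
        sidak = 1 - (1 - pmin) ** 4
        assert adj == pytest.approx(sidak, abs=0.002)

    def test_bounds_envelope(self):
        rng = np.random.default_rng(9)
        base = rng.standard_normal(500)
        d = np.clip(np.round(
            np.column_stack([base + 0.3 * rng.standard_normal(500) for _ in range(3)]) + 1
        ), 0, 2)
        G = GenotypeMatrix(d)
        pv = np.array([0.004, 0.3, 0.6])
        adj = gene_minp(pv, G)
        assert pv.min() <= adj <= min(3 * pv.min(), 1.0)

    def test_correlated_toy_gene_matches_monte_carlo(self):
        """3 SNPs at r~0.9: adjusted p within 3 SE of a simulated minP null."""
        rng = np.random.default_rng(10)
        z = rng.standard_normal(800)
        d = np.clip(np.round(np.column_stack(
            [z + 0.45 * rng.standard_normal(800) for _ in range(3)]) + 1.0), 0, 2)
        G = GenotypeMatrix(d)
        Gc = G.dosages - G.dosages.mean(axis=0)
        R = np.corrcoef(Gc, rowvar=False)
        pmin_obs = 0.01
        adj = gene_minp(np.array([pmin_obs, 0.5, 0.2]), G)
        n_mc = 20000
        L = np.linalg.cholesky(R)
        zs = rng.standard_normal((n_mc, 3)) @ L.T
        pmins = 2 * stats.norm.sf(np.abs(zs)).min(axis=1)
        emp = (pmins <= pmin_obs).mean()
        se = np.sqrt(emp * (1 - emp) / n_mc)
        assert abs(adj - emp) < 3 * se

    def test_invalid_pvalues_rejected(self):
        G = GenotypeMatrix(np.array([[0.0], [1.0], [2.0]]))
        with pytest.raises(ValueError):
            gene_minp(np.array([0.0]), G)
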
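"""Synthetic genotype and questionnaire generators plus experiment drivers."""

import numpy as np
import pytest
from scipy import stats

from gamut.association import cumulative_score
from gamut.kernels import CovariateMatrix
from gamut.simulate import (
    DEFAULT_GAMMA_GENO,
    DEFAULT_GAMMA_PHENO,
    EffectModel,
    ExperimentConfig,
    QuestionnaireModel,
    build_haplotype_pool,
    calibrate_margins,
    default_bdi_model,
    draw_genotypes,
    lrfn5_like_pool,
    run_power_experiment,
    run_size_experiment,
    simulate_questionnaire,
    stat3_like_pool,
)


class TestHaplotypePool:
    def test_realized_frequencies_match_targets(self):
        maf = np.linspace(0.05, 0.45, 10)
        pool = build_haplotype_pool(10, maf, ld_decay=0.5, seed=0, n_haplotypes=10_000)
        assert np.abs(pool.haplotypes.mean(axis=0) - maf).max() < 0.02

    def test_ld_decay_limits(self):
        maf = np.full(6, 0.3)
        indep = build_haplotype_pool(6, maf, ld_decay=0.0, seed=1, n_haplotypes=5000)
        r2 = np.corrcoef(indep.haplotypes.T) ** 2
        assert r2[~np.eye(6, dtype=bool)].max() < 0.01
        tight = build_haplotype_pool(6, maf, ld_decay=0.9999, seed=1, n_haplotypes=5000)
        r2 = np.corrcoef(tight.haplotypes.T) ** 2
        assert np.diag(r2, 1).min() > 0.9

    def test_infeasible_maf_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            pool = build_haplotype_pool(3, np.array([0.0, 0.3, 0.5]), 0.2, seed=2)
        assert pool.haplotypes.shape[1] == 3

    def test_gene_structures(self):
        s = stat3_like_pool()
        l = lrfn5_like_pool()
        assert (s.n_variants, int(s.typed_mask.sum())) == (27, 14)
        assert (l.n_variants, int(l.typed_mask.sum())) == (127, 50)


class TestDrawGenotypes:
    def test_dosage_mean_tracks_allele_frequency(self, stat3_pool):
        G = draw_genotypes(stat3_pool, 20_000, seed=3)
        freq = stat3_pool.haplotypes.mean(axis=0)
        # keep variants in original minor-allele orientation
        assert np.abs(G.dosages.mean(axis=0) - 2 * freq).max() < 0.03

    def test_hardy_weinberg_proportions(self, stat3_pool):
        G = draw_genotypes(stat3_pool, 10_000, seed=4)
        p = stat3_pool.haplotypes.mean(axis=0)[0]
        counts = np.bincount(G.dosages[:, 0].astype(int), minlength=3)
        expected = 10_000 * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, 2) > 1e-4

    def test_confounder_tilts_dosages(self, stat3_pool):
        rng = np.random.default_rng(5)
        u = rng.standard_normal(5000)
        G = draw_genotypes(stat3_pool, 5000, seed=5, confounder=u, gamma_geno=0.3)
        cors = [abs(np.corrcoef(u, G.dosages[:, j])[0, 1]) for j in range(5)]
        assert max(cors) > 0.05


class TestCalibrateMargins:
    def test_uniform_item_quantiles(self):
        cuts = calibrate_margins(np.array([[0.25, 0.25, 0.25, 0.25]]))
        assert np.allclose(cuts, stats.norm.ppf([0.25, 0.5, 0.75]))

    def test_round_trip_recovers_skewed_margin(self):
        freqs = np.array([[0.55, 0.25, 0.12, 0.08]])
        cuts = calibrate_margins(freqs)
        z = np.random.default_rng(6).standard_normal(50_000)
        y = np.searchsorted(cuts[0], z)
        emp = np.bincount(y, minlength=4) / y.size
        assert np.abs(emp - freqs[0]).max() < 0.01

    def test_degenerate_binary_item(self):
        cuts = calibrate_margins(np.array([[0.7, 0.3]]))
        assert cuts.shape == (1, 1)
        assert np.isfinite(cuts).all()

    def test_zero_frequency_level_warns(self):
        with pytest.warns(UserWarning, match="merged"):
            calibrate_margins(np.array([[0.5, 0.0, 0.3, 0.2]]))


class TestQuestionnaire:
    def test_margins_and_latent_correlation_round_trip(self, bdi_model):
        Y, C = simulate_questionnaire(bdi_model, None, None, 50_000, seed=7)
        assert C.n_covariates == 0
        emp = np.bincount(Y.values[:, 0], minlength=4) / Y.n_subjects
        assert np.abs(emp - np.array([0.55, 0.25, 0.12, 0.08])).max() < 0.01
        # ordinal correlation tracks latent correlation attenuated; same-block
        # items (latent 0.45) must correlate clearly above cross-block (0.2)
        corr = np.corrcoef(Y.values.T)
        same_block = corr[0, 1]
        cross_block = corr[0, 14]
        assert same_block > cross_block + 0.1

    def test_affected_items_pick_up_dosage_correlation(self, stat3_pool, bdi_model):
        rng = np.random.default_rng(8)
        G = draw_genotypes(stat3_pool, 50_000, rng)
        eff = EffectModel(0, np.arange(6), 0.2)
        Y, _ = simulate_questionnaire(bdi_model, G, eff, 50_000, rng)
        g = G.dosages[:, 0]
        aff = [abs(np.corrcoef(Y.values[:, j], g)[0, 1]) for j in range(6)]
        unaff = [abs(np.corrcoef(Y.values[:, j], g)[0, 1]) for j in range(6, 21)]
        assert min(aff) > max(unaff) + 0.02

    def test_non_pd_correlation_rejected(self):
        R = np.array([[1.0, 0.9, 0.0], [0.9, 1.0, 0.9], [0.0, 0.9, 1.0]])
        cuts = calibrate_margins(np.tile([0.25, 0.25, 0.25, 0.25], (3, 1)))
        with pytest.raises(ValueError, match="positive definite"):
            QuestionnaireModel(R, cuts)

    def test_seeded_reproducibility(self, bdi_model):
        Y1, _ = simulate_questionnaire(bdi_model, None, None, 100, seed=9)
        Y2, _ = simulate_questionnaire(bdi_model, None, None, 100, seed=9)
        assert np.array_equal(Y1.values, Y2.values)


class TestExperiments:
    def test_size_table_well_formed_and_bounded(self, stat3_pool, bdi_model):
        cfg = ExperimentConfig(N=300, n_reps=60, alphas=(0.05, 0.01), seed=1)
        df = run_size_experiment(cfg, stat3_pool, bdi_model)
        assert len(df) == 4 * 2
        assert df["rate"].between(0, 1).all()
        assert set(df.attrs["pvalues"]) == set(cfg.methods)

    def test_null_effect_power_near_alpha(self, stat3_pool, bdi_model):
        cfg = ExperimentConfig(N=300, n_reps=60, seed=2, methods=("kmr",))
        df = run_power_experiment(cfg, stat3_pool, bdi_model, [0], n_affected=0,
                                  alpha=0.05)
        assert df["power"].iloc[0] < 0.2

    def test_power_monotone_in_effect_size(self, stat3_pool, bdi_model):
        typed = int(np.nonzero(stat3_pool.typed_mask)[0][6])
        cfg = ExperimentConfig(N=800, n_reps=40, seed=3, methods=("gamut_linear",))
        powers = [
            run_power_experiment(cfg, stat3_pool, bdi_model, [typed], 12,
                                 beta=b, alpha=0.05)["power"].iloc[0]
            for b in (0.0, 0.2, 0.5)
        ]
        assert powers[0] <= powers[1] + 0.1
        assert powers[2] >= powers[1]
        assert powers[2] > powers[0]

    def test_experiment_reproducible_under_seed(self, stat3_pool, bdi_model):
        cfg = ExperimentConfig(N=250, n_reps=25, seed=4, methods=("gamut_projection",))
        a = run_size_experiment(cfg, stat3_pool, bdi_model)
        b = run_size_experiment(cfg, stat3_pool, bdi_model)
        assert np.array_equal(a.attrs["pvalues"]["gamut_projection"],
                              b.attrs["pvalues"]["gamut_projection"])
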
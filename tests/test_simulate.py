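"""Generator contracts: distributions, sparsity structure, noise model, determinism."""

import numpy as np
import pytest

from content.simulate import (
    ConfigurationError,
    ExternalCohort,
    PhenotypeConfig,
    SimConfig,
    simulate_effects,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotype,
    simulate_study,
)


class TestGenotypes:
    def test_dosages_are_biallelic_counts(self, small_study):
        panel, _, _ = small_study
        assert np.isin(panel.genotypes, [0, 1, 2]).all()
        assert ((panel.maf >= 0.05) & (panel.maf <= 0.50)).all()

    def test_seeded_determinism(self, small_config):
        a = simulate_genotypes(small_config)
        b = simulate_genotypes(small_config)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.maf, b.maf)

    def test_column_means_match_allele_frequency(self):
        # Monte-Carlo: mean dosage of a Bin(2, p) column is 2p within 3 SE
        cfg = SimConfig(n_genes=1, n_snps_per_gene=40, sample_size_range=(100_000, 100_000), seed=5)
        panel = simulate_genotypes(cfg)
        p = panel.maf[0]
        se = np.sqrt(2 * p * (1 - p) / 100_000)
        assert np.all(np.abs(panel.genotypes[0].mean(axis=0) - 2 * p) < 3 * se + 1e-9)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_genes=0)
        with pytest.raises(ConfigurationError):
            SimConfig(rho=1.0)
        with pytest.raises(ConfigurationError):
            SimConfig(h2_shared=0.9, h2_specific=0.2)


class TestEffects:
    def test_no_heritability_means_no_effects(self):
        cfg = SimConfig(n_genes=4, n_contexts=4, n_snps_per_gene=50, h2_shared=0.0,
                        h2_specific=0.0, causal_prob=1.0, frac_contexts_with_specific=0.0,
                        sample_size_range=(30, 40), seed=0)
        panel = simulate_genotypes(cfg)
        truth = simulate_effects(cfg, panel)
        assert np.all(truth.beta_shared == 0)

    def test_no_specific_contexts_means_no_specific_effects(self):
        cfg = SimConfig(n_genes=4, n_contexts=4, n_snps_per_gene=50,
                        frac_contexts_with_specific=0.0, sample_size_range=(30, 40), seed=0)
        panel = simulate_genotypes(cfg)
        truth = simulate_effects(cfg, panel)
        assert np.all(truth.beta_specific == 0)
        assert not truth.has_specific.any()

    def test_mean_causal_count_matches_bernoulli_rate(self):
        cfg = SimConfig(n_genes=400, n_contexts=2, n_snps_per_gene=500,
                        sample_size_range=(20, 25), seed=3)
        panel = simulate_genotypes(cfg)
        truth = simulate_effects(cfg, panel)
        counts = truth.shared_causal.sum(axis=1)
        expect = 500 * 0.05
        se = np.sqrt(500 * 0.05 * 0.95 / 400)
        assert abs(counts.mean() - expect) < 3 * se

    def test_truly_specific_sites_disjoint_from_shared_causal(self, small_study):
        panel, truth, _ = small_study
        overlap = truth.truly_specific & truth.shared_causal[:, None, :]
        assert not overlap.any()
        # non-Poisson specific causal sites sit on shared-causal SNPs
        subsampled = truth.specific_causal & ~truth.truly_specific
        assert np.all(~subsampled | truth.shared_causal[:, None, :])

    def test_uniform_shared_proportion_partitions_total(self):
        cfg = SimConfig(n_genes=50, n_contexts=2, n_snps_per_gene=30,
                        uniform_shared_proportion=True, sample_size_range=(20, 25), seed=4)
        truth = simulate_effects(cfg, simulate_genotypes(cfg))
        total = truth.h2_shared + truth.h2_specific
        assert np.allclose(total, 0.4)
        assert truth.h2_shared.std() > 0.05  # actually varies across genes


class TestExpression:
    def test_every_individual_observed_and_sizes_in_range(self, small_study):
        _, _, study = small_study
        obs = ~np.isnan(study.expression[0])
        assert obs.any(axis=1).all()
        lo, hi = 60, 120
        sizes = obs.sum(axis=0)
        assert ((sizes >= lo) & (sizes <= hi)).all()

    def test_total_variance_near_one(self):
        cfg = SimConfig(n_genes=6, n_contexts=5, n_snps_per_gene=100,
                        sample_size_range=(4000, 4000), frac_contexts_with_specific=1.0, seed=9)
        panel, truth, study = simulate_study(cfg)
        var = np.nanvar(study.expression, axis=1)  # (J, C)
        assert np.abs(var.mean() - 1.0) < 0.05

    def test_uncorrelated_contexts_when_no_signal_no_rho(self):
        cfg = SimConfig(n_genes=1, n_contexts=4, n_snps_per_gene=10, h2_shared=0.0,
                        h2_specific=0.0, causal_prob=1.0, rho=0.0,
                        frac_contexts_with_specific=0.0,
                        sample_size_range=(50_000, 50_000), seed=2)
        _, _, study = simulate_study(cfg)
        E = study.expression[0]
        corr = np.corrcoef(E.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(50_000) * 1.5

    def test_equicorrelated_noise_reaches_target_rho(self):
        cfg = SimConfig(n_genes=1, n_contexts=4, n_snps_per_gene=10, h2_shared=0.0,
                        h2_specific=0.0, causal_prob=1.0, rho=0.6,
                        frac_contexts_with_specific=0.0,
                        sample_size_range=(50_000, 50_000), seed=2)
        _, _, study = simulate_study(cfg)
        corr = np.corrcoef(study.expression[0].T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.abs(off - 0.6).max() < 0.02

    def test_heritability_bookkeeping(self):
        # empirical var(G beta) / var(E) approaches h2_shared at large I
        cfg = SimConfig(n_genes=3, n_contexts=4, n_snps_per_gene=200,
                        sample_size_range=(100_000, 100_000),
                        frac_contexts_with_specific=0.0, seed=8)
        panel, truth, study = simulate_study(cfg)
        for j in range(3):
            g = truth.genetic_component(panel.genotypes[j], j, 0, "shared")
            ratio = g.var() / np.nanvar(study.expression[j, :, 0])
            assert abs(ratio - 0.3) < 0.02

    def test_determinism_end_to_end(self, small_config):
        a = simulate_study(small_config)[2].expression
        b = simulate_study(small_config)[2].expression
        assert np.array_equal(a, b, equal_nan=True)


@pytest.fixture(scope="module")
def components(small_study):
    panel, truth, _ = small_study
    cohort = ExternalCohort(panel.maf, 3000, seed=11)
    return np.stack([cohort.genetic_components(truth, j) for j in range(panel.n_genes)], axis=1)


class TestPhenotype:

    def test_null_phenotype_is_pure_noise(self, components, small_study):
        _, truth, _ = small_study
        pcfg = PhenotypeConfig(n_causal_genes=2, contexts_per_gene=2, var_explained=0.0, seed=1)
        res = simulate_phenotype(pcfg, truth, components)
        j, c = res.causal_pairs[0]
        r = np.corrcoef(res.phenotype, components[:, j, c])[0, 1]
        assert abs(r) < 0.06
        assert np.all(res.effects == 0)

    def test_phenotype_variance_near_one(self, components, small_study):
        _, truth, _ = small_study
        pcfg = PhenotypeConfig(n_causal_genes=3, contexts_per_gene=2, var_explained=0.2, seed=2)
        res = simulate_phenotype(pcfg, truth, components)
        assert abs(res.phenotype.var() - 1.0) < 0.1

    def test_signal_share_matches_var_explained(self, components, small_study):
        _, truth, _ = small_study
        pcfg = PhenotypeConfig(n_causal_genes=3, contexts_per_gene=2, var_explained=0.5, seed=3)
        res = simulate_phenotype(pcfg, truth, components)
        cols = []
        for (j, c) in res.causal_pairs:
            x = components[:, j, c]
            cols.append((x - x.mean()) / x.std())
        signal = np.column_stack(cols) @ res.effects
        # linearity: regenerating noise leaves E[y | components] = signal
        assert signal.var() / res.phenotype.var() == pytest.approx(0.5, abs=0.2)

    def test_too_few_heritable_genes_raises(self, components, small_study):
        _, truth, _ = small_study
        pcfg = PhenotypeConfig(n_causal_genes=1000, contexts_per_gene=2, seed=0)
        with pytest.raises(Exception):
            simulate_phenotype(pcfg, truth, components)
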
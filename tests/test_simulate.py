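import numpy as np
import pytest

from qrfcca import (
    SimulationDesign,
    build_haplotype_pool,
    run_power_experiment,
    run_type1_experiment,
    sample_genotype_block,
    simulate_genotypes,
    simulate_null_phenotypes,
    simulate_power_phenotypes,
)
from qrfcca.simulate import draw_residual_correlation


class TestDesign:
    def test_snp_partition_must_balance(self):
        with pytest.raises(ValueError, match="n_rare"):
            SimulationDesign(n_snps=100, n_rare=10, n_common=20)

    def test_invalid_regime_and_scenario(self):
        with pytest.raises(ValueError):
            SimulationDesign(correlation_regime="extreme")
        with pytest.raises(ValueError):
            SimulationDesign(scenario=4)


class TestGenotypeSimulation:
    def test_deterministic_given_seed(self):
        d = SimulationDesign(
            n_samples=50, n_snps=30, n_rare=10, n_common=20, n_haplotypes=2000, seed=5
        )
        b1 = simulate_genotypes(d)
        b2 = simulate_genotypes(d)
        np.testing.assert_array_equal(b1.dosage, b2.dosage)

    def test_empirical_maf_tracks_target(self):
        """Common SNP with target MAF 0.2: pool frequency within 3
        binomial SEs (haplotype draws are the binomial trials)."""
        d = SimulationDesign(
            n_snps=10,
            n_rare=2,
            n_common=8,
            common_maf_range=(0.2, 0.2000001),
            n_haplotypes=20000,
            seed=6,
        )
        pool = build_haplotype_pool(d, np.random.default_rng(6))
        freq = pool.haplotypes[:, ~pool.is_rare].mean(axis=0)
        se = np.sqrt(0.2 * 0.8 / d.n_haplotypes)
        assert (np.abs(freq - 0.2) < 3 * se + 1e-3).all()

    def test_ld_rho_zero_gives_independent_snps(self):
        d = SimulationDesign(
            n_snps=40,
            n_rare=0 + 10,
            n_common=30,
            ld_rho=0.0,
            n_haplotypes=4000,
            seed=7,
        )
        pool = build_haplotype_pool(d, np.random.default_rng(7))
        block = sample_genotype_block(pool, 2000, np.random.default_rng(8))
        common = block.maf > 0.05
        X = block.dosage[:, common]
        C = np.corrcoef(X.T)
        off = C[np.triu_indices_from(C, 1)]
        assert abs(off.mean()) < 0.02

    def test_positive_ld_rho_induces_neighbor_correlation(self):
        d = SimulationDesign(
            n_snps=40, n_rare=10, n_common=30, ld_rho=0.9, n_haplotypes=4000, seed=9
        )
        pool = build_haplotype_pool(d, np.random.default_rng(9))
        block = sample_genotype_block(pool, 2000, np.random.default_rng(10))
        common = np.flatnonzero(block.maf > 0.05)
        r = [
            np.corrcoef(block.dosage[:, i], block.dosage[:, j])[0, 1]
            for i, j in zip(common[:-1], common[1:])
            if j == i + 1
        ]
        assert np.mean(r) > 0.2

    def test_rare_and_common_counts(self, gene_pool):
        assert int(gene_pool.is_rare.sum()) == 600
        assert int((~gene_pool.is_rare).sum()) == 400
        assert gene_pool.target_maf[gene_pool.is_rare].max() <= 0.01
        assert gene_pool.target_maf[gene_pool.is_rare].min() >= 0.0005
        assert gene_pool.target_maf[~gene_pool.is_rare].min() > 0.01


class TestNullPhenotypes:
    def test_regime_correlations_concentrate_in_band(self):
        rng = np.random.default_rng(11)
        Y = simulate_null_phenotypes(5000, 8, "high", rng)
        C = np.corrcoef(Y.T)
        off = C[np.triu_indices_from(C, 1)]
        se = 3.0 / np.sqrt(5000)
        assert (off > 0.4 - 3 * se).all() and (off < 0.7 + 3 * se).all()

    def test_point_correlation_limit(self):
        """Bounds collapsed to a point rho: sample correlation converges."""
        rng = np.random.default_rng(12)
        R, repaired = draw_residual_correlation(2, (0.35, 0.35 + 1e-9), rng)
        assert not repaired
        assert R[0, 1] == pytest.approx(0.35, abs=1e-6)
        L = np.linalg.cholesky(R)
        Y = rng.standard_normal((20000, 2)) @ L.T
        assert np.corrcoef(Y.T)[0, 1] == pytest.approx(0.35, abs=3 / np.sqrt(20000))

    def test_repair_keeps_positive_definite(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            R, _ = draw_residual_correlation(15, (0.4, 0.7), rng)
            assert np.linalg.eigvalsh(R).min() > 0
            np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-9)

    def test_independent_of_genotypes(self, small_pool):
        from qrfcca import canonical_correlations

        rng = np.random.default_rng(14)
        block = sample_genotype_block(small_pool, 3000, rng)
        Y = simulate_null_phenotypes(3000, 4, "low", np.random.default_rng(999))
        lams, _, _, _ = canonical_correlations(block.dosage[:, :5], Y)
        assert (lams**2).sum() < 0.02


class TestPowerPhenotypes:
    def test_zero_causal_gating_reduces_to_null(self, small_pool):
        rng = np.random.default_rng(15)
        block = sample_genotype_block(small_pool, 400, rng)
        d = SimulationDesign(
            n_snps=20, n_rare=5, n_common=15, n_traits=6,
            causal_prob=0.0, correlation_regime="moderate", seed=15,
        )
        Y, truth = simulate_power_phenotypes(block, d, rng)
        assert truth["b"].sum() == 0
        np.testing.assert_allclose(truth["genetic_component"], 0.0)
        C = np.corrcoef(Y.T)
        assert (C[np.triu_indices_from(C, 1)] > 0).mean() > 0.8

    def test_variance_decomposition_oracle(self):
        """Single causal SNP, single trait: Var(genetic) ~ 2 MAF (1-MAF) sd(alpha)^2."""
        rng = np.random.default_rng(16)
        n = 20000
        maf = 0.3
        d = SimulationDesign(
            n_snps=2, n_rare=1, n_common=1, n_traits=1,
            causal_prob=1.0, scenario=1, h2_range=(0.01, 0.010000001), seed=16,
        )
        # force a block with known MAF
        from qrfcca import code_genotypes

        calls = rng.binomial(2, maf, size=(n, 2)).astype(float)
        calls[0] = [1, 1]
        block = code_genotypes(calls, [10, 20])
        reps = []
        for r in range(40):
            rr = np.random.default_rng(np.random.SeedSequence(entropy=16, spawn_key=(r,)))
            Y, truth = simulate_power_phenotypes(block, d, rr)
            if truth["t"][0] == 0:
                continue
            g = truth["genetic_component"][:, 0]
            var_emp = g.var()
            var_pred = sum(
                2 * block.maf[j] * (1 - block.maf[j]) * truth["effects"][j, 0] ** 2
                for j in range(block.n_snps)
            )
            reps.append(var_emp / var_pred)
        assert len(reps) > 10
        assert np.mean(reps) == pytest.approx(1.0, abs=0.1)

    def test_scenario_gating_means(self, small_pool):
        rng = np.random.default_rng(17)
        block = sample_genotype_block(small_pool, 100, rng)
        counts = {1: [], 3: []}
        for scenario in (1, 3):
            d = SimulationDesign(
                n_snps=20, n_rare=5, n_common=15, n_traits=10, scenario=scenario, seed=17
            )
            for r in range(150):
                rr = np.random.default_rng(
                    np.random.SeedSequence(entropy=17, spawn_key=(scenario, r))
                )
                _, truth = simulate_power_phenotypes(block, d, rr)
                counts[scenario].append(truth["t"].sum())
        assert np.mean(counts[1]) == pytest.approx(6.0, abs=0.8)  # 0.6 * 10
        assert np.mean(counts[3]) == pytest.approx(2.0, abs=0.6)  # 0.2 * 10
        assert np.mean(counts[1]) > np.mean(counts[3])

    def test_effect_conventions_differ(self, small_pool):
        rng1 = np.random.default_rng(18)
        block = sample_genotype_block(small_pool, 200, rng1)
        d1 = SimulationDesign(
            n_snps=20, n_rare=5, n_common=15, n_traits=5, causal_prob=0.5, seed=18
        )
        d2 = SimulationDesign(
            n_snps=20, n_rare=5, n_common=15, n_traits=5, causal_prob=0.5,
            effect_convention="printed_matrix", seed=18,
        )
        _, t1 = simulate_power_phenotypes(block, d1, np.random.default_rng(18))
        _, t2 = simulate_power_phenotypes(block, d2, np.random.default_rng(18))
        # prose convention scales effects up for rare SNPs; printed scales down
        s1 = np.abs(t1["effects"]).sum()
        s2 = np.abs(t2["effects"]).sum()
        assert s1 > s2


class TestExperiments:
    def test_type1_experiment_structure_and_determinism(self, small_design):
        tab1 = run_type1_experiment(
            small_design, methods=("cca",), nominal_levels=(0.2,),
            sample_sizes=[120], variant_class="all", n_replicates=30, seed=5,
        )
        tab2 = run_type1_experiment(
            small_design, methods=("cca",), nominal_levels=(0.2,),
            sample_sizes=[120], variant_class="all", n_replicates=30, seed=5,
        )
        assert tab1.equals(tab2)
        assert set(tab1.columns) >= {
            "method", "sample_size", "nominal_level", "rejection_rate", "se",
        }

    def test_binomial_se_scaling(self, small_design):
        tab_small = run_type1_experiment(
            small_design, nominal_levels=(0.05,), sample_sizes=[100],
            variant_class="all", n_replicates=100, seed=6,
        )
        tab_big = run_type1_experiment(
            small_design, nominal_levels=(0.05,), sample_sizes=[100],
            variant_class="all", n_replicates=400, seed=6,
        )
        assert tab_small["se"].iloc[0] == pytest.approx(2 * tab_big["se"].iloc[0])

    def test_power_monotone_in_sample_size_and_null_reduction(self, small_design):
        import dataclasses

        d = dataclasses.replace(
            small_design, n_traits=5, correlation_regime="moderate",
            causal_prob=0.3, scenario=1,
        )
        tab = run_power_experiment(
            d, sample_sizes=[100, 600], alpha=0.05, n_replicates=60, seed=8
        )
        p_small = tab.loc[tab.sample_size == 100, "power"].iloc[0]
        p_big = tab.loc[tab.sample_size == 600, "power"].iloc[0]
        assert p_big >= p_small
        # zero-heritability design: power collapses to the nominal level
        d0 = dataclasses.replace(d, h2_range=(1e-12, 2e-12))
        tab0 = run_power_experiment(
            d0, sample_sizes=[300], alpha=0.05, n_replicates=100, seed=9
        )
        p0 = tab0["power"].iloc[0]
        assert abs(p0 - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 100) + 0.02
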
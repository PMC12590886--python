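import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from imfscan.coexpr import (
    adjacency_matrix,
    critical_genes,
    cut_modules,
    detect_outlier_samples,
    gene_statistics,
    module_eigengene,
    module_trait_relationships,
    pick_soft_power,
    tom_similarity,
)
from imfscan.correl import log2_transform
from imfscan.dataio import ExpressionMatrix
from imfscan.synthio import (
    SimulationConfig,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_trait,
)


def expr_of(values):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        gene_ids=[f"g{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        scale="log2",
    )


def module_expression(seed, n_samples=70, module_sizes=(100, 100, 100)):
    """Planted-module latent expression and true labels."""
    cfg = SimulationConfig(
        seed=seed, n_samples=n_samples,
        n_genes=sum(module_sizes), n_unexpressed=0,
        module_sizes=module_sizes, eqtl_plan=(),
    )
    geno = simulate_genotypes(cfg)
    cov = simulate_covariates(cfg)
    expr = simulate_expression(geno, cov, cfg)
    labels = [m for m in cfg.module_of().values() if m is not None]
    return log2_transform(expr), np.asarray(labels), cfg


class TestOutliers:
    def test_extreme_sample_removed(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=(50, 20))
        v[:, 3] += 50.0  # one sample shifted by +50 SD
        retained, _ = detect_outlier_samples(expr_of(v))
        assert "s3" not in retained and len(retained) == 19

    def test_homogeneous_data_fully_retained(self):
        v = np.random.default_rng(1).normal(size=(80, 30))
        retained, _ = detect_outlier_samples(expr_of(v))
        assert len(retained) == 30

    def test_planted_nine_outliers_exactly_removed(self):
        for seed in range(3):
            cfg = SimulationConfig(seed=seed, n_outliers=9, outlier_shift=6.0)
            geno = simulate_genotypes(cfg)
            cov = simulate_covariates(cfg)
            expr = simulate_expression(geno, cov, cfg)
            out_idx = cfg.rng("layout").choice(cfg.n_samples, size=9, replace=False)
            outliers = {cov.sample_ids[i] for i in out_idx}
            retained, _ = detect_outlier_samples(log2_transform(expr))
            assert set(expr.sample_ids) - set(retained) == outliers

    def test_singleton_explosion_raises(self):
        v = np.random.default_rng(2).normal(size=(40, 12))
        with pytest.raises(ValueError, match="larger cut height"):
            detect_outlier_samples(expr_of(v), cut_height=1e-6)


class TestSoftPower:
    def test_deterministic_given_input(self):
        expr, _, _ = module_expression(seed=5)
        assert pick_soft_power(expr) == pick_soft_power(expr)

    def test_vacuous_target_returns_smallest_candidate(self):
        expr, _, _ = module_expression(seed=5)
        assert pick_soft_power(expr, r2_target=0.0) == 1

    def test_too_few_genes_raises(self):
        v = np.random.default_rng(3).normal(size=(10, 20))
        with pytest.raises(ValueError, match=">= 50 genes"):
            pick_soft_power(expr_of(v))


class TestTom:
    def test_identical_rows_with_unit_adjacency_overlap_fully(self):
        A = np.ones((3, 3)) - np.eye(3)
        tom = tom_similarity(A)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_isolated_pair_has_zero_overlap(self):
        A = np.zeros((4, 4))
        A[2, 3] = A[3, 2] = 0.5  # no i-j edge, no shared neighbours for 0,1
        tom = tom_similarity(A)
        assert tom[0, 1] == 0.0

    def test_matches_triple_loop_oracle_on_random_instances(self):
        rng = np.random.default_rng(4)
        for n in (2, 5, 9, 14, 20):
            A = rng.uniform(0, 1, size=(n, n))
            A = (A + A.T) / 2
            np.fill_diagonal(A, 0.0)
            tom = tom_similarity(A)
            k = A.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert tom[i, j] == 1.0
                        continue
                    num = sum(A[i, u] * A[u, j] for u in range(n)) + A[i, j]
                    den = min(k[i], k[j]) + 1 - A[i, j]
                    assert tom[i, j] == pytest.approx(num / den, abs=1e-10)

    def test_non_symmetric_rejected(self):
        A = np.zeros((3, 3))
        A[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_similarity(A)


class TestModules:
    def _assign(self, expr):
        power = pick_soft_power(expr)
        tom = tom_similarity(adjacency_matrix(expr, power))
        return cut_modules(tom, expr.gene_ids, expr=expr)

    def test_planted_modules_recovered(self):
        expr, truth, _ = module_expression(seed=6)
        assignment = self._assign(expr)
        found = [assignment.labels[g] for g in expr.gene_ids]
        assert adjusted_rand_score(truth, found) >= 0.9

    def test_duplicated_gene_gets_same_label(self):
        expr, _, _ = module_expression(seed=7)
        v = np.vstack([expr.values, expr.values[0]])
        dup = ExpressionMatrix(
            gene_ids=expr.gene_ids + ["dup0"], sample_ids=expr.sample_ids,
            values=v, scale="log2",
        )
        assignment = self._assign(dup)
        assert assignment.labels["dup0"] == assignment.labels[expr.gene_ids[0]]

    def test_labels_invariant_to_gene_order(self):
        expr, _, _ = module_expression(seed=8, module_sizes=(60, 60, 60))
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.n_genes)
        shuffled = expr.subset_genes(perm)
        a = self._assign(expr)
        b = self._assign(shuffled)
        la = [a.labels[g] for g in expr.gene_ids]
        lb = [b.labels[g] for g in expr.gene_ids]
        assert adjusted_rand_score(la, lb) == pytest.approx(1.0)

    def test_oversized_min_module_size_leaves_all_unassigned(self):
        expr, _, _ = module_expression(seed=7, module_sizes=(60, 60))
        power = pick_soft_power(expr)
        tom = tom_similarity(adjacency_matrix(expr, power))
        assignment = cut_modules(tom, expr.gene_ids, min_module_size=1000)
        assert set(assignment.labels.values()) == {"unassigned"}


class TestEigengene:
    def test_identical_genes_reproduce_shared_profile(self):
        rng = np.random.default_rng(9)
        profile = rng.normal(size=30)
        v = np.tile(profile, (5, 1))
        eg = module_eigengene(v)
        z = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(eg, z / np.linalg.norm(z), atol=1e-10)

    def test_sign_equivariance_under_global_flip(self):
        rng = np.random.default_rng(10)
        v = rng.normal(size=(6, 25))
        np.testing.assert_allclose(module_eigengene(-v), -module_eigengene(v), atol=1e-10)

    def test_matches_direct_svd_oracle(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=(5, 18))
        Xs = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, keepdims=True)
        _, _, vt = np.linalg.svd(Xs)
        expected = vt[0] * np.sign((Xs @ vt[0]).mean())
        np.testing.assert_allclose(module_eigengene(v), expected, atol=1e-10)

    def test_rank_zero_module_raises(self):
        with pytest.raises(ValueError, match="rank-0|constant"):
            module_eigengene(np.ones((3, 10)))


class TestTraitStatistics:
    def test_trait_equal_to_eigengene_gives_unit_mtr(self):
        expr, _, _ = module_expression(seed=12, module_sizes=(60, 60))
        assignment = self._assignment(expr)
        m = assignment.modules[0]
        trait = assignment.eigengenes[m].copy()
        assignment = module_trait_relationships(expr, assignment, trait)
        r, p = assignment.mtr[m]
        assert r == pytest.approx(1.0, abs=1e-9) and p < 1e-30

    def _assignment(self, expr):
        power = pick_soft_power(expr)
        tom = tom_similarity(adjacency_matrix(expr, power))
        assignment = cut_modules(tom, expr.gene_ids, expr=expr)
        dummy_trait = np.arange(expr.n_samples, dtype=float)
        return module_trait_relationships(expr, assignment, dummy_trait)

    def test_regulator_flagged_critical_on_trait_linked_cohort(self):
        hits = 0
        n_seeds = 8
        for seed in range(n_seeds):
            cfg = SimulationConfig(seed=seed)
            geno = simulate_genotypes(cfg)
            cov = simulate_covariates(cfg)
            expr = simulate_expression(geno, cov, cfg)
            cov_t = simulate_trait(expr, cov, cfg)
            log2 = log2_transform(expr.subset_genes(slice(0, cfg.n_genes)))
            power = pick_soft_power(log2)
            tom = tom_similarity(adjacency_matrix(log2, power))
            assignment = cut_modules(tom, log2.gene_ids, expr=log2)
            assignment = module_trait_relationships(log2, assignment, cov_t.trait)
            table = gene_statistics(log2, assignment, cov_t.trait)
            crit = critical_genes(assignment, table)
            if cfg.regulator_gene in crit:
                hits += 1
        assert hits >= n_seeds - 1

    def test_constant_trait_raises(self):
        expr, _, _ = module_expression(seed=12, module_sizes=(60,))
        assignment = self._assignment(expr)
        with pytest.raises(ValueError, match="constant trait"):
            module_trait_relationships(expr, assignment, np.ones(expr.n_samples))
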
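import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from imfscan.dataio import SampleCovariates
from imfscan.eqtl import (
    bh_fdr,
    classify_relation,
    fit_association,
    qc_genotypes,
    run_scan,
)
from imfscan.exprnorm import rank_inverse_normal
from imfscan.synthio import (
    SimulationConfig,
    latent_expression,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
)

from conftest import toy_genotypes


class TestQc:
    def test_maf_exactly_at_bound_is_retained(self):
        # 20 samples, 2 alt alleles -> MAF = 0.05 exactly
        dosage = np.zeros((20, 1))
        dosage[0, 0] = 2
        g, rep = qc_genotypes(toy_genotypes(dosage))
        assert g.n_snps == 1 and rep.n_removed_maf == 0

    def test_maf_below_bound_removed(self):
        dosage = np.zeros((20, 1))
        dosage[0, 0] = 1  # MAF = 0.025
        g, rep = qc_genotypes(toy_genotypes(dosage))
        assert g.n_snps == 0 and rep.n_removed_maf == 1

    def test_snp_missing_rate_exactly_at_bound_is_retained(self):
        col = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 1.0, 2.0, 1.0, 0.0, 1.0])
        dosage = np.column_stack([col, col])
        dosage[0, 0] = np.nan  # missing rate exactly 0.1
        g, rep = qc_genotypes(toy_genotypes(dosage))
        assert g.n_snps == 2 and rep.n_removed_snp_missing == 0

    def test_mitochondrial_and_scaffold_contigs_removed(self):
        dosage = np.tile([[0.0], [1.0], [2.0]], (2, 4))
        g, rep = qc_genotypes(
            toy_genotypes(dosage, chrom=["MT", "scaffold_12", "9", "chrX"],
                          pos=[1, 1, 1, 1])
        )
        assert set(g.chrom) == {"9", "chrX"} and rep.n_removed_nonchrom == 2

    def test_individuals_filtered_before_snp_filters(self):
        # one sample missing most calls; after dropping it, SNP missingness is 0
        dosage = np.tile([0.0, 1.0, 2.0], (10, 3)).reshape(10, -1)[:, :3]
        dosage = np.column_stack([dosage, dosage])
        dosage[0, :] = np.nan
        g, rep = qc_genotypes(toy_genotypes(dosage, pos=[1, 2, 3, 4, 5, 6]))
        assert rep.n_samples_out == 9
        assert rep.n_removed_snp_missing == 0

    def test_all_samples_removed_raises(self):
        dosage = np.full((5, 2), np.nan)
        with pytest.raises(ValueError, match="all samples"):
            qc_genotypes(toy_genotypes(dosage))


class TestFitAssociation:
    def _cov(self, n, rng=None):
        rng = rng or np.random.default_rng(0)
        return SampleCovariates(
            sample_ids=[f"S{i}" for i in range(n)],
            sex=np.asarray(rng.choice(["M", "F"], n), dtype=object),
            batch=np.asarray(rng.choice(["B1", "B2"], n), dtype=object),
            carcass_weight=rng.normal(100, 5, n),
        )

    def test_noiseless_linear_relation_recovered_exactly(self):
        n = 24
        rng = np.random.default_rng(1)
        cov = self._cov(n, rng)
        S = rng.integers(0, 3, n).astype(float)
        g = 2.0 + 1.5 * S
        rec = fit_association(g, S, cov, snp_id="s", gene_id="g")
        assert rec.beta == pytest.approx(1.5, abs=1e-10)
        assert rec.p_value < 1e-12

    def test_beta_matches_frisch_waugh_partial_regression(self):
        # independent oracle: residualize g and S on covariates, then simple OLS
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(15, 60))
            cov = self._cov(n, rng)
            S = rng.integers(0, 3, n).astype(float)
            g = rng.normal(size=n) + 0.4 * S
            rec = fit_association(g, S, cov, snp_id="s", gene_id="g")
            X, _ = cov.design_matrix()
            H = X @ np.linalg.lstsq(X, np.eye(n), rcond=None)[0]
            gr, sr = g - H @ g, S - H @ S
            beta_fwl = (sr @ gr) / (sr @ sr)
            assert rec.beta == pytest.approx(beta_fwl, abs=1e-10)

    def test_permuting_all_inputs_together_gives_identical_record(self):
        rng = np.random.default_rng(3)
        n = 30
        cov = self._cov(n, rng)
        S = rng.integers(0, 3, n).astype(float)
        g = rng.normal(size=n) + 0.3 * S
        rec = fit_association(g, S, cov, snp_id="s", gene_id="g")
        perm = rng.permutation(n)
        cov_p = SampleCovariates(
            sample_ids=[cov.sample_ids[i] for i in perm],
            sex=cov.sex[perm], batch=cov.batch[perm],
            carcass_weight=cov.carcass_weight[perm],
        )
        rec_p = fit_association(g[perm], S[perm], cov_p, snp_id="s", gene_id="g")
        assert rec_p.beta == pytest.approx(rec.beta, abs=1e-12)
        assert rec_p.p_value == pytest.approx(rec.p_value, rel=1e-9)

    def test_constant_snp_returns_none(self):
        cov = self._cov(20)
        assert fit_association(np.random.default_rng(0).normal(size=20),
                               np.ones(20), cov) is None

    def test_type_one_error_calibrated_under_null(self):
        # null SNP-gene pairs: p < 0.05 should occur for ~5% of pairs
        rng = np.random.default_rng(4)
        n = 79
        cov = self._cov(n, rng)
        hits, total = 0, 2000
        for _ in range(total):
            S = rng.binomial(2, 0.3, n).astype(float)
            g = rng.normal(size=n)
            rec = fit_association(g, S, cov)
            if rec is not None and rec.p_value < 0.05:
                hits += 1
        assert 0.05 == pytest.approx(hits / total, abs=0.02)


class TestClassifyRelation:
    @pytest.mark.parametrize(
        "snp, tss, expected",
        [
            (("9", 2_000_000), ("9", 1_000_000), "cis"),  # exactly 1 Mb away
            (("9", 2_000_001), ("9", 1_000_000), "trans"),  # one bp beyond
            (("9", 500), ("8", 500), "trans"),  # different chromosome
            (("9", 100), ("9", 100), "cis"),
        ],
    )
    def test_window_boundary_inclusive(self, snp, tss, expected):
        assert classify_relation(snp, tss) == expected


class TestBhFdr:
    def test_hand_worked_example(self):
        # sorted p*m/i: [.04,.04,.04,.04] after cumulative min from the right
        np.testing.assert_allclose(
            bh_fdr(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_passes_through(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.37])), [0.37])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(25):
            p = rng.uniform(1e-12, 1, size=rng.integers(1, 300))
            np.testing.assert_allclose(
                bh_fdr(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=100))
    def test_q_is_isotonic_with_p(self, ps):
        p = np.asarray(ps)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all(q <= 1.0) and np.all(q >= p - 1e-15)


class TestRunScan:
    def test_planted_cis_pair_flagged_genome_wide(self):
        cfg = SimulationConfig(seed=13)
        geno = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        expr = simulate_expression(geno, cov, cfg)
        normalized = rank_inverse_normal(expr.subset_genes(slice(0, 120)))
        table = run_scan(normalized, geno, cov)
        planted = table[
            (table.gene_id == cfg.regulator_gene)
            & (table.snp_id == cfg.planted_snp_id(cfg.eqtl_plan[0]))
        ]
        assert len(planted) == 1 and bool(planted.iloc[0].significant_gw)
        assert (table.relation == "cis").all()
        # strict thresholds: flags recompute from p with <
        assert (table.significant_sugg == (table.p < 5e-6)).all()
        assert (table.significant_gw == (table.p < 5e-8)).all()

    def test_empty_expression_raises(self):
        cfg = SimulationConfig(seed=13)
        geno = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        expr = simulate_expression(geno, cov, cfg).subset_genes([])
        with pytest.raises(ValueError, match="empty"):
            run_scan(expr, geno, cov)

    def test_noiseless_simulation_recovers_planted_beta(self):
        cfg = SimulationConfig(seed=21, noise_sd=0.0, module_sizes=(), n_unexpressed=0)
        geno = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        expr = simulate_expression(geno, cov, cfg)
        latent = latent_expression(expr, cfg)
        for e in cfg.eqtl_plan:
            gi = expr.gene_index(e.gene)
            sj = geno.snp_ids.index(cfg.planted_snp_id(e))
            rec = fit_association(latent[gi], geno.dosage[:, sj], cov)
            assert rec.beta == pytest.approx(e.beta, abs=1e-8)
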
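import numpy as np
import pandas as pd
import pytest
from scipy import stats

from imfscan.dataio import GenomicInterval, SampleCovariates
from imfscan.pqtl import (
    LodProfile,
    colocalize,
    find_ld_blocks,
    genotype_stratified_test,
    gwas_scan,
    ld_r2,
    lod_drop_interval,
    lod_profile_from_summary,
    permutation_assoc,
)
from imfscan.synthio import (
    SimulationConfig,
    simulate_covariates,
    simulate_expression,
    simulate_genotypes,
    simulate_trait,
)

from conftest import toy_genotypes


def brute_force_lod_interval(pos, lod, drop=2.0):
    """Independent oracle: filter by the drop rule, then span the
    contiguous retained run containing the peak."""
    order = np.argsort(pos)
    pos, lod = np.asarray(pos)[order], np.asarray(lod)[order]
    peak = int(np.argmax(lod))
    keep = [i for i in range(len(pos)) if lod[i] > lod[peak] - drop]
    run = {peak}
    changed = True
    while changed:
        changed = False
        for i in keep:
            if i not in run and (i - 1 in run or i + 1 in run):
                run.add(i)
                changed = True
    idx = sorted(run)
    return int(pos[idx[0]]), int(pos[idx[-1]])


class TestLodDrop:
    def test_worked_profile_peak_only(self):
        prof = LodProfile("9", np.array([1, 2, 3, 4, 5]) * 10 ** 6,
                          np.array([1.0, 3.0, 7.0, 4.0, 2.0]))
        iv = lod_drop_interval(prof, drop=2)
        assert (iv.start, iv.end) == (3_000_000, 3_000_000)

    def test_worked_profile_wide_support(self):
        prof = LodProfile("9", np.array([1, 2, 3, 4, 5]) * 10 ** 6,
                          np.array([6.0, 6.5, 7.0, 6.5, 1.0]))
        iv = lod_drop_interval(prof, drop=2)
        assert (iv.start, iv.end) == (1_000_000, 4_000_000)

    def test_flat_profile_spans_whole_chromosome(self):
        prof = LodProfile("9", np.array([5, 10, 20]), np.array([2.0, 2.0, 2.0]))
        iv = lod_drop_interval(prof, drop=2)
        assert (iv.start, iv.end) == (5, 20)

    def test_matches_brute_force_on_random_profiles(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(1, 40))
            pos = np.sort(rng.choice(np.arange(1, 10_000), size=n, replace=False))
            lod = np.round(rng.uniform(0, 8, size=n), 3)
            iv = lod_drop_interval(LodProfile("1", pos, lod), drop=2)
            assert (iv.start, iv.end) == brute_force_lod_interval(pos, lod)

    def test_span_all_covers_every_retained_snp(self):
        prof = LodProfile("9", np.array([1, 2, 3, 4, 5]),
                          np.array([6.0, 1.0, 7.0, 1.0, 6.5]))
        iv = lod_drop_interval(prof, drop=2, span_all=True)
        assert (iv.start, iv.end) == (1, 5)
        iv_peak = lod_drop_interval(prof, drop=2)
        assert (iv_peak.start, iv_peak.end) == (3, 3)


class TestLdR2:
    def test_identical_vectors_give_unit_r2(self):
        g = toy_genotypes(np.column_stack([[0, 0, 1, 1, 2, 2]] * 2))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_perfect_negative_correlation_squares_to_one(self):
        g = toy_genotypes(np.column_stack([[0, 0, 1, 1, 2, 2], [2, 2, 1, 1, 0, 0]]))
        assert ld_r2(g, 0, 1) == pytest.approx(1.0)

    def test_monomorphic_snp_gives_nan(self):
        g = toy_genotypes(np.column_stack([[0, 1, 2, 1], [1, 1, 1, 1]]))
        assert np.isnan(ld_r2(g, 0, 1))


class TestLdBlocks:
    def test_planted_blocks_recovered_under_perfect_ld(self):
        cfg = SimulationConfig(seed=19, ld_within_r=1.0, chromosomes=("1",),
                               blocks_per_chrom=4, n_samples=50)
        g = simulate_genotypes(cfg)
        blocks = find_ld_blocks(g)
        assert len(blocks) == 4
        for b, block in enumerate(blocks):
            assert block.snp_ids == [f"snp_1_{b:02d}_{s}" for s in range(5)]
            assert block.min_r2 == pytest.approx(1.0)

    def test_blocks_satisfy_all_pairs_predicate_when_rechecked(self):
        cfg = SimulationConfig(seed=23, ld_within_r=0.95)
        g = simulate_genotypes(cfg)
        blocks = find_ld_blocks(g, r2_min=0.5)
        assert blocks, "expected at least one block"
        prev_end = {}
        for block in blocks:
            for a in range(len(block.snp_indices)):
                for b in range(a + 1, len(block.snp_indices)):
                    assert ld_r2(g, block.snp_indices[a], block.snp_indices[b]) > 0.5
            # disjoint & ordered within chromosome
            if block.chrom in prev_end:
                assert block.start > prev_end[block.chrom]
            prev_end[block.chrom] = block.end

    def test_region_restriction(self):
        cfg = SimulationConfig(seed=19, ld_within_r=1.0, chromosomes=("1",),
                               blocks_per_chrom=4, n_samples=50)
        g = simulate_genotypes(cfg)
        region = GenomicInterval("1", int(g.pos[5]), int(g.pos[9]))
        blocks = find_ld_blocks(g, region=region)
        assert len(blocks) == 1 and blocks[0].snp_indices == list(range(5, 10))


class TestColocalize:
    def _records(self):
        return pd.DataFrame(
            {
                "snp_id": ["s1", "s2", "s3", "s4"],
                "gene_id": ["gA", "gA", "gB", "gA"],
                "chrom_snp": ["9", "9", "9", "9"],
                "pos_snp": [100, 200, 150, 900],
                "relation": ["cis"] * 4,
                "p": [1e-7, 1e-8, 1e-9, 1e-3],
            }
        )

    def test_snp_exactly_at_interval_end_counted(self):
        report = colocalize(GenomicInterval("9", 150, 200), self._records())
        counts = dict(zip(report.gene_id, report.n_eqtls_in_interval))
        assert counts == {"gA": 1, "gB": 1}

    def test_disjoint_interval_reports_nothing(self):
        report = colocalize(GenomicInterval("7", 100, 200), self._records())
        assert report.empty

    def test_non_significant_records_ignored(self):
        report = colocalize(GenomicInterval("9", 800, 1000), self._records())
        assert "gA" not in set(
            report.loc[report.n_eqtls_in_interval > 0, "gene_id"]
        )


class TestPermutation:
    def _setup(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        S = rng.binomial(2, 0.4, n).astype(float)
        cov = SampleCovariates(
            sample_ids=[f"S{i}" for i in range(n)],
            sex=np.asarray(rng.choice(["M", "F"], n), dtype=object),
            batch=np.asarray(rng.choice(["B1", "B2"], n), dtype=object),
            carcass_weight=rng.normal(100, 5, n),
        )
        return S, cov, rng

    def test_dominant_statistic_attains_add_one_lower_bound(self):
        S, cov, rng = self._setup()
        cov.trait = 3.0 * S + 0.001 * rng.normal(size=len(S))
        g = toy_genotypes(S[:, None])
        res = permutation_assoc(g, [0], cov, n_perm=999, seed=1)
        assert res.p_perm[0] == pytest.approx(1 / 1000)

    def test_duplicated_snp_columns_get_identical_p(self):
        S, cov, rng = self._setup(seed=2)
        cov.trait = 0.8 * S + rng.normal(size=len(S))
        g = toy_genotypes(np.column_stack([S, S]))
        res = permutation_assoc(g, [0, 1], cov, n_perm=500, seed=3)
        assert res.p_perm[0] == res.p_perm[1]
        assert res.p_perm_family[0] == res.p_perm_family[1]

    def test_family_wise_p_not_smaller_than_pointwise(self):
        S, cov, rng = self._setup(seed=4)
        cov.trait = rng.normal(size=len(S))
        g = toy_genotypes(np.column_stack([S, rng.binomial(2, 0.3, len(S))]).astype(float))
        res = permutation_assoc(g, [0, 1], cov, n_perm=300, seed=5)
        assert (res.p_perm_family >= res.p_perm - 1e-12).all()

    def test_null_pointwise_p_roughly_uniform(self):
        ps = []
        for seed in range(40):
            S, cov, rng = self._setup(seed=seed + 10)
            cov.trait = rng.normal(size=len(S))
            g = toy_genotypes(S[:, None])
            res = permutation_assoc(g, [0], cov, n_perm=199, seed=seed)
            ps.append(res.p_perm[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestGwasScan:
    def test_planted_block_contains_minimum_p(self, cohort):
        cfg, geno, cov = cohort["config"], cohort["geno"], cohort["cov"]
        gwas = gwas_scan(geno, cov)
        best = int(np.argmin(gwas.p_value))
        block = cohort["config"].regulator_block
        assert str(gwas.chrom[best]) == block[0]
        block_pos = cfg.block_positions(*block)
        assert block_pos[0] <= gwas.pos[best] <= block_pos[-1]

    def test_null_trait_p_uniform(self):
        cfg = SimulationConfig(seed=31, regulator_effect=0.0, chromosomes=("1", "2"),
                               ld_within_r=0.0)
        geno = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg)
        expr = simulate_expression(geno, cov, cfg)
        cov_t = simulate_trait(expr, cov, cfg)
        gwas = gwas_scan(geno, cov_t)
        assert stats.kstest(gwas.p_value, "uniform").pvalue > 0.01

    def test_constant_trait_raises(self, cohort):
        cov = cohort["cov"].subset_samples(cohort["cov"].sample_ids)
        cov.trait = np.full(cov.n_samples, 5.0)
        with pytest.raises(ValueError, match="constant trait"):
            gwas_scan(cohort["geno"], cov)

    def test_profile_extraction_requires_known_chromosome(self, cohort):
        gwas = gwas_scan(cohort["geno"], cohort["cov"])
        with pytest.raises(ValueError, match="no GWAS records"):
            lod_profile_from_summary(gwas, "99")


class TestGenotypeStratified:
    def test_exact_separation(self):
        S = np.array([0.0] * 5 + [2.0] * 5)
        trait = np.array([1.0] * 5 + [9.0] * 5)
        res = genotype_stratified_test(S, trait)
        assert res["classes"][0]["mean"] == 1.0 and res["classes"][2]["mean"] == 9.0
        assert res["p"] < 1e-10

    def test_mean_and_se_hand_formula(self):
        S = np.array([0.0, 0.0, 0.0, 1.0, 1.0])
        trait = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        res = genotype_stratified_test(S, trait)
        assert res["classes"][0]["mean"] == pytest.approx(2.0)
        assert res["classes"][0]["se"] == pytest.approx(1 / np.sqrt(3))

    def test_singleton_class_reported_mean_only(self):
        S = np.array([0.0] * 4 + [1.0] * 4 + [2.0])
        trait = np.arange(9, dtype=float)
        res = genotype_stratified_test(S, trait)
        assert res["classes"][2] == {"n": 1, "mean": 8.0, "se": None}
        assert res["compared"] == (0, 1)

    def test_fewer_than_two_usable_classes_raises(self):
        with pytest.raises(ValueError, match="genotype classes"):
            genotype_stratified_test(np.zeros(6), np.arange(6, dtype=float))
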
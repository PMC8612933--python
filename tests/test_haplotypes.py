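import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ttest_ind

from cicerscan.haplotypes import (
    HaploPhenoResult,
    accession_scores,
    build_ld_blocks,
    duncan_letters,
    haplo_pheno_scan,
    identify_donors,
    local_gebvs,
    stack_haplotypes,
)
from cicerscan.prediction import MarkerEffects, fit_rrblup
from cicerscan.simulate import PopulationSpec, SimConfig, TraitSpec, simulate_genotypes, simulate_phenotypes
from conftest import make_gm


def effects_for(g, beta, mu=0.0):
    beta = np.asarray(beta, dtype=float)
    return MarkerEffects(mu=mu, beta=beta, lambda_=1.0, sigma_g2=1.0, sigma_e2=1.0,
                         freqs=np.zeros(beta.size))


class TestBuildLdBlocks:
    def test_duplicated_columns_one_block(self, rng):
        col = rng.binomial(2, 0.5, 30).astype(np.int8)
        g = make_gm(np.column_stack([col, col, col]), positions=[100, 200, 300])
        blocks = build_ld_blocks(g)
        assert len(blocks) == 1
        assert blocks[0].marker_index.tolist() == [0, 1, 2]

    def test_independent_markers_singletons(self, rng):
        d = rng.binomial(2, rng.uniform(0.3, 0.7, 10), size=(200, 10)).astype(np.int8)
        g = make_gm(d, positions=np.arange(1, 11) * 100)
        blocks = build_ld_blocks(g, r2_min=0.7)
        assert len(blocks) == 10

    def test_span_cap_splits(self, rng):
        col = rng.binomial(2, 0.5, 30).astype(np.int8)
        g = make_gm(
            np.column_stack([col] * 5),
            positions=[1, 100_001, 200_001, 300_001, 400_001],
        )
        blocks = build_ld_blocks(g, max_span=200_000)
        assert len(blocks) >= 2
        pos = g.variants["pos"].to_numpy()
        for b in blocks:
            assert pos[b.marker_index[-1]] - pos[b.marker_index[0]] <= 200_000

    def test_partition_property(self, rng):
        d = rng.integers(0, 3, size=(40, 25)).astype(np.int8)
        g = make_gm(d, positions=np.sort(rng.choice(10_000, 25, replace=False)) + 1)
        blocks = build_ld_blocks(g, r2_min=0.5)
        all_members = np.concatenate([b.marker_index for b in blocks])
        assert sorted(all_members.tolist()) == list(range(25))

    def test_blocks_respect_chromosomes(self, rng):
        col = rng.binomial(2, 0.5, 30).astype(np.int8)
        g = make_gm(np.column_stack([col, col]), positions=[100, 100],
                    chrom=["Ca1", "Ca2"])
        blocks = build_ld_blocks(g)
        assert len(blocks) == 2


class TestLocalGebvs:
    def test_single_marker_block(self):
        g = make_gm([[0], [2], [2]])
        blocks = build_ld_blocks(g)
        blocks = local_gebvs(blocks, effects_for(g, [0.4]), g)
        assert blocks[0].local_gebv == {"0": 0.0, "1": pytest.approx(0.4)}

    def test_two_marker_block_arithmetic(self):
        d = np.array([[2, 2], [0, 0], [2, 2]], dtype=np.int8)
        g = make_gm(d, positions=[10, 20])
        blocks = build_ld_blocks(g, r2_min=0.5)
        assert len(blocks) == 1
        blocks = local_gebvs(blocks, effects_for(g, [0.3, -0.1]), g)
        assert blocks[0].local_gebv["11"] == pytest.approx(0.2)
        assert blocks[0].local_gebv["00"] == pytest.approx(0.0)

    def test_zero_effects_zero_variance(self, rng):
        d = (2 * rng.integers(0, 2, size=(10, 3))).astype(np.int8)
        g = make_gm(d)
        blocks = local_gebvs(build_ld_blocks(g, r2_min=0.0), effects_for(g, [0, 0, 0]), g)
        for b in blocks:
            if b.local_gebv:
                assert b.gebv_variance == pytest.approx(0.0)

    def test_het_accessions_excluded(self):
        d = np.array([[1, 1], [0, 0], [2, 2]], dtype=np.int8)
        g = make_gm(d, positions=[10, 20])
        blocks = local_gebvs(build_ld_blocks(g, r2_min=0.5), effects_for(g, [1.0, 1.0]), g)
        carriers = set(itertools.chain.from_iterable(b.haplotypes.get(h, []) for b in blocks for h in b.haplotypes))
        assert 0 not in carriers  # the het accession contributes nothing

    def test_block_sum_equals_accession_score(self, rng):
        # inbred panel: per-accession sum of 2 x own-haplotype local GEBVs
        # over all blocks equals the marker score
        cfg = SimConfig(
            seed=3, populations=[PopulationSpec("p", 40, 0.2)],
            chrom_lengths={"Ca1": 5_000}, n_variants_per_chrom=60, inbred=True,
        )
        g, _ = simulate_genotypes(cfg)
        beta = rng.normal(0, 0.3, g.n_variants)
        eff = effects_for(g, beta)
        blocks = local_gebvs(build_ld_blocks(g, r2_min=0.3), eff, g)
        scores = accession_scores(eff, g)
        for i in range(g.n_samples):
            total = 0.0
            for b in blocks:
                hap = "".join("1" if x == 2 else "0" for x in g.dosages[i, b.marker_index])
                total += 2.0 * b.local_gebv[hap]
            assert total == pytest.approx(scores[i], abs=1e-8)


class TestStackHaplotypes:
    def _inbred_panel(self, seed=5, n=30, m=24):
        cfg = SimConfig(
            seed=seed, populations=[PopulationSpec("p", n, 0.2)],
            chrom_lengths={"Ca1": 10_000}, n_variants_per_chrom=m, inbred=True,
        )
        g, _ = simulate_genotypes(cfg)
        return g

    def test_dominates_all_accessions(self, rng):
        g = self._inbred_panel()
        eff = effects_for(g, rng.normal(0, 0.5, g.n_variants))
        blocks = local_gebvs(build_ld_blocks(g, r2_min=0.4), eff, g)
        out = stack_haplotypes(blocks, eff, g)
        assert out["stacked_value"] >= out["accession_values"].max() - 1e-10

    def test_attainment_ratio_one(self):
        # single accession duplicated: it carries every best haplotype
        d = (2 * np.array([[1, 0, 1, 1]] * 5)).astype(np.int8)
        g = make_gm(d)
        eff = effects_for(g, [0.5, -0.2, 0.3, 0.1])
        blocks = local_gebvs(build_ld_blocks(g, r2_min=0.0), eff, g)
        out = stack_haplotypes(blocks, eff, g)
        assert out["stacked_value"] == pytest.approx(out["best_accession_value"], abs=1e-12)
        assert out["ratio"] == pytest.approx(1.0)

    def test_bruteforce_oracle_small(self, rng):
        # <= 8 blocks: exhaustive search over observed haplotype combinations
        g = self._inbred_panel(seed=7, n=25, m=16)
        eff = effects_for(g, rng.normal(0, 0.5, g.n_variants))
        blocks = local_gebvs(build_ld_blocks(g, r2_min=0.4), eff, g)
        usable = [b for b in blocks if b.local_gebv]
        if len(usable) > 8:
            usable = usable[:8]
        out = stack_haplotypes(usable, eff, g)
        best = -np.inf
        for combo in itertools.product(*(list(b.local_gebv.values()) for b in usable)):
            best = max(best, 2.0 * sum(combo))
        assert out["stacked_value"] == pytest.approx(best, abs=1e-10)

    def test_dispersed_alleles_ratio_above_one(self):
        # favourable alleles split across two accessions
        d = (2 * np.array([[1, 0], [0, 1], [0, 0]])).astype(np.int8)
        g = make_gm(d, positions=[10, 10_000])
        eff = effects_for(g, [1.0, 1.0])
        blocks = local_gebvs(build_ld_blocks(g, r2_min=0.99), eff, g)
        out = stack_haplotypes(blocks, eff, g)
        assert out["stacked_value"] == pytest.approx(4.0)
        assert out["ratio"] > 1.0


class TestDuncan:
    def test_two_groups_match_t_test(self, rng):
        # with 2 groups Duncan reduces to a two-sample comparison at alpha
        for shift in (0.0, 0.5, 3.0):
            a = rng.normal(0, 1, 20)
            b = rng.normal(shift, 1, 20)
            means = np.array([a.mean(), b.mean()])
            ns = np.array([20, 20])
            df = 38
            mse = (a.var(ddof=1) * 19 + b.var(ddof=1) * 19) / df
            letters = duncan_letters(means, ns, mse, df, alpha=0.05)
            distinct = not (set(letters[0]) & set(letters[1]))
            t_sig = ttest_ind(a, b).pvalue < 0.05
            assert distinct == t_sig, shift

    def test_clear_separation_letters(self):
        means = np.array([10.0, 20.0, 30.0])
        ns = np.array([10, 10, 10])
        letters = duncan_letters(means, ns, mse=1.0, df_error=27)
        assert len(set(letters)) == 3

    def test_identical_means_share_letter(self):
        means = np.array([10.0, 10.01, 10.02])
        letters = duncan_letters(means, np.array([5, 5, 5]), mse=4.0, df_error=12)
        assert len(set(letters)) == 1


def _haplo_fixture(rng, delta=14.0, n_per=20, n_env=2, sd=1.0):
    """Two haplotype groups with a planted trait difference."""
    hapA = [1, 0]
    hapB = [0, 1]
    d = np.array([np.repeat([2 * x for x in hapA], 1) for _ in range(n_per)]
                 + [np.repeat([2 * x for x in hapB], 1) for _ in range(n_per)], dtype=np.int8)
    g = make_gm(d, positions=[100, 200])
    rows = []
    for e in range(n_env):
        for i in range(2 * n_per):
            base = 30.0 if i < n_per else 30.0 - delta
            rows.append((f"s{i}", "100SW", f"E{e}", base + rng.normal(0, sd)))
    pheno = pd.DataFrame(rows, columns=["accession", "trait", "environment", "value"])
    return g, pheno


class TestHaploPhenoScan:
    def test_planted_difference_detected(self, rng):
        g, pheno = _haplo_fixture(rng)
        res = haplo_pheno_scan(g, {"r1": np.array([0, 1])}, pheno, "100SW")[0]
        assert res.superior == "10"
        assert res.is_superior_stable
        assert res.consistency == 2

    def test_direction_min(self, rng):
        g, pheno = _haplo_fixture(rng)
        res = haplo_pheno_scan(g, {"r1": np.array([0, 1])}, pheno, "100SW", direction="min")[0]
        assert res.superior == "01"

    def test_null_no_superior(self, rng):
        g, pheno = _haplo_fixture(rng, delta=0.0)
        res = haplo_pheno_scan(g, {"r1": np.array([0, 1])}, pheno, "100SW")[0]
        assert not res.is_superior_stable

    def test_singleton_groups_removed(self, rng):
        d = np.array([[2, 0]] * 10 + [[0, 2]] * 10 + [[2, 2]], dtype=np.int8)
        g = make_gm(d, positions=[100, 200])
        rows = [(f"s{i}", "t", "E0", float(i < 10) * 10 + np.random.rand()) for i in range(21)]
        pheno = pd.DataFrame(rows, columns=["accession", "trait", "environment", "value"])
        res = haplo_pheno_scan(g, {"r1": np.array([0, 1])}, pheno, "t")[0]
        assert "11" not in set(res.groups["haplotype"])

    def test_too_few_groups_skipped(self, rng):
        d = np.array([[2, 0]] * 10, dtype=np.int8)
        g = make_gm(d, positions=[100, 200])
        rows = [(f"s{i}", "t", "E0", float(i)) for i in range(10)]
        pheno = pd.DataFrame(rows, columns=["accession", "trait", "environment", "value"])
        res = haplo_pheno_scan(g, {"r1": np.array([0, 1])}, pheno, "t")[0]
        assert res.skipped_reason is not None


class TestIdentifyDonors:
    def test_donors_are_carriers_sorted(self, rng):
        g, pheno = _haplo_fixture(rng)
        regions = {"r1": np.array([0, 1])}
        res = haplo_pheno_scan(g, regions, pheno, "100SW")[0]
        donors = identify_donors(res, g, regions, pheno)
        # containment: donors must be homozygous superior-haplotype carriers
        assert set(donors["id"]) <= {f"s{i}" for i in range(20)}
        tm = donors["trait_mean"].to_numpy()
        assert (np.diff(tm) <= 1e-12).all()

    def test_no_superior_errors(self):
        res = HaploPhenoResult("r", "t", pd.DataFrame(), None, "max", 0, 0, False)
        with pytest.raises(ValueError, match="superior"):
            identify_donors(res, make_gm([[0]]), {"r": np.array([0])})
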
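"""Simulator properties: pedigree structure, Mendelian gene drop, trait model."""

import numpy as np
import pandas as pd
import pytest

from wssgblup import SimConfig, simulate_dataset
from wssgblup.popsim import (
    ConfigurationError,
    assign_qtl_and_phenotypes,
    simulate_genotypes,
    simulate_pedigree,
    write_dataset,
)


class TestConfigValidation:
    def test_h2_plus_c2_bound(self):
        with pytest.raises(ConfigurationError, match="h2"):
            SimConfig(h2=0.7, c2_family=0.4)

    def test_shares_must_match_n_qtl(self):
        with pytest.raises(ConfigurationError, match="shares"):
            SimConfig(n_qtl=3, qtl_variance_shares=(0.1,))

    def test_shares_sum_bound(self):
        with pytest.raises(ConfigurationError, match="sum"):
            SimConfig(n_qtl=2, qtl_variance_shares=(0.6, 0.6))


class TestPedigree:
    def test_minimal_two_founders_one_family(self):
        cfg = SimConfig(
            n_founders=2, n_generations=1, n_families_per_gen=1,
            n_offspring_per_family=3, n_chromosomes=1, snps_per_chromosome=10,
            n_qtl=0, qtl_variance_shares=(), seed=0,
        )
        ped = simulate_pedigree(cfg)
        assert len(ped) == 5
        offspring = [i for i in range(5) if ped.sire_idx[i] >= 0]
        assert len(offspring) == 3
        sires = {ped.sire_idx[i] for i in offspring}
        dams = {ped.dam_idx[i] for i in offspring}
        assert len(sires) == 1 and len(dams) == 1 and sires != dams

    def test_zero_generations_founders_only(self):
        cfg = SimConfig(
            n_founders=7, n_generations=0, n_qtl=0, qtl_variance_shares=(),
            n_chromosomes=1, snps_per_chromosome=10, seed=0,
        )
        ped = simulate_pedigree(cfg)
        assert len(ped) == 7
        assert ped.is_founder.all()

    def test_impossible_configuration_raises(self):
        cfg = SimConfig(
            n_founders=3, n_generations=1, n_families_per_gen=5,
            n_offspring_per_family=2, n_chromosomes=1, snps_per_chromosome=10,
            n_qtl=0, qtl_variance_shares=(), seed=0,
        )
        with pytest.raises(ConfigurationError, match="parents"):
            simulate_pedigree(cfg)

    def test_seeded_determinism(self, tmp_path):
        cfg = SimConfig(
            n_founders=50, n_generations=2, n_families_per_gen=20,
            n_offspring_per_family=5, n_chromosomes=2, snps_per_chromosome=40,
            seed=77,
        )
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        p1 = write_dataset(d1, tmp_path / "r1")
        p2 = write_dataset(d2, tmp_path / "r2")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes(), key


@pytest.fixture(scope="module")
def dataset():
    cfg = SimConfig(
        n_founders=40, n_generations=2, n_families_per_gen=15,
        n_offspring_per_family=4, n_chromosomes=3, snps_per_chromosome=80,
        missing_rate=0.0, seed=5,
    )
    return simulate_dataset(cfg)


class TestGeneDrop:
    def test_mendelian_consistency(self, dataset):
        """Every offspring genotype must be attainable from its parents."""
        ped = dataset.pedigree
        M = dataset.truth_codes
        for i in range(len(ped)):
            s, d = ped.sire_idx[i], ped.dam_idx[i]
            if s < 0:
                continue
            # child code must lie within the Mendelian range of parent codes
            lo = (M[s] > 1).astype(float) + (M[d] > 1).astype(float)
            hi = 2.0 - ((M[s] < 1).astype(float) + (M[d] < 1).astype(float))
            assert np.all(M[i] >= lo) and np.all(M[i] <= hi)

    def test_zero_length_chromosome_no_recombination(self):
        """With zero genetic length each gamete is one intact parental
        haplotype, so a founder child's chromosome equals one of the four
        parental haplotype sums."""
        cfg = SimConfig(
            n_founders=10, n_generations=1, n_families_per_gen=4,
            n_offspring_per_family=3, n_chromosomes=2, snps_per_chromosome=30,
            chromosome_length_morgans=0.0, missing_rate=0.0, seed=9,
        )
        ped = simulate_pedigree(cfg)
        geno, truth, founder_haps = simulate_genotypes(ped, cfg)
        founder_row = {}
        k = 0
        for i in range(len(ped)):
            if ped.is_founder[i]:
                founder_row[i] = k
                k += 1
        m = cfg.snps_per_chromosome
        for i in range(len(ped)):
            s, d = ped.sire_idx[i], ped.dam_idx[i]
            if s < 0:
                continue
            hs = founder_haps[2 * founder_row[s]: 2 * founder_row[s] + 2]
            hd = founder_haps[2 * founder_row[d]: 2 * founder_row[d] + 2]
            for c in range(cfg.n_chromosomes):
                sl = slice(c * m, (c + 1) * m)
                child = truth[i, sl]
                candidates = [
                    hs[a, sl] + hd[b, sl] for a in range(2) for b in range(2)
                ]
                assert any(np.array_equal(child, cand) for cand in candidates)

    def test_founder_adjacent_correlation(self):
        """Markov founder haplotypes: mean adjacent-indicator correlation
        close to the configured value (0.9 +/- 0.05 at 1000 haplotypes)."""
        cfg = SimConfig(
            n_founders=500, n_generations=0, n_chromosomes=2,
            snps_per_chromosome=200, founder_hap_correlation=0.9,
            n_qtl=0, qtl_variance_shares=(), seed=13,
        )
        ped = simulate_pedigree(cfg)
        _, _, H = simulate_genotypes(ped, cfg)
        m = cfg.snps_per_chromosome
        cors = []
        for c in range(cfg.n_chromosomes):
            for j in range(1, m):
                a = H[:, c * m + j - 1].astype(float)
                b = H[:, c * m + j].astype(float)
                if a.std() > 0 and b.std() > 0:
                    cors.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(cors) == pytest.approx(0.9, abs=0.05)


class TestTraitModel:
    def test_no_qtl_means_zero_tbv(self):
        cfg = SimConfig(
            n_founders=20, n_generations=1, n_families_per_gen=8,
            n_offspring_per_family=4, n_chromosomes=1, snps_per_chromosome=50,
            n_qtl=0, qtl_variance_shares=(), seed=3,
        )
        ds = simulate_dataset(cfg)
        assert np.all(ds.truth.true_breeding_values.to_numpy() == 0.0)

    def test_tbv_is_dot_product_of_causal_genotypes(self):
        cfg = SimConfig(
            n_founders=30, n_generations=1, n_families_per_gen=12,
            n_offspring_per_family=4, n_chromosomes=2, snps_per_chromosome=60,
            n_qtl=2, qtl_variance_shares=(0.5, 0.5), missing_rate=0.0, seed=4,
        )
        ds = simulate_dataset(cfg)
        t = ds.truth
        assert len(t.background_snp_indices) == 0  # shares sum to 1
        M = ds.truth_codes
        Zc = M - M.mean(axis=0)
        expect = Zc[:, t.qtl_snp_indices] @ t.qtl_effects
        np.testing.assert_allclose(
            t.true_breeding_values.to_numpy(), expect, atol=1e-10
        )

    def test_phenotype_regression_on_tbv_slope_near_one(self):
        """Large-sample additive model: slope of phenotype on TBV ~ 1."""
        cfg = SimConfig(
            n_founders=400, n_generations=1, n_families_per_gen=200,
            n_offspring_per_family=10, n_chromosomes=2, snps_per_chromosome=100,
            n_qtl=4, qtl_variance_shares=(0.1, 0.1, 0.1, 0.1), h2=0.4, seed=21,
        )
        ds = simulate_dataset(cfg)
        merged = ds.phenotypes.merge(
            ds.truth.true_breeding_values.rename("tbv"),
            left_on="animal", right_index=True,
        )
        slope = np.polyfit(merged["tbv"], merged["trait"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.1)

    def test_realized_h2_converges(self):
        """Var(TBV)/Var(y) ~ h2 (+/- 0.05, averaged over 5 seeds, n >= 2000)."""
        ratios = []
        for seed in range(5):
            cfg = SimConfig(
                n_founders=420, n_generations=1, n_families_per_gen=200,
                n_offspring_per_family=10, n_chromosomes=2,
                snps_per_chromosome=100, n_qtl=2,
                qtl_variance_shares=(0.1, 0.1), h2=0.4, seed=400 + seed,
            )
            ds = simulate_dataset(cfg)
            merged = ds.phenotypes.merge(
                ds.truth.true_breeding_values.rename("tbv"),
                left_on="animal", right_index=True,
            )
            ratios.append(merged["tbv"].var() / merged["trait"].var())
        assert np.mean(ratios) == pytest.approx(0.4, abs=0.05)

    def test_family_intraclass_correlation_positive(self):
        """With c2 > 0, within-family correlation exceeds between-family."""
        import scipy.stats as st

        cfg = SimConfig(
            n_founders=220, n_generations=1, n_families_per_gen=100,
            n_offspring_per_family=10, n_chromosomes=2, snps_per_chromosome=80,
            n_qtl=2, qtl_variance_shares=(0.1, 0.1), c2_family=0.15, seed=31,
        )
        ds = simulate_dataset(cfg)
        df = ds.phenotypes
        groups = [g["trait"].to_numpy() for _, g in df.groupby("family")]
        fstat, p = st.f_oneway(*groups)
        assert fstat > 1.0 and p < 0.01

    def test_trait_mean_and_sd_on_target(self):
        cfg = SimConfig(seed=8)  # defaults: ~784 phenotyped
        ds = simulate_dataset(cfg)
        assert ds.phenotypes["trait"].mean() == pytest.approx(48.91, abs=0.5)
        assert ds.phenotypes["trait"].std() == pytest.approx(2.42, abs=0.4)

    def test_harvest_groups_cycle_within_family(self):
        cfg = SimConfig(
            n_founders=20, n_generations=1, n_families_per_gen=8,
            n_offspring_per_family=10, n_chromosomes=1, snps_per_chromosome=30,
            n_harvest_groups=5, seed=6,
        )
        ds = simulate_dataset(cfg)
        counts = ds.phenotypes.groupby(["family", "harvest_group"]).size()
        assert counts.max() == 2  # 10 offspring over 5 weekly groups

    def test_too_many_qtl_raises(self):
        cfg = SimConfig(
            n_founders=10, n_generations=1, n_families_per_gen=4,
            n_offspring_per_family=3, n_chromosomes=1, snps_per_chromosome=5,
            n_qtl=5, qtl_variance_shares=(0.2,) * 5, seed=1,
        )
        ped = simulate_pedigree(cfg)
        geno, truth, _ = simulate_genotypes(ped, cfg)
        # force monomorphism so fewer than 5 polymorphic SNPs remain
        truth[:, :3] = 2.0
        with pytest.raises(ConfigurationError, match="polymorphic"):
            assign_qtl_and_phenotypes(geno, ped, cfg, truth)
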
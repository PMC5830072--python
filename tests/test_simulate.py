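import numpy as np
import pytest
from scipy import stats

import sirescan as ss
from sirescan.simulate import SimulationConfigError


class TestConfigValidation:
    def test_bad_maf_bounds(self):
        with pytest.raises(SimulationConfigError):
            ss.SimulationConfig(maf_low=0.0)
        with pytest.raises(SimulationConfigError):
            ss.SimulationConfig(maf_low=0.3, maf_high=0.2)
        with pytest.raises(SimulationConfigError):
            ss.SimulationConfig(maf_high=0.6)

    def test_qtl_index_bounds(self):
        with pytest.raises(SimulationConfigError, match="out of range"):
            ss.SimulationConfig(n_snps=10, qtl_specs=(ss.QtlSpec(10, "dominance", 1.0),))

    def test_bad_variances(self):
        with pytest.raises(SimulationConfigError):
            ss.SimulationConfig(sigma_e2=0.0)
        with pytest.raises(SimulationConfigError):
            ss.SimulationConfig(sigma_u2=-1.0)


class TestSimulateGenotypes:
    def test_seed_determinism(self):
        cfg = ss.SimulationConfig(n_sires=10, offspring_per_sire=4, n_snps=100, seed=3)
        a = ss.simulate_genotypes(cfg)
        b = ss.simulate_genotypes(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.individual_ids == b.individual_ids
        c = ss.simulate_genotypes(
            ss.SimulationConfig(n_sires=10, offspring_per_sire=4, n_snps=100, seed=4)
        )
        assert not np.array_equal(a.dosages, c.dosages)

    def test_hardy_weinberg_at_half(self):
        cfg = ss.SimulationConfig(
            n_sires=4000, offspring_per_sire=1, n_snps=30, maf_low=0.5, maf_high=0.5, seed=5
        )
        gm = ss.simulate_genotypes(cfg)
        n = gm.n_individuals
        for target, expect in ((0.0, 0.25), (1.0, 0.50), (2.0, 0.25)):
            freq = (gm.dosages == target).mean(axis=0)
            band = 3 * np.sqrt(expect * (1 - expect) / n)
            assert (np.abs(freq - expect) < band).mean() > 0.9  # 3σ per class

    def test_empirical_frequency_tracks_drawn_frequency(self):
        """Every SNP's realised allele count sits inside a 99.9% binomial band
        around its drawn frequency (500 individuals × 2,000 SNPs)."""
        cfg = ss.SimulationConfig(
            n_sires=500, offspring_per_sire=1, n_snps=2000, maf_low=0.05, maf_high=0.5, seed=6
        )
        # reproduce the generator's frequency draw (documented RNG contract:
        # frequencies are the first draw from the config seed)
        p = np.random.default_rng(cfg.seed).uniform(cfg.maf_low, cfg.maf_high, cfg.n_snps)
        gm = ss.simulate_genotypes(cfg)
        counts = gm.dosages.sum(axis=0)
        n_alleles = 2 * gm.n_individuals
        lo = stats.binom.ppf(0.0005, n_alleles, p)
        hi = stats.binom.ppf(0.9995, n_alleles, p)
        inside = (counts >= lo) & (counts <= hi)
        # expected exceedances ≈ 0.001 × 2000 = 2; ten would be wildly unlikely
        assert (~inside).sum() <= 10, f"{(~inside).sum()} SNPs outside their 99.9% band"

    def test_halfsib_relatedness_exceeds_across_family(self):
        cfg = ss.SimulationConfig(n_sires=12, offspring_per_sire=6, n_snps=1500, seed=7)
        gm = ss.simulate_genotypes(cfg)
        g = ss.compute_grm(gm, ridge=0.0).g
        fam = np.repeat(np.arange(12), 6)
        off_diag = ~np.eye(g.shape[0], dtype=bool)
        within = g[(fam[:, None] == fam[None, :]) & off_diag].mean()
        across = g[fam[:, None] != fam[None, :]].mean()
        assert within > across


class TestPlantQtls:
    def test_empty_spec_list(self, small_halfsib):
        _, gm, _, _ = small_halfsib
        np.testing.assert_array_equal(ss.plant_qtls(gm, []), 0.0)

    def test_dominance_carrier_contrast_is_exact_effect(self, small_halfsib):
        _, gm, _, _ = small_halfsib
        b = 1.7
        g = ss.plant_qtls(gm, [ss.QtlSpec(2, ss.CodingModel.DOMINANCE, b)])
        d = gm.dosages[:, 2]
        carriers = g[d >= 1].mean()
        noncarriers = g[d == 0].mean()
        assert carriers - noncarriers == pytest.approx(b)

    def test_overdominance_homozygotes_identical(self, small_halfsib):
        _, gm, _, _ = small_halfsib
        b = -0.9
        g = ss.plant_qtls(gm, [ss.QtlSpec(4, ss.CodingModel.OVERDOMINANCE, b)])
        d = gm.dosages[:, 4]
        homo = g[(d == 0) | (d == 2)]
        assert homo.size and np.ptp(homo) == 0  # both homozygote classes identical
        assert g[d == 1].mean() - homo[0] == pytest.approx(b)

    def test_out_of_range_index(self, small_halfsib):
        _, gm, _, _ = small_halfsib
        with pytest.raises(IndexError):
            ss.plant_qtls(gm, [ss.QtlSpec(gm.n_markers, ss.CodingModel.ADDITIVE, 1.0)])

    def test_effects_sum_across_qtls(self, small_halfsib):
        _, gm, _, _ = small_halfsib
        specs = [
            ss.QtlSpec(0, ss.CodingModel.ADDITIVE, 0.5),
            ss.QtlSpec(1, ss.CodingModel.RECESSIVE, -1.0),
        ]
        total = ss.plant_qtls(gm, specs)
        parts = ss.plant_qtls(gm, specs[:1]) + ss.plant_qtls(gm, specs[1:])
        np.testing.assert_allclose(total, parts)


class TestSimulatePhenotypes:
    def test_residual_only_variance_band(self):
        cfg = ss.SimulationConfig(n_sires=400, offspring_per_sire=1, n_snps=50, seed=8)
        gm = ss.simulate_genotypes(cfg)
        y, truth = ss.simulate_phenotypes(gm, [], sigma_u2=0.0, sigma_e2=4.0, seed=8)
        n = len(y)
        lo, hi = stats.chi2.ppf([0.005, 0.995], df=n - 1) / (n - 1)
        assert lo * 4.0 < y.var(ddof=1) < hi * 4.0
        assert truth.qtls.empty

    def test_duplicated_individuals_share_polygenic_value(self):
        """Identical genotype rows get unit-correlated polygenic draws."""
        cfg = ss.SimulationConfig(n_sires=30, offspring_per_sire=1, n_snps=400, seed=9)
        gm = ss.simulate_genotypes(cfg)
        d = np.vstack([gm.dosages, gm.dosages[:1]])  # duplicate first individual
        gm2 = ss.GenotypeMatrix(
            dosages=d, individual_ids=[*gm.individual_ids, "dup"], markers=gm.markers
        )
        diffs = []
        for seed in range(10):
            y, _ = ss.simulate_phenotypes(gm2, [], sigma_u2=5.0, sigma_e2=1e-8, seed=seed)
            diffs.append(y[-1] - y[0])
        # u for the duplicate equals u for the original up to the GRM ridge
        assert np.std(diffs) < 0.05 * 5.0

    def test_truth_table_records_frequencies(self, small_halfsib):
        _, gm, _, _ = small_halfsib
        specs = [ss.QtlSpec(3, ss.CodingModel.RECESSIVE, 2.0)]
        _, truth = ss.simulate_phenotypes(gm, specs, 1.0, 1.0, seed=1)
        row = truth.qtls.iloc[0]
        assert row["model"] == "recessive"
        assert row["freq_AA"] + row["freq_AB"] + row["freq_BB"] == pytest.approx(1.0)
        assert row["snp_id"] == gm.markers[3].snp_id

    def test_dataset_seed_determinism(self):
        cfg = ss.SimulationConfig(n_sires=8, offspring_per_sire=3, n_snps=60, seed=11)
        gm1, y1, _ = ss.simulate_dataset(cfg)
        gm2, y2, _ = ss.simulate_dataset(cfg)
        np.testing.assert_array_equal(gm1.dosages, gm2.dosages)
        np.testing.assert_array_equal(y1, y2)
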
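import numpy as np
import pytest

import sirescan as ss
from sirescan.coding import NON_ADDITIVE_MODELS

from oracles import dense_gls_wald, ols_slope_z


class TestSnpTest:
    def test_matches_dense_gls_wald_across_codings(self, small_nullfit):
        """Score z ≡ Wald z of a joint GLS fit with the explicit V₀ inverse."""
        gm, y, grm, nf = small_nullfit
        v0 = grm.g * nf.vc.sigma_u2 + np.eye(grm.n) * nf.vc.sigma_e2
        checked = 0
        for j in range(min(gm.n_markers, 25)):
            for model in ss.CodingModel:
                x = ss.encode_genotypes(gm.dosages[:, j], model)
                beta, se, z, p_raw = ss.snp_test(x, nf)
                if not np.isfinite(z):
                    continue
                b_o, se_o, z_o = dense_gls_wald(y, nf.X, x, v0)
                assert z == pytest.approx(z_o, abs=1e-6)
                assert beta == pytest.approx(b_o, abs=1e-6)
                assert se == pytest.approx(se_o, abs=1e-6)
                checked += 1
        assert checked > 50

    def test_orthogonal_vector_gives_zero_statistic(self, small_nullfit):
        """x ∝ V₀·(something orthogonal to residuals) → z = 0, p = 1."""
        _, _, _, nf = small_nullfit
        r = nf.residuals
        # x = V₀·w with w ⊥ r has xᵀV₀⁻¹r = wᵀr = 0, and the fixed-effect
        # projection cannot change the numerator (XᵀV₀⁻¹r = 0)
        rng = np.random.default_rng(0)
        w = rng.standard_normal(len(r))
        w -= (w @ r) / (r @ r) * r
        beta, se, z, p = ss.snp_test(nf.v0_dense() @ w, nf)
        assert abs(z) < 1e-8
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_constant_coded_vector_flagged_untestable(self, small_nullfit):
        _, _, _, nf = small_nullfit
        out = ss.snp_test(np.full(len(nf.y), 2.0), nf)
        assert all(np.isnan(v) for v in out)

    def test_ols_limit_when_no_genetic_variance(self):
        """With σ̂u²=0 and X=intercept the statistic is the classical OLS
        slope z with residual variance fixed at σ̂e²."""
        rng = np.random.default_rng(77)
        cfg = ss.SimulationConfig(n_sires=60, offspring_per_sire=1, n_snps=80, seed=77)
        gm = ss.simulate_genotypes(cfg)
        grm = ss.compute_grm(gm)
        y = rng.standard_normal(gm.n_individuals)
        nf = ss.fit_null(y, None, grm)
        nf.vc.sigma_u2 = 0.0  # force the diagonal limit
        x = gm.dosages[:, 3]
        _, _, z, _ = ss.snp_test(x, nf)
        assert z == pytest.approx(ols_slope_z(y, x, nf.vc.sigma_e2), abs=1e-10)


class TestGenomeScan:
    def test_every_marker_reports_both_nonadd_and_additive(self, small_nullfit):
        gm, y, _, nf = small_nullfit
        res = ss.genome_scan(gm, y, nf, models=[ss.CodingModel.DOMINANCE])
        models = set(res.table["model"])
        assert models == {"dominance", "additive"}
        assert (res.table.groupby("model").size() == gm.n_markers).all()

    def test_scan_rows_match_single_tests(self, small_nullfit):
        gm, y, _, nf = small_nullfit
        res = ss.genome_scan(gm, y, nf)
        for model in ss.CodingModel:
            sub = res.results_for(model).reset_index(drop=True)
            for j in (0, gm.n_markers // 2, gm.n_markers - 1):
                x = ss.encode_genotypes(gm.dosages[:, j], model)
                beta, se, z, p_raw = ss.snp_test(x, nf)
                row = sub.iloc[j]
                if np.isnan(z):
                    assert np.isnan(row["z"])
                else:
                    assert row["z"] == pytest.approx(z, abs=1e-9)
                    assert row["p_raw"] == pytest.approx(p_raw, abs=1e-12)

    def test_marker_order_equivariance(self, small_nullfit):
        gm, y, _, nf = small_nullfit
        perm = np.random.default_rng(5).permutation(gm.n_markers)
        res = ss.genome_scan(gm, y, nf, models=[ss.CodingModel.RECESSIVE])
        res_p = ss.genome_scan(gm.subset_markers(perm), y, nf, models=[ss.CodingModel.RECESSIVE])
        a = res.results_for(ss.CodingModel.RECESSIVE).set_index("snp_id")
        b = res_p.results_for(ss.CodingModel.RECESSIVE).set_index("snp_id")
        for col in ("z", "p_raw", "beta"):
            np.testing.assert_allclose(
                a[col].loc[b.index].to_numpy(), b[col].to_numpy(), atol=1e-12
            )

    def test_id_misalignment_is_hard_error(self, small_nullfit):
        gm, y, _, nf = small_nullfit
        shuffled = ss.GenotypeMatrix(
            dosages=gm.dosages[::-1].copy(),
            individual_ids=list(gm.individual_ids[::-1]),
            markers=gm.markers,
        )
        with pytest.raises(ValueError, match="order|ids"):
            ss.genome_scan(shuffled, y[::-1], nf)

    def test_untestable_recessive_marker_flagged(self, small_nullfit):
        """A marker with no BB individuals is untestable under the recessive
        coding but still testable additively."""
        gm, y, _, nf = small_nullfit
        d = gm.dosages.copy()
        d[:, 0] = np.where(d[:, 0] == 2.0, 1.0, d[:, 0])
        if (d[:, 0] == 1.0).sum() == 0:
            d[0, 0] = 1.0
        gm2 = ss.GenotypeMatrix(dosages=d, individual_ids=list(gm.individual_ids), markers=gm.markers)
        res = ss.genome_scan(gm2, y, nf, models=[ss.CodingModel.RECESSIVE])
        rec = res.results_for(ss.CodingModel.RECESSIVE).iloc[0]
        add = res.results_for(ss.CodingModel.ADDITIVE).iloc[0]
        assert np.isnan(rec["z"]) and np.isnan(rec["p_raw"])
        assert np.isfinite(add["z"])

    def test_overdominance_design_identity(self, small_nullfit):
        """x_od = x_dom − x_rec at the design level, hence the same identity
        links the score numerators."""
        gm, _, _, nf = small_nullfit
        d = gm.imputed_dosages()
        dom = ss.encode_genotypes(d, ss.CodingModel.DOMINANCE)
        rec = ss.encode_genotypes(d, ss.CodingModel.RECESSIVE)
        od = ss.encode_genotypes(d, ss.CodingModel.OVERDOMINANCE)
        np.testing.assert_allclose(dom - rec, od, atol=1e-12)
        vr = nf.v0_solve(nf.residuals)
        np.testing.assert_allclose(
            (dom - dom.mean(0)).T @ vr - (rec - rec.mean(0)).T @ vr,
            (od - od.mean(0)).T @ vr,
            atol=1e-8,
        )

    def test_determinism(self, small_nullfit):
        gm, y, _, nf = small_nullfit
        r1 = ss.genome_scan(gm, y, nf)
        r2 = ss.genome_scan(gm, y, nf)
        assert r1.table.equals(r2.table)


def test_power_ordering_dominant_qtl_small():
    """A planted dominance QTL is detected with a smaller dominance-coding p
    than additive-coding p in most replicates (scaled-down check; the full
    version runs in the acceptance suite)."""
    wins = 0
    n_rep = 20
    for seed in range(n_rep):
        rng_cfg = ss.SimulationConfig(
            n_sires=60, offspring_per_sire=10, n_snps=300,
            maf_low=0.3, maf_high=0.5, sigma_u2=3.0, sigma_e2=7.0, seed=500 + seed,
        )
        gm = ss.simulate_genotypes(rng_cfg)
        # size the effect to ~2% of phenotypic variance under the dominance code
        j = int(np.argmin(np.abs(gm.dosages.mean(0) / 2 - 0.5)))
        code = ss.encode_genotypes(gm.dosages[:, j], ss.CodingModel.DOMINANCE)
        b = np.sqrt(0.02 * 10.0 / code.var())
        y, _ = ss.simulate_phenotypes(
            gm, [ss.QtlSpec(j, ss.CodingModel.DOMINANCE, float(b))], 3.0, 7.0, seed=900 + seed
        )
        grm = ss.compute_grm(gm)
        nf = ss.fit_null(y, None, grm)
        p_dom = ss.snp_test(ss.encode_genotypes(gm.dosages[:, j], ss.CodingModel.DOMINANCE), nf)[3]
        p_add = ss.snp_test(ss.encode_genotypes(gm.dosages[:, j], ss.CodingModel.ADDITIVE), nf)[3]
        wins += p_dom < p_add
    assert wins >= 0.6 * n_rep
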
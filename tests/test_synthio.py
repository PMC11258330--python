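"""Synthetic data generator: statistical structure and determinism."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import logit

from methwas import synthio


class TestScenario:
    @pytest.mark.parametrize("kw", [
        {"rho": 1.0}, {"rho": -0.1}, {"h2_meth": 1.0},
        {"maf_range": (0.0, 0.5)}, {"maf_range": (0.1, 0.6)},
        {"n_ref": 0}, {"n_gwas": 0}, {"name": "bogus"},
    ])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            synthio.SimScenario(**kw)


class TestGenotypes:
    def test_independent_variants_when_rho_zero(self):
        sc = synthio.SimScenario(seed=1, n_ref=10_000, n_blocks=1,
                                 block_size=10, rho=0.0,
                                 maf_range=(0.5, 0.5))
        g = synthio.simulate_genotypes(sc)
        corr = np.corrcoef(g.dosages.T)
        off = corr[~np.eye(10, dtype=bool)]
        assert np.max(np.abs(off)) < 0.05

    def test_adjacent_correlation_matches_latent_oracle(self):
        # brute-force Monte-Carlo of the same latent thresholding model
        sc = synthio.SimScenario(seed=2, n_ref=10_000, n_blocks=1,
                                 block_size=2, rho=0.9)
        g = synthio.simulate_genotypes(sc)
        freq = g.variants["freq"].to_numpy()
        rng = np.random.default_rng(12345)
        z1 = rng.standard_normal(200_000)
        z2 = 0.9 * z1 + np.sqrt(1 - 0.81) * rng.standard_normal(200_000)
        q = 1 - freq
        def cut(z, f):
            qq = 1 - f
            c0 = stats.norm.ppf(qq * qq)
            c1 = stats.norm.ppf(qq * qq + 2 * f * qq)
            return (z >= c0).astype(float) + (z >= c1)
        oracle = np.corrcoef(cut(z1, freq[0]), cut(z2, freq[1]))[0, 1]
        observed = np.corrcoef(g.dosages[:, 0], g.dosages[:, 1])[0, 1]
        assert observed == pytest.approx(oracle, abs=0.1)

    def test_determinism_and_structure(self):
        sc = synthio.SimScenario(seed=3, n_ref=50, n_blocks=2, block_size=5)
        g1 = synthio.simulate_genotypes(sc)
        g2 = synthio.simulate_genotypes(sc)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)
        assert (np.diff(g1.variants["pos"]) > 0).all()
        assert set(np.unique(g1.dosages)) <= {0.0, 1.0, 2.0}

    def test_palindromic_fraction_controllable(self):
        sc = synthio.SimScenario(seed=4, n_ref=10, n_blocks=4,
                                 block_size=50, palindromic_frac=0.5)
        g = synthio.simulate_genotypes(sc)
        assert 0.35 < g.is_palindromic().mean() < 0.65


class TestMethylation:
    def test_zero_heritability_gives_no_cis_signal(self):
        sc = synthio.SimScenario(seed=5, n_ref=500, n_blocks=1,
                                 block_size=10, h2_meth=0.0, k_causal=2)
        g = synthio.simulate_genotypes(sc)
        meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        lat = logit(meth["tissue0"].beta.to_numpy()[0])
        idx = truth.causal["variant_index"].to_numpy()
        x = np.column_stack([np.ones(500), g.dosages[:, idx]])
        beta, res, *_ = np.linalg.lstsq(x, lat, rcond=None)
        r2 = 1 - res[0] / np.sum((lat - lat.mean()) ** 2)
        assert r2 < 0.02

    def test_single_variant_r2_matches_h2(self):
        sc = synthio.SimScenario(seed=6, n_ref=10_000, n_blocks=1,
                                 block_size=10, h2_meth=0.5, k_causal=1)
        g = synthio.simulate_genotypes(sc)
        meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        lat = logit(meth["tissue0"].beta.to_numpy()[0])
        vi = int(truth.causal["variant_index"].iloc[0])
        r = np.corrcoef(lat, g.dosages[:, vi])[0, 1]
        assert r * r == pytest.approx(0.5, abs=0.05)

    def test_fully_shared_effects_identical_across_tissues(self):
        sc = synthio.SimScenario(seed=7, n_ref=200, n_blocks=2,
                                 block_size=10, share_frac=1.0, k_causal=3)
        g = synthio.simulate_genotypes(sc)
        _, truth = synthio.simulate_methylation(g, sc, n_tissues=2)
        wide = truth.causal.pivot_table(index=["cpg_id", "variant_id"],
                                        columns="tissue", values="effect")
        np.testing.assert_allclose(wide["tissue0"], wide["tissue1"],
                                   atol=1e-12)

    def test_beta_values_in_unit_interval_and_deterministic(self):
        sc = synthio.SimScenario(seed=8, n_ref=60, n_blocks=1, block_size=8)
        g = synthio.simulate_genotypes(sc)
        m1, _ = synthio.simulate_methylation(g, sc, n_tissues=2)
        m2, _ = synthio.simulate_methylation(g, sc, n_tissues=2)
        vals = m1["tissue1"].beta.to_numpy()
        assert vals.min() > 0 and vals.max() < 1
        np.testing.assert_array_equal(vals, m2["tissue1"].beta.to_numpy())


class TestGwas:
    def test_null_scenario_uniform_p(self):
        sc = synthio.SimScenario(name="null", seed=9, n_ref=400,
                                 n_blocks=50, block_size=50)
        g = synthio.simulate_genotypes(sc)
        _, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        gwas = synthio.simulate_gwas(g, truth, sc)
        frac = (gwas.table["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_replicate_draws_center_on_generative_mean(self, small_scenario):
        g = synthio.simulate_genotypes(small_scenario)
        _, truth = synthio.simulate_methylation(g, small_scenario,
                                                n_tissues=1)
        t0 = truth.causal["tissue"].iloc[0]
        d = np.zeros(g.n_variants)
        c0 = truth.causal[truth.causal["tissue"] == t0]
        for cpg_id, grp in c0.groupby("cpg_id"):
            alpha = truth.mediation[cpg_id]
            d[grp["variant_index"].to_numpy()] += \
                alpha * grp["effect"].to_numpy()
        beta_true = synthio.marginal_liability_effects(g, d)
        vi = int(np.argmax(np.abs(beta_true)))
        draws = []
        for rep in range(200):
            sc_rep = small_scenario.with_(seed=10_000 + rep)
            gw = synthio.simulate_gwas(g, truth, sc_rep)
            draws.append(gw.table["beta"].iloc[vi])
        se = 1.0 / np.sqrt(small_scenario.n_gwas * 2 *
                           g.effect_allele_freq()[vi] *
                           (1 - g.effect_allele_freq()[vi]))
        assert np.mean(draws) == pytest.approx(
            beta_true[vi], abs=3 * se / np.sqrt(200))

    def test_ld_distinct_partner_is_correlated_distinct_variant(self):
        sc = synthio.SimScenario(name="ld_distinct", seed=10, n_ref=500,
                                 n_blocks=2, block_size=30, k_causal=1)
        g = synthio.simulate_genotypes(sc)
        _, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        synthio.simulate_gwas(g, truth, sc)
        assert len(truth.gwas_direct)
        for _, row in truth.gwas_direct.iterrows():
            causal = truth.causal[truth.causal["cpg_id"] == row["cpg_id"]]
            assert row["variant_id"] not in set(causal["variant_id"])
            top = causal.iloc[causal["effect"].abs().argmax()]
            r = np.corrcoef(g.dosages[:, int(row["variant_index"])],
                            g.dosages[:, int(top["variant_index"])])[0, 1]
            assert abs(r) >= 0.6   # target 0.7 up to estimation noise

    def test_null_mediation_is_exactly_zero(self):
        sc = synthio.SimScenario(name="null", seed=11, n_ref=50,
                                 n_blocks=2, block_size=5)
        g = synthio.simulate_genotypes(sc)
        _, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        assert all(v == 0.0 for v in truth.mediation.values())


class TestExpression:
    def test_linked_pair_correlation_near_target(self):
        sc = synthio.SimScenario(name="mediated_trio", seed=12, n_ref=200,
                                 n_blocks=1, block_size=10, gamma_eqtm=0.75)
        g = synthio.simulate_genotypes(sc)
        meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        expr = synthio.simulate_expression(meth["tissue0"], truth,
                                           n_nuisance=0)
        pair = truth.eqtm.iloc[0]
        lat = logit(meth["tissue0"].beta.loc[pair["cpg_id"]].to_numpy())
        e = expr.expr.loc[pair["gene_id"]].to_numpy()
        # gamma = 0.75 with unit noise implies corr 0.6
        assert np.corrcoef(lat, e)[0, 1] == pytest.approx(0.6, abs=0.15)

    def test_no_links_outside_mediated_trio(self, small_bundle):
        assert len(small_bundle["truth"].eqtm) == 0

    def test_deterministic(self):
        sc = synthio.SimScenario(name="mediated_trio", seed=13, n_ref=50,
                                 n_blocks=1, block_size=5)
        g = synthio.simulate_genotypes(sc)
        meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        e1 = synthio.simulate_expression(meth["tissue0"], truth)
        meth2, truth2 = synthio.simulate_methylation(g, sc, n_tissues=1)
        e2 = synthio.simulate_expression(meth2["tissue0"], truth2)
        np.testing.assert_array_equal(e1.expr.to_numpy(), e2.expr.to_numpy())
        np.testing.assert_array_equal(e1.counts.to_numpy(),
                                      e2.counts.to_numpy())

    def test_linked_genes_pass_expression_filter(self):
        from methwas import eqtm
        sc = synthio.SimScenario(name="mediated_trio", seed=14, n_ref=100,
                                 n_blocks=4, block_size=5)
        g = synthio.simulate_genotypes(sc)
        meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        expr = synthio.simulate_expression(meth["tissue0"], truth,
                                           n_decoys_per_cpg=5)
        kept = set(eqtm.filter_genes(expr.counts, expr.tpm))
        assert set(truth.eqtm["gene_id"]) <= kept
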
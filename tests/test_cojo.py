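"""Summary-statistic conditional analysis and novelty classification."""

import numpy as np
import pandas as pd
import pytest

from methwas import cojo, synthio
from methwas.types import GenotypeMatrix, GwasSummary
from tests.conftest import make_geno


def _gwas(ids, betas, ses, n=50_000):
    from scipy import stats
    z = np.asarray(betas) / np.asarray(ses)
    return GwasSummary(pd.DataFrame({
        "variant_id": ids, "chrom": "1",
        "pos": np.arange(1, len(ids) + 1) * 1000,
        "effect_allele": "A", "other_allele": "G", "freq": 0.3,
        "beta": betas, "se": ses,
        "p": 2 * stats.norm.sf(np.abs(z)), "n": n,
    }))


@pytest.fixture(scope="module")
def ld_panel():
    sc = synthio.SimScenario(seed=31, n_ref=2000, n_blocks=1, block_size=12,
                             rho=0.8)
    g = synthio.simulate_genotypes(sc)
    return g, cojo.ld_matrix(g)


class TestConditionalStats:
    def test_empty_selected_set_is_identity(self, ld_panel):
        g, ld = ld_panel
        ids = list(g.variant_ids[:4])
        gwas = _gwas(ids, [0.1, 0.05, -0.02, 0.0],
                     [0.01, 0.01, 0.01, 0.01])
        cond = cojo.conditional_stats(ids, [], gwas, ld)
        np.testing.assert_array_equal(cond.table["beta"].to_numpy(),
                                      gwas.table["beta"].to_numpy())
        np.testing.assert_array_equal(cond.table["se"].to_numpy(),
                                      gwas.table["se"].to_numpy())

    def test_self_conditioning_zeroes_z(self, ld_panel):
        g, ld = ld_panel
        ids = list(g.variant_ids[:3])
        gwas = _gwas(ids, [0.1, 0.05, 0.02], [0.01] * 3)
        cond = cojo.conditional_stats(ids, [ids[1]], gwas, ld)
        row = cond.table.set_index("variant_id").loc[ids[1]]
        assert row["z"] == 0.0 and row["p"] == 1.0

    def test_perfect_proxy_fully_explained(self):
        rng = np.random.default_rng(32)
        x = rng.binomial(2, 0.4, (3000, 1)).astype(float)
        geno = make_geno(np.column_stack([x, x]))
        ld = cojo.ld_matrix(geno)
        gwas = _gwas(["v0", "v1"], [0.08, 0.08], [0.01, 0.01], n=20_000)
        cond = cojo.conditional_stats(["v1"], ["v0"], gwas, ld)
        assert abs(cond.table["z"].iloc[0]) < 0.5

    def test_conditional_matches_individual_level_regression(self):
        res = __import__("methwas.evaluation", fromlist=["x"]) \
            .conditional_oracle(seed=3, n_cohort=8000)
        assert res["correlation"] > 0.95
        assert res["slope"] == pytest.approx(1.0, abs=0.1)


class TestStepwiseSelect:
    def test_single_causal_block_selects_top_variant(self):
        sc = synthio.SimScenario(name="shared_causal", seed=33, n_ref=500,
                                 n_blocks=1, block_size=20, k_causal=1,
                                 alpha_med=0.2, n_gwas=50_000)
        g = synthio.simulate_genotypes(sc)
        _, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        gwas = synthio.simulate_gwas(g, truth, sc)
        ld = cojo.ld_matrix(g)
        sel = cojo.stepwise_select(gwas, ld)
        assert len(sel) >= 1
        assert sel[0] == gwas.table.loc[gwas.table["p"].idxmin(),
                                        "variant_id"]

    def test_two_independent_causals_both_selected(self):
        hits = 0
        for rep in range(10):
            sc = synthio.SimScenario(name="shared_causal", seed=900 + rep,
                                     n_ref=800, n_blocks=2, block_size=15,
                                     k_causal=1, alpha_med=0.2,
                                     n_gwas=50_000)
            g = synthio.simulate_genotypes(sc)
            _, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
            gwas = synthio.simulate_gwas(g, truth, sc)
            ld = cojo.ld_matrix(g)
            sel = cojo.stepwise_select(gwas, ld)
            blocks = {g.variants.set_index("variant_id")
                      .loc[s, "block"] for s in sel}
            hits += blocks == {0, 1}
        assert hits >= 9

    def test_perfect_proxy_never_coselected(self):
        rng = np.random.default_rng(34)
        x = rng.binomial(2, 0.4, (3000, 1)).astype(float)
        geno = make_geno(np.column_stack([x, x]))
        ld = cojo.ld_matrix(geno)
        gwas = _gwas(["v0", "v1"], [0.09, 0.09], [0.008, 0.008], n=30_000)
        sel = cojo.stepwise_select(gwas, ld)
        assert len(sel) == 1

    def test_no_signal_returns_empty(self, ld_panel):
        g, ld = ld_panel
        ids = list(g.variant_ids)
        gwas = _gwas(ids, [0.001] * len(ids), [0.01] * len(ids))
        assert cojo.stepwise_select(gwas, ld) == []

    def test_order_invariance(self, ld_panel):
        g, ld = ld_panel
        ids = list(g.variant_ids)
        rng = np.random.default_rng(35)
        betas = rng.normal(0, 0.05, len(ids))
        betas[2] = 0.15
        gwas = _gwas(ids, betas, [0.01] * len(ids))
        sel1 = cojo.stepwise_select(gwas, ld)
        perm = rng.permutation(len(ids))
        gwas2 = GwasSummary(gwas.table.iloc[perm].reset_index(drop=True))
        sel2 = cojo.stepwise_select(gwas2, ld)
        assert set(sel1) == set(sel2)

    def test_n_heterogeneity_guard_drops_outliers(self):
        ids = ["v0", "v1", "v2"]
        gwas = _gwas(ids, [0.1, 0.1, 0.1], [0.01, 0.01, 0.01])
        gwas.table.loc[2, "n"] = 10_000     # 80% below the locus median
        filtered = cojo.filter_n_heterogeneity(gwas)
        assert filtered.table["variant_id"].tolist() == ["v0", "v1"]


class TestConditionalMwas:
    def test_empty_selection_reproduces_primary_record(self, small_bundle):
        from methwas import assoc, models, qc
        from methwas.pipeline import prepare_residuals
        g = small_bundle["geno_qc"]
        meth = small_bundle["meth"]["tissue0"]
        gwas = small_bundle["gwas"]
        resid = prepare_residuals(meth)
        row = meth.cpg_annot.iloc[0]
        cis = models.cis_variants(g, row["chrom"], int(row["pos"]))
        model = models.train_elastic_net(
            resid.loc[row["cpg_id"]].to_numpy(),
            qc.mean_impute(g.dosages)[:, cis],
            g.variants.iloc[cis].reset_index(drop=True),
            cpg_id=row["cpg_id"], seed=1)
        if model.n_snps == 0:
            pytest.skip("no weights selected on this fixture")
        ref = assoc.reference_moments(g, model)
        primary = assoc.mwas_z(model, gwas, ref)
        ld = cojo.ld_matrix(g)
        cond = cojo.conditional_stats(list(model.weights["variant_id"]),
                                      [], gwas, ld)
        re_rec = cojo.conditional_mwas(model, cond, ref, gwas)
        assert re_rec.z == pytest.approx(primary.z, abs=1e-9)

    def test_shared_signal_vanishes_after_conditioning(self):
        removed = 0
        for rep in range(10):
            sc = synthio.SimScenario(name="shared_causal", seed=950 + rep,
                                     n_ref=500, n_blocks=1, block_size=20,
                                     k_causal=1, alpha_med=0.2,
                                     n_gwas=50_000)
            g = synthio.simulate_genotypes(sc)
            meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
            gwas = synthio.simulate_gwas(g, truth, sc)
            from methwas import assoc, models, qc
            from methwas.pipeline import prepare_residuals
            resid = prepare_residuals(meth["tissue0"])
            model = models.train_elastic_net(
                resid.iloc[0].to_numpy(), qc.mean_impute(g.dosages),
                g.variants, cpg_id="cg000000", seed=rep)
            if model.n_snps == 0:
                continue
            ref = assoc.reference_moments(g, model)
            ld = cojo.ld_matrix(g)
            sel = cojo.stepwise_select(gwas, ld)
            cond = cojo.conditional_stats(
                list(model.weights["variant_id"]), sel, gwas, ld)
            rec = cojo.conditional_mwas(model, cond, ref, gwas)
            removed += abs(rec.z) < 2
        assert removed >= 8


class TestNovelty:
    @pytest.mark.parametrize("cpg_pos,hit_pos,expected", [
        (5_000_000, 4_200_000, "known_locus"),       # 800 kb away
        (5_000_000, 6_000_001, "putative_novel"),    # 1,000,001 bp, strict
        (5_000_000, 4_000_000, "known_locus"),       # exactly 1 Mb
    ])
    def test_distance_rule(self, cpg_pos, hit_pos, expected):
        hits = pd.DataFrame({"chrom": ["1"], "pos": [hit_pos],
                             "variant_id": ["rs1"]})
        call = cojo.classify_novelty("cg1", "1", cpg_pos, hits)
        assert call.classification == expected
        assert call.distance_bp == abs(cpg_pos - hit_pos)

    def test_other_chromosome_or_no_hits_is_novel(self):
        hits = pd.DataFrame({"chrom": ["2"], "pos": [5_000_000]})
        call = cojo.classify_novelty("cg1", "1", 5_000_000, hits)
        assert call.classification == "putative_novel"
        assert np.isinf(call.distance_bp)
        empty = cojo.classify_novelty("cg1", "1", 5_000_000, pd.DataFrame())
        assert empty.classification == "putative_novel"
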
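"""Cis prediction models: elastic net, cross-tissue fit, best-mQTL."""

import numpy as np
import pandas as pd
import pytest

from methwas import models, qc, synthio
from methwas.pipeline import prepare_residuals
from tests.conftest import make_geno


def _variants(m):
    return pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(m)],
        "chrom": "1", "pos": np.arange(1, m + 1) * 1000,
        "effect_allele": "A", "other_allele": "G",
    })


class TestCisVariants:
    def test_inclusive_window_boundary(self):
        geno = make_geno(np.zeros((2, 2)), pos=[99_999, 100_000])
        idx = models.cis_variants(geno, "1", 600_000)
        assert list(idx) == [1]

    def test_wrong_chromosome_is_empty(self):
        geno = make_geno(np.zeros((2, 3)))
        assert models.cis_variants(geno, "2", 1500).size == 0

    def test_enumerated_fixture(self):
        pos = [1, 40_000, 99_000, 100_001, 250_000, 500_000, 600_000,
               601_000, 1_100_000, 1_100_001]
        geno = make_geno(np.zeros((2, 10)), pos=pos)
        idx = models.cis_variants(geno, "1", 600_000)
        assert list(idx) == [3, 4, 5, 6, 7, 8]   # 100000..1100000 inclusive


class TestElasticNet:
    def test_noise_free_signal_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.binomial(2, 0.4, (100, 5)).astype(float)
        y = 2.0 * x[:, 1]
        m = models.train_elastic_net(y, x, _variants(5), seed=1)
        assert "v1" in set(m.weights["variant_id"])
        assert m.cv_R > 0.99
        assert m.reliable

    def test_lambda_max_end_of_path_zeroes_coefficients(self):
        rng = np.random.default_rng(1)
        x = rng.binomial(2, 0.4, (60, 4)).astype(float)
        y = x[:, 0] + rng.normal(size=60)
        lambdas = models._lambda_path(x, y, 0.5)
        from sklearn.linear_model import ElasticNet
        fit = ElasticNet(alpha=lambdas[0] * 1.0001, l1_ratio=0.5).fit(x, y)
        assert np.all(fit.coef_ == 0)

    def test_kkt_conditions_at_solution(self):
        # implementation-independent subgradient check of the refit
        rng = np.random.default_rng(2)
        x = rng.binomial(2, 0.3, (150, 12)).astype(float)
        y = x[:, 2] - 0.5 * x[:, 7] + rng.normal(size=150)
        m = models.train_elastic_net(y, x, _variants(12), seed=3)
        from sklearn.linear_model import ElasticNet
        lambdas = models._lambda_path(x, y, 0.5)
        # reconstruct the chosen lambda from the stored weights by refit scan
        best_lam, best_diff = None, np.inf
        w_full = np.zeros(12)
        idx = {f"v{i}": i for i in range(12)}
        for _, r in m.weights.iterrows():
            w_full[idx[r["variant_id"]]] = r["weight"]
        for lam in lambdas:
            fit = ElasticNet(alpha=lam, l1_ratio=0.5, max_iter=10000).fit(x, y)
            diff = np.max(np.abs(fit.coef_ - w_full))
            if diff < best_diff:
                best_diff, best_lam = diff, lam
        assert best_diff < 1e-6
        # KKT: |(1/n) X'(y - Xb - b0)| <= lam*alpha + lam*(1-alpha)*|b| rules
        fit = ElasticNet(alpha=best_lam, l1_ratio=0.5, max_iter=10000).fit(x, y)
        n = len(y)
        resid = y - fit.predict(x)
        grad = x.T @ resid / n - best_lam * 0.5 * fit.coef_
        active = fit.coef_ != 0
        np.testing.assert_allclose(
            grad[active], best_lam * 0.5 * np.sign(fit.coef_[active]),
            atol=1e-4)
        assert np.all(np.abs(grad[~active]) <= best_lam * 0.5 + 1e-4)

    def test_all_constant_columns_yield_empty_model(self):
        m = models.train_elastic_net(np.arange(20.0), np.ones((20, 3)),
                                     _variants(3), seed=0)
        assert m.n_snps == 0 and not m.reliable

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            models.train_elastic_net(np.arange(5.0), np.zeros((5, 2)),
                                     _variants(2), seed=0)


class TestCrossTissue:
    def _paired_data(self, seed, n=80, p=10):
        rng = np.random.default_rng(seed)
        x = rng.binomial(2, 0.4, (n, p)).astype(float)
        y = x[:, 1] - 0.8 * x[:, 4] + rng.normal(size=n)
        return x, y

    def test_identical_tissues_give_matching_models(self):
        x, y = self._paired_data(4)
        out = models.train_cross_tissue(
            {"a": y, "b": y.copy()}, {"a": x, "b": x.copy()},
            _variants(10), seed=5)
        assert set(out["a"].weights["variant_id"]) == \
            set(out["b"].weights["variant_id"])
        assert out["a"].cv_R == pytest.approx(out["b"].cv_R, abs=0.02)

    def test_huge_group_penalty_zeroes_everything(self):
        x, y = self._paired_data(6)
        xc = x - x.mean(axis=0)
        gram = [xc.T @ xc] * 2
        xty = [xc.T @ (y - y.mean())] * 2
        beta = models.sparse_group_fit(gram, xty, [len(y)] * 2,
                                       lam1=1e6, lam2=0.0)
        assert np.all(beta == 0)

    def test_sparse_group_kkt(self):
        # zero groups must satisfy ||soft(z_j, lam2)|| <= lam1
        x, y = self._paired_data(7)
        rng = np.random.default_rng(8)
        y2 = x[:, 1] + rng.normal(size=len(y))
        xc = x - x.mean(axis=0)
        gram = [xc.T @ xc, xc.T @ xc]
        xty = [xc.T @ (y - y.mean()), xc.T @ (y2 - y2.mean())]
        n_t = [len(y), len(y2)]
        lam1, lam2 = 0.05, 0.02
        beta = models.sparse_group_fit(gram, xty, n_t, lam1, lam2,
                                       tol=1e-10, max_iter=2000)
        for j in range(beta.shape[0]):
            z = np.array([
                (xty[t][j] - gram[t][j] @ beta[:, t]
                 + gram[t][j, j] * beta[j, t]) / n_t[t] for t in range(2)])
            s = np.sign(z) * np.maximum(np.abs(z) - lam2, 0)
            if np.all(beta[j] == 0):
                assert np.linalg.norm(s) <= lam1 + 1e-6
            else:
                nb = np.linalg.norm(beta[j])
                for t in range(2):
                    a = gram[t][j, j] / n_t[t]
                    lhs = z[t] - a * beta[j, t]
                    rhs = lam1 * beta[j, t] / nb + \
                        lam2 * np.sign(beta[j, t]) if beta[j, t] != 0 else None
                    if beta[j, t] != 0:
                        assert lhs == pytest.approx(rhs, abs=1e-4)

    def test_short_tissue_dropped_with_warning(self):
        x, y = self._paired_data(9)
        with pytest.raises(ValueError):
            models.train_cross_tissue(
                {"a": y, "b": y[:3]}, {"a": x, "b": x[:3]},
                _variants(10), seed=0)


class TestBestMqtl:
    def test_recovers_single_causal_variant(self):
        sc = synthio.SimScenario(seed=20, n_ref=4000, n_blocks=1,
                                 block_size=15, h2_meth=0.5, k_causal=1)
        g = synthio.simulate_genotypes(sc)
        meth, truth = synthio.simulate_methylation(g, sc, n_tissues=1)
        resid = prepare_residuals(meth["tissue0"])
        m = models.train_best_mqtl(resid.iloc[0].to_numpy(),
                                   qc.mean_impute(g.dosages),
                                   g.variants, seed=21)
        assert m.n_snps == 1
        assert m.weights["variant_id"].iloc[0] == \
            truth.causal["variant_id"].iloc[0]
        assert m.cv_R == pytest.approx(np.sqrt(0.5), abs=0.05)

    def test_elastic_net_beats_baseline_with_two_causals(self):
        sc = synthio.SimScenario(seed=22, n_ref=3000, n_blocks=1,
                                 block_size=20, h2_meth=0.4, k_causal=2,
                                 rho=0.3)
        g = synthio.simulate_genotypes(sc)
        meth, _ = synthio.simulate_methylation(g, sc, n_tissues=1)
        y = prepare_residuals(meth["tissue0"]).iloc[0].to_numpy()
        x = qc.mean_impute(g.dosages)
        en = models.train_elastic_net(y, x, g.variants, seed=23)
        bm = models.train_best_mqtl(y, x, g.variants, seed=23)
        assert en.cv_R > bm.cv_R

    def test_pure_noise_rarely_reliable(self):
        rng = np.random.default_rng(24)
        unreliable = 0
        for rep in range(30):
            x = rng.binomial(2, 0.3, (100, 10)).astype(float)
            y = rng.normal(size=100)
            m = models.train_best_mqtl(y, x, _variants(10), seed=rep)
            unreliable += not m.reliable
        assert unreliable >= 27


class TestSelectionAndComparison:
    def _model(self, method, r, p):
        return models.PredictionModel(
            cpg_id="cg1", tissue="t", method=method,
            weights=pd.DataFrame({"variant_id": ["v0"],
                                  "effect_allele": ["A"],
                                  "other_allele": ["G"], "weight": [1.0]}),
            cv_R=r, cv_P=p, n_train=100)

    def test_higher_r_wins_between_reliable_models(self):
        pick = models.select_model([self._model("elastic_net", 0.15, 0.01),
                                    self._model("cross_tissue", 0.25, 0.01)])
        assert pick.method == "cross_tissue"

    def test_only_reliable_candidate_selected(self):
        pick = models.select_model([self._model("elastic_net", 0.2, 0.01),
                                    self._model("cross_tissue", 0.3, 0.5)])
        assert pick.method == "elastic_net"

    def test_none_when_nothing_reliable_and_baseline_ignored(self):
        assert models.select_model(
            [self._model("elastic_net", 0.05, 0.5),
             self._model("best_mqtl", 0.9, 1e-10)]) is None

    def test_paired_t_matches_textbook_formula(self):
        rng = np.random.default_rng(25)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        t, p = models.compare_methods(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert t == pytest.approx(t_hand, abs=1e-6)

    def test_identical_vectors_and_constant_shift(self):
        a = np.array([0.1, 0.2, 0.3, 0.4])
        assert models.compare_methods(a, a) == (0.0, 1.0)
        rng = np.random.default_rng(26)
        b = a - 0.1 + 1e-5 * rng.normal(size=4)
        _, p = models.compare_methods(a, b)
        assert p < 1e-3


def test_null_cv_r_centred_at_zero():
    """Reported cv_R on pure-noise data has mean near 0 across replicates."""
    rng = np.random.default_rng(27)
    rs = []
    for rep in range(40):
        x = rng.binomial(2, 0.3, (100, 8)).astype(float)
        y = rng.normal(size=100)
        m = models.train_elastic_net(y, x, _variants(8), seed=rep)
        rs.append(m.cv_R)
    assert abs(np.mean(rs)) < 0.05
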
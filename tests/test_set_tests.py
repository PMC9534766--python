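"""Score decomposition, Burden/SKAT/SKAT-O statistics and the SPA tail."""

import numpy as np
import pytest
from scipy import stats

from rvset.collapsing import WeightScheme, collapse
from rvset.null_model import fit_null_glm
from rvset.set_tests import (
    ScoreDecomposition,
    burden_test,
    chi2_mixture_sf,
    run_gene,
    score_decompose,
    skat_test,
    skato_test,
    spa_pvalue,
)
from rvset.variant_io import Annotation, MaskSpec

from conftest import make_gvs


def _fit_and_cs(y, x, G, mac_threshold=0.0, scheme=None):
    fit = fit_null_glm(y, x, "binary")
    gvs = make_gvs(G)
    cs = collapse(gvs, scheme or WeightScheme(kind="none"), mac_threshold)
    return fit, cs, score_decompose(fit, cs)


class TestScoreDecompose:
    def test_zero_residuals_give_zero_scores(self, binary_fit_500, rng):
        fit, x = binary_fit_500
        fit.resid = np.zeros_like(fit.resid)
        G = rng.binomial(2, 0.1, size=(500, 4)).astype(float)
        cs = collapse(make_gvs(G), WeightScheme(kind="none"), 0)
        sd = score_decompose(fit, cs)
        np.testing.assert_allclose(sd.S, 0.0)

    def test_single_marker_intercept_only_closed_form(self, rng):
        n = 120
        y = (rng.random(n) < 0.3).astype(float)
        g = rng.binomial(2, 0.2, n).astype(float)
        fit = fit_null_glm(y, None, "binary")
        cs = collapse(make_gvs(g[:, None]), WeightScheme(kind="none"), 0)
        sd = score_decompose(fit, cs)
        mu = y.mean()
        expected = mu * (1 - mu) * np.sum((g - g.mean()) ** 2)
        assert sd.Phi[0, 0] == pytest.approx(expected, abs=1e-10)

    def test_weight_doubling_bilinearity(self, binary_fit_500, rng):
        fit, _ = binary_fit_500
        G = rng.binomial(2, 0.05, size=(500, 3)).astype(float)
        gvs = make_gvs(G)
        cs1 = collapse(gvs, WeightScheme(kind="user_weights", user_w=np.ones(3)), 0)
        cs2 = collapse(gvs, WeightScheme(kind="user_weights", user_w=2 * np.ones(3)), 0)
        sd1, sd2 = score_decompose(fit, cs1), score_decompose(fit, cs2)
        np.testing.assert_allclose(sd2.S, 2 * sd1.S, rtol=1e-12)
        np.testing.assert_allclose(sd2.Phi, 4 * sd1.Phi, rtol=1e-12)

    def test_sparse_and_dense_paths_agree(self, rng):
        n = 6000
        y = (rng.random(n) < 0.1).astype(float)
        x = rng.standard_normal(n)
        fit = fit_null_glm(y, x, "binary")
        G = np.zeros((n, 12))
        for j in range(12):
            G[rng.choice(n, 3, replace=False), j] = 1.0  # sparse path
        cs = collapse(make_gvs(G), WeightScheme(kind="none"), 0)
        sd_sparse = score_decompose(fit, cs)
        cs_dense = collapse(make_gvs(G[:, :7]), WeightScheme(kind="none"), 0)
        sd_dense = score_decompose(fit, cs_dense)  # below the sparse cutoff
        np.testing.assert_allclose(sd_sparse.S[:7], sd_dense.S, atol=1e-10)
        np.testing.assert_allclose(sd_sparse.Phi[:7, :7], sd_dense.Phi, atol=1e-10)


class TestBurden:
    def test_zero_score_p_one(self):
        sd = ScoreDecomposition(S=np.zeros(3), Phi=np.eye(3))
        fit = fit_null_glm(np.r_[np.ones(5), np.zeros(15)], None, "binary")
        cs = collapse(make_gvs(np.eye(20)[:, :3]), WeightScheme(kind="none"), 0)
        p, s, spa = burden_test(sd, fit, cs)
        assert s == 0.0 and p == 1.0

    def test_constant_genotype_zero_variance_p_one(self, rng):
        n = 30
        y = (rng.random(n) < 0.4).astype(float)
        fit = fit_null_glm(y, None, "binary")
        sd = ScoreDecomposition(S=np.array([0.5]), Phi=np.array([[0.0]]))
        cs = collapse(make_gvs(np.r_[np.ones((n, 1))] * 0 + np.eye(n)[:, :1]),
                      WeightScheme(kind="none"), 0)
        p, _, _ = burden_test(sd, fit, cs)
        assert p == 1.0

    def test_k1_reduces_to_single_variant_score_test(self, rng):
        n = 300
        y = (rng.random(n) < 0.4).astype(float)
        g = rng.binomial(2, 0.3, n).astype(float)
        fit = fit_null_glm(y, None, "binary")
        cs = collapse(make_gvs(g[:, None]), WeightScheme(kind="none"), 0)
        sd = score_decompose(fit, cs)
        p, s, spa = burden_test(sd, fit, cs)
        z = sd.S[0] / np.sqrt(sd.Phi[0, 0])
        if not spa:
            assert p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-12)

    def test_balanced_design_spa_close_to_normal(self, rng):
        """At mu = 0.5 the score is nearly symmetric and SPA agrees with the
        normal tail within ~10% relative."""
        n = 2000
        y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
        rng.shuffle(y)
        fit = fit_null_glm(y, None, "binary")
        g = rng.binomial(2, 0.1, n).astype(float)
        s = float(g @ fit.resid)
        var = float(np.sum(g**2 * fit.work_w) - fit.work_w.sum() * (g.mean()) ** 2 * 0)
        # use a moderately deep score to engage the tail
        target_z = 2.5
        s_target = target_z * np.sqrt(np.sum((g - g.mean()) ** 2 * 0.25))
        gp = g - g.mean()
        p_spa = spa_pvalue(s_target, gp, fit.mu_hat)
        p_norm = 2 * stats.norm.sf(target_z)
        assert p_spa == pytest.approx(p_norm, rel=0.10)
        del s, var


class TestSpa:
    def test_zero_score_is_one(self, rng):
        g = rng.binomial(2, 0.3, 20).astype(float)
        assert spa_pvalue(0.0, g, np.full(20, 0.3)) == 1.0

    def test_symmetric_in_sign(self):
        g = np.array([1.0, -1.0] * 10)
        mu = np.full(20, 0.5)
        assert abs(spa_pvalue(3.0, g, mu) - spa_pvalue(-3.0, g, mu)) < 1e-12

    def test_requires_binary_mu(self):
        with pytest.raises(ValueError):
            spa_pvalue(1.0, np.ones(5), np.array([0.0, 0.5, 0.5, 0.5, 0.5]))

    def test_matches_exact_enumeration_at_n12(self):
        """SPA within factor 1.15 of the exact 2^12-outcome enumeration at
        every achievable score in the |z| > 2 trigger region."""
        import itertools

        rng = np.random.default_rng(1)
        g = rng.integers(0, 3, 12).astype(float)
        mu = np.full(12, 0.25)  # intercept-only fit with 3/12 cases
        ys = np.array(list(itertools.product([0, 1], repeat=12)), dtype=float)
        probs = np.prod(np.where(ys == 1, mu, 1 - mu), axis=1)
        S = ys @ g - g @ mu
        sdv = np.sqrt(np.sum(g * g * mu * (1 - mu)))
        checked = 0
        for s in np.unique(np.round(S, 9)):
            if s / sdv <= 2:
                continue
            exact = probs[S >= s - 1e-9].sum() + probs[S <= -s + 1e-9].sum()
            if exact < 1e-7:
                continue
            p = spa_pvalue(float(s), g, mu)
            assert p / exact < 1.15 and exact / p < 1.15, (s, p, exact)
            checked += 1
        assert checked >= 5


class TestSkat:
    def test_k1_reduces_to_chi2(self):
        sd = ScoreDecomposition(S=np.array([2.0]), Phi=np.array([[1.5]]))
        q, p, method = skat_test(sd)
        assert q == 4.0
        assert p == pytest.approx(stats.chi2.sf(4.0 / 1.5, 1), rel=1e-12)

    def test_zero_statistic_p_one(self):
        sd = ScoreDecomposition(S=np.zeros(3), Phi=np.eye(3))
        _, p, _ = skat_test(sd)
        assert p == 1.0

    def test_degenerate_phi_p_one(self):
        sd = ScoreDecomposition(S=np.array([1.0, 1.0]), Phi=np.zeros((2, 2)))
        _, p, method = skat_test(sd)
        assert p == 1.0 and method == "degenerate"

    def test_mixture_tail_matches_normal_score_bootstrap(self):
        """The mixture-of-chi-square tail agrees within 3 Monte Carlo s.e.
        with 200,000 draws of Q = S'S for S ~ N(0, Phi) — the null model the
        tail computation asserts."""
        rng = np.random.default_rng(12)
        n = 10
        y = np.array([1, 0, 0, 1, 0, 0, 0, 1, 0, 0], dtype=float)
        fit = fit_null_glm(y, None, "binary")
        G = np.minimum(rng.integers(0, 3, (n, 3)), 1).astype(float)
        cs = collapse(make_gvs(G), WeightScheme(kind="none"), 0)
        sd = score_decompose(fit, cs)
        q, p, _ = skat_test(sd)
        B = 200_000
        L = np.linalg.cholesky(sd.Phi + 1e-12 * np.eye(3))
        S = np.random.default_rng(99).standard_normal((B, 3)) @ L.T
        Qb = (S**2).sum(axis=1)
        p_boot = float((Qb >= q).mean())
        se = np.sqrt(p_boot * (1 - p_boot) / B)
        assert abs(p - p_boot) < 3 * se

    def test_mixture_tail_exact_for_equal_eigenvalues(self):
        # lam = (a, a) makes Q / a chi-square with 2 df
        for a, q in [(0.5, 8.0), (1.0, 3.0)]:
            p, method = chi2_mixture_sf(q, np.array([a, a]))
            assert p == pytest.approx(stats.chi2.sf(q / a, 2), rel=1e-3)


class TestSkatO:
    @pytest.fixture
    def sd(self, binary_fit_500, rng):
        fit, _ = binary_fit_500
        G = rng.binomial(2, 0.05, size=(500, 5)).astype(float)
        cs = collapse(make_gvs(G), WeightScheme(), mac_threshold=10)
        return score_decompose(fit, cs), fit, cs

    def test_rho_one_equals_burden(self, sd):
        sd, fit, cs = sd
        p1 = skato_test(sd, [1.0])
        s = sd.S.sum()
        z2 = s**2 / sd.Phi.sum()
        assert p1 == pytest.approx(float(stats.chi2.sf(z2, 1)), abs=1e-10)

    def test_rho_zero_equals_skat(self, sd):
        sd, _, _ = sd
        _, p_skat, _ = skat_test(sd)
        assert skato_test(sd, [0.0]) == pytest.approx(p_skat, abs=1e-10)

    def test_full_grid_between_bounds(self, sd):
        sd, _, _ = sd
        grid = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)
        p = skato_test(sd, grid)
        _, p_skat, _ = skat_test(sd)
        p_burden = skato_test(sd, [1.0])
        t_min = min(p_skat, p_burden)
        assert t_min * 0.5 <= p <= min(t_min * len(grid), 1.0) + 1e-12

    def test_grid_outside_unit_interval_rejected(self, sd):
        sd, _, _ = sd
        with pytest.raises(ValueError):
            skato_test(sd, [0.0, 1.5])


class TestRunGene:
    def _mixed_gene(self, rng, n=400):
        mafs = [0.02, 0.004, 0.0008, 0.0008, 0.004]
        annos = ["lof", "lof", "lof", "missense", "synonymous"]
        d = np.column_stack([rng.binomial(2, f, n) for f in mafs]).astype(float)
        d[0, 2] = 1  # ensure polymorphic ultra-rare
        d[1, 3] = 1
        return make_gvs(d, annos)

    def test_grid_produces_one_result_per_populated_cell(self, rng):
        n = 400
        y = (rng.random(n) < 0.2).astype(float)
        fit = fit_null_glm(y, None, "binary")
        gvs = self._mixed_gene(rng, n)
        masks = [MaskSpec(frozenset({"lof"}), 0.5),
                 MaskSpec(frozenset({"missense"}), 0.5),
                 MaskSpec(frozenset({"synonymous"}), 0.5)]
        res = run_gene(fit, gvs, masks, WeightScheme(), 10)
        assert len(res) == 3
        assert all(0 < r.p_skato <= 1 for r in res)

    def test_cells_with_no_qualifying_variants_are_omitted(self, rng):
        n = 400
        y = (rng.random(n) < 0.2).astype(float)
        fit = fit_null_glm(y, None, "binary")
        gvs = self._mixed_gene(rng, n)
        masks = [MaskSpec(frozenset({"lof"}), 0.5),
                 MaskSpec(frozenset({"other"}), 0.5)]
        res = run_gene(fit, gvs, masks, WeightScheme(), 10)
        assert [r.mask.label() for r in res] == ["lof"]

    def test_identical_variant_content_identical_pvalues(self, rng):
        n = 400
        y = (rng.random(n) < 0.2).astype(float)
        fit = fit_null_glm(y, None, "binary")
        gvs = self._mixed_gene(rng, n)
        # both masks keep exactly the lof variants (all have maf <= 0.03)
        masks = [MaskSpec(frozenset({"lof"}), 0.5),
                 MaskSpec(frozenset({"lof"}), 0.04)]
        r1, r2 = run_gene(fit, gvs, masks, WeightScheme(), 10)
        assert r1.p_burden == r2.p_burden
        assert r1.p_skat == r2.p_skat
        assert r1.p_skato == r2.p_skato

    def test_permutation_invariance(self, rng):
        n = 300
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.25).astype(float)
        gvs = self._mixed_gene(rng, n)
        mask = [MaskSpec(frozenset({"lof", "missense", "synonymous"}), 0.5)]
        fit = fit_null_glm(y, x, "binary")
        res = run_gene(fit, gvs, mask, WeightScheme(), 10)[0]
        perm = rng.permutation(n)
        fit_p = fit_null_glm(y[perm], x[perm], "binary")
        gvs_p = make_gvs(gvs.dosage[perm], [v.annotation for v in gvs.variants])
        res_p = run_gene(fit_p, gvs_p, mask, WeightScheme(), 10)[0]
        assert res.p_burden == pytest.approx(res_p.p_burden, abs=1e-12)
        assert res.p_skat == pytest.approx(res_p.p_skat, abs=1e-12)
        assert res.p_skato == pytest.approx(res_p.p_skato, abs=1e-12)

    def test_marker_counts_follow_collapsing_law(self, rng):
        n = 400
        y = (rng.random(n) < 0.2).astype(float)
        fit = fit_null_glm(y, None, "binary")
        gvs = self._mixed_gene(rng, n)
        mask = [MaskSpec(frozenset({"lof", "missense", "synonymous"}), 0.5)]
        r = run_gene(fit, gvs, mask, WeightScheme(), 10)[0]
        sub_mac = gvs.mac
        expected = int((sub_mac > 10).sum()) + (1 if (sub_mac <= 10).any() else 0)
        assert r.m_markers == expected
        assert r.m_markers_pre == gvs.n_variants
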
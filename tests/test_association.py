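"""Partial correlations (three routes), networks, contingency enrichment,
Hotelling T^2, stratified CDFs and the simple differential test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from areclip.association import (CollinearityError, DegenerateControlError,
                                 contingency_enrichment,
                                 correlation_null_band, hotelling_t2,
                                 partial_correlation, pcor_network,
                                 simple_de, spearman_matrix, stratified_cdf)


def random_frame(rng, n, k):
    return pd.DataFrame(rng.normal(size=(n, k)),
                        columns=[f"v{i}" for i in range(k)])


class TestSpearmanMatrix:
    def test_monotone_relations_give_unit_correlation(self, rng):
        x = rng.normal(size=50)
        fm = pd.DataFrame({"x": x, "y": x, "z": -x ** 3})
        m = spearman_matrix(fm)
        assert m.loc["x", "y"] == pytest.approx(1.0)
        assert m.loc["x", "z"] == pytest.approx(-1.0)

    def test_equals_rank_then_pearson_oracle(self, rng):
        fm = random_frame(rng, 50, 4)
        m = spearman_matrix(fm)
        oracle = np.corrcoef(
            np.column_stack([stats.rankdata(fm[c]) for c in fm]),
            rowvar=False)
        np.testing.assert_allclose(m.to_numpy(), oracle, atol=1e-12)

    def test_matches_scipy_spearmanr(self, rng):
        fm = random_frame(rng, 80, 3)
        ref = stats.spearmanr(fm.to_numpy()).statistic
        np.testing.assert_allclose(spearman_matrix(fm).to_numpy(), ref,
                                   atol=1e-12)

    def test_constant_column_flagged_nan(self, rng):
        fm = random_frame(rng, 30, 2)
        fm["c"] = 7.0
        m = spearman_matrix(fm)
        assert m["c"].isna().all()
        assert np.isfinite(m.loc["v0", "v1"])


class TestPartialCorrelation:
    def test_empty_controls_reduce_to_spearman(self, rng):
        fm = random_frame(rng, 40, 2)
        res = partial_correlation(fm, "v0", "v1", ())
        ref = stats.spearmanr(fm["v0"], fm["v1"]).statistic
        assert res.rho_xy_given_z == pytest.approx(ref, abs=1e-12)
        assert res.rho_xy == pytest.approx(ref, abs=1e-12)

    def test_first_order_closed_form(self):
        # rho_xy = rho_xz = rho_zy = 0.5 -> rho_xy.z = 1/3
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        from areclip.association import _recursive_route

        val = _recursive_route(corr, 0, 1, (2,))
        assert val == pytest.approx((0.5 - 0.25) / (1 - 0.25))
        assert val == pytest.approx(1.0 / 3.0)

    @pytest.mark.parametrize("n,k", [(20, 3), (60, 4), (100, 6)])
    def test_three_routes_agree(self, rng, n, k):
        fm = random_frame(rng, n, k)
        controls = [f"v{i}" for i in range(2, k)]
        vals = [partial_correlation(fm, "v0", "v1", controls,
                                    method=m).rho_xy_given_z
                for m in ("residual", "recursive", "matrix")]
        assert max(vals) - min(vals) < 1e-10

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        fm = random_frame(rng, 70, 4)
        res = partial_correlation(fm, "v0", "v1", ["v2", "v3"])
        ref = pg.partial_corr(fm, x="v0", y="v1", covar=["v2", "v3"],
                              method="spearman")["r"].iloc[0]
        assert res.rho_xy_given_z == pytest.approx(float(ref), abs=1e-10)

    def test_recursion_order_invariant(self, rng):
        fm = random_frame(rng, 80, 5)
        controls = ["v2", "v3", "v4"]
        a = partial_correlation(fm, "v0", "v1", controls,
                                method="recursive").rho_xy_given_z
        b = partial_correlation(fm, "v0", "v1", controls[::-1],
                                method="recursive").rho_xy_given_z
        assert a == pytest.approx(b, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        fm = random_frame(rng, 60, 4)
        controls = ["v2", "v3"]
        base = partial_correlation(fm, "v0", "v1",
                                   controls).rho_xy_given_z
        fm2 = fm.copy()
        fm2["v0"] = np.exp(fm2["v0"])
        fm2["v2"] = fm2["v2"] ** 3
        trans = partial_correlation(fm2, "v0", "v1",
                                    controls).rho_xy_given_z
        assert trans == pytest.approx(base, abs=1e-12)

    def test_residuals_orthogonal_to_controls(self, rng):
        fm = random_frame(rng, 50, 4)
        res = partial_correlation(fm, "v0", "v1", ["v2", "v3"],
                                  method="residual")
        Z = res.intermediates["design"]
        assert np.abs(Z.T @ res.intermediates["resid_x"]).max() < 1e-8
        assert np.abs(Z.T @ res.intermediates["resid_y"]).max() < 1e-8

    def test_confound_scenario_partial_vanishes(self):
        from areclip.synthetic import generate_confounded_features

        df = generate_confounded_features(2000, beta_direct=0.4,
                                          noise_sd=0.5, seed=17)
        raw = partial_correlation(df, "n_sites_confounded", "log2fc", ())
        given = partial_correlation(df, "n_sites_confounded", "log2fc",
                                    ["n_sites_direct"])
        band = correlation_null_band(len(df), n_controls=1, alpha=0.01)
        assert raw.rho_xy > band          # looks regulatory...
        assert abs(given.rho_xy_given_z) < band  # ...but is confounded

    def test_control_equal_to_y_degenerate(self, rng):
        fm = random_frame(rng, 30, 2)
        fm["y2"] = fm["v1"]
        with pytest.raises(DegenerateControlError):
            partial_correlation(fm, "v0", "v1", ["y2"], method="residual")

    def test_collinear_controls_rejected(self, rng):
        fm = random_frame(rng, 30, 3)
        fm["dup"] = fm["v2"] * 2.0
        with pytest.raises((CollinearityError, DegenerateControlError)):
            partial_correlation(fm, "v0", "v1", ["v2", "dup"],
                                method="matrix")

    def test_x_in_controls_rejected(self, rng):
        fm = random_frame(rng, 30, 3)
        with pytest.raises(ValueError):
            partial_correlation(fm, "v0", "v1", ["v0"])

    def test_too_few_rows_rejected(self, rng):
        fm = random_frame(rng, 4, 4)
        with pytest.raises(ValueError):
            partial_correlation(fm, "v0", "v1", ["v2", "v3"])


class TestNetwork:
    def test_independent_variables_fall_in_null_band(self, rng):
        fm = random_frame(rng, 5000, 3)
        net = pcor_network(fm, ["v0", "v1", "v2"])
        band = correlation_null_band(5000, n_controls=1, alpha=0.01)
        for e in net.edges:
            assert abs(e.partial_correlation) < band

    def test_direct_effects_survive_mutual_control(self):
        # sites and length both depress expression; sites and length are
        # themselves positively related — both direct edges keep their sign
        rng = np.random.default_rng(8)
        n = 3000
        length = rng.gamma(2.0, 1.0, size=n)
        sites = rng.poisson(0.8 * length)
        fc = -0.5 * sites - 0.3 * length + rng.normal(0, 0.7, size=n)
        fm = pd.DataFrame({"n_sites": sites, "utr3_len": length,
                           "log2fc": fc})
        net = pcor_network(fm, ["n_sites", "utr3_len", "log2fc"])
        assert net.edge("log2fc", "n_sites").partial_correlation < 0
        assert net.edge("log2fc", "utr3_len").partial_correlation < 0
        assert net.edge("n_sites", "utr3_len").partial_correlation > 0
        # raw and partial agree in sign for the direct edges
        assert net.edge("log2fc", "n_sites").correlation < 0

    def test_duplicate_column_raises_collinearity(self, rng):
        fm = random_frame(rng, 40, 3)
        fm["v3"] = fm["v2"]
        with pytest.raises((CollinearityError, DegenerateControlError)):
            pcor_network(fm, ["v0", "v1", "v2", "v3"])


class TestContingency:
    def test_odds_ratio_arithmetic(self):
        has_sites = [True] * 30 + [False] * 30
        down = ["down"] * 20 + ["up"] * 10 + ["down"] * 10 + ["up"] * 20
        res = contingency_enrichment(has_sites, down)
        assert res.odds_ratio == pytest.approx(4.0)
        assert res.table == ((20, 10), (10, 20))

    def test_matches_scipy_fisher(self, rng):
        has_sites = rng.random(200) < 0.4
        down = rng.random(200) < 0.5
        res = contingency_enrichment(has_sites, down)
        a = int(np.sum(has_sites & down))
        b = int(np.sum(has_sites & ~down))
        c = int(np.sum(~has_sites & down))
        d = int(np.sum(~has_sites & ~down))
        _, p = stats.fisher_exact([[a, b], [c, d]])
        assert res.p_value == pytest.approx(p)

    def test_null_gives_or_near_one_uniform_p(self):
        rng = np.random.default_rng(3)
        ors, ps = [], []
        for _ in range(200):
            res = contingency_enrichment(rng.random(300) < 0.5,
                                         rng.random(300) < 0.5)
            ors.append(res.odds_ratio)
            ps.append(res.p_value)
        assert np.median(ors) == pytest.approx(1.0, abs=0.15)
        # p values roughly uniform: KS against U(0,1) not extreme
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_down_ratio_reported(self):
        has_sites = [True] * 40 + [False] * 40
        down = [True] * 20 + [False] * 20 + [True] * 10 + [False] * 30
        res = contingency_enrichment(has_sites, down)
        assert res.ratio_down == pytest.approx(2.0)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            contingency_enrichment([True, True], ["down", "up"])


class TestHotelling:
    def test_identical_groups_zero_statistic(self, rng):
        a = rng.normal(size=(20, 2))
        res = hotelling_t2(a, a.copy())
        assert res.t2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        a = rng.normal(size=(40, 2))
        b = rng.normal(size=(55, 2)) + [0.4, -0.2]
        res = hotelling_t2(a, b)
        ref = pg.multivariate_ttest(a, b)
        assert res.t2 == pytest.approx(float(ref["T2"].iloc[0]))
        assert res.p_value == pytest.approx(float(ref["pval"].iloc[0]))

    def test_shifted_groups_match_noncentral_expectation(self):
        # identity covariance, shift delta: E[T2] ~ df2/(df2-2)*(p + lam)
        # with lam = n1 n2/(n1+n2) |delta|^2; check simulated mean within 3 SD
        rng = np.random.default_rng(12)
        delta = np.array([0.5, 0.3])
        n = 100
        t2s = []
        for _ in range(300):
            a = rng.normal(size=(n, 2))
            b = rng.normal(size=(n, 2)) + delta
            t2s.append(hotelling_t2(a, b).t2)
        lam = n * n / (2 * n) * float(delta @ delta)
        p, df2 = 2, 2 * n - 2 - 1
        scale = p * (2 * n - 2) / df2
        expected = scale * df2 / (df2 - 2) * (p + lam) / p
        t2s = np.asarray(t2s)
        se = t2s.std(ddof=1) / np.sqrt(len(t2s))
        assert abs(t2s.mean() - expected) < 3 * se + 0.05 * expected

    def test_permuted_labels_give_uniform_p(self):
        rng = np.random.default_rng(4)
        pool = rng.normal(size=(80, 2))
        ps = []
        for _ in range(200):
            idx = rng.permutation(80)
            ps.append(hotelling_t2(pool[idx[:40]], pool[idx[40:]]).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            hotelling_t2(rng.normal(size=(2, 2)), rng.normal(size=(10, 2)))
        flat = np.tile([[1.0, 2.0]], (10, 1))
        with pytest.raises(ValueError):
            hotelling_t2(flat, flat)


class TestStratifiedCdf:
    def test_reference_group_has_zero_ks(self, rng):
        vals = rng.normal(size=100)
        groups = np.repeat(["a", "b"], 50)
        res = stratified_cdf(vals, groups, reference="a")
        assert res.ks["a"] == (0.0, 1.0)

    def test_cdf_endpoints_and_monotonicity(self, rng):
        vals = rng.normal(size=90)
        groups = np.repeat(["x", "y", "z"], 30)
        res = stratified_cdf(vals, groups)
        for df in res.cdfs.values():
            c = df["cdf"].to_numpy()
            assert c[-1] == pytest.approx(1.0)
            assert c[0] == pytest.approx(1.0 / len(c))
            assert np.all(np.diff(c) >= 0)

    def test_site_count_strata_shift_left(self):
        # more sites => stochastically smaller log2FC => left-shifted CDF
        rng = np.random.default_rng(30)
        counts = np.repeat([0, 1, 3], 400)
        fc = -0.5 * counts + rng.normal(0, 0.5, size=counts.size)
        res = stratified_cdf(fc, counts, reference=0)
        med = {g: np.median(df["value"]) for g, df in res.cdfs.items()}
        assert med[3] < med[1] < med[0]
        assert res.ks[3][0] > res.ks[1][0] > 0

    def test_group_with_no_finite_values_dropped_with_warning(self, rng):
        vals = np.r_[rng.normal(size=40), [np.nan] * 5]
        groups = np.array(["a"] * 20 + ["b"] * 20 + ["c"] * 5)
        with pytest.warns(UserWarning, match="dropped"):
            res = stratified_cdf(vals, groups, reference="a")
        assert set(res.cdfs) == {"a", "b"}
        assert res.dropped == ["c"]


class TestSimpleDe:
    def _matrix(self, rng, n_genes=50, delta=None):
        base = rng.normal(8, 1, size=(n_genes, 1))
        ctrl = base + rng.normal(0, 0.1, size=(n_genes, 3))
        treat = base + rng.normal(0, 0.1, size=(n_genes, 3))
        if delta is not None:
            treat = treat + delta[:, None]
        return np.hstack([ctrl, treat]), ["c"] * 3 + ["t"] * 3

    def test_identical_groups_zero_fold_change(self, rng):
        X = np.tile(rng.normal(size=(30, 1)), (1, 6))
        out = simple_de(X, ["c"] * 3 + ["t"] * 3)
        assert np.allclose(out["log2fc"], 0.0)
        assert out["p_value"].isna().all()  # zero variance flagged

    def test_null_bonferroni_type_i_control(self):
        rng = np.random.default_rng(77)
        X, labels = self._matrix(rng, n_genes=1000)
        out = simple_de(X, labels)
        assert (out["p_bonferroni"] < 0.01).sum() <= 1

    def test_planted_fold_change_detected(self):
        rng = np.random.default_rng(5)
        delta = np.zeros(50)
        delta[7] = 2.0  # 4-fold
        X, labels = self._matrix(rng, delta=delta)
        out = simple_de(X, labels, gene_ids=[f"g{i}" for i in range(50)])
        assert out.loc[7, "log2fc"] == pytest.approx(2.0, abs=0.3)
        assert out.loc[7, "p_bonferroni"] < 0.05

    def test_two_groups_required(self, rng):
        with pytest.raises(ValueError):
            simple_de(rng.normal(size=(5, 6)), ["a"] * 6)
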
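"""Model ladder, ANCOVA, PCA, Bray-Curtis and PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from thermotrait.community_stats import (
    ancova_trait_abundance,
    bray_curtis,
    function_regressions,
    pairwise_permanova,
    pca_composition,
    permanova,
    polynomial_lrt,
)


class TestPolynomialLrt:
    def test_exact_quadratic_chosen_with_r2_one(self):
        x = np.linspace(10, 35, 30)
        y = 2.0 - 0.03 * (x - 22.0) ** 2
        mc = polynomial_lrt(x, y)
        assert mc.chosen == "quadratic"
        assert mc.r2 == pytest.approx(1.0, abs=1e-9)
        assert mc.coefficients["x2"] == pytest.approx(-0.03, rel=1e-6)

    def test_constant_response_chooses_null(self):
        x = np.linspace(0, 10, 20)
        mc = polynomial_lrt(x, np.full(20, 3.0))
        assert mc.chosen == "null"
        assert mc.f_stat is None

    def test_exact_line_chooses_linear(self):
        x = np.linspace(0, 10, 25)
        mc = polynomial_lrt(x, 1.0 + 0.5 * x)
        assert mc.chosen == "linear"
        assert mc.coefficients["x"] == pytest.approx(0.5, rel=1e-8)

    def test_lrt_statistics_nonnegative_and_nested_rss_monotone(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 50)
        y = 0.2 * x + rng.normal(0, 1, 50)
        mc = polynomial_lrt(x, y)
        for _, stat, df, p in mc.lrt_stats:
            assert stat >= 0
            assert 0 <= p <= 1
            assert df == 1

    def test_collinear_design_rejected(self):
        with pytest.raises(ValueError):
            polynomial_lrt(np.full(10, 2.0), np.arange(10.0))


class TestAncova:
    def test_flat_abundance_gives_zero_slopes(self):
        levels = np.repeat([10.0, 20.0, 30.0], 8)
        trait = np.tile(np.linspace(18, 35, 8), 3)
        abund = np.full(24, 0.125)
        res = ancova_trait_abundance(abund, trait, levels)
        for lv, slope in res.per_level_slopes.items():
            assert slope[0] == pytest.approx(0.0, abs=1e-10)

    def test_known_per_level_slopes_recovered_exactly(self):
        slopes_true = {10.0: -0.01, 25.0: 0.0, 35.0: 0.02}
        rows = []
        for lv, b in slopes_true.items():
            for tr in np.linspace(18, 35, 10):
                rows.append((0.2 + b * tr, tr, lv))
        abund, trait, levels = map(np.array, zip(*rows))
        res = ancova_trait_abundance(abund, trait, levels)
        for lv, b in slopes_true.items():
            assert res.per_level_slopes[lv][0] == pytest.approx(b, abs=1e-10)
        assert res.r2 == pytest.approx(1.0, abs=1e-9)

    def test_df_bookkeeping_full_interaction_six_levels(self):
        # 295 observations over 6 levels -> overall F on (11, 283) df
        rng = np.random.default_rng(1)
        n_per = [50, 50, 50, 50, 50, 45]
        levels = np.concatenate([np.full(n, t) for n, t in
                                 zip(n_per, [10., 15., 20., 25., 30., 35.])])
        trait = rng.uniform(18, 35, levels.size)
        abund = rng.uniform(0, 1, levels.size)
        res = ancova_trait_abundance(abund, trait, levels)
        assert res.n == 295
        assert res.overall_f[1] == 11
        assert res.overall_f[2] == 283
        assert len(res.pairwise_contrasts) == 15

    def test_single_taxon_level_flagged_inestimable(self):
        levels = np.array([10.0] * 6 + [35.0] * 6)
        trait = np.array([18, 20, 22, 24, 26, 28] + [30.0] * 6)
        abund = np.linspace(0, 1, 12)
        res = ancova_trait_abundance(abund, trait, levels)
        assert res.per_level_slopes[35.0] is None
        assert res.per_level_slopes[10.0] is not None

    def test_slope_recovery_within_2se_under_own_model(self):
        # simulated under the fitted model; slopes should land within 2 SE
        # in the vast majority of replicate draws
        rng = np.random.default_rng(7)
        hits = total = 0
        for _ in range(200):
            levels = np.repeat([10.0, 25.0, 35.0], 20)
            trait = np.tile(np.linspace(18, 35, 20), 3)
            true_slopes = {10.0: -0.01, 25.0: 0.005, 35.0: 0.02}
            abund = np.array([
                0.3 + true_slopes[lv] * tr for lv, tr in zip(levels, trait)
            ]) + rng.normal(0, 0.05, 60)
            res = ancova_trait_abundance(abund, trait, levels)
            for lv, b in true_slopes.items():
                est, se = res.per_level_slopes[lv]
                total += 1
                hits += abs(est - b) <= 2 * se
        assert hits / total >= 0.93


class TestPca:
    def test_identical_rows_degenerate(self):
        res = pca_composition(np.tile([0.2, 0.3, 0.5], (6, 1)))
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.var_explained, 0.0)

    def test_two_taxa_on_simplex_line_single_component(self):
        p = np.linspace(0.1, 0.9, 8)
        res = pca_composition(np.column_stack([p, 1 - p]))
        assert res.var_explained[0] == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(3)
        x = rng.dirichlet(np.ones(4), size=10)
        res = pca_composition(x)
        centered = x - x.mean(axis=0)
        recon = res.scores @ res.loadings.T
        np.testing.assert_allclose(recon, centered, atol=1e-10)

    def test_loadings_orthonormal_and_var_nonincreasing(self):
        rng = np.random.default_rng(4)
        x = rng.dirichlet(np.ones(5), size=12)
        res = pca_composition(x)
        gram = res.loadings.T @ res.loadings
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-10)
        assert np.all(np.diff(res.var_explained) <= 1e-12)
        assert res.var_explained.sum() <= 1.0 + 1e-9

    def test_matches_sklearn(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        rng = np.random.default_rng(5)
        x = rng.dirichlet(np.ones(4), size=15)
        ours = pca_composition(x)
        ref = sklearn_pca(n_components=3).fit(x)
        np.testing.assert_allclose(
            ours.var_explained[:3], ref.explained_variance_ratio_, atol=1e-10)
        np.testing.assert_allclose(
            np.abs(ours.loadings[:, :3]), np.abs(ref.components_.T), atol=1e-8)


class TestBrayCurtis:
    def test_identity_and_disjoint_supports(self):
        x = np.array([[1.0, 2.0, 0.0], [1.0, 2.0, 0.0], [0.0, 0.0, 5.0]])
        d = bray_curtis(x)
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(1.0)
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)

    def test_direct_formula_example(self):
        d = bray_curtis(np.array([[2.0, 2.0], [1.0, 3.0]]))
        assert d[0, 1] == pytest.approx(0.25)

    def test_matches_scipy(self):
        from scipy.spatial.distance import pdist, squareform
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 1, size=(10, 5))
        np.testing.assert_allclose(bray_curtis(x),
                                   squareform(pdist(x, "braycurtis")),
                                   atol=1e-12)

    def test_all_zero_pair_flagged_nan(self):
        x = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        d = bray_curtis(x)
        assert np.isnan(d[0, 1])

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis(np.array([[1.0, -0.1], [0.2, 0.3]]))


def _brute_force_permanova_p(dist, groups):
    """Independent enumeration oracle: classic among/within SS formula."""
    dist = np.asarray(dist, float)
    groups = np.asarray(groups)
    n = len(groups)
    labels = np.unique(groups)
    a = labels.size

    def pseudo_f(g):
        ss_total = (dist[np.triu_indices(n, 1)] ** 2).sum() / n
        ss_within = 0.0
        for lab in labels:
            idx = np.where(g == lab)[0]
            sub = dist[np.ix_(idx, idx)]
            ss_within += (sub[np.triu_indices(len(idx), 1)] ** 2).sum() / len(idx)
        ss_among = ss_total - ss_within
        return (ss_among / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(groups)
    seen = set()
    count = 0
    for perm in itertools.permutations(range(n)):
        key = tuple(groups[list(perm)])
        if key in seen:
            continue
        seen.add(key)
        if pseudo_f(np.asarray(key)) >= f_obs - 1e-12:
            count += 1
    return f_obs, count / len(seen)


class TestPermanova:
    @pytest.fixture
    def toy(self):
        rng = np.random.default_rng(8)
        x = np.vstack([rng.normal(0, 1, (3, 4)), rng.normal(0.8, 1, (3, 4))])
        dist = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        groups = np.array(["a"] * 3 + ["b"] * 3)
        return dist, groups

    def test_exact_enumeration_matches_brute_force_oracle(self, toy):
        dist, groups = toy
        f_oracle, p_oracle = _brute_force_permanova_p(dist, groups)
        res = permanova(dist, groups, exact=True)
        assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-10)
        assert res.p_perm == pytest.approx(p_oracle, abs=1e-12)
        assert res.n_perm == 19  # 20 distinct 3/3 splits minus identity

    def test_monte_carlo_converges_to_exact(self, toy):
        dist, groups = toy
        exact = permanova(dist, groups, exact=True)
        mc = permanova(dist, groups, n_perm=9999, seed=0)
        assert mc.p_perm == pytest.approx(exact.p_perm, abs=0.03)

    def test_matches_skbio_pseudo_f(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(9)
        x = np.vstack([rng.dirichlet(np.ones(4), 6),
                       rng.dirichlet(np.ones(4) * 3, 6)])
        dist = bray_curtis(x)
        groups = ["a"] * 6 + ["b"] * 6
        ours = permanova(dist, groups, n_perm=99, seed=1)
        dm = skbio_stats.DistanceMatrix(dist)
        ref = skbio_stats.permanova(dm, grouping=list(groups), permutations=99)
        assert ours.pseudo_f == pytest.approx(float(ref["test statistic"]),
                                              rel=1e-8)

    def test_separated_clusters_minimal_p(self):
        x = np.vstack([np.tile([0.0, 0.0], (10, 1)) + np.arange(10)[:, None] * 0.01,
                       np.tile([10.0, 10.0], (10, 1)) + np.arange(10)[:, None] * 0.01])
        dist = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = permanova(dist, ["a"] * 10 + ["b"] * 10, n_perm=199, seed=1)
        assert res.p_perm == pytest.approx(1 / 200)

    def test_invariant_to_group_relabeling(self, toy):
        dist, groups = toy
        renamed = np.where(groups == "a", "zzz", "aaa")
        res_a = permanova(dist, groups, n_perm=199, seed=3)
        res_b = permanova(dist, renamed, n_perm=199, seed=3)
        assert res_a.pseudo_f == pytest.approx(res_b.pseudo_f, rel=1e-12)
        assert res_a.p_perm == res_b.p_perm

    def test_singleton_group_rejected(self, toy):
        dist, _ = toy
        with pytest.raises(ValueError, match="singleton"):
            permanova(dist, ["a"] * 5 + ["b"])

    def test_continuous_mode_df(self, toy):
        dist, _ = toy
        res = permanova(dist, np.array([10, 15, 20, 25, 30, 35.0]),
                        n_perm=99, seed=0, continuous=True)
        assert res.df == (1, 4)
        assert res.pseudo_f >= 0


class TestPairwisePermanova:
    def test_six_groups_fifteen_tests_bonferroni(self):
        rng = np.random.default_rng(10)
        x = rng.dirichlet(np.ones(5), size=24)
        dist = bray_curtis(x)
        groups = np.repeat([10, 15, 20, 25, 30, 35], 4)
        table = pairwise_permanova(dist, groups, n_perm=49, seed=2)
        assert len(table) == 15
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-12).all()
        assert (table["p_adjusted"] <= 1.0).all()
        np.testing.assert_allclose(
            table["p_adjusted"],
            np.minimum(1.0, table["p_raw"] * 15), atol=1e-12)


class TestFunctionRegressions:
    def test_hump_shaped_biomass_chooses_quadratic(self):
        rng = np.random.default_rng(11)
        temp = np.repeat([10., 15, 20, 25, 30, 35], 20)
        biomass = 0.8 - 0.002 * (temp - 22.0) ** 2 + rng.normal(0, 0.02, 120)
        even = np.clip(0.9 - 0.001 * (temp - 22.0) ** 2
                       + rng.normal(0, 0.05, 120), 0, 1)
        out = function_regressions(temp, even, biomass)
        assert out["biomass_vs_temp"].chosen == "quadratic"

    def test_linear_noiseless_biomass_vs_evenness(self):
        temp = np.repeat([10., 20, 30], 10)
        even = np.tile(np.linspace(0.2, 1.0, 10), 3)
        biomass = 0.1 + 0.6 * even
        out = function_regressions(temp, even, biomass)
        assert out["biomass_vs_evenness"].chosen == "linear"

    def test_undefined_evenness_excluded(self):
        temp = np.repeat([10., 20, 30], 8)
        even = np.tile(np.linspace(0.2, 1.0, 8), 3)
        even[[0, 5]] = np.nan  # monoculture replicates
        biomass = 0.1 + 0.6 * even
        biomass[[0, 5]] = 0.5
        out = function_regressions(temp, even, biomass)
        assert out["biomass_vs_evenness"].n == 22
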
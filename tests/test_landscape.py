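"""Environmental PCA, distance-set assembly, and the distance LMM."""

import numpy as np
import pandas as pd
import pytest

from aflpscape.amova import pairwise_phist
from aflpscape.landscape import (
    DistanceSet,
    GEO_FLOOR_KM,
    build_distance_set,
    environment_pca,
    fit_distance_lmm,
    haversine_km,
    parametric_bootstrap_lrt,
    unfold,
    unfold_categories,
)
from aflpscape.pipeline import ENV_VARIABLES


def _refold(vec, P):
    G = np.zeros((P, P))
    idx = np.tril_indices(P, k=-1)
    G[idx] = vec
    return G + G.T


@pytest.fixture(scope="module")
def template_distance_set(default_dataset):
    ds = default_dataset
    phist, pops = pairwise_phist(ds.band_matrix)
    pca = environment_pca(ds.site_table, ENV_VARIABLES)
    return build_distance_set(
        phist, pops, ds.site_table, pca,
        ds.truth["clusters"], ds.truth["admixed"],
    )


class TestEnvironmentPca:
    def test_perfectly_correlated_pair_loads_on_one_axis(self):
        df = pd.DataFrame({
            "population": list("abcde"),
            "x": [1.0, 2, 3, 4, 5], "y": [2.0, 4, 6, 8, 10],
        })
        res = environment_pca(df, ["x", "y"])
        assert res.variance_explained[0] == pytest.approx(1.0, abs=1e-12)

    def test_variance_fractions_sum_to_one(self, default_dataset):
        res = environment_pca(default_dataset.site_table, ENV_VARIABLES)
        assert res.variance_explained.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_eigendecomposition_oracle(self, default_dataset):
        site = default_dataset.site_table
        res = environment_pca(site, ENV_VARIABLES)
        X = site[ENV_VARIABLES].to_numpy(float)
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        vals, vecs = np.linalg.eig(np.corrcoef(Z, rowvar=False))
        order = np.argsort(vals.real)[::-1]
        scores = Z @ vecs.real[:, order]
        for k in range(4):
            diff = min(
                np.max(np.abs(res.scores[:, k] - scores[:, k])),
                np.max(np.abs(res.scores[:, k] + scores[:, k])),
            )
            assert diff < 1e-10

    def test_constant_variable_named_in_error(self, default_dataset):
        site = default_dataset.site_table.copy()
        site["flatvar"] = 1.0
        with pytest.raises(ValueError, match="flatvar"):
            environment_pca(site, ["rainfall", "flatvar"])


class TestBuildDistanceSet:
    def test_linearization_values(self, default_dataset):
        ds = default_dataset
        pops = ds.band_matrix.populations()
        phist = np.zeros((9, 9))
        phist[0, 1] = phist[1, 0] = 0.5
        pca = environment_pca(ds.site_table, ENV_VARIABLES)
        out = build_distance_set(phist, pops, ds.site_table, pca,
                                 ds.truth["clusters"], ds.truth["admixed"])
        assert out.genetic[0, 1] == pytest.approx(1.0)
        assert out.genetic[0, 2] == 0.0  # Phi = 0 -> linearized 0

    def test_negative_phi_clamped_monotone(self, default_dataset):
        ds = default_dataset
        pops = ds.band_matrix.populations()
        phist = np.zeros((9, 9))
        phist[0, 1] = phist[1, 0] = -0.05
        phist[0, 2] = phist[2, 0] = 0.2
        phist[0, 3] = phist[3, 0] = 0.4
        pca = environment_pca(ds.site_table, ENV_VARIABLES)
        out = build_distance_set(phist, pops, ds.site_table, pca,
                                 ds.truth["clusters"], ds.truth["admixed"])
        assert out.genetic[0, 1] == 0.0
        assert out.genetic[0, 1] <= out.genetic[0, 2] < out.genetic[0, 3]

    def test_colocated_sites_floored(self, default_dataset):
        ds = default_dataset
        site = ds.site_table.copy()
        site.loc[1, ["latitude", "longitude"]] = site.loc[0, ["latitude", "longitude"]].values
        pops = ds.band_matrix.populations()
        phist, _ = pairwise_phist(ds.band_matrix)
        pca = environment_pca(site, ENV_VARIABLES)
        out = build_distance_set(phist, pops, site, pca,
                                 ds.truth["clusters"], ds.truth["admixed"])
        assert out.geographic[0, 1] == pytest.approx(np.log(GEO_FLOOR_KM))

    def test_category_counts_for_two_plus_seven_design(self, default_dataset):
        # 9 populations: clusters of 2 and 7, admixed inside the 7
        ds = default_dataset
        pops = ds.band_matrix.populations()
        clusters = {p: ("C1" if p in ("P1", "P2") else "C2") for p in pops}
        phist, _ = pairwise_phist(ds.band_matrix)
        pca = environment_pca(ds.site_table, ENV_VARIABLES)
        out = build_distance_set(phist, pops, ds.site_table, pca,
                                 clusters, {"P9"})
        cats = unfold_categories(out)
        assert len(cats) == 36
        counts = {c: cats.count(c) for c in set(cats)}
        assert counts["admixed"] == 8
        assert counts["within"] == 1 + 15  # C2(2) + 6-pop remainder of C1(7)... lexicon: C1 pairs
        assert sum(counts.values()) == 36

    def test_haversine_sanity(self):
        # one degree of latitude is ~111 km
        assert haversine_km(32.0, 35.5, 33.0, 35.5) == pytest.approx(111.2, abs=0.5)


class TestDistanceLmm:
    def test_category_means_fit_perfectly(self, template_distance_set):
        ds = template_distance_set
        cats = unfold_categories(ds)
        means = {"within": 0.1, "between": 0.6, "admixed": 0.3}
        y = np.array([means[c] for c in cats])
        d2 = DistanceSet(ds.populations, _refold(y, 9), ds.geographic,
                         ds.environmental, ds.category)
        fit = fit_distance_lmm(d2, fixed=())
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)
        assert fit.sigma2 < 1e-10

    def test_loglik_matches_dense_gls_oracle(self, template_distance_set):
        from aflpscape.landscape import _design
        fit = fit_distance_lmm(template_distance_set, fixed=("geo", "env"))
        y, X, _, Z, _ = _design(template_distance_set, ("geo", "env"))
        V = fit.sigma_u2 * (Z @ Z.T) + fit.sigma2 * np.eye(len(y))
        r = y - X @ fit.beta
        sign, logdet = np.linalg.slogdet(V)
        oracle = -0.5 * (len(y) * np.log(2 * np.pi) + logdet
                         + r @ np.linalg.solve(V, r))
        assert fit.loglik == pytest.approx(oracle, abs=1e-6)

    def test_adding_fixed_effect_never_lowers_loglik(self, template_distance_set):
        f0 = fit_distance_lmm(template_distance_set, fixed=())
        f1 = fit_distance_lmm(template_distance_set, fixed=("geo",))
        f2 = fit_distance_lmm(template_distance_set, fixed=("geo", "env"))
        assert f1.loglik >= f0.loglik - 1e-8
        assert f2.loglik >= f1.loglik - 1e-8

    def test_beta_recovery_coverage(self, template_distance_set):
        ds = template_distance_set
        env = unfold(ds.environmental)
        cats = unfold_categories(ds)
        levels = sorted(set(cats))
        Z = np.array([[c == lv for lv in levels] for c in cats], dtype=float)
        rng = np.random.default_rng(2024)
        cover = 0
        reps = 100
        for _ in range(reps):
            u = rng.normal(0, 0.2, len(levels))
            y = 0.1 + 0.3 * env + Z @ u + rng.normal(0, 0.15, len(env))
            d2 = DistanceSet(ds.populations, _refold(y, 9), ds.geographic,
                             ds.environmental, ds.category)
            fit = fit_distance_lmm(d2, fixed=("env",))
            k = fit.fixed_names.index("env")
            cover += abs(fit.beta[k] - 0.3) <= 2 * fit.beta_se[k]
        assert cover / reps >= 0.93


class TestParametricBootstrap:
    def test_identical_models_give_p_one(self, template_distance_set):
        bt = parametric_bootstrap_lrt(
            template_distance_set, ("geo",), ("geo",), B=49, seed=0
        )
        assert bt.lr_observed == pytest.approx(0.0, abs=1e-8)
        assert bt.p_value == 1.0

    def test_planted_effect_detected(self, template_distance_set):
        ds = template_distance_set
        env = unfold(ds.environmental)
        cats = unfold_categories(ds)
        levels = sorted(set(cats))
        Z = np.array([[c == lv for lv in levels] for c in cats], dtype=float)
        rng = np.random.default_rng(5)
        u = rng.normal(0, 0.15, len(levels))
        y = 0.3 + 0.5 * env + Z @ u + rng.normal(0, 0.3, len(env))
        d2 = DistanceSet(ds.populations, _refold(y, 9), ds.geographic,
                         ds.environmental, ds.category)
        bt = parametric_bootstrap_lrt(d2, ("env",), (), B=199, seed=1)
        assert bt.p_value < 0.05

    def test_invariant_to_population_relabeling(self, template_distance_set):
        ds = template_distance_set
        bt1 = parametric_bootstrap_lrt(ds, ("env",), (), B=99, seed=3)
        relabeled = DistanceSet(
            [f"Q{i}" for i in range(9)], ds.genetic, ds.geographic,
            ds.environmental, ds.category,
        )
        bt2 = parametric_bootstrap_lrt(relabeled, ("env",), (), B=99, seed=3)
        assert bt1.p_value == bt2.p_value


class TestSensitivityModes:
    def test_fixed_category_mode_matches_dummy_ols(self, template_distance_set):
        from aflpscape.landscape import _design
        ds = template_distance_set
        fit = fit_distance_lmm(ds, fixed=("env",), category_mode="fixed")
        assert fit.sigma_u2 == 0.0
        y, X, _, Z, levels = _design(ds, ("env",))
        D = np.column_stack([X, Z[:, 1:]])
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        np.testing.assert_allclose(fit.beta, beta, atol=1e-8)

    def test_fine_categories_split_per_cluster(self, default_dataset):
        ds = default_dataset
        pops = ds.band_matrix.populations()
        phist, _ = pairwise_phist(ds.band_matrix)
        pca = environment_pca(ds.site_table, ENV_VARIABLES)
        out = build_distance_set(phist, pops, ds.site_table, pca,
                                 ds.truth["clusters"], ds.truth["admixed"],
                                 fine_categories=True)
        cats = set(unfold_categories(out))
        assert cats == {"within:C1", "within:C2", "between",
                        "admixed:C1", "admixed:C2"}
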
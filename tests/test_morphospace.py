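"""Collinearity screening, k-means morphospace, MANOVA, PGLS, LRT."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import convmorph as cm
from convmorph import morphospace as mo
from convmorph.tree import bm_covariance


class TestScreenCollinear:
    def test_identical_columns_second_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(40)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.standard_normal(40)})
        assert mo.screen_collinear(df) == ["a", "c"]

    def test_orthogonal_columns_all_kept(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
        assert mo.screen_collinear(df) == list("abcd")

    def test_known_correlation_structure(self):
        rng = np.random.default_rng(2)
        n = 500
        a = rng.standard_normal(n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.standard_normal(n)  # r ~ 0.8
        c = rng.standard_normal(n)
        d = 0.3 * c + np.sqrt(1 - 0.09) * rng.standard_normal(n)  # r ~ 0.3
        df = pd.DataFrame({"a": a, "b": b, "c": c, "d": d})
        assert mo.screen_collinear(df, r_max=0.75) == ["a", "c", "d"]

    def test_constant_column_warns_and_drops(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            kept = mo.screen_collinear(df)
        assert kept == ["a"]


class TestKMeans:
    def test_three_well_separated_blobs_recovered(self):
        rng = np.random.default_rng(3)
        centers = np.array([[0.0, 0.0], [20.0, 0.0], [0.0, 20.0]])
        X = np.vstack([c + rng.standard_normal((30, 2)) for c in centers])
        truth = np.repeat([1, 2, 3], 30)
        res = cm.kmeans_morphospace(X, k_range=range(1, 7), seed=0)
        assert res.chosen_k == 3
        # perfect agreement up to label permutation
        table = pd.crosstab(truth, res.assignment.to_numpy())
        assert (table.max(axis=1) == 30).all()

    def test_k_equals_n_gives_zero_wss(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((8, 3))
        res = cm.kmeans_morphospace(X, k_range=range(1, 9), seed=0)
        assert res.wss[8] == pytest.approx(0.0, abs=1e-20)

    def test_wss_nonincreasing(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((40, 3))
        res = cm.kmeans_morphospace(X, k_range=range(1, 9), n_init=10, seed=0)
        w = [res.wss[k] for k in sorted(res.wss)]
        assert all(b <= a + 1e-9 for a, b in zip(w, w[1:]))

    def test_duplicated_rows_share_cluster(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((15, 2))
        res = cm.kmeans_morphospace(np.vstack([X, X]), k_range=[3], seed=0)
        a = res.assignment.to_numpy()
        assert (a[:15] == a[15:]).all()

    def test_k_above_n_rejected(self):
        with pytest.raises(ValueError):
            cm.kmeans_morphospace(np.zeros((4, 2)), k_range=[5], seed=0)


class TestClusterAssociation:
    def test_two_groups_one_variable_equals_t_squared(self):
        rng = np.random.default_rng(7)
        y = rng.standard_normal(30)
        g = pd.Series([1] * 15 + [2] * 15)
        res = mo.cluster_association(g, y[:, None])
        t, p = stats.ttest_ind(y[:15], y[15:])
        assert res["F"] == pytest.approx(t**2, abs=1e-8)
        assert res["p"] == pytest.approx(p, abs=1e-8)

    def test_separated_clusters_highly_significant(self):
        rng = np.random.default_rng(8)
        g = pd.Series([1] * 20 + [2] * 20)
        y = np.where(g == 1, 0.0, 50.0)[:, None] + rng.standard_normal((40, 1))
        res = mo.cluster_association(g, y)
        assert res["p"] < 1e-6

    def test_null_p_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            g = pd.Series(rng.integers(1, 4, size=36))
            if g.nunique() < 2:
                continue
            y = rng.standard_normal((36, 3))
            ps.append(mo.cluster_association(g, y, tukey=False)["p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_relatedness_predictor_accepted(self, yule20):
        cov = bm_covariance(yule20)
        g = pd.Series(([1] * 10 + [2] * 10), index=cov.taxa)
        res = mo.cluster_association(g, cov)
        assert 0 <= res["p"] <= 1
        assert res["tukey"]

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            mo.cluster_association(pd.Series([1, 1, 1]), np.zeros((3, 1)))


class TestPGLS:
    def test_identity_correlation_equals_ols(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            X = rng.standard_normal((25, 3))
            y = rng.standard_normal(25)
            res = mo.pgls_fit(y, X)
            beta = np.linalg.lstsq(
                np.column_stack([np.ones(25), X]), y, rcond=None
            )[0]
            assert np.allclose(res.params.ravel(), beta, atol=1e-10)

    def test_null_slopes_centered_on_zero(self, yule20):
        cov = bm_covariance(yule20)
        rng = np.random.default_rng(11)
        slopes = []
        for r in range(200):
            y = cm.simulate_bm(yule20, [1.0], [0.0], seed=3000 + r)[:, 0]
            x = rng.standard_normal(20)
            res = mo.pgls_fit(y, x[:, None], R=cov)
            slopes.append(res.params[1, 0])
        assert abs(np.mean(slopes)) < 3 * np.std(slopes) / np.sqrt(len(slopes))

    def test_true_effect_recovered(self, yule20):
        """y = 2*x + BM noise: the GLS slope lands near 2 on average."""
        rng = np.random.default_rng(12)
        cov = bm_covariance(yule20)
        slopes = []
        for r in range(150):
            x = rng.standard_normal(20)
            y = 2.0 * x + cm.simulate_bm(yule20, [0.5], [0.0], seed=4000 + r)[:, 0]
            slopes.append(mo.pgls_fit(y, x[:, None], R=cov).params[1, 0])
        assert np.mean(slopes) == pytest.approx(2.0, abs=0.05)

    def test_singular_design_names_aliased_columns(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(ValueError, match="b"):
            mo.PGLS(np.arange(10.0), X)

    def test_multivariate_loglik_sums_per_feature(self):
        rng = np.random.default_rng(13)
        X = rng.standard_normal((25, 2))
        Y = rng.standard_normal((25, 3))
        joint = mo.pgls_fit(Y, X)
        total = sum(mo.pgls_fit(Y[:, j], X).loglik for j in range(3))
        assert joint.loglik == pytest.approx(total, abs=1e-8)


class TestLRT:
    def test_identical_models_give_zero_statistic(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((20, 2))
        y = rng.standard_normal(20)
        res = mo.pgls_fit(y, X)
        out = mo.lrt_compare(res, res)
        assert out.statistic == 0.0
        assert out.p == 1.0

    def test_null_statistic_mean_near_one(self):
        rng = np.random.default_rng(15)
        stats_ = []
        for _ in range(300):
            X = pd.DataFrame(rng.standard_normal((40, 2)), columns=["a", "b"])
            Xz = X.assign(z=rng.standard_normal(40))
            y = X.to_numpy() @ [1.0, -0.5] + rng.standard_normal(40)
            stats_.append(
                mo.lrt_compare(mo.pgls_fit(y, Xz), mo.pgls_fit(y, X)).statistic
            )
        assert np.mean(stats_) == pytest.approx(1.0, abs=0.25)

    def test_strong_effect_highly_significant(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(40)
        y = 3.0 * x + 0.3 * rng.standard_normal(40)
        full = mo.pgls_fit(y, pd.DataFrame({"x": x}))
        reduced = mo.pgls_fit(y, None)
        assert mo.lrt_compare(full, reduced).p < 1e-3

    def test_non_nested_rejected(self):
        rng = np.random.default_rng(17)
        y = rng.standard_normal(20)
        m1 = mo.pgls_fit(y, pd.DataFrame({"a": rng.standard_normal(20)}))
        m2 = mo.pgls_fit(y, pd.DataFrame({"b": rng.standard_normal(20)}))
        with pytest.raises(ValueError, match="nested"):
            mo.lrt_compare(m1, m2)

    def test_statistic_nonnegative_on_random_nested_fits(self):
        rng = np.random.default_rng(18)
        for _ in range(100):
            X = pd.DataFrame(rng.standard_normal((15, 3)), columns=list("abc"))
            y = rng.standard_normal(15)
            full = mo.pgls_fit(y, X)
            red = mo.pgls_fit(y, X[["a"]])
            assert mo.lrt_compare(full, red).statistic >= 0.0

    def test_combined_model_tends_to_best_adj_r2(self, yule20):
        """Habitat + relatedness together fit at least as well as either
        alone, on average over replicates (not per dataset)."""
        cov = bm_covariance(yule20)
        rng = np.random.default_rng(19)
        wins = 0
        reps = 40
        for r in range(reps):
            x = rng.standard_normal(20)
            y = 1.0 * x + cm.simulate_bm(yule20, [1.0], [0.0], seed=6000 + r)[:, 0]
            both = mo.pgls_fit(y, x[:, None], R=cov)
            hab = mo.pgls_fit(y, x[:, None])
            rel = mo.pgls_fit(y, None, R=cov)
            wins += both.adj_r2 >= max(hab.adj_r2, rel.adj_r2) - 0.05
        assert wins / reps >= 0.8


class TestSexDifference:
    def test_detects_injected_dimorphism(self, yule16):
        cfg = cm.SimConfig(n_species=16, n_specimens=20, seed=21)
        truth = cm.simulate_convergent(yule16, cfg)
        spec = cm.simulate_specimens(truth)
        spec.loc[spec["sex"] == "M", "elytral_length"] += 1.0
        res = mo.sex_difference(spec, "elytral_length")
        assert res["p"] < 1e-6
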
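"""Phylogenetic ridge regression and rate-shift searches."""

import numpy as np
import pytest

import convmorph as cm
from convmorph.rates import PhylogeneticRidge, build_path_matrix


class TestPathMatrix:
    def test_analytic_three_tip(self, three_tip_tree):
        pm = build_path_matrix(three_tip_tree)
        t = three_tip_tree
        rows = {lab: pm.L[pm.taxa.index(lab)] for lab in "ABC"}
        # every tip's row sums to its depth; C's row has a single 2 entry
        assert rows["A"].sum() == pytest.approx(2.0)
        assert rows["B"].sum() == pytest.approx(2.0)
        assert sorted(rows["C"]) == pytest.approx([0, 0, 0, 2])
        # A and B share exactly one branch (the AB stem of length 1)
        shared = (rows["A"] > 0) & (rows["B"] > 0)
        assert shared.sum() == 1
        assert rows["A"][shared][0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_row_sums_equal_tip_depths(self, seed):
        t = cm.simulate_yule_tree(15, 1.0, seed=seed)
        pm = build_path_matrix(t)
        depths = t.depths()[t.tip_ids]
        assert np.allclose(pm.L.sum(axis=1), depths)

    def test_star_tree_diagonal(self):
        t = cm.parse_newick("(A:1,B:2,C:3);")
        pm = build_path_matrix(t)
        off = pm.L - np.diag(np.diag(pm.L))
        assert np.count_nonzero(pm.L) == 3
        assert np.allclose(off[np.eye(3) == 0], 0) or np.count_nonzero(off) == 0


class TestFitRidge:
    def test_star_tree_lambda0_closed_form(self):
        t = cm.parse_newick("(A:1,B:1,C:1,D:1);")
        y = np.array([1.0, 2.0, 4.0, 5.0])
        res = cm.fit_ridge(t, y, lam=0.0)
        assert res.root_estimate[0] == pytest.approx(y.mean(), abs=1e-10)
        assert np.allclose(res.coefs.ravel(), y - y.mean(), atol=1e-8)

    def test_star_tree_unequal_lengths_closed_form(self):
        t = cm.parse_newick("(A:1,B:2,C:4,D:8);")
        y = np.array([3.0, -1.0, 2.0, 6.0])
        res = cm.fit_ridge(t, y, lam=0.0)
        # limit of the ridge path: root is the 1/l^2-weighted mean
        w = 1.0 / np.array([1.0, 2.0, 4.0, 8.0]) ** 2
        root = (w @ y) / w.sum()
        assert res.root_estimate[0] == pytest.approx(root, abs=1e-10)
        beta = (y - root) / np.array([1.0, 2.0, 4.0, 8.0])
        assert np.allclose(res.coefs.ravel(), beta, atol=1e-8)

    def test_constant_response_gives_zero_rates(self, yule20):
        for lam in (0.0, 1.0, 100.0):
            res = cm.fit_ridge(yule20, np.full(20, 3.7), lam=lam)
            assert np.abs(res.rates).max() < 1e-10
            assert res.root_estimate[0] == pytest.approx(3.7)

    def test_huge_penalty_shrinks_rates_to_zero(self, yule20):
        y = cm.simulate_bm(yule20, [1.0], [0.0], seed=0)
        res = cm.fit_ridge(yule20, y, lam=1e9)
        assert np.abs(res.coefs).max() < 1e-6

    def test_lambda0_interpolates_tips(self, yule20):
        y = cm.simulate_bm(yule20, [1.0], [0.0], seed=1)
        res = cm.fit_ridge(yule20, y, lam=0.0)
        assert np.abs(res.fittedvalues - y).max() < 1e-8

    def test_negative_lambda_rejected(self, yule20):
        y = cm.simulate_bm(yule20, [1.0], [0.0], seed=2)
        with pytest.raises(ValueError):
            PhylogeneticRidge(yule20, y).fit(lam=-1.0)


class TestSelectLambda:
    def test_finite_positive_on_bm_simulations(self, yule20):
        ok = 0
        for r in range(100):
            y = cm.simulate_bm(yule20, [1.0], [0.0], seed=1000 + r)
            model = PhylogeneticRidge(yule20, y)
            lam = model.select_lambda(model.X[:, 0])
            ok += np.isfinite(lam) and lam > 0
        assert ok >= 95

    def test_zero_variance_warns_and_returns_grid_max(self, yule20):
        model = PhylogeneticRidge(yule20, np.zeros(20))
        with pytest.warns(UserWarning, match="zero-variance"):
            lam = model.select_lambda(model.X[:, 0])
        assert lam > 1e2  # top of the scaled grid


class TestShiftSearchClade:
    def test_equal_rates_give_p_near_one(self, yule20):
        res = cm.fit_ridge(yule20, yule20.depths()[yule20.tip_ids], lam=1e9)
        # force exactly equal rates: every permutation ties the statistic
        res.standardized_rates = np.ones(len(res.branches))
        shifts = res.search_shift_clade(n_rand=200, seed=0, method="permutation")
        assert all(s.p_raw > 0.99 for s in shifts)

    def test_small_nrand_rejected(self, yule20):
        y = cm.simulate_bm(yule20, [1.0], [0.0], seed=3)
        res = cm.fit_ridge(yule20, y)
        with pytest.raises(ValueError):
            res.search_shift_clade(n_rand=50)

    def test_p_invariant_to_trait_scaling(self, yule20):
        """Rescaling the trait rescales the statistic but not the p-values."""
        y = cm.simulate_bm(yule20, [1.0], [0.0], seed=4)
        r1 = cm.PhylogeneticRidge(yule20, y).fit()
        r2 = cm.PhylogeneticRidge(yule20, 1000.0 * y).fit()
        s1 = r1.search_shift_clade(n_rand=300, seed=7)
        s2 = r2.search_shift_clade(n_rand=300, seed=7)
        assert [s.p_raw for s in s1] == [s.p_raw for s in s2]

    def test_bonferroni_is_m_times_raw(self, yule20):
        y = cm.simulate_bm(yule20, [1.0], [0.0], seed=5)
        res = cm.fit_ridge(yule20, y)
        shifts = res.search_shift_clade(n_rand=200, seed=0)
        m = len(shifts)
        for s in shifts:
            assert s.p_adjusted == pytest.approx(min(1.0, s.p_raw * m))


class TestShiftSearchState:
    @staticmethod
    def _painted_states(tree, node):
        """All tips under ``node`` get state 'fast', the rest 'slow'."""
        desc = tree.tip_descendants()[node]
        return {
            tree.labels[t]: ("fast" if t in desc else "slow")
            for t in tree.tip_ids
        }

    def test_single_state_errors(self, yule20):
        y = cm.simulate_bm(yule20, [1.0], [0.0], seed=6)
        res = cm.fit_ridge(yule20, y)
        states = {sp: "alpine" for sp in yule20.taxa}
        with pytest.raises(ValueError):
            res.search_shift_state(states, n_rand=200)

    def test_antisymmetry_of_two_state_statistics(self, yule20):
        y = cm.simulate_bm(yule20, [1.0], [0.0], seed=7)
        res = cm.fit_ridge(yule20, y)
        node = next(
            v for v in range(yule20.n_nodes)
            if yule20.labels[v] is None and yule20.parent[v] >= 0
            and 4 <= len(yule20.tip_descendants()[v]) <= 10
        )
        shifts = res.search_shift_state(self._painted_states(yule20, node), n_rand=200)
        assert len(shifts) == 2
        assert shifts[0].rate_delta == pytest.approx(-shifts[1].rate_delta, abs=1e-12)

    def test_painted_fast_subtree_detected(self):
        tree = cm.simulate_yule_tree(30, 1.0, seed=13)
        node = next(
            v for v in range(tree.n_nodes)
            if tree.labels[v] is None and tree.parent[v] >= 0
            and 6 <= len(tree.tip_descendants()[v]) <= 12
        )
        desc = tree.tip_descendants()[node]
        branches = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
        clade = set()
        stack = [node]
        ch = tree.children()
        while stack:
            v = stack.pop()
            clade.add(v)
            stack.extend(ch[v])
        scale = np.array([100.0 if b in clade else 1.0 for b in branches])
        hits = 0
        for r in range(20):
            y = cm.simulate_bm(tree, [1.0], [0.0], seed=300 + r, branch_scale=scale)
            res = cm.fit_ridge(tree, y)
            shifts = res.search_shift_state(
                self._painted_states(tree, node), n_rand=500, seed=r
            )
            fast = next(s for s in shifts if s.unit == "fast")
            hits += fast.p_raw < 0.05 and fast.direction == "faster"
        assert hits >= 16

    def test_null_p_values_uniform(self, yule20):
        """Random state labels => p uniform on (0,1)."""
        from scipy import stats

        rng = np.random.default_rng(0)
        ps = []
        for r in range(200):
            y = cm.simulate_bm(yule20, [1.0], [0.0], seed=5000 + r)
            res = cm.fit_ridge(yule20, y)
            labels = rng.permutation(["a"] * 10 + ["b"] * 10)
            states = dict(zip(yule20.taxa, labels))
            try:
                shifts = res.search_shift_state(states, n_rand=199, seed=r)
            except ValueError:
                continue
            ps.append(shifts[0].p_raw)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestParameterRecovery:
    def test_slowed_clade_has_lower_estimated_rates(self):
        """A clade simulated with sigma^2/100 shows lower median |rate|."""
        tree = cm.simulate_yule_tree(30, 1.0, seed=17)
        node = next(
            v for v in range(tree.n_nodes)
            if tree.labels[v] is None and tree.parent[v] >= 0
            and 6 <= len(tree.tip_descendants()[v]) <= 12
        )
        branches = [v for v in range(tree.n_nodes) if tree.parent[v] >= 0]
        clade = set()
        stack = [node]
        ch = tree.children()
        while stack:
            v = stack.pop()
            clade.add(v)
            stack.extend(ch[v])
        scale = np.array([0.01 if b in clade else 1.0 for b in branches])
        inmask = np.array([b in clade for b in branches])
        wins = 0
        for r in range(30):
            y = cm.simulate_bm(tree, [1.0], [0.0], seed=900 + r, branch_scale=scale)
            res = cm.fit_ridge(tree, y)
            wins += np.median(res.rates[inmask]) < np.median(res.rates[~inmask])
        assert wins >= 27  # >= 90 percent of replicates
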
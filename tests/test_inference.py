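import itertools

import numpy as np
import pandas as pd
import pytest

import treefst as tf
from treefst import PopulationTree
from treefst.inference import (
    cluster_phase,
    design_system,
    fit_thetas,
    improve_phase,
    infer,
)

from _helpers import (
    all_rooted_binary_topologies,
    noiseless_s,
    random_binary_tree,
    theta_by_clade,
)


class TestDesignSystem:
    def test_star_three_tips(self):
        t = PopulationTree.star(["a", "b", "c"])
        s = pd.DataFrame(0.9, index=t.tips, columns=t.tips)
        np.fill_diagonal(s.values, np.nan)
        x, y, rows, branches = design_system(t, s)
        assert x.shape == (6, 3)
        assert branches == ["a", "b", "c"]
        for (k, _), row in zip(rows, x):
            assert row.sum() == 1 and row[branches.index(k)] == 1
        np.testing.assert_allclose(y, -np.log(0.9))

    def test_nonshared_branch_indicators(self, bench_tree):
        s = noiseless_s(bench_tree)
        x, y, rows, branches = design_system(bench_tree, s)
        i = rows.index(("C", "E"))
        on = {branches[j] for j in np.flatnonzero(x[i])}
        assert on == {"3", "C"}

    def test_binary_dimensions(self, bench_tree):
        k = len(bench_tree.tips)
        x, _, rows, branches = design_system(bench_tree, noiseless_s(bench_tree))
        assert x.shape == (k * (k - 1), 2 * (k - 1))

    def test_undefined_rows_dropped(self, bench_tree):
        s = noiseless_s(bench_tree)
        s.at["A", "B"] = np.nan
        _, _, rows, _ = design_system(bench_tree, s)
        assert ("A", "B") not in rows and ("B", "A") in rows


class TestFitThetas:
    def test_noiseless_exact_recovery(self, bench_tree):
        fit = fit_thetas(bench_tree, noiseless_s(bench_tree))
        assert fit.xi <= 1e-16
        for q in bench_tree.branches:
            assert fit.tree.theta[q] == pytest.approx(bench_tree.theta[q],
                                                      abs=1e-8)

    def test_two_units_closed_form(self):
        t = PopulationTree.star(["x", "y"])
        s = pd.DataFrame([[np.nan, 0.8], [0.7, np.nan]],
                         index=["x", "y"], columns=["x", "y"])
        fit = fit_thetas(t, s)
        assert fit.tree.theta["x"] == pytest.approx(1 - 0.8, rel=1e-12)
        assert fit.tree.theta["y"] == pytest.approx(1 - 0.7, rel=1e-12)

    def test_matches_grid_search_oracle(self):
        """NNLS solution of a small 3-branch system agrees with a dense
        grid search over the non-negative orthant."""
        t = PopulationTree.star(["a", "b", "c"],
                                {"a": 0.05, "b": 0.10, "c": 0.15})
        s = noiseless_s(t)
        # perturb away from the consistent system so the optimum is not 0
        rng = np.random.default_rng(0)
        s.values[~np.isnan(s.values)] *= np.exp(rng.normal(0, 0.02, 6))
        s = s.clip(upper=1.0)
        x, y, _, branches = design_system(t, s)
        fit = fit_thetas(t, s)
        step = 1e-3
        grid = np.arange(0.0, 0.25, step)
        g1, g2, g3 = np.meshgrid(grid, grid, grid, indexing="ij")
        resid = np.zeros(g1.shape)
        for xi_row, yi in zip(x, y):
            resid += (yi - xi_row[0] * g1 - xi_row[1] * g2 - xi_row[2] * g3) ** 2
        best = np.unravel_index(np.argmin(resid), resid.shape)
        gamma_grid = np.array([grid[i] for i in best])
        gamma_fit = -np.log1p(-np.array([fit.tree.theta[q] for q in branches]))
        np.testing.assert_allclose(gamma_fit, gamma_grid, atol=step)

    def test_dropped_rows_warn_not_fail(self, bench_tree):
        s = noiseless_s(bench_tree)
        s.loc["A", :] = np.nan  # all rows with first unit A removed
        with pytest.warns(UserWarning):
            fit = fit_thetas(bench_tree, s)
        assert fit.xi >= 0.0


class TestClusterPhase:
    def test_two_units_trivial(self):
        s = pd.DataFrame([[np.nan, 0.9], [0.85, np.nan]],
                         index=["x", "y"], columns=["x", "y"])
        fit = cluster_phase(s)
        assert fit.tree.is_binary() and set(fit.tree.tips) == {"x", "y"}

    def test_noiseless_recovery_matches_exhaustive_search(self, bench_tree):
        """The greedy clustering phase finds the global minimiser of the
        objective over all 105 rooted binary 5-tip topologies."""
        s = noiseless_s(bench_tree)
        fit = cluster_phase(s)
        assert tf.topology_equal(fit.tree, bench_tree)
        best_xi, best_tree = np.inf, None
        n_topologies = 0
        for cand in all_rooted_binary_topologies(bench_tree.tips):
            n_topologies += 1
            f = fit_thetas(cand, s)
            if f.xi < best_xi:
                best_xi, best_tree = f.xi, cand
        assert n_topologies == 105
        assert tf.topology_equal(best_tree, bench_tree)
        assert fit.xi <= best_xi + 1e-12

    def test_candidate_fit_count_is_cubic(self, monkeypatch):
        """K - 2 merge steps evaluate C(j, 2) candidate fits at child count
        j, so sum_{j=3..K} C(j, 2) fits in total."""
        import treefst.inference as inf_mod

        calls = {"n": 0}
        real = inf_mod.fit_thetas

        def counting(tree, s):
            calls["n"] += 1
            return real(tree, s)

        monkeypatch.setattr(inf_mod, "fit_thetas", counting)
        k = 6
        tree = random_binary_tree([f"t{i}" for i in range(k)],
                                  np.random.default_rng(0))
        inf_mod.cluster_phase(noiseless_s(tree))
        expected = 1 + sum(j * (j - 1) // 2 for j in range(3, k + 1))
        assert calls["n"] == expected


class TestImprovePhase:
    def test_optimum_left_unchanged(self, bench_tree):
        s = noiseless_s(bench_tree)
        start = fit_thetas(bench_tree, s)
        out = improve_phase(start, s, seed=5)
        assert tf.topology_equal(out.tree, bench_tree)
        assert out.xi <= start.xi

    def test_misgrafted_tip_relocated(self, bench_tree):
        """Swap tips D and E, then improve on noiseless data: the true
        topology is restored and the objective drops to ~0."""
        s = noiseless_s(bench_tree)
        parent = {n: bench_tree.parent(n) for n in bench_tree.nodes}
        parent["D"], parent["E"] = parent["E"], parent["D"]
        wrong = PopulationTree(parent)
        start = fit_thetas(wrong, s)
        assert start.xi > 1e-6
        out = improve_phase(start, s, seed=2)
        assert tf.topology_equal(out.tree, bench_tree)
        assert out.xi <= 1e-16

    def test_xi_never_increases(self, bench_tree):
        cfg = tf.ScenarioConfig(tree=bench_tree, gametes_per_unit=10,
                                n_sites=100)
        rep = tf.simulate_replicate(cfg, np.random.default_rng(8))
        s = tf.s_matrix(tf.pair_sums(rep.counts))
        start = cluster_phase(s)
        out = improve_phase(start, s, seed=1)
        assert out.xi <= start.xi + 1e-12


class TestEndToEnd:
    @pytest.mark.parametrize("k,seed", [(4, 0), (5, 1), (6, 2), (7, 3)])
    def test_noiseless_identifiability_random_trees(self, k, seed):
        """Noiseless S from a random binary tree (theta in [0.02, 0.3]) is
        enough to recover the topology and thetas to 1e-6."""
        rng = np.random.default_rng(seed)
        truth = random_binary_tree([f"t{i}" for i in range(k)], rng)
        s = noiseless_s(truth)
        fit = improve_phase(cluster_phase(s), s, seed=seed)
        assert tf.topology_equal(fit.tree, truth)
        got, want = theta_by_clade(fit.tree), theta_by_clade(truth)
        assert max(abs(got[c] - want[c]) for c in want) < 1e-6

    def test_seeded_determinism(self, bench_tree):
        cfg = tf.ScenarioConfig(tree=bench_tree, gametes_per_unit=10,
                                n_sites=200)
        rep = tf.simulate_replicate(cfg, np.random.default_rng(4))
        r1 = tf.CoancestryModel(rep.counts).fit(seed=7)
        r2 = tf.CoancestryModel(rep.counts).fit(seed=7)
        assert r1.to_newick() == r2.to_newick()
        assert r1.xi == r2.xi
        pd.testing.assert_frame_equal(r1.fst_h, r2.fst_h)

    def test_duplicated_unit_gets_zero_branch_pair(self, bench_tree):
        cfg = tf.ScenarioConfig(tree=bench_tree, gametes_per_unit=25,
                                n_sites=2000)
        rep = tf.simulate_replicate(cfg, np.random.default_rng(6))
        acm = rep.counts
        dup = tf.AlleleCountMatrix(
            acm.unit_labels + ["Adup"], acm.loci,
            np.column_stack([acm.ref_count, acm.ref_count[:, 0]]),
            np.column_stack([acm.n_gametes, acm.n_gametes[:, 0]]),
        )
        res = tf.CoancestryModel(dup).fit(seed=0)
        # identical units: sibling tips with ~zero branch lengths
        assert res.tree.parent("A") == res.tree.parent("Adup")
        assert res.tree.theta["A"] == pytest.approx(0.0, abs=1e-8)
        assert res.tree.theta["Adup"] == pytest.approx(0.0, abs=1e-8)
        assert res.fst_h.at["A", "Adup"] == pytest.approx(0.0, abs=1e-8)

    def test_two_units_composed_closed_form(self):
        tree = PopulationTree.star(["x", "y"], {"x": 0.1, "y": 0.2})
        cfg = tf.ScenarioConfig(tree=tree, gametes_per_unit=50, n_sites=5000)
        rep = tf.simulate_replicate(cfg, np.random.default_rng(11))
        ps = tf.pair_sums(rep.counts)
        s = tf.s_matrix(ps)
        fit, est = infer(rep.counts, seed=0)
        tx = 1 - min(s.at["x", "y"], 1.0)
        ty = 1 - min(s.at["y", "x"], 1.0)
        assert fit.tree.theta["x"] == pytest.approx(tx, abs=1e-10)
        assert fit.tree.theta["y"] == pytest.approx(ty, abs=1e-10)
        assert est.H.at["x", "y"] == pytest.approx((tx + ty) / 2, abs=1e-10)

    def test_estimator_low_bias(self, bench_tree):
        """Mean tree-based mismatch estimate across replicates is within
        3 SE of the true value."""
        cfg = tf.ScenarioConfig(tree=bench_tree, gametes_per_unit=25,
                                n_sites=1000)
        rng = np.random.default_rng(13)
        vals = []
        for i in range(120):
            rep = tf.simulate_replicate(cfg, rng)
            res = tf.CoancestryModel(rep.counts).fit(seed=i)
            vals.append(res.fst_h.at["A", "B"])
        vals = np.array(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - bench_tree.fst_h("A", "B")) < 3 * se
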
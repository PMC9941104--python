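"""Independent contrasts, squared-change parsimony, phylogenetic signal."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import valveshape as vs
from valveshape.data import ValidationError
from valveshape.phylo import signal_statistic_matrix


class TestIndependentContrasts:
    def test_two_tip_contrast(self):
        t = vs.read_newick("(A:1,B:1);")
        c = vs.independent_contrasts(t, {"A": [3.0], "B": [1.0]})
        assert abs(abs(c.contrasts[0, 0]) - 2 / np.sqrt(2)) < 1e-12
        assert c.n == 1

    def test_constant_tips_give_zero(self):
        t = vs.simulate_yule_tree(9, seed=2)
        vals = {l: [5.0, -1.0] for l in t.tip_labels}
        c = vs.independent_contrasts(t, vals)
        assert np.abs(c.contrasts).max() < 1e-12
        assert c.contrasts.shape == (8, 2)

    def test_balanced_four_taxon_hand_pruning(self):
        """Cherries (A,B) and (C,D) with values (0,0) and (3,3), unit
        branches: two zero contrasts and one deep contrast of
        (0-3)/sqrt(1.5+1.5) = -sqrt(3)."""
        t = vs.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        c = vs.independent_contrasts(
            t, {"A": [0.0], "B": [0.0], "C": [3.0], "D": [3.0]}
        )
        got = sorted(np.round(c.contrasts.ravel(), 9).tolist(), key=abs)
        assert got[0] == got[1] == 0.0
        assert abs(got[2]) == pytest.approx(np.sqrt(3), abs=1e-9)

    def test_row_count_and_label_mismatch(self):
        t = vs.simulate_yule_tree(6, seed=1)
        vals = {l: [0.0] for l in t.tip_labels}
        assert vs.independent_contrasts(t, vals).contrasts.shape[0] == 5
        vals.pop(t.tip_labels[0])
        with pytest.raises(ValidationError):
            vs.independent_contrasts(t, vals)

    def test_contrasts_uncorrelated_with_node_height_under_bm(self):
        """Brownian data: standardized contrasts carry no trend with the
        standardization variance (adequate standardization)."""
        rng = np.random.default_rng(7)
        rs = []
        for rep in range(8):
            t = vs.simulate_yule_tree(200, seed=100 + rep)
            x = _simulate_bm(t, rng)
            c = vs.independent_contrasts(t, pd.DataFrame({"x": x}, index=t.tip_labels))
            rs.append(np.corrcoef(np.abs(c.contrasts[:, 0]), c.variances)[0, 1])
        assert abs(float(np.mean(rs))) < 0.1


def _simulate_bm(tree, rng, rate=1.0):
    vals = {}
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            vals[node] = 0.0
        else:
            vals[node] = vals[node.parent_node] + rng.normal(
                0, np.sqrt(rate * node.edge.length)
            )
    return pd.Series(
        {n.taxon.label: vals[n] for n in tree.tree.leaf_node_iter()}
    )[tree.tip_labels].to_numpy()


class TestSquaredChangeParsimony:
    def test_constant_tips(self):
        t = vs.simulate_yule_tree(7, seed=4)
        anc = vs.squared_change_parsimony(t, {l: [2.5] for l in t.tip_labels})
        assert anc.tree_length == pytest.approx(0.0, abs=1e-18)
        for nid in anc.node_order:
            assert anc.states[nid][0] == pytest.approx(2.5, abs=1e-12)

    def test_two_tip_closed_form(self):
        t = vs.read_newick("(A:1,B:2);")
        anc = vs.squared_change_parsimony(t, {"A": [0.0], "B": [6.0]})
        assert anc.states["node0"][0] == pytest.approx(2.0, abs=1e-12)
        assert anc.tree_length == pytest.approx(12.0, abs=1e-12)

    def test_matches_generic_numerical_minimizer(self, rng):
        """5-taxon random instance: states and minimum agree with scipy
        BFGS minimizing the weighted sum of squared changes directly."""
        t = vs.simulate_yule_tree(5, seed=9)
        X = pd.DataFrame(rng.normal(size=(5, 2)), index=t.tip_labels)
        anc = vs.squared_change_parsimony(t, X)

        nodes = list(t.tree.preorder_node_iter())
        internal = [n for n in nodes if not n.is_leaf()]
        tips = {n.taxon.label: X.loc[n.taxon.label].to_numpy() for n in
                t.tree.leaf_node_iter()}

        def objective(flat):
            states = {n: flat[2 * i: 2 * i + 2] for i, n in enumerate(internal)}
            def val(n):
                return tips[n.taxon.label] if n.is_leaf() else states[n]
            tot = 0.0
            for n in nodes:
                if n.parent_node is None:
                    continue
                d = val(n) - val(n.parent_node)
                tot += float(d @ d) / n.edge.length
            return tot

        res = optimize.minimize(objective, np.zeros(2 * len(internal)),
                                method="BFGS", tol=1e-14)
        assert anc.tree_length == pytest.approx(res.fun, abs=1e-8)
        best = anc.matrix().ravel()
        # map optimizer solution into the same node order
        ids = {n: i for i, n in enumerate(internal)}
        from valveshape.phylo import _internal_ids
        nid = _internal_ids(t)
        opt = np.concatenate(
            [res.x[2 * ids[n]: 2 * ids[n] + 2] for n in internal]
        )
        order_opt = {nid[n]: res.x[2 * ids[n]: 2 * ids[n] + 2] for n in internal}
        for name in anc.node_order:
            np.testing.assert_allclose(anc.states[name], order_opt[name], atol=1e-6)

    @pytest.mark.parametrize("n_tips", [4, 6, 8])
    def test_equals_bm_gls_reconstruction(self, rng, n_tips):
        """Weighted squared-change parsimony equals the Brownian-motion
        GLS ancestral estimates computed by brute-force matrix inversion
        (root by GLS mean, internal nodes by conditional expectation)."""
        t = vs.simulate_yule_tree(n_tips, seed=20 + n_tips)
        X = pd.DataFrame(rng.normal(size=(n_tips, 1)), index=t.tip_labels)
        anc = vs.squared_change_parsimony(t, X)

        labels = t.tip_labels
        idx = {l: i for i, l in enumerate(labels)}
        # tip-tip covariance = shared path length from the root
        V = np.zeros((n_tips, n_tips))
        depth = {}
        for node in t.tree.preorder_node_iter():
            depth[node] = (depth.get(node.parent_node, 0.0)
                           + (node.edge.length or 0.0))
            if node.parent_node is None:
                continue
            leaves = [l.taxon.label for l in node.leaf_iter()]
            for a in leaves:
                for b in leaves:
                    V[idx[a], idx[b]] += node.edge.length
        Vi = np.linalg.inv(V)
        one = np.ones(n_tips)
        x = X.loc[labels].to_numpy().ravel()
        root_hat = float(one @ Vi @ x) / float(one @ Vi @ one)

        from valveshape.phylo import _internal_ids
        nid = _internal_ids(t)
        for node in t.tree.preorder_internal_node_iter():
            # covariance of internal node with each tip = shared path length
            cov = np.zeros(n_tips)
            anc_chain = set()
            p = node
            while p is not None:
                anc_chain.add(p)
                p = p.parent_node
            for leaf in t.tree.leaf_node_iter():
                # walk up from leaf accumulating shared branch lengths
                q, shared = leaf, 0.0
                chain = []
                while q is not None:
                    chain.append(q)
                    q = q.parent_node
                # shared ancestors of node and leaf
                common = [c for c in chain if c in anc_chain]
                mrca = common[0]
                cov[idx[leaf.taxon.label]] = depth[mrca]
            est = root_hat + cov @ Vi @ (x - root_hat * one)
            assert anc.states[nid[node]][0] == pytest.approx(est, abs=1e-8)

    def test_quadratic_form_route_agrees(self, rng):
        t = vs.simulate_yule_tree(10, seed=6)
        X = pd.DataFrame(rng.normal(size=(10, 3)), index=t.tip_labels)
        anc = vs.squared_change_parsimony(t, X)
        K, order = signal_statistic_matrix(t)
        Xo = X.loc[order].to_numpy()
        assert anc.tree_length == pytest.approx(
            float(np.einsum("id,ij,jd->", Xo, K, Xo)), rel=1e-10
        )

    def test_tree_length_invariant_under_equal_value_relabel(self, rng):
        t = vs.simulate_yule_tree(6, seed=8)
        labels = t.tip_labels
        vals = {l: [1.0, 2.0] for l in labels}
        base = vs.squared_change_parsimony(t, vals).tree_length
        swapped = dict(vals)
        swapped[labels[0]], swapped[labels[1]] = vals[labels[1]], vals[labels[0]]
        assert vs.squared_change_parsimony(t, swapped).tree_length == base


class TestSignalPermutation:
    def test_two_tips_p_is_one(self):
        t = vs.read_newick("(A:1,B:1);")
        _, p = vs.phylo_signal_permutation(t, {"A": [0.0], "B": [3.0]},
                                           n_perm=99, seed=0)
        assert p == 1.0

    def test_strong_signal_detected(self, rng):
        t = vs.simulate_yule_tree(46, seed=13)
        x = _simulate_bm(t, rng, rate=1.0)
        df = pd.DataFrame({"x": x}, index=t.tip_labels)
        tl, p = vs.phylo_signal_permutation(t, df, n_perm=199, seed=1)
        assert p < 0.05

    def test_bad_nperm_rejected(self):
        t = vs.read_newick("(A:1,B:1);")
        with pytest.raises(ValueError):
            vs.phylo_signal_permutation(t, {"A": [0.0], "B": [1.0]}, n_perm=0)

    def test_seed_reproducibility(self, rng):
        t = vs.simulate_yule_tree(12, seed=3)
        df = pd.DataFrame(rng.normal(size=(12, 2)), index=t.tip_labels)
        r1 = vs.phylo_signal_permutation(t, df, n_perm=199, seed=42)
        r2 = vs.phylo_signal_permutation(t, df, n_perm=199, seed=42)
        assert r1 == r2


class TestPhylomorphospace:
    def test_two_tip_layout(self):
        t = vs.read_newick("(A:1,B:2);")
        scores = pd.DataFrame([[0.0, 0.0], [6.0, 3.0]], index=["A", "B"])
        nodes, edges = vs.phylomorphospace(t, scores)
        assert len(nodes) == 3 and len(edges) == 2
        root = nodes[~nodes["is_tip"]].iloc[0]
        assert root["x"] == pytest.approx(2.0)  # weighted mean (w = 1/length)
        assert root["y"] == pytest.approx(1.0)

    def test_edge_count_2n_minus_2(self):
        t = vs.simulate_yule_tree(15, seed=5)
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(rng.normal(size=(15, 2)), index=t.tip_labels)
        nodes, edges = vs.phylomorphospace(t, scores)
        assert len(edges) == 2 * 15 - 2
        assert len(nodes) == 2 * 15 - 1

    def test_tips_keep_input_coordinates(self):
        t = vs.simulate_yule_tree(6, seed=2)
        rng = np.random.default_rng(1)
        scores = pd.DataFrame(rng.normal(size=(6, 2)), index=t.tip_labels)
        nodes, _ = vs.phylomorphospace(t, scores)
        for lab in t.tip_labels:
            np.testing.assert_allclose(
                nodes.loc[lab, ["x", "y"]].to_numpy(float),
                scores.loc[lab].to_numpy(),
            )

    def test_axis_mismatch_rejected(self):
        t = vs.read_newick("(A:1,B:2);")
        scores = pd.DataFrame([[0.0, 0, 0], [1, 1, 1]], index=["A", "B"])
        with pytest.raises(ValidationError):
            vs.phylomorphospace(t, scores)
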
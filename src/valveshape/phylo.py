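"""Phylogenetic comparative methods for multivariate valve traits.

Implements the three pieces the comparative stage of the pipeline needs:

* Felsenstein's phylogenetically independent contrasts (pruning algorithm),
  multivariate: one standardized contrast row per internal node of a
  binary tree.
* Squared-change parsimony ancestral reconstruction: internal-node values
  minimizing the branch-length-weighted sum of squared changes, which for
  positive branch lengths coincides with the Brownian-motion ML (GLS)
  estimates; the attained minimum ("tree length") doubles as the
  phylogenetic-signal statistic.
* A permutation test of phylogenetic signal: tip rows are shuffled jointly
  across trait dimensions and the observed tree length compared with the
  permutation distribution (signal = shorter-than-random tree; add-one
  p-value convention).

Plus the phylomorphospace projection: tips and reconstructed ancestors on
two chosen axes, with the tree's edges as a plot-ready edge list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ValidationError
from .trees import PhyloTree


@dataclass
class ContrastSet:
    """Standardized independent contrasts, one row per internal node."""

    contrasts: np.ndarray  # (n_tips - 1, p)
    node_ids: list[str]
    variances: np.ndarray  # standardization variances v_a + v_b per contrast

    @property
    def n(self) -> int:
        return self.contrasts.shape[0]


@dataclass
class AncestralStates:
    """Squared-change-parsimony reconstruction."""

    states: dict  # node id -> (p,) vector (internal nodes)
    tree_length: float  # minimized sum over edges of (delta)^2 / length
    node_order: list[str]

    def matrix(self) -> np.ndarray:
        return np.vstack([self.states[nid] for nid in self.node_order])


def _tip_matrix(tree: PhyloTree, tip_values) -> tuple[np.ndarray, dict]:
    """Validate tip values against the tree; return (matrix, label -> row)."""
    if isinstance(tip_values, pd.DataFrame):
        labels = [str(i) for i in tip_values.index]
        X = tip_values.to_numpy(dtype=float)
    elif isinstance(tip_values, dict):
        labels = list(tip_values)
        X = np.vstack([np.atleast_1d(np.asarray(tip_values[l], float)) for l in labels])
    else:
        raise ValidationError(
            "tip_values must be a DataFrame indexed by tip label or a dict"
        )
    if X.ndim == 1:
        X = X[:, None]
    tree_tips = set(tree.tip_labels)
    if set(labels) != tree_tips:
        raise ValidationError(
            f"tip labels do not match tree tips; missing from values: "
            f"{sorted(tree_tips - set(labels))}, extra: {sorted(set(labels) - tree_tips)}"
        )
    return X, {l: i for i, l in enumerate(labels)}


def _internal_ids(tree: PhyloTree) -> dict:
    """Deterministic internal node ids (preorder numbering)."""
    ids = {}
    counter = 0
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            ids[node] = node.taxon.label
        else:
            ids[node] = f"node{counter}"
            counter += 1
    return ids


def independent_contrasts(tree: PhyloTree, tip_values) -> ContrastSet:
    """Felsenstein's pruning algorithm, vector-valued.

    At each internal node with children (a, b) carrying values x_a, x_b and
    effective branch lengths v_a, v_b, the standardized contrast is
    (x_a - x_b) / sqrt(v_a + v_b); the node takes the variance-weighted mean
    value and its parent branch is extended by v_a v_b / (v_a + v_b).
    """
    if not tree.is_binary():
        raise ValidationError("contrasts require a binary tree; resolve polytomies")
    X, row_of = _tip_matrix(tree, tip_values)
    ids = _internal_ids(tree)
    values: dict = {}
    lengths: dict = {}
    contrasts, variances, node_ids = [], [], []
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            values[node] = X[row_of[node.taxon.label]]
            lengths[node] = float(node.edge.length)
            continue
        a, b = node.child_nodes()
        va, vb = lengths[a], lengths[b]
        contrasts.append((values[a] - values[b]) / np.sqrt(va + vb))
        variances.append(va + vb)
        node_ids.append(ids[node])
        values[node] = (values[a] / va + values[b] / vb) / (1 / va + 1 / vb)
        base = float(node.edge.length) if node.parent_node is not None else 0.0
        lengths[node] = base + va * vb / (va + vb)
    return ContrastSet(
        contrasts=np.vstack(contrasts),
        node_ids=node_ids,
        variances=np.asarray(variances),
    )


def squared_change_parsimony(
    tree: PhyloTree, tip_values, weighted: bool = True
) -> AncestralStates:
    """Exact squared-change-parsimony ancestral states.

    Minimizes sum over edges of (x_parent - x_child)^2 / l_edge (weighted;
    ``weighted=False`` uses unit weights), via the standard two-pass
    algorithm: a postorder pass computing conditional (downpass) values and
    variances, then a preorder pass blending each node's downpass value
    with its parent's final value.  ``tree_length`` is the attained
    minimum summed over all trait dimensions.
    """
    X, row_of = _tip_matrix(tree, tip_values)
    ids = _internal_ids(tree)

    def elen(node):
        if not weighted:
            return 1.0
        l = float(node.edge.length)
        if l <= 0:
            raise ValidationError("squared-change parsimony needs positive lengths")
        return l

    down_val, down_var = {}, {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            down_val[node] = X[row_of[node.taxon.label]]
            down_var[node] = 0.0
            continue
        num, denom = 0.0, 0.0
        for ch in node.child_nodes():
            v = down_var[ch] + elen(ch)
            num = num + down_val[ch] / v
            denom += 1.0 / v
        down_val[node] = num / denom
        down_var[node] = 1.0 / denom

    final: dict = {}
    for node in tree.tree.preorder_node_iter():
        if node.is_leaf():
            final[node] = down_val[node]
            continue
        if node.parent_node is None:
            final[node] = down_val[node]
            continue
        v_down = down_var[node]
        l_par = elen(node)
        w_down, w_par = 1.0 / v_down if v_down > 0 else None, 1.0 / l_par
        if w_down is None:  # degenerate: no tip information below? cannot happen
            final[node] = final[node.parent_node]
        else:
            final[node] = (down_val[node] * w_down + final[node.parent_node] * w_par) / (
                w_down + w_par
            )

    tree_length = 0.0
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        delta = final[node] - final[node.parent_node]
        tree_length += float((delta**2).sum()) / elen(node)

    states = {ids[n]: final[n] for n in tree.tree.preorder_node_iter()}
    order = [ids[n] for n in tree.tree.preorder_node_iter() if not n.is_leaf()]
    return AncestralStates(
        states=states, tree_length=tree_length, node_order=order
    )


def signal_statistic_matrix(tree: PhyloTree, weighted: bool = True):
    """Quadratic-form matrix of the squared-change-parsimony tree length.

    Minimizing sum over edges of (x_parent - x_child)^2 / l over ancestral
    states is a quadratic program whose minimum is x' K x per trait
    dimension, where K is the Schur complement of the edge-weight graph
    Laplacian onto the tips.  Returns (K, tip_labels); used to evaluate
    many permutations cheaply, and cross-checked against the two-pass
    reconstruction.
    """
    nodes = list(tree.tree.preorder_node_iter())
    tips = [n for n in nodes if n.is_leaf()]
    internal = [n for n in nodes if not n.is_leaf()]
    index = {n: i for i, n in enumerate(tips)}
    index.update({n: len(tips) + j for j, n in enumerate(internal)})
    m = len(nodes)
    L = np.zeros((m, m))
    for node in nodes:
        if node.parent_node is None:
            continue
        w = 1.0 / float(node.edge.length) if weighted else 1.0
        i, j = index[node], index[node.parent_node]
        L[i, i] += w
        L[j, j] += w
        L[i, j] -= w
        L[j, i] -= w
    nt = len(tips)
    Ltt, Lta, Laa = L[:nt, :nt], L[:nt, nt:], L[nt:, nt:]
    K = Ltt - Lta @ np.linalg.solve(Laa, Lta.T)
    return K, [n.taxon.label for n in tips]


def phylo_signal_permutation(
    tree: PhyloTree,
    tip_values,
    n_perm: int = 10_000,
    seed=None,
    weighted: bool = True,
):
    """Permutation test of phylogenetic signal via squared-change parsimony.

    Tip rows are permuted jointly across all trait dimensions; signal means
    the observed tree length is *shorter* than under permutation, so
    p = (#{TL_perm <= TL_obs} + 1) / (n_perm + 1).  Tree lengths are
    evaluated through the exact quadratic form of the parsimony minimum.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X, row_of = _tip_matrix(tree, tip_values)
    K, tip_order = signal_statistic_matrix(tree, weighted=weighted)
    Xo = X[[row_of[l] for l in tip_order]]
    obs = float(np.einsum("id,ij,jd->", Xo, K, Xo))
    rng = np.random.default_rng(seed)
    count = 0
    n = Xo.shape[0]
    for _ in range(n_perm):
        Xp = Xo[rng.permutation(n)]
        tl = float(np.einsum("id,ij,jd->", Xp, K, Xp))
        if tl <= obs + 1e-12:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return obs, p


def phylomorphospace(
    tree: PhyloTree,
    tip_scores,
    ancestors: AncestralStates | None = None,
):
    """Node coordinates and edge list for a phylomorphospace plot.

    ``tip_scores`` is an (n, 2) DataFrame indexed by tip label (two PCA
    axes).  Ancestors default to the squared-change-parsimony
    reconstruction on the same two axes; if supplied, they must provide a
    vector of length 2 for every internal node.
    """
    if isinstance(tip_scores, pd.DataFrame):
        if tip_scores.shape[1] != 2:
            raise ValidationError("tip_scores must have exactly 2 axes")
    else:
        raise ValidationError("tip_scores must be a DataFrame indexed by tip label")
    if ancestors is None:
        ancestors = squared_change_parsimony(tree, tip_scores)
    ids = _internal_ids(tree)
    rows, edges = [], []
    for node in tree.tree.preorder_node_iter():
        nid = ids[node]
        if node.is_leaf():
            xy = tip_scores.loc[nid].to_numpy(dtype=float)
        else:
            if nid not in ancestors.states:
                raise ValidationError(f"ancestor state missing for {nid}")
            xy = np.asarray(ancestors.states[nid], float)
            if xy.shape != (2,):
                raise ValidationError(
                    f"ancestral state for {nid} has {xy.shape} axes, expected 2"
                )
        rows.append({"node": nid, "is_tip": node.is_leaf(), "x": xy[0], "y": xy[1]})
        if node.parent_node is not None:
            edges.append((ids[node.parent_node], nid))
    nodes = pd.DataFrame(rows).set_index("node")
    return nodes, edges
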
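"""Independent brute-force oracles shared by unit and acceptance tests."""

import numpy as np
import pandas as pd


def brute_force_sequential_ss(meta, Y):
    """Explicit hat-matrix projections of the growing ANOVA design; SS read
    off as differences of projected squared norms (independent of the
    package's lstsq-based route)."""
    n = len(meta)
    mats = [np.ones((n, 1))]
    for col in ("species", "sex", "specimen_id", "side"):
        mats.append(pd.get_dummies(meta[col]).to_numpy(float))
    ss, dfs = [], []
    X = np.empty((n, 0))
    for M in mats:
        X = np.hstack([X, M])
        hat = X @ np.linalg.pinv(X)
        ss.append(float(((hat @ Y) ** 2).sum()))
        dfs.append(int(round(np.trace(hat))))
    effects = {}
    for i, name in enumerate(
        ["species", "sex", "individual", "directional_asymmetry"], start=1
    ):
        effects[name] = (ss[i] - ss[i - 1], dfs[i] - dfs[i - 1])
    effects["fluctuating_asymmetry"] = (float((Y**2).sum()) - ss[-1], n - dfs[-1])
    return effects


def bm_covariance(tree):
    """Tip-tip Brownian covariance (shared root-to-MRCA path lengths)."""
    labels = tree.tip_labels
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    V = np.zeros((n, n))
    for node in tree.tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        leaves = [l.taxon.label for l in node.leaf_iter()]
        for a in leaves:
            for b in leaves:
                V[idx[a], idx[b]] += node.edge.length
    return V, labels
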
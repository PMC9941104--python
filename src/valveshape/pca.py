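"""Principal component analysis of shape data, with wireframe extremes.

Two flavours are used in the pipeline: mean-centred PCA of species-average
residuals, and *uncentred* PCA of independent contrasts (contrasts have
zero expectation, so no mean is removed).  The decomposition is of the
covariance matrix with divisor n - 1 in both cases; eigenvector signs are
fixed deterministically (the largest-magnitude loading of each component is
made positive) so scores are reproducible across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PCModel:
    """Fitted principal components.

    eigenvalues are descending and non-negative and sum to the total
    variance (trace of the covariance matrix); eigenvector columns are
    orthonormal; ``scores[i, j]`` is observation i on component j.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (p, n_comp), columns are components
    scores: np.ndarray  # (n, n_comp)
    mean: np.ndarray  # (p,), zeros for uncentred fits
    variance_fraction: np.ndarray
    centering: str

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def project(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return (X - self.mean) @ self.eigenvectors

    def summary(self) -> str:
        lines = [f"PCA ({self.centering}-centred), {self.n_components} components"]
        cum = 0.0
        for i, (ev, vf) in enumerate(
            zip(self.eigenvalues[:10], self.variance_fraction[:10]), start=1
        ):
            cum += vf
            lines.append(
                f"  PC{i}: eigenvalue {ev:.6g}, {100 * vf:.1f}% "
                f"(cumulative {100 * cum:.1f}%)"
            )
        return "\n".join(lines)


class ShapePCA:
    """PCA model; ``centering='none'`` for independent contrasts."""

    def __init__(self, matrix, centering: str = "mean"):
        if centering not in ("mean", "none"):
            raise ValueError("centering must be 'mean' or 'none'")
        X = np.asarray(matrix, float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need an (n >= 2, p) matrix")
        self.X = X
        self.centering = centering

    def fit(self) -> PCModel:
        X = self.X
        n, p = X.shape
        mean = X.mean(axis=0) if self.centering == "mean" else np.zeros(p)
        Xc = X - mean
        # SVD route: eigenvalues of Xc'Xc/(n-1) without forming p x p matrix
        U, svals, Vt = np.linalg.svd(Xc, full_matrices=False)
        eigenvalues = svals**2 / (n - 1)
        eigenvectors = Vt.T
        # deterministic sign: largest-|loading| entry positive
        for j in range(eigenvectors.shape[1]):
            col = eigenvectors[:, j]
            if col[np.argmax(np.abs(col))] < 0:
                eigenvectors[:, j] = -col
        scores = Xc @ eigenvectors
        total = eigenvalues.sum()
        frac = eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
        return PCModel(
            eigenvalues=eigenvalues,
            eigenvectors=eigenvectors,
            scores=scores,
            mean=mean,
            variance_fraction=frac,
            centering=self.centering,
        )


def pca(matrix, centering: str = "mean") -> PCModel:
    """Functional wrapper around :class:`ShapePCA`."""
    return ShapePCA(matrix, centering=centering).fit()


def outline_edges(k: int = 48, n_dorsal: int = 28, n_ventral: int = 18):
    """Neighbour-linking edge list for the anchor-first landmark convention.

    Landmarks are ordered [anterior anchor, posterior anchor, dorsal 1..nd,
    ventral 1..nv]; the wireframe walks anterior -> dorsal arc -> posterior
    -> ventral arc -> anterior.
    """
    if 2 + n_dorsal + n_ventral != k:
        raise ValueError("k must equal 2 + n_dorsal + n_ventral")
    walk = [0] + list(range(2, 2 + n_dorsal)) + [1] + list(
        range(2 + n_dorsal, k)
    )
    return [(walk[i], walk[(i + 1) % len(walk)]) for i in range(len(walk))]


def pc_extremes(model: PCModel, pc: int, magnitude: float, edges=None):
    """Shapes at mean -/+ magnitude x eigenvector for wireframe plots.

    Returns ``(minus, plus, edges)`` where minus/plus are (k, 2) landmark
    arrays and edges is the neighbour-linking edge list (outline order with
    the two anchors included).  Re-projecting either extreme onto the model
    gives a score of -/+ magnitude on ``pc`` and 0 elsewhere.
    """
    if not (0 <= pc < model.n_components):
        raise IndexError(f"pc {pc} out of range [0, {model.n_components})")
    vec = model.eigenvectors[:, pc]
    minus = (model.mean - magnitude * vec).reshape(-1, 2)
    plus = (model.mean + magnitude * vec).reshape(-1, 2)
    k = minus.shape[0]
    if edges is None:
        if k == 48:
            edges = outline_edges(48)
        else:
            edges = [(i, (i + 1) % k) for i in range(k)]
    return minus, plus, edges
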
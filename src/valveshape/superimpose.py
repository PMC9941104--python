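"""Generalized Procrustes superimposition of 2-D valve outlines.

The pipeline follows the standard partial-Procrustes convention: every
configuration is centred at the origin and scaled to unit centroid size,
then iteratively rotated to the running consensus.  Reflections are never
allowed in the per-shape rotation fit — valve side is handled explicitly by
:func:`reflect_side` *before* superimposition ("matching symmetry"), so a
left valve enters the GPA already mirrored into right-valve orientation.

Shapes near the consensus can optionally be projected orthogonally onto the
tangent space at the consensus, the linear space in which all downstream
multivariate statistics operate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import LandmarkConfiguration


class DegenerateShapeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# size and elementary transforms
# ---------------------------------------------------------------------------

def centroid_size(config) -> float:
    """Centroid size: sqrt of summed squared landmark distances to centroid.

    Accepts a LandmarkConfiguration or a (k, 2) coordinate array.  Scales
    linearly under uniform scaling of the configuration.
    """
    coords = config.coords if hasattr(config, "coords") else np.asarray(config, float)
    centred = coords - coords.mean(axis=0)
    cs = float(np.sqrt((centred**2).sum()))
    if cs <= 0 or not np.isfinite(cs):
        raise DegenerateShapeError("all landmarks coincide; centroid size is zero")
    return cs


def reflect_side(
    config: LandmarkConfiguration,
    side_to_reflect: str = "left",
    axis: str = "vertical",
) -> LandmarkConfiguration:
    """Mirror one valve side into the other's orientation.

    ``axis='vertical'`` negates x about the configuration centroid (an
    anterior-posterior flip); ``'horizontal'`` negates y.  Landmark order is
    preserved — pair analyses rely on landmark i matching landmark i across
    sides.  Reflecting twice is the identity.
    """
    if config.side != side_to_reflect:
        return config
    coords = config.coords.copy()
    centroid = coords.mean(axis=0)
    j = 0 if axis == "vertical" else 1
    coords[:, j] = 2 * centroid[j] - coords[:, j]
    return config.with_coords(coords)


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (det=+1) minimizing ||A @ R - B||_F for (k,2) inputs."""
    M = A.T @ B
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, d]) @ Vt


# ---------------------------------------------------------------------------
# generalized Procrustes analysis
# ---------------------------------------------------------------------------

@dataclass
class AlignedSample:
    """Result of a generalized Procrustes fit.

    Attributes
    ----------
    shapes : (n, 2k) ndarray
        Procrustes coordinates (row = flattened (k,2), x then y interleaved
        per landmark), each centred at the origin with unit centroid size.
    centroid_sizes : (n,) ndarray
        Pre-scaling centroid sizes in physical units.
    consensus : (2k,) ndarray
        Coordinate-wise mean of the aligned shapes.
    """

    shapes: np.ndarray
    centroid_sizes: np.ndarray
    consensus: np.ndarray
    iterations: int
    converged: bool
    labels: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.shapes.shape[0]

    @property
    def k(self) -> int:
        return self.shapes.shape[1] // 2

    def shape_matrix(self, i: int) -> np.ndarray:
        return self.shapes[i].reshape(-1, 2)

    def procrustes_distances(self) -> np.ndarray:
        """Euclidean distance of each aligned shape to the consensus."""
        return np.linalg.norm(self.shapes - self.consensus, axis=1)


def _as_coord_array(configs) -> tuple[np.ndarray, list]:
    if isinstance(configs, np.ndarray):
        X = np.asarray(configs, float)
        if X.ndim == 2:  # (n, 2k) flattened
            X = X.reshape(X.shape[0], -1, 2)
        return X, list(range(X.shape[0]))
    arrs = [c.coords for c in configs]
    labels = [(c.specimen_id, c.side) for c in configs]
    return np.stack(arrs), labels


def gpa(configs, tol: float = 1e-10, max_iter: int = 100) -> AlignedSample:
    """Generalized Procrustes superimposition.

    Translation is removed, each shape scaled to unit centroid size, and
    rotations fitted iteratively against the consensus until the root-mean-
    square change of the consensus drops below ``tol`` (default 1e-10) or
    ``max_iter`` iterations.  Reflections are forbidden.  The reported
    consensus is the exact coordinate-wise mean of the aligned shapes.
    """
    X, labels = _as_coord_array(configs)
    n, k, _ = X.shape
    if n < 2:
        raise ValueError("GPA needs at least two configurations")
    X = X - X.mean(axis=1, keepdims=True)
    sizes = np.sqrt((X**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0) or not np.all(np.isfinite(sizes)):
        raise DegenerateShapeError("degenerate (zero centroid size) configuration")
    X = X / sizes[:, None, None]

    consensus = X[0].copy()
    consensus /= np.linalg.norm(consensus)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            X[i] = X[i] @ optimal_rotation(X[i], consensus)
        new_consensus = X.mean(axis=0)
        new_consensus /= np.linalg.norm(new_consensus)
        delta = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"GPA did not converge in {max_iter} iterations", stacklevel=2)
    _canonicalize_orientation(X)
    # final consensus: exact mean of aligned shapes
    consensus_mean = X.mean(axis=0)
    return AlignedSample(
        shapes=X.reshape(n, 2 * k),
        centroid_sizes=sizes,
        consensus=consensus_mean.ravel(),
        iterations=iterations,
        converged=converged,
        labels=labels,
    )


def _canonicalize_orientation(X: np.ndarray) -> None:
    """Rotate the whole aligned sample to a deterministic orientation.

    The consensus is aligned with its principal axes (major axis on x) and
    the residual 180-degree ambiguity fixed by the sign of the consensus'
    third moments.  Only proper rotations are applied, so Procrustes
    residuals are untouched; this makes the GPA output invariant to
    arbitrary similarity transforms of the inputs (up to shapes with a
    perfectly isotropic, symmetric consensus, where orientation is
    inherently ambiguous).
    """
    consensus = X.mean(axis=0)
    _, _, Vt = np.linalg.svd(consensus, full_matrices=False)
    R = Vt.T
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    c = consensus @ R
    # 180-degree flip: prefer positive third moment on x, then on y
    mx, my = (c[:, 0] ** 3).sum(), (c[:, 1] ** 3).sum()
    if mx < -1e-12 or (abs(mx) <= 1e-12 and my < -1e-12):
        R = -R  # rotation by pi
    X[:] = X @ R


def tangent_project(aligned: AlignedSample) -> AlignedSample:
    """Orthogonal projection onto the tangent space at the consensus.

    Each shape x is replaced by x - (<x, c> - <c, c>) c / <c, c>, i.e. its
    orthogonal projection onto the hyperplane through the consensus c and
    orthogonal to it.  The consensus itself is a fixed point and the map is
    idempotent; shapes close to the consensus move negligibly.
    """
    c = aligned.consensus
    cc = float(c @ c)
    coef = (aligned.shapes @ c - cc) / cc
    shapes = aligned.shapes - np.outer(coef, c)
    return AlignedSample(
        shapes=shapes,
        centroid_sizes=aligned.centroid_sizes,
        consensus=shapes.mean(axis=0),
        iterations=aligned.iterations,
        converged=aligned.converged,
        labels=aligned.labels,
    )


# ---------------------------------------------------------------------------
# outline resampling
# ---------------------------------------------------------------------------

def resample_outline(
    points: np.ndarray,
    anchors: tuple[int, int],
    n_dorsal: int = 28,
    n_ventral: int = 18,
) -> np.ndarray:
    """Resample a closed outline into anchor + equidistant pseudo-landmarks.

    The outline (an ordered (m, 2) polygon, implicitly closed) is split at
    the two anchor vertices into a dorsal arc (following vertex order from
    anchor 1 to anchor 2) and a ventral arc (anchor 2 back to anchor 1).
    Each arc receives the requested number of interior points at equal
    arc-length spacing (n points divide the arc into n+1 equal sub-arcs).

    Returns a (2 + n_dorsal + n_ventral, 2) array with the two anchors
    first, then dorsal, then ventral points — k = 48 for the default 28/18.
    """
    pts = np.asarray(points, float)
    i1, i2 = anchors
    if i1 == i2:
        raise ValueError("anchor indices must be distinct")
    m = pts.shape[0]
    order = np.arange(m)
    dorsal_idx = np.roll(order, -i1)
    split = int(np.where(dorsal_idx == i2)[0][0])
    arc_d = pts[dorsal_idx[: split + 1]]
    arc_v = pts[np.concatenate([dorsal_idx[split:], dorsal_idx[:1]])]
    dorsal = _equidistant_interior(arc_d, n_dorsal)
    ventral = _equidistant_interior(arc_v, n_ventral)
    return np.vstack([pts[i1], pts[i2], dorsal, ventral])


def _equidistant_interior(arc: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(arc, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("zero-length arc between anchors")
    targets = total * np.arange(1, n + 1) / (n + 1)
    out = np.empty((n, 2))
    for j, t in enumerate(targets):
        i = int(np.searchsorted(s, t, side="right") - 1)
        i = min(i, len(seg) - 1)
        frac = (t - s[i]) / seg[i] if seg[i] > 0 else 0.0
        out[j] = arc[i] + frac * (arc[i + 1] - arc[i])
    return out


def slide_semilandmarks(
    aligned: AlignedSample,
    sliding_indices,
    max_iter: int = 5,
) -> AlignedSample:
    """Optional minimum-bending-energy sliding of outline semilandmarks.

    Each listed semilandmark may slide along the chord direction of its
    outline neighbours to minimize thin-plate-spline bending energy against
    the consensus.  OFF by default in the pipeline: the reference analyses
    treat the resampled outline points as fixed landmarks.
    """
    shapes = aligned.shapes.copy().reshape(aligned.n, -1, 2)
    ref = aligned.consensus.reshape(-1, 2)
    for _ in range(max_iter):
        L_inv = _bending_energy_inverse(ref)
        for i in range(aligned.n):
            shapes[i] = _slide_one(shapes[i], ref, L_inv, sliding_indices)
        realigned = gpa(shapes)
        shapes = realigned.shapes.reshape(aligned.n, -1, 2)
        ref = realigned.consensus.reshape(-1, 2)
    return realigned


def _bending_energy_inverse(ref: np.ndarray) -> np.ndarray:
    k = ref.shape[0]
    r2 = ((ref[:, None, :] - ref[None, :, :]) ** 2).sum(-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(r2 > 0, r2 * np.log(r2) / 2.0, 0.0)
    P = np.hstack([np.ones((k, 1)), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    Linv = np.linalg.pinv(L)
    return Linv[:k, :k]


def _slide_one(shape, ref, be_inv, sliding_indices):
    k = shape.shape[0]
    out = shape.copy()
    for idx in sliding_indices:
        prev_pt, next_pt = shape[(idx - 1) % k], shape[(idx + 1) % k]
        tangent = next_pt - prev_pt
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent = tangent / norm
        # one Newton step of bending energy along the tangent direction
        grad = 2 * (be_inv[idx] @ (out - ref))
        hess = 2 * be_inv[idx, idx]
        if hess <= 0:
            continue
        step = -float(grad @ tangent) / hess
        step = np.clip(step, -norm / 4, norm / 4)
        out[idx] = out[idx] + step * tangent
    return out
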
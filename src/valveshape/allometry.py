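"""Multivariate regression of shape on log centroid size (allometry).

Three levels are supported, mirroring the standard comparative workflow:

``total``
    Ordinary regression of (species-average) shape on log CS, with
    intercept.
``pooled_within``
    Group (species) means are removed from both sides first, pooling the
    within-group slopes.
``evolutionary``
    Inputs are phylogenetically independent contrasts, and the regression
    is forced through the origin (contrasts have zero expectation).

The strength of allometry is reported as the percentage of total shape
variation predicted by size in the summed-squares (Procrustes) metric, and
its significance by a permutation test that shuffles the size values
against the shapes (add-one p-value convention, seeded generator).

Size correction returns residuals re-centred on the consensus, so the
corrected data live in the same tangent space as the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODES = ("total", "pooled_within", "evolutionary")


@dataclass
class AllometryResults:
    """Fitted allometric regression.

    ``coefficients`` is the 2k shape-change vector per unit log CS;
    ``percent_predicted`` is SS_predicted / SS_total x 100.
    """

    coefficients: np.ndarray
    intercept: np.ndarray | None
    percent_predicted: float
    permutation_p: float | None
    residuals: np.ndarray
    fitted: np.ndarray
    mode: str
    mean_shape: np.ndarray
    n_perm: int = 0

    @property
    def allometric_direction(self) -> np.ndarray:
        """Unit vector of the estimated allometric shape change."""
        norm = np.linalg.norm(self.coefficients)
        if norm == 0:
            return self.coefficients
        return self.coefficients / norm

    def summary(self) -> str:
        lines = [
            f"Shape-on-log(CS) regression ({self.mode})",
            f"  n = {self.residuals.shape[0]}, p = {self.residuals.shape[1]} coordinates",
            f"  predicted variation: {self.percent_predicted:.2f}%",
        ]
        if self.permutation_p is not None:
            lines.append(
                f"  permutation p ({self.n_perm} rounds): {self.permutation_p:.4f}"
            )
        return "\n".join(lines)


class ShapeAllometry:
    """Model object for shape-on-size regression at one of three levels.

    Parameters
    ----------
    shapes : (n, 2k) array
        Procrustes (tangent-space) coordinates, or independent contrasts of
        them in ``evolutionary`` mode.
    log_cs : (n,) array
        Log centroid sizes (or their contrasts).
    groups : sequence, only for ``pooled_within``
        Group label per row; group means are removed before fitting.
    """

    def __init__(self, shapes, log_cs, mode: str = "total", groups=None):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.shapes = np.asarray(shapes, float)
        self.log_cs = np.asarray(log_cs, float).ravel()
        if self.shapes.ndim != 2 or self.shapes.shape[0] != self.log_cs.shape[0]:
            raise ValueError("shapes must be (n, p) matching log_cs length")
        if self.shapes.shape[0] < 3:
            raise ValueError("need at least 3 observations")
        self.mode = mode
        self.groups = None if groups is None else np.asarray(groups)
        if mode == "pooled_within" and self.groups is None:
            raise ValueError("pooled_within mode requires group labels")

    def _design(self):
        Y, x = self.shapes, self.log_cs
        if self.mode == "total":
            Yc, xc = Y - Y.mean(axis=0), x - x.mean()
        elif self.mode == "pooled_within":
            Yc, xc = Y.astype(float).copy(), x.astype(float).copy()
            for g in np.unique(self.groups):
                m = self.groups == g
                Yc[m] -= Yc[m].mean(axis=0)
                xc[m] -= xc[m].mean()
        else:  # evolutionary: through the origin
            Yc, xc = Y, x
        return Yc, xc

    def fit(self, n_perm: int = 10_000, seed=None) -> AllometryResults:
        Yc, xc = self._design()
        sxx = float(xc @ xc)
        if sxx <= 0:
            raise ValueError("no size variation: log CS is constant")
        beta = (xc @ Yc) / sxx  # per-coordinate least squares slope
        fitted_c = np.outer(xc, beta)
        resid_c = Yc - fitted_c
        ss_total = float((Yc**2).sum())
        ss_pred = float((fitted_c**2).sum())
        percent = 100.0 * ss_pred / ss_total if ss_total > 0 else 0.0

        perm_p = None
        if n_perm and n_perm > 0:
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_perm):
                xp = rng.permutation(xc)
                sp = float(xp @ xp)
                ss_p = float(((xp @ Yc) ** 2).sum()) / sp
                if ss_p >= ss_pred - 1e-12:
                    count += 1
            perm_p = (count + 1) / (n_perm + 1)

        mean_shape = self.shapes.mean(axis=0)
        intercept = None
        if self.mode == "total":
            intercept = mean_shape - beta * self.log_cs.mean()
        return AllometryResults(
            coefficients=beta,
            intercept=intercept,
            percent_predicted=percent,
            permutation_p=perm_p,
            residuals=resid_c,
            fitted=fitted_c,
            mode=self.mode,
            mean_shape=mean_shape,
            n_perm=n_perm or 0,
        )


def regress_shape_on_size(
    shapes,
    log_cs,
    mode: str = "total",
    n_perm: int = 10_000,
    seed=None,
    groups=None,
) -> AllometryResults:
    """Functional wrapper around :class:`ShapeAllometry`."""
    return ShapeAllometry(shapes, log_cs, mode=mode, groups=groups).fit(
        n_perm=n_perm, seed=seed
    )


def size_correct(shapes, fit: AllometryResults) -> np.ndarray:
    """Remove the estimated allometric component from ``shapes``.

    Returns residuals + consensus, i.e. shapes with the size-predicted
    component subtracted but re-centred on the sample mean.  Regressing the
    output on the same sizes yields ~0% predicted variation.
    """
    shapes = np.asarray(shapes, float)
    if shapes.shape != fit.residuals.shape:
        raise ValueError(
            f"shape matrix {shapes.shape} does not match the fitted sample "
            f"{fit.residuals.shape}"
        )
    return fit.residuals + fit.mean_shape


def species_averages(aligned_shapes, centroid_sizes, species_labels):
    """Per-species mean Procrustes coordinates and log of mean CS.

    Procrustes coordinates are averaged arithmetically per species; CS is
    averaged arithmetically per species *then* logged (order documented:
    log of the mean, not mean of the logs).  Returns (species, mean_shapes,
    mean_log_cs) with species sorted for determinism.
    """
    shapes = np.asarray(aligned_shapes, float)
    cs = np.asarray(centroid_sizes, float)
    labels = np.asarray(species_labels)
    species = sorted(set(labels.tolist()))
    mean_shapes = np.vstack([shapes[labels == s].mean(axis=0) for s in species])
    mean_logcs = np.array([np.log(cs[labels == s].mean()) for s in species])
    return species, mean_shapes, mean_logcs
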
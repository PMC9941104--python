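"""Procrustes ANOVA for paired (left/right) valve data.

The design quantifies, in one sequential (Type I) least-squares
decomposition, the classic effects of a matching-symmetry analysis:

    species -> sex -> individual (nested in species x sex) -> side
    (directional asymmetry) -> individual x side (fluctuating asymmetry)

For shape, sums of squares are summed Procrustes deviations over all 2k
coordinates and every univariate degree of freedom is multiplied by 2k - 4,
the dimension of the shape tangent space for k 2-D landmarks.  Goodall's F
ratios use the mixed-model error strata: species and sex are tested over
the individual mean square; individual and directional asymmetry over the
fluctuating-asymmetry mean square.  Pillai's trace is reported alongside
for the shape analysis, computed on the rank support of the relevant
hypothesis-plus-error cross-product matrix.

The fluctuating-asymmetry (individual x side) stratum is the terminal
error: with one digitization per valve it coincides with the residual, and
no measurement-error term is modelled.  Sequential fitting guarantees that
effect sums of squares add up exactly to the total sum of squares about the
grand mean, balanced design or not.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import ClassifierTable, ValidationError
from .superimpose import AlignedSample

EFFECT_ORDER = [
    "species",
    "sex",
    "individual",
    "directional_asymmetry",
    "fluctuating_asymmetry",
]

#: error stratum used in each Goodall's F ratio
ERROR_TERM = {
    "species": "individual",
    "sex": "individual",
    "individual": "fluctuating_asymmetry",
    "directional_asymmetry": "fluctuating_asymmetry",
}


def goodall_f(ss_effect: float, df_effect: int, ss_error: float, df_error: int):
    """Goodall's F statistic and its parametric upper-tail p-value.

    F = (SS_effect / df_effect) / (SS_error / df_error), referred to the
    F(df_effect, df_error) distribution.  Invariant to common rescaling of
    both sums of squares.
    """
    if df_effect <= 0 or df_error <= 0:
        raise ValueError("degrees of freedom must be positive")
    if ss_error <= 0:
        warnings.warn("zero error sum of squares; F is infinite", stacklevel=2)
        return math.inf, 0.0
    F = (ss_effect / df_effect) / (ss_error / df_error)
    p = float(stats.f.sf(F, df_effect, df_error))
    return float(F), p


def pillai_trace(
    effect_sscp: np.ndarray,
    error_sscp: np.ndarray,
    df_effect: int,
    df_error: int | None = None,
):
    """Pillai's trace PT = tr(H (H + E)^-1) and an F-approximation p-value.

    Near-singular shape cross-product matrices are handled by restricting
    the inverse to the rank support of H + E; the support dimension is the
    effective number of variables in the F approximation.  ``df_error``
    defaults to the rank of E (a conservative stand-in when the univariate
    error degrees of freedom are unknown).
    """
    H = np.asarray(effect_sscp, float)
    E = np.asarray(error_sscp, float)
    if df_effect <= 0:
        raise ValueError("df_effect must be positive")
    T = (H + E + (H + E).T) / 2
    evals, evecs = np.linalg.eigh(T)
    tol = max(float(evals[-1]), 0.0) * len(evals) * np.finfo(float).eps
    support = evals > tol
    p_eff = int(support.sum())
    if p_eff == 0:
        return 0.0, 1.0
    V = evecs[:, support]
    T_inv = V @ np.diag(1.0 / evals[support]) @ V.T
    PT = float(np.trace(H @ T_inv))
    s = min(p_eff, df_effect)
    PT = min(max(PT, 0.0), float(s))
    if df_error is None:
        df_error = int(
            (np.linalg.eigvalsh((E + E.T) / 2) > tol).sum()
        )
    m = (abs(df_effect - p_eff) - 1) / 2.0
    nn = (df_error - p_eff - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if PT >= s:
        return PT, 0.0
    if df1 <= 0 or df2 <= 0:
        return PT, float("nan")
    F = (df2 / df1) * PT / (s - PT)
    p = float(stats.f.sf(F, df1, df2))
    return PT, p


@dataclass
class EffectRow:
    """One row of the ANOVA table (SS, df, MS, Goodall's F, Pillai)."""

    effect: str
    SS: float
    df: int
    MS: float = float("nan")
    F: float | None = None
    p: float | None = None
    PT: float | None = None
    p_PT: float | None = None


class ProcrustesANOVAResults:
    """Fitted ANOVA table plus the estimated directional-asymmetry vector."""

    def __init__(self, effects, response, k, total_ss, da_vector, n_obs, flags):
        self.effects = effects
        self.response = response
        self.k = k
        self.total_ss = total_ss
        self.directional_asymmetry_vector = da_vector
        self.n_obs = n_obs
        self.flags = flags

    def __getitem__(self, name: str) -> EffectRow:
        for row in self.effects:
            if row.effect == name:
                return row
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "effect": r.effect,
                    "SS": r.SS,
                    "MS": r.MS,
                    "df": r.df,
                    "F": r.F,
                    "p": r.p,
                    "PT": r.PT,
                    "p_PT": r.p_PT,
                }
                for r in self.effects
            ]
        )

    @staticmethod
    def _fmt_p(p):
        if p is None or (isinstance(p, float) and math.isnan(p)):
            return ""
        return "< 0.0001" if p < 1e-4 else f"{p:.4f}"

    def summary(self) -> str:
        lines = [
            f"Procrustes ANOVA ({self.response}), n = {self.n_obs} valves, "
            f"k = {self.k} landmarks",
            f"{'Effect':<24}{'SS':>18}{'MS':>18}{'df':>8}{'F':>10}"
            f"{'p':>10}{'PT':>8}{'p(PT)':>10}",
        ]
        for r in self.effects:
            lines.append(
                f"{r.effect:<24}{r.SS:>18.8f}{r.MS:>18.10f}{r.df:>8d}"
                + format("" if r.F is None else f"{r.F:.2f}", ">10")
                + format(self._fmt_p(r.p), ">10")
                + format("" if r.PT is None else f"{r.PT:.2f}", ">8")
                + format(self._fmt_p(r.p_PT), ">10")
            )
        return "\n".join(lines)


class ProcrustesANOVA:
    """Mixed-design ANOVA of jointly superimposed left/right valves.

    Parameters
    ----------
    aligned : AlignedSample
        Joint GPA of all valves, left valves reflected beforehand.
    metadata : DataFrame
        One row per aligned shape, columns ``specimen_id, species, sex,
        side``, in the same order as ``aligned.shapes``.
    """

    def __init__(self, aligned: AlignedSample, metadata: pd.DataFrame):
        if len(metadata) != aligned.n:
            raise ValidationError("metadata rows must match aligned shapes")
        required = {"specimen_id", "species", "sex", "side"}
        missing = required - set(metadata.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        self.aligned = aligned
        self.metadata = metadata.reset_index(drop=True)

    @classmethod
    def from_dataset(cls, aligned: AlignedSample, dataset) -> "ProcrustesANOVA":
        return cls(aligned, dataset.metadata_frame())

    # -- internals ---------------------------------------------------------
    def _complete_pairs(self):
        meta = self.metadata
        counts = meta.groupby("specimen_id")["side"].nunique()
        complete = set(counts[counts == 2].index)
        dropped = sorted(set(meta["specimen_id"]) - complete)
        if dropped:
            warnings.warn(
                f"excluding {len(dropped)} one-sided individual(s) from the "
                "asymmetry ANOVA",
                stacklevel=3,
            )
        return meta["specimen_id"].isin(complete).to_numpy(), dropped

    @staticmethod
    def _dummies(labels) -> np.ndarray:
        return pd.get_dummies(pd.Series(labels).astype(str)).to_numpy(dtype=float)

    def fit(self, response: str = "shape") -> ProcrustesANOVAResults:
        if response not in ("shape", "size"):
            raise ValueError("response must be 'shape' or 'size'")
        keep, dropped = self._complete_pairs()
        meta = self.metadata.loc[keep].reset_index(drop=True)
        if meta.empty:
            raise ValidationError("no individuals with both valves present")
        flags = {"excluded_one_sided": dropped}
        per_species = (
            meta.drop_duplicates("specimen_id").groupby("species")["specimen_id"].count()
        )
        flags["single_individual_species"] = sorted(per_species[per_species == 1].index)
        if flags["single_individual_species"]:
            warnings.warn(
                f"{len(flags['single_individual_species'])} species have a "
                "single individual (zero individual-level df contribution)",
                stacklevel=2,
            )

        if response == "shape":
            Y = self.aligned.shapes[keep]
            mult = 2 * self.aligned.k - 4
        else:
            Y = self.aligned.centroid_sizes[keep].astype(float)[:, None]
            mult = 1

        n = Y.shape[0]
        blocks = [
            np.ones((n, 1)),
            self._dummies(meta["species"]),
            self._dummies(meta["sex"]),
            self._dummies(meta["specimen_id"]),
            self._dummies(meta["side"]),
        ]

        # cumulative least-squares fits of the growing design
        fitted, ranks = [], []
        X = np.empty((n, 0))
        for B in blocks:
            X = np.hstack([X, B])
            beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
            fitted.append(X @ beta)
            ranks.append(int(rank))

        rows: list[EffectRow] = []
        deltas = []
        for i, name in enumerate(EFFECT_ORDER[:4], start=1):
            delta = fitted[i] - fitted[i - 1]
            deltas.append(delta)
            ss_uni = float((delta**2).sum())
            df_uni = ranks[i] - ranks[i - 1]
            rows.append(EffectRow(effect=name, SS=ss_uni, df=df_uni * mult))
        resid = Y - fitted[-1]
        rows.append(
            EffectRow(
                effect="fluctuating_asymmetry",
                SS=float((resid**2).sum()),
                df=(n - ranks[-1]) * mult,
            )
        )
        for r in rows:
            r.MS = r.SS / r.df if r.df > 0 else float("nan")

        by_name = {r.effect: r for r in rows}
        for name in EFFECT_ORDER[:4]:
            row, err = by_name[name], by_name[ERROR_TERM[name]]
            if row.df > 0 and err.df > 0:
                row.F, row.p = goodall_f(row.SS, row.df, err.SS, err.df)

        da_vector = None
        if response == "shape":
            E_strata = {
                "individual": deltas[2].T @ deltas[2],
                "fluctuating_asymmetry": resid.T @ resid,
            }
            for name in EFFECT_ORDER[:4]:
                row = by_name[name]
                err = by_name[ERROR_TERM[name]]
                df_uni, derr_uni = row.df // mult, err.df // mult
                if df_uni > 0 and derr_uni > 0:
                    H = deltas[EFFECT_ORDER.index(name)].T @ deltas[
                        EFFECT_ORDER.index(name)
                    ]
                    row.PT, row.p_PT = pillai_trace(
                        H, E_strata[ERROR_TERM[name]], df_uni, df_error=derr_uni
                    )
            right = meta["side"].to_numpy() == "right"
            da_vector = Y[right].mean(axis=0) - Y[~right].mean(axis=0)

        grand_ss = float(((Y - Y.mean(axis=0)) ** 2).sum())
        return ProcrustesANOVAResults(
            effects=rows,
            response=response,
            k=self.aligned.k,
            total_ss=grand_ss,
            da_vector=da_vector,
            n_obs=n,
            flags=flags,
        )


def procrustes_anova(
    aligned: AlignedSample,
    classifier_or_metadata,
    response: str = "shape",
) -> ProcrustesANOVAResults:
    """Functional wrapper around :class:`ProcrustesANOVA`."""
    if isinstance(classifier_or_metadata, ClassifierTable):
        meta = []
        for sid, side in aligned.labels:
            row = classifier_or_metadata.lookup(sid)
            meta.append(
                {
                    "specimen_id": sid,
                    "species": row["species"],
                    "sex": row["sex"],
                    "side": side,
                }
            )
        metadata = pd.DataFrame(meta)
    else:
        metadata = classifier_or_metadata
    return ProcrustesANOVA(aligned, metadata).fit(response=response)
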
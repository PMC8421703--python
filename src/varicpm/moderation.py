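"""Simple-effects (moderation) analysis of recovery on neural variability.

Fits, by ordinary least squares,

    recovery = b0 + b1 * V + b2 * Ic + b3 * (V * Ic) + e

where ``V`` is the mean variability of the important nodes (left on its
natural scale, so slopes are per unit variability) and ``Ic`` is
interdependence mean-centered before forming the product.  The simple slope
of recovery on ``V`` at interdependence ``mean + c`` is ``b1 + b3*c``
exactly, with standard error from the coefficient covariance

    SE^2 = Var(b1) + c^2 Var(b3) + 2 c Cov(b1, b3),

evaluated at c = +SD (high interdependence) and c = -SD (low).  Two-sided
p-values use the t distribution with the residual degrees of freedom.  The
analysis runs on the full cohort and, when group labels are given, within
each depression group (centering and SD recomputed within the subset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = ["SimpleSlope", "SimpleEffectsResult", "simple_effects"]


@dataclass(frozen=True)
class SimpleSlope:
    at: str  # "high" (M + SD) or "low" (M - SD)
    slope: float
    se: float
    p: float


@dataclass
class SimpleEffectsResult:
    """Interaction-model coefficients and conditional slopes for one subset."""

    n: int
    params: np.ndarray  # b0, b1 (V), b2 (Ic), b3 (V*Ic)
    bse: np.ndarray
    cov_params: np.ndarray
    df_resid: int
    i_mean: float
    i_sd: float
    slope_high: SimpleSlope
    slope_low: SimpleSlope

    def slope_at(self, c: float) -> tuple[float, float, float]:
        """Slope of recovery on V at interdependence ``mean + c``: (b, SE, p)."""
        b = float(self.params[1] + self.params[3] * c)
        var = (
            self.cov_params[1, 1]
            + c * c * self.cov_params[3, 3]
            + 2 * c * self.cov_params[1, 3]
        )
        se = float(np.sqrt(var))
        t = b / se
        p = float(2 * stats.t.sf(abs(t), self.df_resid))
        return b, se, p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": ["intercept", "v_mean", "interdependence_c", "v_mean:interdependence_c"],
                "coef": self.params,
                "se": self.bse,
            }
        )


def _fit_subset(v: np.ndarray, i: np.ndarray, y: np.ndarray) -> SimpleEffectsResult:
    n = y.size
    if n < 5:
        raise ValueError(f"need at least 5 participants, got {n}")
    ic = i - i.mean()
    X = np.column_stack([np.ones(n), v, ic, v * ic])
    if np.linalg.matrix_rank(X) < 4:
        raise ValueError("collinear design; moderation model is not identifiable")
    fit = sm.OLS(y, X).fit()
    sd = float(i.std(ddof=1))
    res = SimpleEffectsResult(
        n=n,
        params=np.asarray(fit.params, float),
        bse=np.asarray(fit.bse, float),
        cov_params=np.asarray(fit.cov_params(), float),
        df_resid=int(fit.df_resid),
        i_mean=float(i.mean()),
        i_sd=sd,
        slope_high=SimpleSlope("high", 0, 0, 1),
        slope_low=SimpleSlope("low", 0, 0, 1),
    )
    res.slope_high = SimpleSlope("high", *res.slope_at(+sd))
    res.slope_low = SimpleSlope("low", *res.slope_at(-sd))
    return res


def simple_effects(
    v_mean: np.ndarray,
    interdependence: np.ndarray,
    recovery: np.ndarray,
    groups: Sequence[str] | None = None,
) -> dict[str, SimpleEffectsResult]:
    """Moderation analysis on all participants and per depression group.

    ``v_mean`` is each participant's mean variability over the important
    nodes.  Returns a dict keyed ``"all"`` plus one entry per group label
    (``"none"`` labels are skipped for the subgroup fits but kept in
    ``"all"``).
    """
    v = np.asarray(v_mean, dtype=float)
    i = np.asarray(interdependence, dtype=float)
    y = np.asarray(recovery, dtype=float)
    if not v.shape == i.shape == y.shape or v.ndim != 1:
        raise ValueError("v_mean, interdependence, recovery must be aligned vectors")
    out = {"all": _fit_subset(v, i, y)}
    if groups is not None:
        g = np.asarray(groups)
        if g.shape != v.shape:
            raise ValueError("groups must align with the participant vectors")
        for label in pd.unique(g):
            if label == "none":
                continue
            rows = g == label
            out[str(label)] = _fit_subset(v[rows], i[rows], y[rows])
    return out
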
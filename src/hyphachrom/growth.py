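"""Growth-curve fitting, rank-sum testing, and comparative ddCt.

The growth model is the three-parameter log-logistic response

    OD(t) = d / (1 + exp(b * (log t - log e)))

with plateau d, ED50 e (the time of half-maximal absorbance) and
relative slope b; negative b gives an increasing curve, matching the
drc sign convention.  Between-strain distance and count comparisons use
the unpaired two-sided Wilcoxon/Mann-Whitney rank-sum test; transcript
levels use the comparative ddCt method with relative level 2^(-ddCt).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin

from .simulate import log_logistic

__all__ = [
    "GrowthCurveFit",
    "RankSumResult",
    "DdctResult",
    "LogLogisticModel",
    "fit_log_logistic",
    "rank_sum_test",
    "ddct",
    "subtract_blank",
]


@dataclass
class GrowthCurveFit:
    b: float  # relative slope (negative = increasing curve)
    d: float  # plateau, OD units
    e: float  # ED50, h
    se_b: float
    se_d: float
    se_e: float
    resid_sd: float
    converged: bool
    monotone_warning: bool = False


class LogLogisticModel(BaseEstimator, RegressorMixin):
    """Least-squares three-parameter log-logistic growth fit.

    Multi-start Levenberg-Marquardt: d starts at the maximal OD, e at
    the time the curve first crosses half its maximum, and the slope is
    started from each value in ``b_starts``; the best residual sum of
    squares wins.  Standard errors come from the Jacobian at the
    optimum.

    Attributes after ``fit(t, od)``: ``b_``, ``d_``, ``e_``, ``se_b_``,
    ``se_d_``, ``se_e_``, ``resid_sd_``, ``converged_``.
    """

    def __init__(self, b_starts: tuple[float, ...] = (-1.0, -5.0, -10.0),
                 max_nfev: int = 10000):
        self.b_starts = b_starts
        self.max_nfev = max_nfev

    def fit(self, t, od=None):
        t = np.asarray(t, dtype=float).ravel()
        od = np.asarray(od, dtype=float).ravel()
        if t.size != od.size:
            raise ValueError("t and od must have equal length")
        if t.size < 6:
            raise ValueError("need at least 6 points")
        if np.any(t <= 0):
            raise ValueError("all times must be > 0")

        d0 = float(np.max(od))
        half = d0 / 2.0
        above = t[od >= half]
        e0 = float(above.min()) if above.size else float(np.median(t))
        e0 = max(e0, float(t.min()))

        best = None
        for b0 in self.b_starts:
            try:
                popt, pcov = optimize.curve_fit(
                    log_logistic, t, od, p0=(b0, d0, e0),
                    maxfev=self.max_nfev,
                    bounds=((-np.inf, 1e-12, 1e-12), (np.inf, np.inf, np.inf)),
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((od - log_logistic(t, *popt)) ** 2))
            if best is None or rss < best[0]:
                best = (rss, popt, pcov)
        if best is None:
            self.converged_ = False
            self.b_ = self.d_ = self.e_ = np.nan
            self.se_b_ = self.se_d_ = self.se_e_ = np.nan
            self.resid_sd_ = np.nan
            return self
        rss, popt, pcov = best
        dof = max(t.size - 3, 1)
        se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
        self.b_, self.d_, self.e_ = map(float, popt)
        self.se_b_, self.se_d_, self.se_e_ = map(float, se)
        self.resid_sd_ = float(np.sqrt(rss / dof))
        self.converged_ = True
        # a decreasing best fit (positive b) against growth data is suspect
        self.monotone_warning_ = self.b_ > 0
        return self

    def predict(self, t):
        return log_logistic(np.asarray(t, dtype=float), self.b_, self.d_, self.e_)

    def result(self) -> GrowthCurveFit:
        return GrowthCurveFit(
            b=self.b_, d=self.d_, e=self.e_,
            se_b=self.se_b_, se_d=self.se_d_, se_e=self.se_e_,
            resid_sd=self.resid_sd_, converged=self.converged_,
            monotone_warning=getattr(self, "monotone_warning_", False),
        )


def fit_log_logistic(t, od) -> GrowthCurveFit:
    """Fit OD(t) = d/(1+exp(b*(log t - log e))); see LogLogisticModel."""
    return LogLogisticModel().fit(t, od).result()


def subtract_blank(od_table: pd.DataFrame) -> pd.DataFrame:
    """Background preprocessing: subtract each replicate's first reading."""
    out = od_table.copy()
    for c in out.columns:
        if c != "time_h":
            out[c] = out[c] - out[c].iloc[0]
    return out


@dataclass
class RankSumResult:
    statistic: float
    p: float
    n1: int
    n2: int
    method: str


def rank_sum_test(x, y) -> RankSumResult:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test for two independent
    samples.  Mid-ranks handle ties; the exact null distribution is used
    when min(n1, n2) <= 8 and there are no ties, otherwise the normal
    approximation with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if min(x.size, y.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return RankSumResult(
        statistic=float(res.statistic), p=float(min(res.pvalue, 1.0)),
        n1=int(x.size), n2=int(y.size), method=method,
    )


@dataclass
class DdctResult:
    dct_sample: float
    dct_calibrator: float
    ddct: float
    relative_level: float


def ddct(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> DdctResult:
    """Comparative ddCt quantification against an endogenous control.

    ddCt = (Ct_target,sample - Ct_ref,sample)
         - (Ct_target,calibrator - Ct_ref,calibrator);
    relative expression level = 2^(-ddCt).
    """
    for v in (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    dct_s = ct_target_sample - ct_ref_sample
    dct_c = ct_target_calibrator - ct_ref_calibrator
    dd = dct_s - dct_c
    return DdctResult(dct_s, dct_c, dd, float(2.0 ** (-dd)))
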
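"""Robust regression statistics for trait-vs-position scaling relationships.

The central estimator is Theil-Sen: the slope is the median of all pairwise
slopes, the intercept the median of the residuals y - slope*x, and the 95%
confidence interval is read directly from the 2.5th/97.5th percentiles of
the pairwise-slope distribution.  Monotonic association is measured by
Kendall's tau-b.  Scaling exponents come from OLS on log10-transformed
data, and a single-breakpoint continuous piecewise (hinge) regression
captures a change of slope.  Residual diagnostics cover normality
(Lilliefors), homoscedasticity (Breusch-Pagan) and independence
(Durbin-Watson).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats as sps
from statsmodels.stats.diagnostic import het_breuschpagan
import statsmodels.api as sm


@dataclass(frozen=True)
class ScalingFit:
    method: str  # "theil_sen" or "ols_loglog"
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    kendall_tau: float
    tau_p_value: float
    n: int


@dataclass(frozen=True)
class PiecewiseFit:
    breakpoint: float
    left_slope: float
    right_slope: float
    left_intercept: float
    sse: float


@dataclass(frozen=True)
class ResidualDiagnostics:
    lilliefors_stat: float
    lilliefors_p: float
    breusch_pagan_stat: float
    breusch_pagan_p: float
    durbin_watson: float


def _as_xy(x: Sequence[float], y: Sequence[float], min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    return x, y


def pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """All slopes (y_j - y_i)/(x_j - x_i) over i < j, skipping pairs with equal x."""
    i, j = np.triu_indices(x.size, k=1)
    dx = x[j] - x[i]
    keep = dx != 0
    return (y[j] - y[i])[keep] / dx[keep]


def theil_sen(x: Sequence[float], y: Sequence[float]) -> ScalingFit:
    """Theil-Sen fit with the CI taken from the pairwise-slope distribution.

    Pairs with equal x contribute no slope; ties in y contribute slope 0.
    """
    x, y = _as_xy(x, y, 2)
    if np.all(x == x[0]):
        raise ValueError("all x identical: slope undefined")
    slopes = pairwise_slopes(x, y)
    slope = float(np.median(slopes))
    intercept = float(np.median(y - slope * x))
    ci_low, ci_high = (float(q) for q in np.percentile(slopes, [2.5, 97.5]))
    tau, p = kendall_tau(x, y)
    return ScalingFit("theil_sen", slope, intercept, ci_low, ci_high, tau, p, int(x.size))


def kendall_tau(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b with two-sided p value.

    The p value is exact (full enumeration over permutations) for n <= 10
    without ties, otherwise from the normal approximation.
    """
    x, y = _as_xy(x, y, 2)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("tau undefined for a constant vector")
    has_ties = np.unique(x).size < x.size or np.unique(y).size < y.size
    method = "exact" if (x.size <= 10 and not has_ties) else "asymptotic"
    res = sps.kendalltau(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def loglog_fit(x: Sequence[float], y: Sequence[float]) -> ScalingFit:
    """OLS of log10(y) on log10(x); the slope is the scaling exponent.

    The CI is the standard 95% t-interval on the OLS slope.
    """
    x, y = _as_xy(x, y, 3)
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("log-log fit requires strictly positive data")
    lx, ly = np.log10(x), np.log10(y)
    res = sps.linregress(lx, ly)
    tcrit = sps.t.ppf(0.975, x.size - 2)
    tau, p = kendall_tau(x, y)
    return ScalingFit(
        "ols_loglog",
        float(res.slope),
        float(res.intercept),
        float(res.slope - tcrit * res.stderr),
        float(res.slope + tcrit * res.stderr),
        tau,
        p,
        int(x.size),
    )


def _hinge_sse(x: np.ndarray, y: np.ndarray, c: float) -> tuple[float, np.ndarray]:
    """SSE of the continuous hinge fit y ~ b0 + b1*x + b2*(x-c)_+ at breakpoint c."""
    design = np.column_stack([np.ones_like(x), x, np.maximum(x - c, 0.0)])
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid), beta


def piecewise_fit(x: Sequence[float], y: Sequence[float]) -> PiecewiseFit:
    """Continuous two-segment linear regression with one breakpoint.

    Candidate breakpoints are the midpoints between consecutive distinct x
    values that leave >= 3 distinct x on each side; the grid minimiser is
    refined by golden-section search between its neighbouring candidates.
    Ties go to the smallest breakpoint.  On data with no slope change the
    fit degenerates gracefully: both slopes agree and the breakpoint sits
    at the first candidate.
    """
    x, y = _as_xy(x, y, 6)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    xu = np.unique(x)
    mids = (xu[:-1] + xu[1:]) / 2.0
    candidates = [c for c in mids if (xu < c).sum() >= 3 and (xu > c).sum() >= 3]
    if not candidates:
        raise ValueError("need >= 3 distinct x values on each side of a breakpoint")

    sses = np.array([_hinge_sse(x, y, c)[0] for c in candidates])
    best = int(np.argmin(sses))  # first minimum == smallest breakpoint on ties

    lo = candidates[best - 1] if best > 0 else candidates[best]
    hi = candidates[best + 1] if best < len(candidates) - 1 else candidates[best]
    if hi > lo:
        c_star = float(
            optimize.minimize_scalar(
                lambda c: _hinge_sse(x, y, c)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-10 * max(1.0, hi - lo)},
            ).x
        )
        # keep the refinement only if it actually improves on the grid point
        if _hinge_sse(x, y, c_star)[0] > sses[best]:
            c_star = float(candidates[best])
    else:
        c_star = float(candidates[best])

    sse, beta = _hinge_sse(x, y, c_star)
    return PiecewiseFit(
        breakpoint=c_star,
        left_slope=float(beta[1]),
        right_slope=float(beta[1] + beta[2]),
        left_intercept=float(beta[0]),
        sse=sse,
    )


def lilliefors_statistic(residuals: np.ndarray) -> float:
    """Kolmogorov-Smirnov distance to a normal with estimated mean and sd."""
    e = np.sort(np.asarray(residuals, dtype=float))
    n = e.size
    sd = e.std(ddof=1)
    if sd == 0:
        raise ValueError("residuals are constant; Lilliefors undefined")
    z = (e - e.mean()) / sd
    cdf = sps.norm.cdf(z)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo)))


def _lilliefors_mc_p(stat: float, n: int, n_sims: int, rng: np.random.Generator) -> float:
    # vectorised null simulation: rows of standard normals, standardised per row
    sims = rng.standard_normal((n_sims, n))
    sims.sort(axis=1)
    z = (sims - sims.mean(axis=1, keepdims=True)) / sims.std(axis=1, ddof=1, keepdims=True)
    cdf = sps.norm.cdf(z)
    hi = np.arange(1, n + 1) / n
    lo = np.arange(0, n) / n
    null_stats = np.maximum((hi - cdf).max(axis=1), (cdf - lo).max(axis=1))
    return float((np.sum(null_stats >= stat) + 1) / (n_sims + 1))


def residual_diagnostics(
    x: Sequence[float],
    residuals: Sequence[float],
    *,
    n_sims: int = 10_000,
    seed: int = 0,
) -> ResidualDiagnostics:
    """Normality, homoscedasticity and independence checks on fit residuals.

    Lilliefors p is Monte-Carlo (``n_sims`` seeded null replicates);
    Breusch-Pagan is the LM statistic against the single regressor x
    (chi-squared, 1 df); Durbin-Watson is sum(diff(e)^2)/sum(e^2) in the
    given residual order.
    """
    x, e = _as_xy(x, residuals, 5)
    if np.ptp(e) == 0:
        # constant residuals: no variance trend (BP = 0), normality undefined
        lf_stat = lf_p = float("nan")
        bp_stat, bp_p = 0.0, 1.0
    else:
        lf_stat = lilliefors_statistic(e)
        lf_p = _lilliefors_mc_p(lf_stat, e.size, n_sims, np.random.default_rng(seed))
        if np.ptp(e**2) == 0:  # e.g. alternating +1/-1: squared residuals constant
            bp_stat, bp_p = 0.0, 1.0
        else:
            exog = sm.add_constant(x)
            bp_stat, bp_p, _, _ = het_breuschpagan(e, exog)
    sum_sq = float(np.sum(e**2))
    dw = float(np.sum(np.diff(e) ** 2) / sum_sq) if sum_sq > 0 else float("nan")
    return ResidualDiagnostics(
        lilliefors_stat=lf_stat,
        lilliefors_p=lf_p,
        breusch_pagan_stat=float(bp_stat),
        breusch_pagan_p=float(bp_p),
        durbin_watson=dw,
    )
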
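"""Mean vessel length from pneumatic gas-conductivity trimming series.

Successively cutting a segment shorter opens more vessels to the vacuum
reservoir, so gas conductivity rises exponentially as the remaining length
x shrinks.  Writing C(x) = C0 * exp(lambda_v * x) with lambda_v < 0, the
vessel length distribution follows the density

    P(x) = x * lambda_v**2 * exp(lambda_v * x),

whose mean — the mean vessel length L_V — is -2/lambda_v.  lambda_v is
obtained as the ordinary least-squares slope of ln(conductivity) against x;
a raw nonlinear exponential fit is available behind a flag for comparison.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import optimize, stats

from .model import PneumatronSeries, VesselLengthFit

logger = logging.getLogger(__name__)

#: warn when the conductivity before any trimming exceeds this fraction of
#: the final (shortest-length) conductivity — a sign of many open vessels.
OPEN_VESSEL_WARN_FRACTION = 0.10


def mean_vessel_length(lambda_v: float) -> float:
    """Mean vessel length -2/lambda_v (m) from a fitted decay slope."""
    if lambda_v >= 0:
        raise ValueError(f"lambda_v must be negative, got {lambda_v}")
    return -2.0 / lambda_v


def vessel_length_pdf(x, lambda_v: float):
    """Vessel length probability density x * lambda_v**2 * exp(lambda_v * x).

    Normalised on [0, inf) for any lambda_v < 0; accepts scalar or array x.
    """
    if lambda_v >= 0:
        raise ValueError(f"lambda_v must be negative, got {lambda_v}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("vessel length x must be >= 0")
    out = x * lambda_v**2 * np.exp(lambda_v * x)
    return float(out) if out.ndim == 0 else out


def fit_lambda(
    series: PneumatronSeries,
    *,
    log_fit: bool = True,
    open_vessel_warn_fraction: float = OPEN_VESSEL_WARN_FRACTION,
) -> VesselLengthFit:
    """Fit the conductivity decay slope lambda_v of one trimming series.

    By default fits OLS of ln(gas_conductivity) on remaining length, the
    reading consistent with the exponential model; ``log_fit=False``
    instead fits C0*exp(lambda*x) directly by nonlinear least squares
    (initialised from the log fit).

    Raises if the fitted slope is non-negative — a series that does not
    decay with length carries no vessel-length signal.
    """
    x = np.asarray(series.remaining_length, dtype=float)
    c = np.asarray(series.gas_conductivity, dtype=float)

    # Conductivity at full length ~ open vessels reaching through the whole
    # segment; a large value relative to the fully trimmed end is suspect.
    if c[0] > open_vessel_warn_fraction * c[-1]:
        logger.warning(
            "%s: conductivity at maximum length is %.1f%% of the final trimmed "
            "value; many open vessels may bias the mean vessel length",
            series.segment_id,
            100.0 * c[0] / c[-1],
        )

    res = stats.linregress(x, np.log(c))
    lam = float(res.slope)
    r2 = float(res.rvalue**2)

    if not log_fit:
        def model(xv, c0, lamv):
            return c0 * np.exp(lamv * xv)

        popt, _ = optimize.curve_fit(
            model, x, c, p0=[float(np.exp(res.intercept)), lam], maxfev=10000
        )
        lam = float(popt[1])
        ss_res = float(np.sum((c - model(x, *popt)) ** 2))
        ss_tot = float(np.sum((c - c.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    if lam >= 0:
        raise ValueError(
            f"{series.segment_id}: non-decaying series (fitted lambda_v = {lam:.4g})"
        )
    return VesselLengthFit(
        segment_id=series.segment_id,
        lambda_v=lam,
        mean_vessel_length=mean_vessel_length(lam),
        r_squared=r2,
        n_points=x.size,
    )
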
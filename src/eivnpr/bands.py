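"""Tube-formula simultaneous confidence bands and the DE-calling rule.

The band around the fitted curve is

    g_hat(x) +/- c * sigma_hat(x) * ||l(x)||,

where l(x) are the equivalent-kernel weights and the critical value c
solves the volume-of-tubes equation

    (kappa0 / pi) exp(-c^2 / 2) + 2 (1 - Phi(c)) = alpha,

with kappa0 the length of the normalized weight path,
kappa0 = int ||d/dx (l(x)/||l(x)||)|| dx, over the fitting interval.
At kappa0 = 0 the equation reduces to the pointwise normal quantile.

A miRNA is called differentially expressed only when its observed point
falls strictly outside the band AND its expression clears the basal
reference level (by default, mean log background + 2 SD of the control
array), which guards against noise-driven calls among weakly expressed
miRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .concordance import Trend
from .exceptions import DataError, NumericalError
from .regression import EIVDataset, EIVFit

__all__ = [
    "ConfidenceBand",
    "DECall",
    "tube_kappa0",
    "critical_value",
    "build_band",
    "detect",
]


@dataclass
class ConfidenceBand:
    """Simultaneous band for the curve, plus the detection-region inputs.

    ``lower``/``upper`` bound the regression curve itself (half width
    c * sigma(x) * ||l(x)||).  ``sigma_fn`` and ``l_norm``, when present,
    let :func:`detect` widen the region to observation scale,
    c * sigma(x) * sqrt(1 + ||l(x)||^2): an individual observation scatters
    around the curve with SD sigma(x) on top of the curve-estimate
    uncertainty, so comparing single points against the curve band alone
    would flag a large share of perfectly null miRNAs.
    """

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    c_crit: float
    sigma_fn: np.ndarray | None = None
    l_norm: np.ndarray | None = None


@dataclass(frozen=True)
class DECall:
    mirna_id: str
    W: float
    Y: float
    outside_band: bool
    basal_ok: bool
    call: Trend


def tube_kappa0(fit: EIVFit) -> float:
    """Tube-formula constant: arc length of the normalized weight path.

    T(x) = l(x)/||l(x)||; kappa0 = int ||T'(x)|| dx by centered finite
    differences and trapezoid integration on the fit grid.
    """
    if fit.grid.size < 16:
        raise DataError("grid too coarse for the tube constant (need >= 16 points)")
    T = fit.weights / fit.l_norm[:, None]
    dT = np.gradient(T, fit.grid, axis=0)
    speed = np.sqrt(np.sum(dT * dT, axis=1))
    kappa0 = float(np.trapezoid(speed, fit.grid))
    fit.kappa0 = kappa0
    return kappa0


def critical_value(alpha_sig: float, kappa0: float) -> float:
    """Solve the tube equation for the simultaneous critical value c.

    Bisection on [0, 10] to 1e-6.  With kappa0 = 0 this returns the
    two-sided pointwise normal quantile.
    """
    if not 0.0 < alpha_sig < 1.0:
        raise DataError("alpha_sig must lie in (0, 1)")
    if kappa0 < 0:
        raise DataError("kappa0 must be non-negative")

    def f(c: float) -> float:
        return kappa0 / np.pi * np.exp(-0.5 * c * c) + 2.0 * norm.sf(c) - alpha_sig

    lo, hi = 0.0, 10.0
    if f(hi) > 0:
        raise NumericalError("no root of the tube equation in [0, 10]")
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_band(fit: EIVFit, alpha_sig: float = 0.05) -> ConfidenceBand:
    """Simultaneous confidence band at level 1 - alpha_sig."""
    if fit.sigma_fn is None:
        raise DataError("fit has no variance function; run a variance estimator first")
    kappa0 = fit.kappa0 if fit.kappa0 is not None else tube_kappa0(fit)
    c = critical_value(alpha_sig, kappa0)
    half = c * fit.sigma_fn * fit.l_norm
    return ConfidenceBand(
        grid=fit.grid,
        lower=fit.g_hat - half,
        upper=fit.g_hat + half,
        level=1.0 - alpha_sig,
        c_crit=c,
        sigma_fn=fit.sigma_fn,
        l_norm=fit.l_norm,
    )


def detect(
    data: EIVDataset,
    band: ConfidenceBand,
    basal_threshold: float,
) -> list[DECall]:
    """Classify each miRNA by band exclusion plus basal-level screen.

    When the band carries its variance ingredients the exclusion region is
    widened to observation scale (half width c * sigma * sqrt(1 + ||l||^2));
    otherwise the band edges themselves are used.  A point exactly on the
    boundary counts as inside.  Points whose W falls outside the band grid
    use the nearest endpoint (with a warning).  The call is UP/DOWN only
    when the point lies outside the region and max(W, Y) clears the basal
    threshold; otherwise ND.
    """
    ids = data.mirna_ids or [f"obs-{i}" for i in range(data.n)]
    if np.any(data.W < band.grid[0]) or np.any(data.W > band.grid[-1]):
        warnings.warn("some W values fall outside the band grid; using the "
                      "nearest band endpoint")
    lower = np.interp(data.W, band.grid, band.lower)
    upper = np.interp(data.W, band.grid, band.upper)
    if band.sigma_fn is not None and band.l_norm is not None:
        mid = 0.5 * (lower + upper)
        sig = np.interp(data.W, band.grid, band.sigma_fn)
        ln = np.interp(data.W, band.grid, band.l_norm)
        half = band.c_crit * sig * np.sqrt(1.0 + ln * ln)
        lower = mid - half
        upper = mid + half
    calls = []
    for i in range(data.n):
        above = data.Y[i] > upper[i]
        below = data.Y[i] < lower[i]
        outside = bool(above or below)
        basal_ok = bool(max(data.W[i], data.Y[i]) >= basal_threshold)
        if outside and basal_ok:
            call = Trend.UP if above else Trend.DOWN
        else:
            call = Trend.ND
        calls.append(
            DECall(mirna_id=ids[i], W=float(data.W[i]), Y=float(data.Y[i]),
                   outside_band=outside, basal_ok=basal_ok, call=call)
        )
    return calls
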
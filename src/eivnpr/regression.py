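"""Local-linear errors-in-variables regression with adaptive bandwidths.

The regression model is Y_i = g(X_i) + error, observed through W_i = X_i +
U_i with heteroscedastic normal measurement error U_i ~ N(0, sigma_{U,i}^2).
The local-linear deconvolution estimator is

    g_hat(x) = (S2 T0 - S1 T1) / (S2 S0 - S1^2),

    S_k(x) = (1/n) sum_j h_j^{-1} K_{U,k}((x - W_j)/h_j),
    T_k(x) = (1/n) sum_j Y_j h_j^{-1} K_{U,k}((x - W_j)/h_j),

built from the deconvolution kernels of :mod:`eivnpr.kernels`.  The
estimator is linear in Y: g_hat(x) = sum_j l_j(x) Y_j, and the equivalent
weights l(x) and their Euclidean norms are recorded because they drive the
simultaneous confidence bands.

Bandwidths are adaptive in the spirit of the classical variable-bandwidth
kernel estimator: a pilot deconvolution density estimate f~ of the
predictor is formed, local factors lambda_i = (f~(W_i)/g)^(-alpha) with g
the geometric mean rescale a global parameter h0 into per-observation
bandwidths h_i = h0 * lambda_i (the bandwidth travels with the observation,
not the evaluation point).  (h0, alpha) are chosen by exact leave-one-out
cross-validation.

Implementation note: all kernel sums are computed through a Fourier-side
change of variables u = t/h_j which makes the oscillatory factor
cos(u (x - W_j)) separable in x and W; each weight matrix then reduces to
two dense matrix products instead of per-pair quadratures.  On a common
quadrature grid this is algebraically identical to evaluating
``deconv_kernel`` pairwise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, NumericalError
from .kernels import DEFAULT_SPEC, KernelSpec, _half_range_nodes
from .array_data import MiRNASummary

__all__ = [
    "EIVDataset",
    "BandwidthPlan",
    "EIVFit",
    "pilot_density",
    "bandwidth_factors",
    "make_plan",
    "fit",
    "predict",
    "cv_score",
    "select_bandwidth",
    "dataset_from_summaries",
    "dataset_from_replicate_summaries",
]

_MIN_N = 10


@dataclass
class EIVDataset:
    """Observed (W, Y) pairs with per-point measurement-error SDs on W."""

    W: np.ndarray
    Y: np.ndarray
    sigma_u: np.ndarray
    mirna_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        self.sigma_u = np.asarray(self.sigma_u, dtype=float)
        if not (self.W.shape == self.Y.shape == self.sigma_u.shape):
            raise DataError("W, Y, sigma_u must have equal lengths")
        if np.any(self.sigma_u < 0):
            raise DataError("sigma_u must be non-negative")

    @property
    def n(self) -> int:
        return self.W.size

    def require_fittable(self) -> None:
        if self.n < _MIN_N:
            raise DataError(f"need at least {_MIN_N} observations, got {self.n}")


@dataclass
class BandwidthPlan:
    """Global smoothing parameter, sensitivity exponent, and local factors."""

    h0: float
    alpha_sens: float
    lam: np.ndarray

    def __post_init__(self) -> None:
        if self.h0 <= 0:
            raise DataError("h0 must be positive")
        if not 0.0 <= self.alpha_sens <= 1.0:
            raise DataError("alpha_sens must lie in [0, 1]")
        self.lam = np.asarray(self.lam, dtype=float)
        if np.any(self.lam <= 0):
            raise DataError("bandwidth factors must be positive")

    @property
    def h(self) -> np.ndarray:
        """Per-observation bandwidths h_i = h0 * lambda_i."""
        return self.h0 * self.lam


@dataclass
class EIVFit:
    """Fitted curve, equivalent-kernel weights and band ingredients."""

    grid: np.ndarray
    g_hat: np.ndarray
    l_norm: np.ndarray
    weights: np.ndarray            # (grid, n) equivalent weights l_j(x)
    bandwidth_plan: BandwidthPlan
    sigma_fn: np.ndarray | None = None   # residual SD on grid
    kappa0: float | None = None
    n_fallback: int = 0


def _kernel_sum_matrices(
    x: np.ndarray,
    W: np.ndarray,
    h: np.ndarray,
    sigma_u: np.ndarray,
    spec: KernelSpec = DEFAULT_SPEC,
):
    """Matrices s_k[i, j] = h_j^{k-1} K_{U,k}((x_i - W_j)/h_j), k = 0, 1, 2.

    The h_j^k rescaling expresses the order-k local-polynomial design in
    the original units of W: in the error-free limit
    s_k[i, j] -> (x_i - W_j)^k K((x_i - W_j)/h_j) / h_j, so observations
    with different local bandwidths enter one consistent weighted
    least-squares system.  (With a constant bandwidth the h^k factors cancel
    from the local-linear ratio, so this matches the unscaled convention.)

    Uses the substitution u = t/h_j so that one fixed quadrature rule runs
    on a common frequency interval [0, 1/min(h_j)] for all observations and
    the oscillatory factors separate into products of trigonometric
    matrices.
    """
    x = np.asarray(x, dtype=float)
    W = np.asarray(W, dtype=float)
    h = np.broadcast_to(np.asarray(h, dtype=float), W.shape)
    u_max = 1.0 / float(np.min(h))
    u, w = _half_range_nodes(spec, u_max)
    phibar = np.exp(-0.5 * np.square(sigma_u[:, None] * u[None, :])).mean(axis=0)
    with np.errstate(over="ignore", divide="ignore"):
        inv = 1.0 / phibar
    if np.any(inv > spec.inv_cf_cap):
        warnings.warn(
            "1/phi_bar_U capped during fit; bandwidth may be too small for "
            "the measurement-error level"
        )
        inv = np.minimum(inv, spec.inv_cf_cap)
    th = np.outer(h, u)                       # (n, m): t = u * h_j
    wi = (w * inv)[None, :] / np.pi
    hcol = np.asarray(h, dtype=float)[:, None]
    B0 = spec.psi(0, th) * wi                 # (n, m); psi vanishes where t > 1
    B1 = spec.psi(1, th) * wi * hcol
    B2 = spec.psi(2, th) * wi * (hcol * hcol)
    uW = np.outer(W, u)
    CW, SW = np.cos(uW), np.sin(uW)
    ux = np.outer(x, u)
    Cx, Sx = np.cos(ux), np.sin(ux)
    s0 = Cx @ (B0 * CW).T + Sx @ (B0 * SW).T
    s1 = Sx @ (B1 * CW).T - Cx @ (B1 * SW).T
    s2 = Cx @ (B2 * CW).T + Sx @ (B2 * SW).T
    if not (np.all(np.isfinite(s0)) and np.all(np.isfinite(s1))
            and np.all(np.isfinite(s2))):
        raise NumericalError("kernel sums overflowed; increase the bandwidth")
    return s0, s1, s2


def _linear_smoother(
    x: np.ndarray,
    W: np.ndarray,
    Y: np.ndarray,
    h: np.ndarray,
    sigma_u: np.ndarray,
    spec: KernelSpec = DEFAULT_SPEC,
):
    """Local-linear deconvolution fit at points ``x``.

    Returns (g_hat, L, n_fallback) where L is the equivalent-weight matrix.
    Grid points where the local-linear denominator is degenerate fall back
    to the local-constant estimate T0/S0.
    """
    n = W.size
    s0, s1, s2 = _kernel_sum_matrices(x, W, h, sigma_u, spec)
    S0 = s0.mean(axis=1)
    S1 = s1.mean(axis=1)
    S2 = s2.mean(axis=1)
    den = S0 * S2 - S1 * S1
    scale = np.abs(S0 * S2)
    # regularize only near-degenerate points: a blanket ridge would perturb
    # the exact local-linear algebra everywhere else
    weak_den = np.abs(den) <= 1e-10 * scale
    den_r = np.where(weak_den, den + 1e-10 * scale * np.sign(den + (den == 0)),
                     den)
    bad = np.abs(den_r) <= 1e-12 * (scale + np.abs(S1 * S1)) + 1e-300
    L = np.empty_like(s0)
    good = ~bad
    L[good] = (S2[good, None] * s0[good] - S1[good, None] * s1[good]) / (
        n * den_r[good, None]
    )
    n_fallback = int(bad.sum())
    if n_fallback:
        warnings.warn(
            f"local-linear system degenerate at {n_fallback} point(s); "
            "falling back to local-constant estimate"
        )
        s0_bad = s0[bad]
        S0_bad = S0[bad]
        safe = np.where(np.abs(S0_bad) > 1e-300, S0_bad, np.nan)
        L[bad] = s0_bad / (n * safe[:, None])
    g_hat = L @ Y
    return g_hat, L, n_fallback


def pilot_density(
    data: EIVDataset,
    h_pilot: float,
    spec: KernelSpec = DEFAULT_SPEC,
    floor: float = 1e-10,
) -> np.ndarray:
    """Deconvolution kernel density estimate of the predictor at each W_i.

    f~(W_i) = (1/(n h)) sum_j K_{U,0}((W_i - W_j)/h), floored at a small
    positive constant (deconvolution estimates can dip below zero).
    """
    if h_pilot <= 0:
        raise NumericalError("pilot bandwidth must be positive")
    h = np.full(data.n, float(h_pilot))
    s0, _, _ = _kernel_sum_matrices(data.W, data.W, h, data.sigma_u, spec)
    return np.maximum(s0.mean(axis=1), floor)


def bandwidth_factors(f_tilde: np.ndarray, alpha_sens: float) -> np.ndarray:
    """Local bandwidth factors lambda_i = (f~(W_i)/g)^(-alpha).

    g is the geometric mean of the pilot density values, so the factors have
    geometric mean one and alpha = 0 recovers a fixed bandwidth.
    """
    f_tilde = np.asarray(f_tilde, dtype=float)
    if np.any(f_tilde <= 0):
        raise DataError("pilot density values must be positive")
    if not 0.0 <= alpha_sens <= 1.0:
        raise DataError("alpha_sens must lie in [0, 1]")
    g = np.exp(np.mean(np.log(f_tilde)))
    return (f_tilde / g) ** (-alpha_sens)


def make_plan(
    data: EIVDataset,
    h0: float,
    alpha_sens: float,
    spec: KernelSpec = DEFAULT_SPEC,
) -> BandwidthPlan:
    """Build the adaptive bandwidth plan for given (h0, alpha)."""
    if alpha_sens == 0.0:
        lam = np.ones(data.n)
    else:
        lam = bandwidth_factors(pilot_density(data, h0, spec), alpha_sens)
    return BandwidthPlan(h0=h0, alpha_sens=alpha_sens, lam=lam)


def fit(
    data: EIVDataset,
    plan: BandwidthPlan,
    spec: KernelSpec = DEFAULT_SPEC,
    grid_size: int = 256,
) -> EIVFit:
    """Fit the local-linear deconvolution estimator on an equally spaced grid
    spanning [min W, max W]."""
    data.require_fittable()
    grid = np.linspace(data.W.min(), data.W.max(), grid_size)
    g_hat, L, n_fb = _linear_smoother(grid, data.W, data.Y, plan.h,
                                      data.sigma_u, spec)
    l_norm = np.sqrt(np.sum(L * L, axis=1))
    return EIVFit(grid=grid, g_hat=g_hat, l_norm=l_norm, weights=L,
                  bandwidth_plan=plan, n_fallback=n_fb)


def predict(
    data: EIVDataset,
    plan: BandwidthPlan,
    x,
    spec: KernelSpec = DEFAULT_SPEC,
) -> np.ndarray:
    """Evaluate the fitted curve at arbitrary points."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    g, _, _ = _linear_smoother(x, data.W, data.Y, plan.h, data.sigma_u, spec)
    return g


def cv_score(
    data: EIVDataset,
    h0: float,
    alpha_sens: float,
    spec: KernelSpec = DEFAULT_SPEC,
) -> float:
    """Exact leave-one-out cross-validation score for (h0, alpha).

    CV = sum_i (Y_i - g_hat_{-i}(W_i))^2, where the leave-one-out fit
    removes observation i from the kernel sums while keeping the bandwidth
    plan (computed on the full data) fixed.  Degenerate leave-one-out
    systems are skipped with a warning.
    """
    data.require_fittable()
    plan = make_plan(data, h0, alpha_sens, spec)
    W, Y = data.W, data.Y
    s0, s1, s2 = _kernel_sum_matrices(W, W, plan.h, data.sigma_u, spec)
    d0, d1, d2 = np.diag(s0).copy(), np.diag(s1).copy(), np.diag(s2).copy()
    S0 = s0.sum(axis=1) - d0
    S1 = s1.sum(axis=1) - d1
    S2 = s2.sum(axis=1) - d2
    T0 = s0 @ Y - d0 * Y
    T1 = s1 @ Y - d1 * Y
    den = S0 * S2 - S1 * S1
    scale = np.abs(S0 * S2) + np.abs(S1 * S1)
    ok = np.abs(den) > 1e-12 * (scale + 1e-300)
    n_skipped = int((~ok).sum())
    if n_skipped:
        warnings.warn(
            f"leave-one-out fit degenerate at {n_skipped} observation(s); "
            "those terms were skipped"
        )
    g_loo = (S2[ok] * T0[ok] - S1[ok] * T1[ok]) / den[ok]
    resid = Y[ok] - g_loo
    return float(np.sum(resid * resid))


def _default_h0_grid(data: EIVDataset, size: int = 10) -> np.ndarray:
    """Log-spaced global bandwidths around the normal-reference rule for W."""
    sd = float(np.std(data.W, ddof=1))
    iqr = float(np.subtract(*np.percentile(data.W, [75, 25])))
    spread = min(sd, iqr / 1.349) if iqr > 0 else sd
    h_ref = 1.06 * spread * data.n ** (-1 / 5)
    return np.geomspace(h_ref / 3.0, 3.0 * h_ref, size)


DEFAULT_ALPHA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def select_bandwidth(
    data: EIVDataset,
    h0_grid=None,
    alpha_grid=DEFAULT_ALPHA_GRID,
    spec: KernelSpec = DEFAULT_SPEC,
) -> BandwidthPlan:
    """Grid search of (h0, alpha) minimizing the leave-one-out CV score.

    Ties are broken toward the larger (smoother) h0.
    """
    if h0_grid is None:
        h0_grid = _default_h0_grid(data)
    h0_grid = np.asarray(h0_grid, dtype=float)
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if h0_grid.size == 0 or alpha_grid.size == 0:
        raise DataError("bandwidth grids must be non-empty")
    best = None
    for h0 in h0_grid:
        for alpha in alpha_grid:
            try:
                score = cv_score(data, float(h0), float(alpha), spec)
            except NumericalError:
                continue
            if (best is None or score < best[0]
                    or (score == best[0] and h0 > best[1])):
                best = (score, float(h0), float(alpha))
    if best is None:
        raise NumericalError("all bandwidth grid points were degenerate")
    return make_plan(data, best[1], best[2], spec)


def dataset_from_summaries(
    control: list[MiRNASummary],
    treated: list[MiRNASummary],
) -> EIVDataset:
    """Join per-miRNA summaries of a control/treated pair into a dataset.

    W and sigma_u come from the control side, Y from the treated side; the
    treated-side measurement error is absorbed into the regression residual.
    Only miRNAs present on both sides enter.
    """
    ctrl = {s.mirna_id: s for s in control}
    ids = sorted(ctrl.keys() & {s.mirna_id for s in treated})
    trt = {s.mirna_id: s for s in treated}
    if not ids:
        raise DataError("no miRNA is usable on both the control and treated side")
    return EIVDataset(
        W=np.array([ctrl[i].mean_log for i in ids]),
        Y=np.array([trt[i].mean_log for i in ids]),
        sigma_u=np.array([ctrl[i].se_log for i in ids]),
        mirna_ids=list(ids),
    )


def dataset_from_replicate_summaries(
    control_lists: list[list[MiRNASummary]],
    treated_lists: list[list[MiRNASummary]],
    min_arrays: int = 2,
) -> EIVDataset:
    """Pool replicate arrays: across-array means and standard errors.

    For each miRNA observed on at least ``min_arrays`` arrays per condition,
    W (control) and Y (treated) are the across-array means of the per-array
    mean log intensities and sigma_u is the standard error across control
    arrays.
    """

    def collect(lists):
        vals: dict[str, list[float]] = {}
        for lst in lists:
            for s in lst:
                vals.setdefault(s.mirna_id, []).append(s.mean_log)
        return vals

    cvals = collect(control_lists)
    tvals = collect(treated_lists)
    ids = sorted(
        i for i in cvals.keys() & tvals.keys()
        if len(cvals[i]) >= min_arrays and len(tvals[i]) >= min_arrays
    )
    if not ids:
        raise DataError("no miRNA has enough replicate arrays on both sides")
    W, Y, su = [], [], []
    for i in ids:
        c = np.array(cvals[i])
        t = np.array(tvals[i])
        W.append(c.mean())
        Y.append(t.mean())
        su.append(c.std(ddof=1) / math.sqrt(c.size))
    return EIVDataset(W=np.array(W), Y=np.array(Y), sigma_u=np.array(su),
                      mirna_ids=list(ids))
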
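"""Array normalization: normalizer-probe ML fitting plus benchmarks.

``normalize_by_normalizers`` estimates one log-scale offset per array from
the designated stably-expressed normalizer probes (snoRNA/U6 controls) with
a two-way additive maximum-likelihood fit, iteratively discarding
normalizers whose residual dispersion is significantly larger than the
rest.  The benchmark methods — global median scaling, quantile
normalization, and MA-plot LOESS with or without median preservation —
operate on net intensities and mirror the conventions of the established
microarray packages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .array_data import ArrayProfile, Flag, ProbeRecord
from .exceptions import DataError

__all__ = [
    "NormalizerModel",
    "normalize_by_normalizers",
    "normalize_median",
    "normalize_quantile",
    "normalize_loess",
    "normalize_loess_m",
]


@dataclass
class NormalizerModel:
    """Fitted per-array offsets and per-normalizer baselines."""

    offsets: dict            # array_id -> delta_a (log scale), sum zero
    baselines: dict          # normalizer_id -> beta_j (log scale)
    kept: list
    dropped: dict            # normalizer_id -> reason
    n_iter: int


def _scale_profile(profile: ArrayProfile, factor) -> ArrayProfile:
    """Return a profile whose net intensities are multiplied by ``factor``.

    ``factor`` may be a scalar or a per-record sequence; backgrounds are
    untouched, signals are reconstructed as background + scaled net.
    """
    factors = np.broadcast_to(np.asarray(factor, dtype=float),
                              (len(profile.records),))
    records = [
        replace(r, signal=max(r.background + r.net * f, 0.0))
        for r, f in zip(profile.records, factors)
    ]
    return ArrayProfile(
        array_id=profile.array_id,
        condition=profile.condition,
        treatment=profile.treatment,
        records=records,
        log_bg_mean=profile.log_bg_mean,
        log_bg_sd=profile.log_bg_sd,
    )


def _additive_fit(values: dict, arrays: list, normalizers: list,
                  tol: float = 1e-12, max_sweeps: int = 500):
    """ML fit of v_ja = beta_j + delta_a by alternating means (sum delta = 0).

    ``values`` maps (normalizer_id, array_id) -> mean log intensity; missing
    cells are allowed (unbalanced designs converge through the sweeps).
    """
    beta = {j: 0.0 for j in normalizers}
    delta = {a: 0.0 for a in arrays}
    for _ in range(max_sweeps):
        change = 0.0
        for a in arrays:
            obs = [values[(j, a)] - beta[j] for j in normalizers if (j, a) in values]
            new = float(np.mean(obs)) if obs else 0.0
            change = max(change, abs(new - delta[a]))
            delta[a] = new
        for j in normalizers:
            obs = [values[(j, a)] - delta[a] for a in arrays if (j, a) in values]
            new = float(np.mean(obs)) if obs else 0.0
            change = max(change, abs(new - beta[j]))
            beta[j] = new
        if change < tol:
            break
    # identifiability: centre the offsets, absorb the shift into baselines
    shift = float(np.mean(list(delta.values())))
    delta = {a: d - shift for a, d in delta.items()}
    beta = {j: b + shift for j, b in beta.items()}
    return beta, delta


def normalize_by_normalizers(
    profiles: list[ArrayProfile],
    normalizer_ids,
    sig_level: float = 0.05,
    min_normalizers: int = 3,
    max_iter: int = 10,
) -> tuple[NormalizerModel, list[ArrayProfile]]:
    """Estimate and remove per-array offsets from normalizer probes.

    Unflagged normalizer probes with positive net intensity provide one mean
    log value per (normalizer, array) cell; the two-way additive model
    v_ja = beta_j + delta_a is fitted by ML, each normalizer's residual
    variance is tested against the pooled others (F ratio, one drop per
    iteration, worst offender first) until no normalizer is significantly
    over-dispersed or only ``min_normalizers`` remain.  Each array's net
    intensities are then divided by exp(delta_a).
    """
    if len(profiles) < 2:
        raise DataError("need at least 2 arrays for normalizer normalization")
    normalizer_ids = list(normalizer_ids)
    arrays = [p.array_id for p in profiles]
    values: dict = {}
    for p in profiles:
        per_norm: dict = {}
        for r in p.records:
            if r.mirna_id in normalizer_ids and r.flag is Flag.OK and r.net > 0:
                per_norm.setdefault(r.mirna_id, []).append(math.log(r.net))
        for j, logs in per_norm.items():
            values[(j, p.array_id)] = float(np.mean(logs))
        if not per_norm:
            warnings.warn(
                f"array {p.array_id}: all normalizer probes flagged; its "
                "offset comes from the remaining structure"
            )
    usable = sorted({j for (j, _a) in values})
    if len(usable) < min_normalizers:
        raise DataError(
            f"only {len(usable)} usable normalizers (< {min_normalizers}); "
            "expand the search to include the spike-in probes"
        )
    dropped: dict = {}
    kept = list(usable)
    beta: dict = {}
    delta: dict = {}
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        beta, delta = _additive_fit(values, arrays, kept)
        if len(kept) <= min_normalizers:
            break
        # one-vs-rest residual variance test
        res: dict = {j: [] for j in kept}
        for (j, a), v in values.items():
            if j in res:
                res[j].append(v - beta[j] - delta[a])
        worst = None
        for j in kept:
            r_j = np.asarray(res[j])
            df_j = r_j.size - 1
            others = np.concatenate([np.asarray(res[k]) for k in kept if k != j])
            df_o = others.size - len(kept) + 1
            if df_j < 1 or df_o < 1:
                continue
            s_j = float(np.sum(r_j ** 2)) / df_j
            s_o = float(np.sum(others ** 2)) / df_o
            if s_o <= 0:
                continue
            p_val = float(stats.f.sf(s_j / s_o, df_j, df_o))
            if p_val < sig_level and (worst is None or p_val < worst[1]):
                worst = (j, p_val)
        if worst is None:
            break
        kept.remove(worst[0])
        dropped[worst[0]] = f"over-dispersed (p={worst[1]:.3g})"
        values = {k: v for k, v in values.items() if k[0] in kept}
    model = NormalizerModel(
        offsets={a: delta.get(a, 0.0) for a in arrays},
        baselines={j: beta[j] for j in kept},
        kept=kept,
        dropped=dropped,
        n_iter=n_iter,
    )
    normalized = [
        _scale_profile(p, math.exp(-model.offsets[p.array_id])) for p in profiles
    ]
    return model, normalized


def normalize_median(profiles: list[ArrayProfile]) -> list[ArrayProfile]:
    """Scale each array so its median net intensity equals the global median.

    The global median is the median of the per-array medians.
    """
    if not profiles:
        raise DataError("no profiles to normalize")
    medians = []
    for p in profiles:
        med = float(np.median([r.net for r in p.records]))
        if med == 0:
            raise DataError(f"array {p.array_id}: zero median net intensity")
        medians.append(med)
    global_med = float(np.median(medians))
    return [_scale_profile(p, global_med / m) for p, m in zip(profiles, medians)]


def normalize_quantile(profiles: list[ArrayProfile]) -> list[ArrayProfile]:
    """Force all arrays to share the across-array mean order statistics.

    Requires equal probe counts; ties receive the mean of the order
    statistics at their average rank.  Idempotent.
    """
    if not profiles:
        raise DataError("no profiles to normalize")
    counts = {len(p.records) for p in profiles}
    if len(counts) != 1:
        raise DataError("quantile normalization requires equal probe counts "
                        f"per array, got {sorted(counts)}")
    nets = np.array([[r.net for r in p.records] for p in profiles])
    n = nets.shape[1]
    mean_sorted = np.sort(nets, axis=1).mean(axis=0)
    out = []
    for p, row in zip(profiles, nets):
        ranks = stats.rankdata(row, method="average")
        new_net = np.interp(ranks, np.arange(1, n + 1), mean_sorted)
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = np.where(row != 0, new_net / row, 1.0)
        q = _scale_profile(p, factors)
        # zero-net probes cannot be scaled; set their nets explicitly
        recs = [
            r if orig != 0 else replace(r, signal=max(r.background + tgt, 0.0))
            for r, orig, tgt in zip(q.records, row, new_net)
        ]
        out.append(ArrayProfile(array_id=p.array_id, condition=p.condition,
                                treatment=p.treatment, records=recs,
                                log_bg_mean=p.log_bg_mean,
                                log_bg_sd=p.log_bg_sd))
    return out


def _ma_pair(a: ArrayProfile, b: ArrayProfile, min_shared: int = 20):
    """Shared positive-net probes of a pair, with their M and A values."""
    nets_a = {r.probe_id: r.net for r in a.records if r.net > 0}
    nets_b = {r.probe_id: r.net for r in b.records if r.net > 0}
    shared = sorted(nets_a.keys() & nets_b.keys())
    if len(shared) < min_shared:
        raise DataError(
            f"only {len(shared)} shared positive probes (< {min_shared})"
        )
    la = np.array([math.log(nets_a[p]) for p in shared])
    lb = np.array([math.log(nets_b[p]) for p in shared])
    return shared, la - lb, 0.5 * (la + lb)


def _apply_m_correction(pair, shared, correction) -> tuple[ArrayProfile, ArrayProfile]:
    """Split a log-ratio correction symmetrically between the two arrays."""
    corr = dict(zip(shared, correction))
    out = []
    for prof, sign in zip(pair, (-0.5, +0.5)):
        factors = [
            math.exp(sign * corr[r.probe_id]) if r.probe_id in corr else 1.0
            for r in prof.records
        ]
        out.append(_scale_profile(prof, factors))
    return out[0], out[1]


def normalize_loess(
    pair: tuple[ArrayProfile, ArrayProfile],
    span: float = 0.75,
) -> tuple[ArrayProfile, ArrayProfile]:
    """MA-plot LOESS normalization of a two-array pair.

    M (log ratio, first array over second) is regressed on A (mean log) by
    locally weighted linear regression (tricube weights, 3 robustness
    iterations) and the fit is subtracted from M.
    """
    shared, m, a = _ma_pair(*pair)
    fit_vals = lowess(m, a, frac=span, it=3, return_sorted=False)
    return _apply_m_correction(pair, shared, fit_vals)


def normalize_loess_m(
    pair: tuple[ArrayProfile, ArrayProfile],
    span: float = 0.75,
) -> tuple[ArrayProfile, ArrayProfile]:
    """LOESS-M: LOESS detrending that preserves the global median log-ratio.

    The intensity-dependent trend is removed as in LOESS, then the corrected
    log-ratios are shifted so that their median equals the original median M
    exactly.  (Subtracting ``fit - median(M)`` directly restores the median
    only approximately; the explicit re-centering makes the invariance
    exact.)
    """
    shared, m, a = _ma_pair(*pair)
    fit_vals = lowess(m, a, frac=span, it=3, return_sorted=False)
    resid = m - fit_vals
    correction = fit_vals + float(np.median(resid)) - float(np.median(m))
    return _apply_m_correction(pair, shared, correction)
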
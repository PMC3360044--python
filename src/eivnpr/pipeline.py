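"""High-level detection workflows tying the stages together.

Two workflows are supported: a single treated/control array pair (the
normalization step can be bypassed because the regression itself absorbs a
common shift into the curve), and replicate arrays per condition, where the
normalizer-probe ML normalization aligns arrays before per-miRNA pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bands as _bands
from . import regression as _reg
from . import variance as _var
from .array_data import (ArrayProfile, Condition, neighborhood_error_sd,
                         profile_qc, summarize)
from .exceptions import DataError
from .kernels import DEFAULT_SPEC, KernelSpec
from .normalization import NormalizerModel, normalize_by_normalizers

__all__ = ["DetectionResult", "run_detection"]


@dataclass
class DetectionResult:
    dataset: _reg.EIVDataset
    fit: _reg.EIVFit
    band: _bands.ConfidenceBand
    calls: list
    qc: list
    basal_threshold: float
    normalizer_model: NormalizerModel | None
    dropped_mirnas: dict

    def calls_frame(self) -> pd.DataFrame:
        lower = np.interp(self.dataset.W, self.band.grid, self.band.lower)
        upper = np.interp(self.dataset.W, self.band.grid, self.band.upper)
        if self.band.sigma_fn is not None and self.band.l_norm is not None:
            mid = 0.5 * (lower + upper)
            sig = np.interp(self.dataset.W, self.band.grid, self.band.sigma_fn)
            ln = np.interp(self.dataset.W, self.band.grid, self.band.l_norm)
            half = self.band.c_crit * sig * np.sqrt(1.0 + ln * ln)
            lower, upper = mid - half, mid + half
        return pd.DataFrame(
            {
                "mirna_id": [c.mirna_id for c in self.calls],
                "W": [c.W for c in self.calls],
                "Y": [c.Y for c in self.calls],
                "lower": lower,
                "upper": upper,
                "outside_band": [c.outside_band for c in self.calls],
                "basal_ok": [c.basal_ok for c in self.calls],
                "call": [c.call.value for c in self.calls],
            }
        )

    def band_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.band.grid,
                "g_hat": self.fit.g_hat,
                "lower": self.band.lower,
                "upper": self.band.upper,
            }
        )

    def qc_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "array_id": [q.array_id for q in self.qc],
                "pct_flagged": [q.pct_flagged for q in self.qc],
                "mean_snr": [q.mean_snr for q in self.qc],
                "max_snr": [q.max_snr for q in self.qc],
            }
        )


def run_detection(
    control_profiles: list[ArrayProfile],
    treated_profiles: list[ArrayProfile],
    keep_weak: bool = False,
    alpha_sig: float = 0.05,
    basal_multiplier: float = 2.0,
    normalize: str = "auto",
    normalizer_ids=None,
    variance_method: str = "simple",
    n_bag: int = 50,
    h0_grid=None,
    alpha_grid=_reg.DEFAULT_ALPHA_GRID,
    grid_size: int = 256,
    k_neighbors: int = 50,
    spec: KernelSpec = DEFAULT_SPEC,
    seed: int = 0,
) -> DetectionResult:
    """QC, optional normalization, summarization, EIV fit, band, DE calls.

    ``normalize`` is "none", "normalizers", or "auto" (normalizers when
    replicate arrays and normalizer ids are available, none otherwise).
    """
    if not control_profiles or not treated_profiles:
        raise DataError("need at least one control and one treated profile")
    qc = [profile_qc(p) for p in control_profiles + treated_profiles]
    model = None
    if normalize == "auto":
        normalize = (
            "normalizers"
            if normalizer_ids and len(control_profiles) + len(treated_profiles) > 2
            else "none"
        )
    if normalize == "normalizers":
        if not normalizer_ids:
            raise DataError("normalizer normalization requested but no "
                            "normalizer ids given")
        model, both = normalize_by_normalizers(
            control_profiles + treated_profiles, normalizer_ids
        )
        control_profiles = both[: len(control_profiles)]
        treated_profiles = both[len(control_profiles):]
    elif normalize != "none":
        raise DataError(f"unknown normalization mode {normalize!r}")

    dropped: dict = {}

    def summaries_of(profiles):
        out = []
        for p in profiles:
            s, d = summarize(p, keep_weak=keep_weak)
            dropped[p.array_id] = d
            out.append(s)
        return out

    ctrl_sums = summaries_of(control_profiles)
    trt_sums = summaries_of(treated_profiles)
    if len(control_profiles) > 1 and len(treated_profiles) > 1:
        data = _reg.dataset_from_replicate_summaries(ctrl_sums, trt_sums)
    else:
        ctrl = ctrl_sums[0]
        if len(ctrl) >= k_neighbors:
            ctrl = neighborhood_error_sd(ctrl, k_neighbors)
        data = _reg.dataset_from_summaries(ctrl, trt_sums[0])

    plan = _reg.select_bandwidth(data, h0_grid=h0_grid, alpha_grid=alpha_grid,
                                 spec=spec)
    fit = _reg.fit(data, plan, spec=spec, grid_size=grid_size)
    if variance_method == "simple":
        _var.variance_simple(data, fit, spec=spec)
    elif variance_method == "deconv":
        _var.variance_deconv(data, fit, n_bag=n_bag,
                             rng=np.random.default_rng(seed), spec=spec)
    else:
        raise DataError(f"unknown variance method {variance_method!r}")
    _bands.tube_kappa0(fit)
    band = _bands.build_band(fit, alpha_sig)
    ref = control_profiles[0]
    basal = ref.log_bg_mean + basal_multiplier * ref.log_bg_sd
    calls = _bands.detect(data, band, basal)
    return DetectionResult(
        dataset=data, fit=fit, band=band, calls=calls, qc=qc,
        basal_threshold=basal, normalizer_model=model, dropped_mirnas=dropped,
    )
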
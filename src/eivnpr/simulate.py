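"""Synthetic probe-level profiles from the two-component error model.

Each probe's net intensity is generated as

    y = mu * exp(eta) + eps,   eta ~ N(0, sigma_eta^2),  eps ~ N(0, sigma_eps^2)

so the measurement SD is proportional to the expression level at high
abundance (multiplicative component) while staying bounded away from zero
for unexpressed species (additive component).  On top of the net intensity
a background draw is added to form the reported signal, per-array
normalization offsets delta_a act multiplicatively (exp(delta_a)) on the
expressed component, and quality flags are assigned by the same rules the
image-processing software applies: contaminated spots (outliers), negative
net intensities, and signals within two background SDs of the background.

A designated set of miRNAs carries a log-scale differential-expression
shift on the treated side; the generator emits the matching truth table so
every downstream stage can be benchmarked against known classes.

Default concentrations mimic the profiled regime of LNA miRNA arrays: the
majority of miRNAs (75% of probes by default) sit at or below the
background level, the rest spread log-uniformly up to ``mu_max_fold`` times
the background.  The defaults are calibrated so that a simulated array
shows the QC profile such arrays typically report: well over half of the
probes flagged, mean signal-to-noise ratio below 10, and maximum SNR of
order 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .array_data import ArrayProfile, Condition, Flag, ProbeRecord
from .exceptions import DataError

__all__ = [
    "TwoComponentParams",
    "DEFAULT_NORMALIZERS",
    "simulate_pair",
    "simulate_replicates",
    "make_de_effect",
]

#: The 12 designated normalizer species carried on each array.
DEFAULT_NORMALIZERS = (
    "hsa_SNORD2", "hsa_SNORD3", "hsa_SNORD4A", "hsa_SNORD6",
    "hsa_SNORD10", "hsa_SNORD12", "hsa_SNORD13", "hsa_SNORD14B",
    "hsa_SNORD15A", "hsa_SNORD118", "U6-snRNA-1", "U6-snRNA-2",
)


@dataclass(frozen=True)
class TwoComponentParams:
    """Parameters of the two-component probe-intensity generator.

    ``mu_control`` and ``de_effect`` may be given explicitly (vectors of
    length ``n_mirna``); when left ``None`` the concentrations are drawn
    from the default weak/expressed mixture and no miRNA is differentially
    expressed.  ``array_offsets`` are log-scale per-array normalization
    offsets delta_a, in order controls first then treated arrays.
    """

    n_mirna: int = 560
    mu_control: tuple | None = None
    de_effect: tuple | None = None
    sigma_eta: float = 0.15
    sigma_eps: float = 20.0
    n_probes: int = 4
    background_mean: float = 100.0
    background_sd: float = 35.0
    weak_fraction: float = 0.75
    mu_min_fold: float = 0.02
    weak_max_fold: float = 1.0
    mu_max_fold: float = 20.0
    normalizer_ids: tuple = DEFAULT_NORMALIZERS
    normalizer_mu_fold: float = 30.0
    normalizer_sigma_eta: float = 0.05
    array_offsets: tuple | None = None
    outlier_fraction: float = 0.01
    flag_weak_k: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigma_eta", "sigma_eps", "background_sd",
                     "normalizer_sigma_eta"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        if self.mu_control is not None:
            mu = np.asarray(self.mu_control, dtype=float)
            if mu.size != self.n_mirna:
                raise DataError("mu_control length must equal n_mirna")
            if np.any(mu < 0):
                raise DataError("mu_control must be non-negative")
        if self.de_effect is not None:
            de = np.asarray(self.de_effect, dtype=float)
            if de.size != self.n_mirna:
                raise DataError("de_effect length must equal n_mirna")


def make_de_effect(
    n_mirna: int,
    n_up: int,
    n_down: int,
    log_fc: float = float(np.log(4.0)),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random assignment of up/down log-scale shifts to ``n_up + n_down`` miRNAs."""
    if n_up + n_down > n_mirna:
        raise DataError("more DE miRNAs requested than available")
    rng = rng or np.random.default_rng(0)
    de = np.zeros(n_mirna)
    idx = rng.choice(n_mirna, size=n_up + n_down, replace=False)
    de[idx[:n_up]] = log_fc
    de[idx[n_up:]] = -log_fc
    return de


def _resolve(params: TwoComponentParams, rng: np.random.Generator):
    """Materialize concentration and effect vectors (shared across arrays)."""
    bg = params.background_mean
    n = params.n_mirna
    ids = [f"mir-{i + 1:04d}" for i in range(n)]
    if params.mu_control is not None:
        mu = np.asarray(params.mu_control, dtype=float).copy()
    else:
        weak = rng.random(n) < params.weak_fraction
        lo, mid, hi = params.mu_min_fold * bg, params.weak_max_fold * bg, params.mu_max_fold * bg
        mu = np.where(
            weak,
            np.exp(rng.uniform(np.log(lo), np.log(mid), size=n)),
            np.exp(rng.uniform(np.log(mid), np.log(hi), size=n)),
        )
    de = (np.asarray(params.de_effect, dtype=float).copy()
          if params.de_effect is not None else np.zeros(n))
    sigma_eta = np.full(n, float(params.sigma_eta))
    # normalizers: extra stable, highly expressed, never differentially expressed
    ids += list(params.normalizer_ids)
    mu = np.concatenate([mu, np.full(len(params.normalizer_ids),
                                     params.normalizer_mu_fold * bg)])
    de = np.concatenate([de, np.zeros(len(params.normalizer_ids))])
    sigma_eta = np.concatenate(
        [sigma_eta, np.full(len(params.normalizer_ids), params.normalizer_sigma_eta)]
    )
    return ids, mu, de, sigma_eta


def _simulate_array(
    array_id: str,
    condition: Condition,
    ids,
    mu: np.ndarray,
    sigma_eta: np.ndarray,
    delta: float,
    params: TwoComponentParams,
    rng: np.random.Generator,
) -> ArrayProfile:
    n_entries = len(ids)
    R = params.n_probes
    eta = rng.normal(0.0, 1.0, size=(n_entries, R)) * sigma_eta[:, None]
    eps = rng.normal(0.0, params.sigma_eps, size=(n_entries, R))
    net = mu[:, None] * np.exp(delta + eta) + eps
    # background is a local-median statistic on real arrays; it fluctuates
    # but never approaches zero, so the draws are floored at half the mean
    bg = np.maximum(rng.normal(params.background_mean, params.background_sd,
                               size=(n_entries, R)), 0.5 * params.background_mean)
    signal = net + bg
    flags = np.full((n_entries, R), Flag.OK, dtype=object)
    if params.outlier_fraction > 0:
        out_mask = rng.random((n_entries, R)) < params.outlier_fraction
        signal = np.where(out_mask, signal * rng.uniform(0.2, 3.0,
                                                         size=(n_entries, R)), signal)
        flags[out_mask] = Flag.OUTLIER
    neg_mask = (signal <= bg) & (flags == Flag.OK)
    flags[neg_mask] = Flag.NEGATIVE
    # weak-signal rule, as the image software would apply it array-wide
    bg_sd = float(np.std(bg, ddof=1))
    weak_mask = (signal < bg + params.flag_weak_k * bg_sd) & (flags == Flag.OK)
    flags[weak_mask] = Flag.POOR
    signal = np.maximum(signal, 0.0)
    records = [
        ProbeRecord(
            probe_id=f"{ids[i]}_p{r + 1}",
            mirna_id=ids[i],
            signal=float(signal[i, r]),
            background=float(bg[i, r]),
            flag=flags[i, r],
        )
        for i in range(n_entries)
        for r in range(R)
    ]
    return ArrayProfile(array_id=array_id, condition=condition, records=records)


def _truth_table(ids, mu, de, normalizer_ids) -> pd.DataFrame:
    cls = np.where(de > 0, "up", np.where(de < 0, "down", "nd"))
    return pd.DataFrame(
        {
            "mirna_id": ids,
            "true_class": cls,
            "mu_control": mu,
            "de_effect": de,
            "is_normalizer": [i in set(normalizer_ids) for i in ids],
        }
    )


def simulate_replicates(
    params: TwoComponentParams, n_arrays_per_condition: int = 1
) -> tuple[list[ArrayProfile], pd.DataFrame]:
    """Generate replicate control and treated arrays plus the truth table.

    Arrays are returned controls first (CTRL-1..R) then treated (TRT-1..R).
    Each array draws from its own deterministic sub-stream of the master
    seed, so the same seed reproduces byte-identical output.
    """
    if n_arrays_per_condition < 1:
        raise DataError("n_arrays_per_condition must be >= 1")
    R = n_arrays_per_condition
    ss = np.random.SeedSequence(params.seed)
    master = np.random.default_rng(ss.spawn(1)[0])
    ids, mu, de, sigma_eta = _resolve(params, master)
    mu_treated = mu * np.exp(de)
    offsets = (np.asarray(params.array_offsets, dtype=float)
               if params.array_offsets is not None else np.zeros(2 * R))
    if offsets.size != 2 * R:
        raise DataError("array_offsets must have length 2 * n_arrays_per_condition")
    children = ss.spawn(2 * R + 1)[1:]
    profiles = []
    for a in range(R):
        profiles.append(
            _simulate_array(f"CTRL-{a + 1}", Condition.CONTROL, ids, mu,
                            sigma_eta, float(offsets[a]), params,
                            np.random.default_rng(children[a]))
        )
    for a in range(R):
        profiles.append(
            _simulate_array(f"TRT-{a + 1}", Condition.TREATED, ids, mu_treated,
                            sigma_eta, float(offsets[R + a]), params,
                            np.random.default_rng(children[R + a]))
        )
    return profiles, _truth_table(ids, mu, de, params.normalizer_ids)


def simulate_pair(
    params: TwoComponentParams,
) -> tuple[ArrayProfile, ArrayProfile, pd.DataFrame]:
    """One treated and one control array from the same concentration draw."""
    profiles, truth = simulate_replicates(params, 1)
    control, treated = profiles
    return treated, control, truth
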
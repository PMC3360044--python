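"""Three-way regulation-trend classification and weighted-kappa agreement.

Two platforms (e.g. an LNA array pipeline and qRT-PCR) each classify every
miRNA as down-regulated, non-differentially expressed, or up-regulated.
Their agreement is summarized by a 3x3 classification table and Cohen's
weighted kappa with the Fleiss-Cohen (quadratic) weighting scheme,

    w_ij = 1 - (i - j)^2 / (k - 1)^2,   k = 3 categories,

so exact agreement weighs 1, adjacent categories 0.75, and opposite
trends 0.  kappa_w = (p_obs_w - p_exp_w) / (1 - p_exp_w) with the weighted
observed and chance agreements, interpreted on the Landis-Koch bands.

Simple callers based on fold change and on the t-test over technical
replicates are included for benchmarking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .exceptions import DataError

__all__ = [
    "Trend",
    "ClassificationTable",
    "KappaResult",
    "classify_fc",
    "classify_ttest",
    "build_table",
    "weighted_kappa",
    "fleiss_cohen_weights",
    "interpret_kappa",
]


class Trend(Enum):
    """Regulation trend; ordered DOWN < ND < UP for the distance weights."""

    DOWN = "DOWN"
    ND = "ND"
    UP = "UP"


_ORDER = (Trend.DOWN, Trend.ND, Trend.UP)
_INDEX = {t: i for i, t in enumerate(_ORDER)}


@dataclass(frozen=True)
class ClassificationTable:
    """3x3 counts n_ij, platform A on rows and platform B on columns."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise DataError("classification table must be 3x3")
        if np.any(c < 0):
            raise DataError("counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(np.int64))

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class KappaResult:
    kappa_w: float
    p_obs_w: float
    p_exp_w: float
    weights: np.ndarray
    label: str


def classify_fc(log_ratio: float, cutoff: float = 2.0) -> Trend:
    """Fold-change caller on a natural-log treated-control difference.

    UP when the fold change reaches ``cutoff`` (default two-fold), DOWN when
    it falls below 1/cutoff, otherwise ND.
    """
    if cutoff <= 1.0:
        raise DataError("fold-change cutoff must exceed 1")
    thr = math.log(cutoff)
    if log_ratio >= thr:
        return Trend.UP
    if log_ratio <= -thr:
        return Trend.DOWN
    return Trend.ND


def classify_ttest(
    values_treated,
    values_control,
    sig_level: float = 0.05,
    paired: bool = False,
    fc_cutoff: float = 2.0,
) -> Trend:
    """t-test caller on replicate log intensities.

    Two-sided t-test on the difference of means; the trend follows the sign
    of the difference when p < sig_level.  With fewer than two usable
    replicates on either side the fold-change rule is used instead (with a
    warning), mirroring practice when flagged probes leave too few measures.
    """
    t = np.asarray(values_treated, dtype=float)
    c = np.asarray(values_control, dtype=float)
    if t.size < 2 or c.size < 2 or (paired and t.size != c.size):
        warnings.warn("not enough replicates for a t-test; falling back to "
                      "the fold-change rule")
        return classify_fc(float(t.mean() - c.mean()), fc_cutoff)
    if paired:
        res = stats.ttest_rel(t, c)
    else:
        res = stats.ttest_ind(t, c, equal_var=True)
    if np.isnan(res.pvalue) or res.pvalue >= sig_level:
        return Trend.ND
    return Trend.UP if t.mean() > c.mean() else Trend.DOWN


def build_table(calls_a, calls_b) -> ClassificationTable:
    """Tally matched calls from two platforms into a 3x3 table."""
    calls_a = list(calls_a)
    calls_b = list(calls_b)
    if len(calls_a) != len(calls_b):
        raise DataError("call lists must have equal length")
    if not calls_a:
        raise DataError("empty call lists")
    counts = np.zeros((3, 3), dtype=np.int64)
    for a, b in zip(calls_a, calls_b):
        counts[_INDEX[Trend(a)], _INDEX[Trend(b)]] += 1
    return ClassificationTable(counts=counts)


def fleiss_cohen_weights(k: int = 3) -> np.ndarray:
    """Quadratic agreement weights w_ij = 1 - (i - j)^2 / (k - 1)^2."""
    i = np.arange(k)
    return 1.0 - np.subtract.outer(i, i) ** 2 / (k - 1) ** 2


def weighted_kappa(
    table: ClassificationTable, weights: np.ndarray | None = None
) -> KappaResult:
    """Weighted kappa of a classification table.

    With the default Fleiss-Cohen weights this is the quadratic weighted
    kappa; passing the identity matrix recovers unweighted Cohen's kappa.
    """
    n = table.total
    if n < 1:
        raise DataError("empty classification table")
    w = fleiss_cohen_weights(3) if weights is None else np.asarray(weights, float)
    p = table.counts / n
    row = table.row_marginals / n
    col = table.col_marginals / n
    p_obs = float(np.sum(w * p))
    p_exp = float(np.sum(w * np.outer(row, col)))
    if p_exp >= 1.0 - 1e-15:
        warnings.warn("chance agreement is 1; kappa undefined for this margin "
                      "pattern")
        kappa = float("nan")
        label = "undefined"
    else:
        kappa = (p_obs - p_exp) / (1.0 - p_exp)
        label = interpret_kappa(kappa)
    return KappaResult(kappa_w=kappa, p_obs_w=p_obs, p_exp_w=p_exp,
                       weights=w, label=label)


_BANDS = [
    (0.0, "no agreement"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
]


def interpret_kappa(kappa_w: float) -> str:
    """Landis-Koch interpretation; exact boundaries go to the lower band."""
    if math.isnan(kappa_w):
        return "undefined"
    if kappa_w <= 0.0:
        return "no agreement"
    for upper, label in _BANDS[1:]:
        if kappa_w <= upper:
            return label
    return "almost perfect"
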
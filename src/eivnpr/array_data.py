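"""Probe-level array data: reading, quality control, flagging, summarization.

One-colour miRNA arrays report, for every probe, a signal intensity, a
background intensity, and a quality flag assigned by the image-processing
software.  This module reads such probe tables, computes signal-to-noise
based quality statistics, applies the weak-signal flagging rule, and
collapses technical replicate probes into per-miRNA means and standard
errors of natural-log net intensity — the (W, Y, sigma_u) inputs of the
errors-in-variables regression layer.

All logarithms are natural logs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError, FormatError

__all__ = [
    "Flag",
    "Condition",
    "ProbeRecord",
    "ArrayProfile",
    "MiRNASummary",
    "QCSummary",
    "TableDialect",
    "read_profile",
    "write_profile",
    "snr",
    "profile_qc",
    "flag_weak",
    "summarize",
    "neighborhood_error_sd",
    "write_summaries",
    "read_summaries",
]


class Flag(Enum):
    """Probe quality flag as assigned by image-processing software."""

    OK = "OK"
    POOR = "POOR"
    NEGATIVE = "NEGATIVE"
    OUTLIER = "OUTLIER"
    EMPTY = "EMPTY"


class Condition(Enum):
    TREATED = "TREATED"
    CONTROL = "CONTROL"


#: Default mapping from ImaGene-style integer flags to the enum.
DEFAULT_FLAG_MAP = {
    0: Flag.OK,
    1: Flag.POOR,
    2: Flag.NEGATIVE,
    3: Flag.OUTLIER,
    4: Flag.EMPTY,
}


@dataclass(frozen=True)
class ProbeRecord:
    """One probe's measurements: signal, background, quality flag."""

    probe_id: str
    mirna_id: str
    signal: float
    background: float
    flag: Flag = Flag.OK

    def __post_init__(self) -> None:
        if self.signal < 0 or self.background < 0:
            raise DataError(
                f"probe {self.probe_id}: intensities must be non-negative "
                f"(signal={self.signal}, background={self.background})"
            )

    @property
    def net(self) -> float:
        """Net intensity: background-subtracted signal (may be negative)."""
        return self.signal - self.background


@dataclass
class ArrayProfile:
    """All probes of one array plus its log-background noise statistics."""

    array_id: str
    condition: Condition
    records: list[ProbeRecord]
    treatment: str = ""
    log_bg_mean: float = field(default=float("nan"))
    log_bg_sd: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not self.records:
            raise DataError(f"array {self.array_id}: no probe records")
        if math.isnan(self.log_bg_mean) or math.isnan(self.log_bg_sd):
            self._recompute_bg_stats()

    def _recompute_bg_stats(self) -> None:
        bg = np.array([r.background for r in self.records], dtype=float)
        bg = bg[bg > 0]
        if bg.size == 0:
            self.log_bg_mean = float("nan")
            self.log_bg_sd = float("nan")
            return
        logs = np.log(bg)
        self.log_bg_mean = float(np.mean(logs))
        self.log_bg_sd = float(np.std(logs, ddof=1)) if logs.size > 1 else 0.0

    @property
    def basal_threshold(self) -> float:
        """Default basal reference: mean log background + 2 SD."""
        return self.log_bg_mean + 2.0 * self.log_bg_sd

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_id": [r.probe_id for r in self.records],
                "mirna_id": [r.mirna_id for r in self.records],
                "signal": [r.signal for r in self.records],
                "background": [r.background for r in self.records],
                "flag": [r.flag.value for r in self.records],
            }
        )


@dataclass(frozen=True)
class MiRNASummary:
    """Per-miRNA mean and standard error of log net intensity.

    ``mean_log`` plays the role of the observed log expression (W on the
    control side, Y on the treated side); ``se_log`` is the measurement-error
    SD attached to it.
    """

    mirna_id: str
    n_probes: int
    mean_log: float
    se_log: float

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise DataError(f"{self.mirna_id}: n_probes must be >= 1")
        if self.se_log < 0:
            raise DataError(f"{self.mirna_id}: se_log must be >= 0")


@dataclass(frozen=True)
class QCSummary:
    array_id: str
    pct_flagged: float
    mean_snr: float
    max_snr: float


@dataclass(frozen=True)
class TableDialect:
    """Column names, separator, and flag code mapping of a probe table."""

    probe_id: str = "probe_id"
    mirna_id: str = "mirna_id"
    signal: str = "signal"
    background: str = "background"
    flag: str = "flag"
    sep: str = "\t"
    flag_map: dict = field(default_factory=lambda: dict(DEFAULT_FLAG_MAP))


DEFAULT_DIALECT = TableDialect()


def _map_flag(raw, flag_map: dict) -> Flag:
    if isinstance(raw, Flag):
        return raw
    # try the dialect's code table first, then enum names
    for key in (raw, str(raw), int(raw) if str(raw).lstrip("-").isdigit() else None):
        if key is not None and key in flag_map:
            return flag_map[key]
    try:
        return Flag[str(raw).upper()]
    except KeyError:
        raise FormatError(f"unknown flag value {raw!r}") from None


def read_profile(
    path,
    dialect: TableDialect = DEFAULT_DIALECT,
    array_id: str | None = None,
    condition: Condition = Condition.CONTROL,
    treatment: str = "",
) -> ArrayProfile:
    """Read a tab-separated probe table into an :class:`ArrayProfile`.

    Raises :class:`FormatError` naming the missing column, the offending
    line for non-numeric intensities, or "no data rows" for a header-only
    file.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=dialect.sep, dtype=str)
    for col in (dialect.probe_id, dialect.mirna_id, dialect.signal,
                dialect.background, dialect.flag):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: no data rows")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        row = dict(zip(df.columns, row))
        try:
            sig = float(row[dialect.signal])
            bg = float(row[dialect.background])
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}: non-numeric intensity on line {line_no}"
            ) from None
        if not (math.isfinite(sig) and math.isfinite(bg)):
            raise FormatError(f"{path}: non-numeric intensity on line {line_no}")
        records.append(
            ProbeRecord(
                probe_id=str(row[dialect.probe_id]),
                mirna_id=str(row[dialect.mirna_id]),
                signal=sig,
                background=bg,
                flag=_map_flag(row[dialect.flag], dialect.flag_map),
            )
        )
    return ArrayProfile(
        array_id=array_id or path.stem,
        condition=condition,
        treatment=treatment,
        records=records,
    )


def write_profile(profile: ArrayProfile, path, dialect: TableDialect = DEFAULT_DIALECT) -> None:
    """Write a probe table in the same dialect :func:`read_profile` reads."""
    inverse = {}
    for code, fl in dialect.flag_map.items():
        inverse.setdefault(fl, code)
    df = profile.to_frame()
    df["flag"] = [inverse.get(Flag(v), v) for v in df["flag"]]
    df.columns = [dialect.probe_id, dialect.mirna_id, dialect.signal,
                  dialect.background, dialect.flag]
    df.to_csv(path, sep=dialect.sep, index=False)


def snr(record: ProbeRecord) -> float:
    """Signal-to-noise ratio: net intensity divided by background.

    A ratio above 1 means the signal exceeds the noise.  Undefined when the
    background is zero.
    """
    if record.background == 0:
        raise DataError(f"probe {record.probe_id}: SNR undefined (background = 0)")
    return (record.signal - record.background) / record.background


def profile_qc(profile: ArrayProfile) -> QCSummary:
    """Array-level QC: flagged fraction, mean and maximum probe SNR."""
    n = len(profile.records)
    flagged = sum(1 for r in profile.records if r.flag is not Flag.OK)
    snrs = [snr(r) for r in profile.records if r.background > 0]
    if not snrs:
        raise DataError(f"array {profile.array_id}: no probe with positive background")
    return QCSummary(
        array_id=profile.array_id,
        pct_flagged=flagged / n,
        mean_snr=float(np.mean(snrs)),
        max_snr=float(np.max(snrs)),
    )


def flag_weak(profile: ArrayProfile, k: float = 2.0) -> ArrayProfile:
    """Flag probes whose signal is within ``k`` background SDs of background.

    A probe with signal < background + k * SD(background across the array)
    is marked POOR unless it already carries a NEGATIVE/EMPTY/OUTLIER flag.
    Idempotent; never unsets a flag.
    """
    if len(profile.records) < 2:
        raise DataError(
            f"array {profile.array_id}: need >= 2 records to estimate background SD"
        )
    bg_sd = float(np.std([r.background for r in profile.records], ddof=1))
    new_records = []
    for r in profile.records:
        if r.flag is Flag.OK and r.signal < r.background + k * bg_sd:
            r = replace(r, flag=Flag.POOR)
        new_records.append(r)
    return ArrayProfile(
        array_id=profile.array_id,
        condition=profile.condition,
        treatment=profile.treatment,
        records=new_records,
        log_bg_mean=profile.log_bg_mean,
        log_bg_sd=profile.log_bg_sd,
    )


def summarize(
    profile: ArrayProfile, keep_weak: bool = False
) -> tuple[list[MiRNASummary], list[str]]:
    """Collapse technical replicate probes to per-miRNA log summaries.

    OUTLIER probes are always excluded; with ``keep_weak=False`` the
    POOR/NEGATIVE/EMPTY probes are excluded as well.  Probes with
    non-positive net intensity cannot enter a log summary and are dropped.
    Returns the summaries (sorted by miRNA id) and the ids of miRNAs left
    with no usable probe.
    """
    excluded = {Flag.OUTLIER}
    if not keep_weak:
        excluded |= {Flag.POOR, Flag.NEGATIVE, Flag.EMPTY}
    groups: dict[str, list[float]] = {}
    seen: dict[str, bool] = {}
    for r in profile.records:
        seen.setdefault(r.mirna_id, False)
        if r.flag in excluded:
            continue
        if r.net <= 0:
            continue
        groups.setdefault(r.mirna_id, []).append(math.log(r.net))
        seen[r.mirna_id] = True
    summaries = []
    for mirna_id in sorted(groups):
        logs = np.array(groups[mirna_id])
        n = logs.size
        se = float(np.std(logs, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        summaries.append(
            MiRNASummary(mirna_id=mirna_id, n_probes=int(n),
                         mean_log=float(np.mean(logs)), se_log=se)
        )
    dropped = sorted(m for m, ok in seen.items() if not ok)
    if dropped and not summaries:
        warnings.warn(f"array {profile.array_id}: no usable probes at all")
    return summaries, dropped


def neighborhood_error_sd(
    summaries: list[MiRNASummary], k_neighbors: int = 50
) -> list[MiRNASummary]:
    """Fill zero standard errors by pooling nearby miRNAs.

    When a miRNA has a single usable probe its within-miRNA SD is undefined;
    its measurement-error SD is then borrowed from the ``k_neighbors``
    summaries closest in mean log intensity, by pooling their per-probe
    SDs (weighted by degrees of freedom).  The neighborhood is symmetric in
    the rank of mean_log and truncated at the boundaries.
    """
    if k_neighbors < 2:
        raise DataError("k_neighbors must be >= 2")
    if len(summaries) < k_neighbors:
        raise DataError(
            f"need at least {k_neighbors} summaries, got {len(summaries)}"
        )
    order = np.argsort([s.mean_log for s in summaries])
    ranked = [summaries[i] for i in order]
    n = len(ranked)
    out = list(summaries)
    for pos, s in enumerate(ranked):
        if s.se_log > 0 and s.n_probes > 1:
            continue
        lo = max(0, min(pos - k_neighbors // 2, n - k_neighbors))
        neigh = [t for t in ranked[lo: lo + k_neighbors] if t is not s]
        num = 0.0
        dof = 0
        for t in neigh:
            sd = t.se_log * math.sqrt(t.n_probes)
            d = max(t.n_probes - 1, 1)
            num += d * sd * sd
            dof += d
        pooled_sd = math.sqrt(num / dof) if dof > 0 else 0.0
        out[order[pos]] = replace(s, se_log=pooled_sd / math.sqrt(s.n_probes))
    return out


def write_summaries(summaries: list[MiRNASummary], path) -> None:
    pd.DataFrame(
        {
            "mirna_id": [s.mirna_id for s in summaries],
            "n_probes": [s.n_probes for s in summaries],
            "mean_log": [s.mean_log for s in summaries],
            "se_log": [s.se_log for s in summaries],
        }
    ).to_csv(path, sep="\t", index=False)


def read_summaries(path) -> list[MiRNASummary]:
    df = pd.read_csv(path, sep="\t")
    return [
        MiRNASummary(str(r.mirna_id), int(r.n_probes), float(r.mean_log),
                     float(r.se_log))
        for r in df.itertuples(index=False)
    ]
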
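"""Fly locomotor activity and sleep analysis.

Activity arrives as per-minute infrared beam-crossing counts per fly
(TriKinetics DAM monitor text format).  Rhythmicity is scored with the
Sokolove–Bushell chi-square periodogram on 15-min bins using the classic
criteria power >= 40, peak width >= 4 h and period 24 +/- 8 h.  Sleep is
any run of >= 5 consecutive zero-activity minutes, totalled per 60-min bin;
flies that die (terminal silence) are removed before group statistics,
which use two-sided Wilcoxon rank-sum tests at alpha = 0.01 because sleep
distributions are bounded and non-normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ActivityRecord",
    "PeriodogramResult",
    "SleepProfile",
    "read_dam",
    "write_dam",
    "chi2_periodogram",
    "score_sleep",
    "remove_dead",
    "compare_sleep",
    "actogram_matrix",
]

DAM_CHANNELS = 32
DAM_META_FIELDS = 10  # index, date, time, status + 6 auxiliary fields


@dataclass
class ActivityRecord:
    """Per-minute beam-crossing counts for one fly (one monitor channel)."""

    fly_id: str
    counts: np.ndarray           # non-negative ints, 1-min grid
    monitor: str = "M1"
    channel: int = 1
    start_min: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise ValueError("activity counts must be non-negative")

    @property
    def minutes(self) -> np.ndarray:
        return self.start_min + np.arange(len(self.counts))

    @property
    def duration_h(self) -> float:
        return len(self.counts) / 60.0


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    qp: np.ndarray
    sig_line: np.ndarray
    peak_period_h: float
    power: float
    width_h: float
    rhythmic: bool
    flat: bool = False   # record carried no variance (e.g. all zeros)


@dataclass
class SleepProfile:
    fly_id: str
    bin_sleep_min: np.ndarray    # sleep minutes per 60-min bin
    daily_total_min: np.ndarray  # per complete 24-h day
    dead: bool = False

    @property
    def n_bins(self) -> int:
        return len(self.bin_sleep_min)


# ---------------------------------------------------------------------------
# DAM text I/O
#
# Dialect: one line per minute, tab separated; fields 1..10 are reading
# index, date (DD Mon YY), time (HH:MM:SS), monitor status and six auxiliary
# fields (zero here), followed by 32 integer channel counts (42 fields).
# ---------------------------------------------------------------------------

def write_dam(records: Sequence[ActivityRecord], path, monitor: str = "M1") -> None:
    recs = list(records)
    if len(recs) > DAM_CHANNELS:
        raise ValueError(f"a DAM monitor has {DAM_CHANNELS} channels")
    n_min = max((len(r.counts) for r in recs), default=0)
    counts = np.zeros((n_min, DAM_CHANNELS), dtype=int)
    for i, r in enumerate(recs):
        counts[: len(r.counts), i] = r.counts
    with open(path, "w") as fh:
        for m in range(n_min):
            hh, mm = divmod(m, 60)
            d, hh = divmod(hh, 24)
            meta = [str(m + 1), f"{1 + d:02d} Jan 24", f"{hh:02d}:{mm:02d}:00", "1"] + ["0"] * 6
            fh.write("\t".join(meta + [str(c) for c in counts[m]]) + "\n")


def read_dam(path, fly_ids: Optional[Sequence[str]] = None, n_flies: Optional[int] = None) -> list[ActivityRecord]:
    """Parse a DAM monitor file into one record per channel.

    ``n_flies`` limits the channels returned (a monitor always stores 32
    columns even when fewer tubes are loaded).
    """
    rows = []
    monitor = "M1"
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != DAM_META_FIELDS + DAM_CHANNELS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {DAM_META_FIELDS + DAM_CHANNELS} "
                    f"tab-separated fields, got {len(parts)}"
                )
            try:
                rows.append([int(v) for v in parts[DAM_META_FIELDS:]])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer count ({exc})") from None
    if not rows:
        warnings.warn(f"{path}: empty DAM file")
        return []
    counts = np.asarray(rows)
    n = n_flies if n_flies is not None else DAM_CHANNELS
    out = []
    for ch in range(n):
        fid = fly_ids[ch] if fly_ids is not None else f"{monitor}c{ch + 1:02d}"
        out.append(ActivityRecord(fid, counts[:, ch], monitor, ch + 1))
    return out


# ---------------------------------------------------------------------------
# Chi-square periodogram
# ---------------------------------------------------------------------------

def _qp_statistic(binned: np.ndarray, period_bins: int) -> float:
    """Sokolove–Bushell Qp for one candidate period (in bins)."""
    n = len(binned)
    grand = binned.mean()
    var = binned.var()
    if var == 0:
        return 0.0
    cols = np.arange(n) % period_bins
    sums = np.bincount(cols, weights=binned, minlength=period_bins)
    cnts = np.bincount(cols, minlength=period_bins)
    means = sums / cnts
    return float(np.sum(cnts * (means - grand) ** 2) / var)


def chi2_periodogram(
    rec: ActivityRecord,
    bin_min: float = 15.0,
    period_range_h: tuple[float, float] = (16.0, 32.0),
    alpha: float = 0.05,
    power_min: float = 40.0,
    width_min_h: float = 4.0,
) -> PeriodogramResult:
    """Chi-square periodogram rhythmicity of one fly.

    Counts are summed into ``bin_min`` bins and folded at every integer
    number of bins spanning ``period_range_h``; Qp at period P bins is
    compared with the chi-square (P-1 df) quantile at 1 - alpha.  The fly is
    rhythmic when the peak rises ``power_min`` above the significance line
    over a contiguous super-threshold width of at least ``width_min_h``
    with the peak period inside the (24 +/- 8 h) search range.
    """
    if rec.duration_h < 3 * 24:
        raise ValueError("chi-square periodogram needs >= 3 days of data")
    bw = int(round(bin_min))
    n_bins = len(rec.counts) // bw
    binned = rec.counts[: n_bins * bw].reshape(n_bins, bw).sum(axis=1).astype(float)

    bin_h = bin_min / 60.0
    p_lo = int(np.ceil(period_range_h[0] / bin_h))
    p_hi = int(np.floor(period_range_h[1] / bin_h))
    period_bins = np.arange(p_lo, p_hi + 1)
    periods_h = period_bins * bin_h

    flat = binned.var() == 0
    qp = np.array([_qp_statistic(binned, p) for p in period_bins])
    sig = stats.chi2.ppf(1 - alpha, period_bins - 1)

    excess = qp - sig
    k = int(np.argmax(excess))
    power = float(excess[k])
    above = excess > 0
    width_h = 0.0
    if above[k]:
        i = k
        while i > 0 and above[i - 1]:
            i -= 1
        j = k
        while j < len(above) - 1 and above[j + 1]:
            j += 1
        width_h = float((j - i + 1) * bin_h)
    peak = float(periods_h[k])
    rhythmic = (
        not flat
        and power >= power_min
        and width_h >= width_min_h
        and period_range_h[0] <= peak <= period_range_h[1]
    )
    return PeriodogramResult(periods_h, qp, sig, peak, power, width_h, rhythmic, flat)


# ---------------------------------------------------------------------------
# Sleep
# ---------------------------------------------------------------------------

def _zero_runs(counts: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of zero counts as half-open (start, end) minute pairs."""
    zero = counts == 0
    if not zero.any():
        return []
    edges = np.diff(zero.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if zero[0]:
        starts.insert(0, 0)
    if zero[-1]:
        ends.append(len(counts))
    return list(zip(starts, ends))


def score_sleep(rec: ActivityRecord, min_run_min: int = 5, bin_min: int = 60) -> SleepProfile:
    """Score sleep with the 5-min inactivity rule and total per 60-min bin.

    Every minute belonging to a zero-activity run of at least
    ``min_run_min`` minutes is sleep, including the run's first minutes;
    runs spanning bin boundaries contribute their minutes to each bin they
    overlap, so sleep + wake = bin length for complete bins.
    """
    sleep = np.zeros(len(rec.counts), dtype=bool)
    for s, e in _zero_runs(rec.counts):
        if e - s >= min_run_min:
            sleep[s:e] = True
    n_bins = int(np.ceil(len(sleep) / bin_min))
    padded = np.zeros(n_bins * bin_min, dtype=bool)
    padded[: len(sleep)] = sleep
    per_bin = padded.reshape(n_bins, bin_min).sum(axis=1)
    bins_per_day = int(24 * 60 / bin_min)
    n_days = n_bins // bins_per_day
    daily = per_bin[: n_days * bins_per_day].reshape(n_days, bins_per_day).sum(axis=1)
    return SleepProfile(rec.fly_id, per_bin, daily)


def remove_dead(
    records: Sequence[ActivityRecord], tail_zero_h: float = 24.0
) -> tuple[list[ActivityRecord], list[ActivityRecord]]:
    """Split records into (kept, dead).

    A fly is dead when its final zero-activity run reaches the end of the
    record and spans at least ``tail_zero_h`` hours — the automated stand-in
    for manual curation of very long terminal silences.
    """
    kept, removed = [], []
    for rec in records:
        runs = _zero_runs(rec.counts)
        dead = False
        if runs:
            s, e = runs[-1]
            dead = e == len(rec.counts) and (e - s) >= tail_zero_h * 60
        (removed if dead else kept).append(rec)
    return kept, removed


def compare_sleep(
    ctrl: Sequence[SleepProfile],
    wls: Sequence[SleepProfile],
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin and per-day Wilcoxon rank-sum comparison of sleep minutes.

    Returns ``(bins, days)`` tables with the two-sided p-value, the
    difference in group medians (wls - ctrl) and a significance flag at
    ``alpha``.  Bins missing from either group are omitted.
    """

    def _table(ctrl_mat: np.ndarray, wls_mat: np.ndarray, index_name: str) -> pd.DataFrame:
        rows = []
        n = min(ctrl_mat.shape[1], wls_mat.shape[1])
        for b in range(n):
            a, w = ctrl_mat[:, b], wls_mat[:, b]
            if len(a) < 2 or len(w) < 2:
                continue
            if np.ptp(np.concatenate([a, w])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(w, a, alternative="two-sided").pvalue)
            rows.append(
                {
                    index_name: b,
                    "median_ctrl": float(np.median(a)),
                    "median_wls": float(np.median(w)),
                    "median_diff": float(np.median(w) - np.median(a)),
                    "p": p,
                    "significant": p < alpha,
                }
            )
        return pd.DataFrame(rows)

    cb = np.vstack([p.bin_sleep_min for p in ctrl])
    wb = np.vstack([p.bin_sleep_min for p in wls])
    cd = np.vstack([p.daily_total_min for p in ctrl])
    wd = np.vstack([p.daily_total_min for p in wls])
    return _table(cb, wb, "bin"), _table(cd, wd, "day")


def actogram_matrix(rec: ActivityRecord, double_plot: bool = True) -> np.ndarray:
    """Per-day activity raster, max-normalized to [0, 1].

    Double plotting concatenates day d with day d+1 into 48-h rows, the
    conventional layout for reading phase drift by eye.
    """
    mpd = 24 * 60
    n_days = len(rec.counts) // mpd
    if n_days < 2:
        raise ValueError("actogram needs >= 2 complete days")
    mat = rec.counts[: n_days * mpd].reshape(n_days, mpd).astype(float)
    peak = mat.max()
    if peak > 0:
        mat = mat / peak
    if not double_plot:
        return mat
    return np.hstack([mat[:-1], mat[1:]])
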
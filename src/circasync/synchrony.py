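"""Ensemble synchrony of detrended oscillator waveforms.

The order parameter R of a cell set over a 24-h segment is the
variance-ratio synchronization index

    R = Var_t( mean_i x_i(t) ) / mean_i( Var_t x_i(t) )

computed on entire detrended waveforms rather than phase estimates.  R is
1 for identical traces, 0 for perfectly cancelling ones, and ~1/N for N
independent noise traces; it is invariant to a common multiplicative
scaling.  Segments are bounded by the control schedule's lights-on times
(also for shifted groups) with a 1-day rolling window, and no cell is
discarded (flat cells drop out of the denominator only).

Group differences in R get empirical confidence bands from a
randomization: cells from both groups are pooled and repeatedly split
into two disjoint random subsets of the smaller group's size; the 2.5/97.5
and 0.5/99.5 percentiles of the per-day null differences form the 95% and
99% bands.

Phase reports use circular statistics on reliably rhythmic windows only:
vector-mean direction and resultant length rho with the Rayleigh test
(p ~ exp(-z)(1 + (2z - z^2)/(4n) - (24z - 132z^2 + 76z^3 - 9z^4)/(288n^2)),
z = n rho^2), standardized so ZT0 is the control-group mean phase on day 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .rhythm import DetrendedTrace, EmbeddedPhase, RhythmCall, SineFitWindow

__all__ = [
    "SynchronySeries",
    "RandomizationResult",
    "CircularPhaseSummary",
    "order_parameter",
    "delta_r_bands",
    "rayleigh_p",
    "circular_summary",
    "phase_ensemble_export",
]

DAY_H = 24.0


@dataclass
class SynchronySeries:
    group: str
    day_midpoints_h: np.ndarray
    r: np.ndarray                  # in [0, 1]; NaN where < 2 usable cells
    n_cells: int


@dataclass
class RandomizationResult:
    day_midpoints_h: np.ndarray
    observed: np.ndarray           # R_wls - R_ctrl per day
    band95: tuple[np.ndarray, np.ndarray]
    band99: tuple[np.ndarray, np.ndarray]
    n_rand: int
    n_subset: int
    seed: int

    @property
    def significant_95(self) -> np.ndarray:
        lo, hi = self.band95
        return (self.observed < lo) | (self.observed > hi)

    @property
    def significant_99(self) -> np.ndarray:
        lo, hi = self.band99
        return (self.observed < lo) | (self.observed > hi)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "day_midpoint_h": self.day_midpoints_h,
                "delta_r": self.observed,
                "lo95": self.band95[0], "hi95": self.band95[1],
                "lo99": self.band99[0], "hi99": self.band99[1],
                "sig95": self.significant_95, "sig99": self.significant_99,
            }
        )


@dataclass
class CircularPhaseSummary:
    group: str
    midpoint_h: float
    mean_phase_zt_h: float
    rho: float
    rayleigh_p: float
    n: int
    alpha_threshold_radius: float


def _segment_matrix(
    cells: Sequence[DetrendedTrace], lights_on: Sequence[float], roll_step_h: float = 24.0
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-cell samples of every 24-h segment.

    Returns (segments, midpoints) where segments has shape
    (n_cells, n_segments, n_samples).  Segment d covers [on_d, on_d + 24)
    for each lights-on boundary that fits inside every trace.
    """
    t0 = cells[0].t
    dt = float(t0[1] - t0[0])
    for c in cells:
        if len(c.t) != len(t0) or abs(c.t[0] - t0[0]) > 1e-6:
            raise ValueError("all cells must share one time grid")
    n_seg_samples = int(round(DAY_H / dt))
    starts, mids = [], []
    for on in lights_on:
        s = int(round((on - t0[0]) / dt))
        if s >= 0 and s + n_seg_samples <= len(t0):
            starts.append(s)
            mids.append(on + DAY_H / 2)
    if not starts:
        raise ValueError("no 24-h segment fits inside the traces")
    segs = np.stack(
        [[c.x[s:s + n_seg_samples] for s in starts] for c in cells]
    )
    return segs, np.array(mids)


def _r_from_segments(segs: np.ndarray) -> np.ndarray:
    """R per segment from a (n_cells, n_seg, n_samples) stack."""
    num = segs.mean(axis=0).var(axis=-1)          # Var_t of ensemble mean
    cell_var = segs.var(axis=-1)                  # (n_cells, n_seg)
    usable = cell_var > 0
    n_ok = usable.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        den = np.where(n_ok > 0, np.sum(np.where(usable, cell_var, 0.0), axis=0)
                       / np.maximum(n_ok, 1), np.nan)
        r = num / den
    r = np.where(n_ok >= 2, r, np.nan)
    return r


def order_parameter(
    cells: Sequence[DetrendedTrace],
    lights_on: Sequence[float],
    group: str = "",
) -> SynchronySeries:
    """Order parameter R per 24-h lights-on-bounded segment.

    ``lights_on`` must come from the *control* schedule so shifted and
    unshifted groups are scored on identical segments.  Cells with zero
    variance in a segment are excluded from that segment's denominator
    (with a warning); no cell is otherwise discarded.
    """
    if len(cells) < 2:
        raise ValueError("order parameter needs >= 2 cells")
    segs, mids = _segment_matrix(cells, lights_on)
    if (segs.var(axis=-1) == 0).any():
        warnings.warn("flat cell segment(s) excluded from the R denominator")
    r = _r_from_segments(segs)
    return SynchronySeries(group, mids, r, len(cells))


def delta_r_bands(
    ctrl: Sequence[DetrendedTrace],
    wls: Sequence[DetrendedTrace],
    lights_on: Sequence[float],
    n_rand: int = 5000,
    seed: int = 0,
    chunk: int = 256,
) -> RandomizationResult:
    """Randomization confidence bands for the per-day difference in R.

    The observed statistic is R(wls) - R(ctrl) per 24-h segment.  The null
    pools all cells and draws two disjoint subsets of size
    ``min(len(ctrl), len(wls))`` per replicate; bands are the empirical
    2.5/97.5 and 0.5/99.5 percentiles of the null differences.
    """
    if len(ctrl) < 2 or len(wls) < 2:
        raise ValueError("both groups need >= 2 cells")
    n_sub = min(len(ctrl), len(wls))
    pool = list(ctrl) + list(wls)
    if len(pool) < 2 * n_sub:
        raise ValueError("pool smaller than two disjoint subsets")
    segs, mids = _segment_matrix(pool, lights_on)
    n_cells = len(pool)

    obs = _r_from_segments(segs[len(ctrl):]) - _r_from_segments(segs[:len(ctrl)])

    rng = np.random.default_rng(seed)
    null = np.empty((n_rand, len(mids)))
    cell_var = segs.var(axis=-1)
    done = 0
    while done < n_rand:
        m = min(chunk, n_rand - done)
        perms = np.argsort(rng.random((m, n_cells)), axis=1)
        ia, ib = perms[:, :n_sub], perms[:, n_sub:2 * n_sub]
        for block, sign in ((ia, -1.0), (ib, 1.0)):
            sub = segs[block]                      # (m, n_sub, n_seg, T)
            num = sub.mean(axis=1).var(axis=-1)    # (m, n_seg)
            cv = cell_var[block]                   # (m, n_sub, n_seg)
            ok = cv > 0
            n_ok = ok.sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                den = np.where(ok, cv, 0.0).sum(axis=1) / np.maximum(n_ok, 1)
                r = np.where(n_ok >= 2, num / den, np.nan)
            if sign < 0:
                null[done:done + m] = -r
            else:
                null[done:done + m] += r
        done += m

    lo95, hi95 = np.nanpercentile(null, [2.5, 97.5], axis=0)
    lo99, hi99 = np.nanpercentile(null, [0.5, 99.5], axis=0)
    return RandomizationResult(mids, obs, (lo95, hi95), (lo99, hi99),
                               n_rand, n_sub, seed)


def rayleigh_p(rho: float, n: int) -> float:
    """Rayleigh uniformity test p-value (series approximation in 1/n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    z = n * rho * rho
    p = np.exp(-z) * (
        1 + (2 * z - z * z) / (4 * n)
        - (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n * n)
    )
    return float(min(max(p, 0.0), 1.0))


def circular_summary(
    fits_per_cell: dict[str, Sequence[SineFitWindow]],
    calls_per_cell: dict[str, Sequence[RhythmCall]],
    reference_phase_h: float,
    group: str = "",
    alpha: float = 0.05,
) -> list[CircularPhaseSummary]:
    """Circular phase statistics per window midpoint over a cell group.

    Only reliably rhythmic windows contribute.  Phases are mapped to
    angles relative to ``reference_phase_h`` (ZT0 = control-group mean
    phase on day 3); midpoints where no cell qualifies are omitted, not
    reported as zero.
    """
    by_mid: dict[float, list[float]] = {}
    for cid, fits in fits_per_cell.items():
        calls = calls_per_cell[cid]
        for f, call in zip(fits, calls):
            if not call.reliably_rhythmic or f.skipped:
                continue
            # absolute peak time mod 24 h relative to the reference
            zt = (f.peak_time_h - reference_phase_h) % DAY_H
            by_mid.setdefault(round(f.midpoint_h, 6), []).append(zt)
    out = []
    for mid in sorted(by_mid):
        zts = np.array(by_mid[mid])
        theta = 2 * np.pi * zts / DAY_H
        vec = np.mean(np.exp(1j * theta))
        rho = float(np.abs(vec))
        mean_zt = float((np.angle(vec) * DAY_H / (2 * np.pi)) % DAY_H)
        n = len(zts)
        out.append(
            CircularPhaseSummary(
                group, mid, mean_zt, rho, rayleigh_p(rho, n), n,
                float(np.sqrt(-np.log(alpha) / n)),
            )
        )
    return out


def mean_phase_on_day(
    fits_per_cell: dict[str, Sequence[SineFitWindow]],
    day: int = 3,
) -> float:
    """Circular mean absolute peak time (h mod 24) over all windows whose
    midpoint falls on the given day — the ZT0 reference convention."""
    angles = []
    for fits in fits_per_cell.values():
        for f in fits:
            if f.skipped or not np.isfinite(f.period_h):
                continue
            if day * DAY_H <= f.midpoint_h < (day + 1) * DAY_H:
                angles.append(2 * np.pi * (f.peak_time_h % DAY_H) / DAY_H)
    if not angles:
        raise ValueError(f"no usable windows on day {day}")
    vec = np.mean(np.exp(1j * np.array(angles)))
    return float((np.angle(vec) * DAY_H / (2 * np.pi)) % DAY_H)


def phase_ensemble_export(
    embedded: dict[str, EmbeddedPhase],
    groups: dict[str, str],
    control_ids: Sequence[str],
) -> pd.DataFrame:
    """Long-format phase/amplitude ensemble table for disk animations.

    Angles are reported relative to the circular mean phase of the control
    cells at each time; radii are per-cell max-normalized to [0, 1].  No
    rendering is performed — the table is sufficient to re-render phase
    ensemble animations.
    """
    if not embedded:
        raise ValueError("no embedded phases")
    t0 = next(iter(embedded.values())).t
    ctrl = [embedded[c] for c in control_ids]
    if not ctrl:
        raise ValueError("no control cells")
    ref = np.angle(np.mean(np.exp(1j * np.stack([e.phase_rad for e in ctrl])), axis=0))
    rows = []
    for cid, e in embedded.items():
        rel = np.angle(np.exp(1j * (e.phase_rad - ref)))
        rmax = e.amplitude.max()
        radius = e.amplitude / rmax if rmax > 0 else e.amplitude
        rows.append(pd.DataFrame({
            "t_h": e.t, "cell_id": cid, "group": groups.get(cid, ""),
            "rel_phase_rad": rel, "radius_norm": radius, "valid": e.valid,
        }))
    return pd.concat(rows, ignore_index=True)
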
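"""Per-cell bioluminescence trace containers and long-format CSV I/O.

A :class:`CellTrace` is one cell's photons-per-minute time series on a
uniform grid (default 45-min cadence), labelled by brain, circadian neuron
subgroup (s-LNv, l-LNv, LNd, DN1, DN3) and reporter (PER or TIM).  Values
may be negative after per-frame background subtraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

SUBGROUPS = ("s-LNv", "l-LNv", "LNd", "DN1", "DN3")


@dataclass
class CellTrace:
    cell_id: str
    brain_id: str
    subgroup: str
    t: np.ndarray  # hours, uniform grid
    y: np.ndarray  # photons/min (or raw intensity before calibration)
    reporter: str = "PER"
    units: str = "photons/min"
    missing: Optional[np.ndarray] = None  # True where the sample is a gap

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("sampling must be uniform")
        if self.missing is None:
            self.missing = np.zeros(len(self.t), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)

    @property
    def dt_h(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan

    def trimmed(self, hours: float) -> "CellTrace":
        """Drop samples with t < hours (post-dissection transient)."""
        if hours >= self.t[-1]:
            raise ValueError("trim would remove the entire record")
        keep = self.t >= hours
        return CellTrace(
            self.cell_id, self.brain_id, self.subgroup,
            self.t[keep], self.y[keep], self.reporter, self.units,
            self.missing[keep],
        )


@dataclass
class GroundTruth:
    """Simulator ground truth for recovery oracles: per-cell unwrapped phase
    (radians) and instantaneous amplitude on the sampling grid, plus the
    intrinsic free-running period of every cell."""

    t: np.ndarray                      # hours, sampling grid
    phase: dict[str, np.ndarray]       # cell_id -> unwrapped phi(t), radians
    amplitude: dict[str, np.ndarray]   # cell_id -> A(t) >= 0, photons/min
    period: dict[str, float]           # cell_id -> tau_i, hours
    subgroup: dict[str, str] = field(default_factory=dict)


def traces_to_frame(traces: Iterable[CellTrace]) -> pd.DataFrame:
    rows = []
    for tr in traces:
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": tr.cell_id,
                    "brain_id": tr.brain_id,
                    "subgroup": tr.subgroup,
                    "reporter": tr.reporter,
                    "t_h": tr.t,
                    "photons_per_min": tr.y,
                    "missing": tr.missing,
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=["cell_id", "brain_id", "subgroup", "reporter", "t_h", "photons_per_min", "missing"]
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_traces(df: pd.DataFrame) -> list[CellTrace]:
    out = []
    for cid, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("t_h")
        out.append(
            CellTrace(
                cell_id=str(cid),
                brain_id=str(sub["brain_id"].iloc[0]),
                subgroup=str(sub["subgroup"].iloc[0]),
                t=sub["t_h"].to_numpy(),
                y=sub["photons_per_min"].to_numpy(),
                reporter=str(sub["reporter"].iloc[0]) if "reporter" in sub else "PER",
                missing=sub["missing"].to_numpy() if "missing" in sub else None,
            )
        )
    return out


def write_traces(traces: Iterable[CellTrace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path) -> list[CellTrace]:
    return frame_to_traces(pd.read_csv(path))
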
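"""Light protocols as explicit interval sequences.

A schedule is an ordered, contiguous list of half-open ``[start_h, end_h)``
light/dark intervals covering the whole experiment, in continuous hours from
experiment start.  Day ``d`` spans ``[24 d, 24 (d + 1))``.  Supported
protocol families:

* ``standard_ld`` -- 12 h light / 12 h dark per day.
* ``ld_strobe``  -- each of the 12 daytime hours is one short light pulse
  (default 15 min) followed by darkness, then a 12 h dark night.  The strobe
  simulates daytime while leaving most of each hour dark for imaging.
* ``spp``        -- skeleton photoperiod: two pulses per day flanking the
  12 h day (dawn pulse starts at lights-on, dusk pulse ends at lights-off).
* ``ll``         -- the pulse/dark cycle continues through the night hours
  (no 12 h dark night).
* ``dd``         -- constant darkness.

A weekend light shift (WLS) delays every light transition by ``delay_h``
from the dusk of ``delay_start_day`` until the morning of ``advance_day``,
when the original phase snaps back.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Optional, Sequence

__all__ = [
    "Interval",
    "LightSchedule",
    "WLSSpec",
    "ProtocolSpec",
    "build_protocol",
    "apply_wls",
    "light_state",
    "lights_on_times",
]

State = Literal["light", "dark"]

DAY_H = 24.0
DAYTIME_H = 12.0


@dataclass(frozen=True)
class Interval:
    start_h: float
    end_h: float
    state: State
    epoch_label: str = ""

    @property
    def duration_h(self) -> float:
        return self.end_h - self.start_h


@dataclass
class LightSchedule:
    """Ordered, contiguous light/dark intervals covering [0, total_duration)."""

    intervals: list[Interval]
    day_length_h: float = DAY_H

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule must contain at least one interval")
        prev_end = 0.0
        for iv in self.intervals:
            if abs(iv.start_h - prev_end) > 1e-9:
                raise ValueError(
                    f"intervals not contiguous at t={iv.start_h:g} h (expected {prev_end:g})"
                )
            if iv.end_h <= iv.start_h:
                raise ValueError(f"non-positive interval at t={iv.start_h:g} h")
            prev_end = iv.end_h
        self._starts = [iv.start_h for iv in self.intervals]

    @property
    def total_duration_h(self) -> float:
        return self.intervals[-1].end_h

    @property
    def n_days(self) -> int:
        return int(round(self.total_duration_h / self.day_length_h))

    def light_intervals(self) -> list[Interval]:
        return [iv for iv in self.intervals if iv.state == "light"]

    def total_light_h(self) -> float:
        return sum(iv.duration_h for iv in self.light_intervals())

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["start_h", "end_h", "state", "epoch_label"])
            for iv in self.intervals:
                w.writerow([f"{iv.start_h:.6f}", f"{iv.end_h:.6f}", iv.state, iv.epoch_label])

    @classmethod
    def from_csv(cls, path) -> "LightSchedule":
        ivs = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                ivs.append(
                    Interval(float(row["start_h"]), float(row["end_h"]), row["state"], row["epoch_label"])
                )
        return cls(ivs)


@dataclass(frozen=True)
class WLSSpec:
    """Weekend light shift: delay_h applied from the dusk of delay_start_day
    (0-based) through the night before advance_day, when phase is restored."""

    delay_h: float = 3.0
    delay_start_day: int = 2
    advance_day: int = 5


@dataclass(frozen=True)
class ProtocolSpec:
    kind: Literal["standard_ld", "ld_strobe", "spp", "ll", "dd"]
    n_days: int
    pulse_min: float = 15.0
    dd_tail_days: int = 0
    wls: Optional[WLSSpec] = None

    def __post_init__(self) -> None:
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.dd_tail_days < 0:
            raise ValueError("dd_tail_days must be >= 0")
        if not 0 < self.pulse_min < 60:
            raise ValueError("pulse_min must lie in (0, 60)")
        if self.wls is not None:
            if self.kind not in ("ld_strobe", "standard_ld"):
                raise ValueError("WLS applies only to ld_strobe or standard_ld protocols")
            if self.wls.delay_h <= 0:
                raise ValueError("wls.delay_h must be > 0")
            if not (0 <= self.wls.delay_start_day < self.wls.advance_day < self.n_days):
                raise ValueError("wls day indices must satisfy 0 <= delay_start < advance < n_days")


def _merge(intervals: Iterable[Interval]) -> list[Interval]:
    """Merge adjacent intervals with identical state and label."""
    out: list[Interval] = []
    for iv in intervals:
        if out and out[-1].state == iv.state and out[-1].epoch_label == iv.epoch_label:
            out[-1] = replace(out[-1], end_h=iv.end_h)
        else:
            out.append(iv)
    return out


def _day_intervals(kind: str, day0: float, pulse_h: float, label: str) -> list[Interval]:
    ivs: list[Interval] = []
    if kind == "standard_ld":
        ivs.append(Interval(day0, day0 + DAYTIME_H, "light", label))
        ivs.append(Interval(day0 + DAYTIME_H, day0 + DAY_H, "dark", label))
    elif kind == "ld_strobe":
        for h in range(int(DAYTIME_H)):
            ivs.append(Interval(day0 + h, day0 + h + pulse_h, "light", label))
            ivs.append(Interval(day0 + h + pulse_h, day0 + h + 1, "dark", label))
        ivs.append(Interval(day0 + DAYTIME_H, day0 + DAY_H, "dark", label))
    elif kind == "ll":
        # pulse/dark cycle runs through the night hours as well
        for h in range(int(DAY_H)):
            ivs.append(Interval(day0 + h, day0 + h + pulse_h, "light", label))
            ivs.append(Interval(day0 + h + pulse_h, day0 + h + 1, "dark", label))
    elif kind == "spp":
        ivs.append(Interval(day0, day0 + pulse_h, "light", label))
        ivs.append(Interval(day0 + pulse_h, day0 + DAYTIME_H - pulse_h, "dark", label))
        ivs.append(Interval(day0 + DAYTIME_H - pulse_h, day0 + DAYTIME_H, "light", label))
        ivs.append(Interval(day0 + DAYTIME_H, day0 + DAY_H, "dark", label))
    elif kind == "dd":
        ivs.append(Interval(day0, day0 + DAY_H, "dark", "DD"))
    else:  # pragma: no cover - guarded by ProtocolSpec
        raise ValueError(f"unknown protocol kind {kind!r}")
    return ivs


def build_protocol(spec: ProtocolSpec) -> LightSchedule:
    """Construct the interval sequence for a protocol specification."""
    pulse_h = spec.pulse_min / 60.0
    ivs: list[Interval] = []
    for d in range(spec.n_days):
        ivs.extend(_day_intervals(spec.kind, DAY_H * d, pulse_h, "weekday"))
    for d in range(spec.n_days, spec.n_days + spec.dd_tail_days):
        ivs.extend(_day_intervals("dd", DAY_H * d, pulse_h, "DD"))
    schedule = LightSchedule(_merge(ivs))
    if spec.wls is not None:
        schedule = apply_wls(
            schedule,
            delay_h=spec.wls.delay_h,
            delay_start_day=spec.wls.delay_start_day,
            advance_day=spec.wls.advance_day,
        )
    return schedule


def _slice_pattern(schedule: LightSchedule, lo: float, hi: float) -> list[Interval]:
    """Intervals of the schedule clipped to [lo, hi)."""
    out = []
    for iv in schedule.intervals:
        s, e = max(iv.start_h, lo), min(iv.end_h, hi)
        if e - s > 1e-9:
            out.append(Interval(s, e, iv.state, iv.epoch_label))
    return out


def _translate(ivs: Sequence[Interval], dt: float, label: str | None = None) -> list[Interval]:
    return [
        Interval(iv.start_h + dt, iv.end_h + dt, iv.state, label if label is not None else iv.epoch_label)
        for iv in ivs
    ]


def apply_wls(
    schedule: LightSchedule,
    delay_h: float,
    delay_start_day: int,
    advance_day: int,
    extend_evening: bool = True,
) -> LightSchedule:
    """Insert a weekend light shift into an entrainment schedule.

    From the dusk (hour 12) of ``delay_start_day`` every light transition is
    translated ``delay_h`` later; from the morning of ``advance_day`` the
    original phase is restored.  With ``extend_evening`` (default, "staying
    up late") the freed gap right after the original dusk repeats the final
    ``delay_h`` hours of the preceding day-light pattern; otherwise it is
    dark.
    """
    if delay_h == 0:
        return schedule
    if delay_h < 0:
        raise ValueError("delay_h must be >= 0")
    if not 0 <= delay_start_day < advance_day:
        raise ValueError("need 0 <= delay_start_day < advance_day")
    t_dusk = DAY_H * delay_start_day + DAYTIME_H
    t_advance = DAY_H * advance_day
    if t_advance > schedule.total_duration_h:
        raise ValueError("advance_day lies outside the schedule")
    if delay_h > DAYTIME_H:
        raise ValueError("delay_h larger than the night would make intervals overlap")

    head = _slice_pattern(schedule, 0.0, t_dusk)
    if extend_evening:
        gap = _translate(
            _slice_pattern(schedule, t_dusk - delay_h, t_dusk), delay_h, "weekend_delayed"
        )
    else:
        gap = [Interval(t_dusk, t_dusk + delay_h, "dark", "weekend_delayed")]
    shifted = _translate(
        _slice_pattern(schedule, t_dusk, t_advance - delay_h), delay_h, "weekend_delayed"
    )
    tail = _slice_pattern(schedule, t_advance, schedule.total_duration_h)
    return LightSchedule(_merge(head + gap + shifted + tail), schedule.day_length_h)


def light_state(schedule: LightSchedule, t: float) -> State:
    """State of the unique interval containing ``t`` ([start, end) convention;
    the closing boundary of the record maps to the last interval)."""
    if t < 0 or t > schedule.total_duration_h:
        raise ValueError(f"t={t:g} h outside schedule [0, {schedule.total_duration_h:g}]")
    if t == schedule.total_duration_h:
        return schedule.intervals[-1].state
    i = bisect_right(schedule._starts, t) - 1
    return schedule.intervals[i].state


def lights_on_times(
    schedule: LightSchedule, include_flags: bool = False
) -> list[float] | list[tuple[float, bool]]:
    """Per-day lights-on: the start of each day's first light interval.

    Days with no light (DD) get entries extrapolated with 24-h spacing from
    the last lit day's phase; with ``include_flags`` each entry is a
    ``(hour, extrapolated)`` pair.
    """
    n_days = schedule.n_days
    if n_days < 1:
        raise ValueError("schedule shorter than one day")
    lights = schedule.light_intervals()
    ons: list[tuple[float, bool]] = []
    last_real: Optional[float] = None
    for d in range(n_days):
        lo, hi = DAY_H * d, DAY_H * (d + 1)
        day_lights = [iv.start_h for iv in lights if lo - 1e-9 <= iv.start_h < hi - 1e-9]
        if day_lights:
            on = min(day_lights)
            last_real = on
            ons.append((on, False))
        elif last_real is not None:
            ons.append((last_real + DAY_H * (d - int(last_real // DAY_H)), True))
        else:
            # leading DD days: nothing to extrapolate from yet, use day start
            ons.append((lo, True))
    if include_flags:
        return ons
    return [t for t, _ in ons]
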
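"""End-to-end experiment orchestration.

A run simulates (or loads) a control arm and a weekend-light-shift (WLS)
arm — 15L45D strobe entrainment for 8 days plus a 3-day constant-darkness
tail, with the WLS arm delayed 3 h from the evening of the third recorded
day and advanced back on the morning of the sixth — then detrends every
cell, fits sliding-window sinusoids, classifies reliable rhythmicity,
computes per-subgroup order-parameter series and randomization bands for
the R difference, summarizes circular phase, and scores fly sleep in both
arms.  All outputs are CSV plus one machine-readable JSON summary; a
single master seed expands deterministically into per-stage child seeds so
any stage can be rerun in isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import behavior, rhythm, simulate, synchrony
from .light import LightSchedule, ProtocolSpec, WLSSpec, build_protocol, lights_on_times
from .simulate import ActivityParams, CellSimConfig
from .traces import CellTrace, write_traces

__all__ = ["RunConfig", "run_experiment", "trim_initial", "stage_seeds"]

log = logging.getLogger("circasync")

STAGES = ("sim_ctrl", "sim_wls", "activity_ctrl", "activity_wls", "randomization", "lomb")


def stage_seeds(seed: int) -> dict[str, int]:
    """Deterministic per-stage child seeds from one master seed."""
    state = np.random.SeedSequence(seed).generate_state(len(STAGES))
    return {name: int(s % (2**31)) for name, s in zip(STAGES, state)}


@dataclass
class RunConfig:
    """Fully serializable description of one experiment run."""

    n_days_ld: int = 8
    dd_tail_days: int = 3
    pulse_min: float = 15.0
    wls_delay_h: float = 3.0
    wls_delay_start_day: int = 2     # evening of the third recorded day
    wls_advance_day: int = 5         # morning of the sixth day
    n_brains: int = 6
    n_flies: int = 32
    n_rand: int = 5000
    trim_h: float = 12.0
    window_h: float = 48.0
    step_h: float = 6.0
    gof_min: float = 0.82
    period_range_h: tuple[float, float] = (16.0, 32.0)
    sleep_alpha: float = 0.01
    power_min: float = 40.0
    width_min_h: float = 4.0
    reference_day: int = 3
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_mapping(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "period_range_h" in d:
            d = {**d, "period_range_h": tuple(d["period_range_h"])}
        return cls(**d)

    def schedules(self) -> tuple[LightSchedule, LightSchedule]:
        ctrl = build_protocol(
            ProtocolSpec("ld_strobe", self.n_days_ld, self.pulse_min, self.dd_tail_days)
        )
        wls = build_protocol(
            ProtocolSpec(
                "ld_strobe", self.n_days_ld, self.pulse_min, self.dd_tail_days,
                wls=WLSSpec(self.wls_delay_h, self.wls_delay_start_day, self.wls_advance_day),
            )
        )
        return ctrl, wls


def trim_initial(traces: Sequence[CellTrace], hours: float = 12.0) -> list[CellTrace]:
    """Drop the first hours of each record (post-dissection transient);
    raw files keep the full record, analysis uses the trimmed one."""
    if hours == 0:
        return list(traces)
    return [tr.trimmed(hours) for tr in traces]


def _percent_rhythmic(calls: Sequence[rhythm.RhythmCall]) -> float:
    if not calls:
        return float("nan")
    return 100.0 * np.mean([c.reliably_rhythmic for c in calls])


def _analyze_arm(
    traces: Sequence[CellTrace],
    config: RunConfig,
    lights_on_ctrl: Sequence[float],
) -> dict:
    det = {tr.cell_id: rhythm.dwt_detrend(tr, trim_h=config.trim_h) for tr in traces}
    fits = {
        cid: rhythm.sine_fit_windows(d, config.window_h, config.step_h, config.period_range_h)
        for cid, d in det.items()
    }
    calls = {
        cid: rhythm.classify_rhythmic(f, det[cid].sigma_noise, config.period_range_h,
                                      config.gof_min)
        for cid, f in fits.items()
    }
    subgroups = sorted({str(tr.subgroup) for tr in traces})
    r_series = {}
    for sub in subgroups + ["all"]:
        cells = [d for d in det.values() if sub == "all" or d.subgroup == sub]
        r_series[sub] = synchrony.order_parameter(cells, lights_on_ctrl, group=sub)
    pct = {
        sub: float(_percent_rhythmic(
            [c for cid in calls for c in calls[cid] if det[cid].subgroup == sub]
        ))
        for sub in subgroups
    }
    return {"detrended": det, "fits": fits, "calls": calls,
            "r_series": r_series, "pct_rhythmic": pct}


def _fits_table(arm: str, res: dict) -> pd.DataFrame:
    rows = []
    for cid, fits in res["fits"].items():
        d = res["detrended"][cid]
        for f, call in zip(fits, res["calls"][cid]):
            rows.append({
                "arm": arm, "cell_id": cid, "subgroup": d.subgroup,
                "midpoint_h": f.midpoint_h, "period_h": f.period_h,
                "amplitude": f.amplitude, "phase_h": f.phase_h, "gof": f.gof,
                "rhythmic": call.reliably_rhythmic,
                "failed_criteria": "|".join(sorted(call.failed_criteria)),
            })
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Execute both arms end to end; returns (and optionally writes) the
    machine-readable summary."""
    seeds = stage_seeds(config.seed)
    sched_ctrl, sched_wls = config.schedules()
    lights_on_ctrl = lights_on_times(sched_ctrl)

    def _stage(name, fn, *args, **kw):
        log.info("stage %s starting", name)
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    cfg_ctrl = CellSimConfig(n_brains=config.n_brains, seed=seeds["sim_ctrl"])
    cfg_wls = CellSimConfig(n_brains=config.n_brains, seed=seeds["sim_wls"])
    traces_ctrl, truth_ctrl = _stage("simulate_ctrl", simulate.simulate_cell_ensemble,
                                     cfg_ctrl, sched_ctrl)
    traces_wls, truth_wls = _stage("simulate_wls", simulate.simulate_cell_ensemble,
                                   cfg_wls, sched_wls)

    res_ctrl = _stage("analyze_ctrl", _analyze_arm, traces_ctrl, config, lights_on_ctrl)
    res_wls = _stage("analyze_wls", _analyze_arm, traces_wls, config, lights_on_ctrl)

    reference = synchrony.mean_phase_on_day(res_ctrl["fits"], day=config.reference_day)
    circ = []
    for arm, res in (("ctrl", res_ctrl), ("wls", res_wls)):
        for sub in sorted({d.subgroup for d in res["detrended"].values()}):
            fits = {c: f for c, f in res["fits"].items()
                    if res["detrended"][c].subgroup == sub}
            calls = {c: res["calls"][c] for c in fits}
            for s in synchrony.circular_summary(fits, calls, reference, group=f"{arm}:{sub}"):
                circ.append(s)

    rand_seed = seeds["randomization"]
    bands = {}
    subgroups = sorted({d.subgroup for d in res_ctrl["detrended"].values()})
    for i, sub in enumerate(subgroups + ["all"]):
        cc = [d for d in res_ctrl["detrended"].values() if sub == "all" or d.subgroup == sub]
        cw = [d for d in res_wls["detrended"].values() if sub == "all" or d.subgroup == sub]
        bands[sub] = _stage(
            f"randomization_{sub}", synchrony.delta_r_bands,
            cc, cw, lights_on_ctrl, n_rand=config.n_rand, seed=rand_seed + i,
        )

    act_ctrl, _ = _stage("activity_ctrl", simulate.simulate_activity,
                         config.n_flies, sched_ctrl, ActivityParams(),
                         seeds["activity_ctrl"])
    act_wls, _ = _stage("activity_wls", simulate.simulate_activity,
                        config.n_flies, sched_wls, ActivityParams(),
                        seeds["activity_wls"])
    kept_ctrl, dead_ctrl = behavior.remove_dead(act_ctrl)
    kept_wls, dead_wls = behavior.remove_dead(act_wls)
    sleep_ctrl = [behavior.score_sleep(r) for r in kept_ctrl]
    sleep_wls = [behavior.score_sleep(r) for r in kept_wls]
    sleep_bins, sleep_days = behavior.compare_sleep(sleep_ctrl, sleep_wls,
                                                    alpha=config.sleep_alpha)

    wls_window_days = [
        d for d in range(config.wls_delay_start_day, min(config.wls_advance_day + 2,
                                                         config.n_days_ld))
    ]
    summary = {
        "config": dataclasses.asdict(config),
        "seeds": seeds,
        "n_cells": {"ctrl": len(traces_ctrl), "wls": len(traces_wls)},
        "r_by_day": {
            arm: {sub: [None if np.isnan(v) else round(float(v), 4)
                        for v in res["r_series"][sub].r]
                  for sub in res["r_series"]}
            for arm, res in (("ctrl", res_ctrl), ("wls", res_wls))
        },
        "day_midpoints_h": [float(v) for v in
                            res_ctrl["r_series"]["all"].day_midpoints_h],
        "delta_r": {
            sub: {
                "observed": [None if np.isnan(v) else round(float(v), 4)
                             for v in b.observed],
                "significant_days_95": [int(i) for i in np.flatnonzero(
                    np.nan_to_num(b.significant_95))],
            }
            for sub, b in bands.items()
        },
        "pct_reliably_rhythmic": {
            "ctrl": res_ctrl["pct_rhythmic"], "wls": res_wls["pct_rhythmic"],
        },
        "reference_phase_h": round(float(reference), 3),
        "wls_window_days": wls_window_days,
        "sleep": {
            "n_flies": {"ctrl": len(sleep_ctrl), "wls": len(sleep_wls)},
            "n_dead": {"ctrl": len(dead_ctrl), "wls": len(dead_wls)},
            "significant_bins": [int(b) for b in
                                 sleep_bins.loc[sleep_bins["significant"], "bin"]],
            "significant_days": [int(d) for d in
                                 sleep_days.loc[sleep_days["significant"], "day"]],
        },
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())
        sched_ctrl.to_csv(out / "schedule_ctrl.csv")
        sched_wls.to_csv(out / "schedule_wls.csv")
        write_traces(traces_ctrl, out / "traces_ctrl.csv")
        write_traces(traces_wls, out / "traces_wls.csv")
        pd.concat([_fits_table("ctrl", res_ctrl), _fits_table("wls", res_wls)],
                  ignore_index=True).to_csv(out / "sine_fits.csv", index=False)
        rrows = []
        for arm, res in (("ctrl", res_ctrl), ("wls", res_wls)):
            for sub, rs in res["r_series"].items():
                for m, v in zip(rs.day_midpoints_h, rs.r):
                    rrows.append({"arm": arm, "group": sub, "day_midpoint_h": m,
                                  "R": v, "n_cells": rs.n_cells})
        pd.DataFrame(rrows).to_csv(out / "r_series.csv", index=False)
        pd.concat(
            [b.to_frame().assign(group=sub) for sub, b in bands.items()],
            ignore_index=True,
        ).to_csv(out / "delta_r_bands.csv", index=False)
        pd.DataFrame([dataclasses.asdict(c) for c in circ]).to_csv(
            out / "circular_summary.csv", index=False)
        sleep_bins.to_csv(out / "sleep_bins.csv", index=False)
        sleep_days.to_csv(out / "sleep_days.csv", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
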
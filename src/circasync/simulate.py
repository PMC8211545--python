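"""Synthetic data with known ground truth for every pipeline stage.

Cell ensembles
--------------
Each cell is a damped phase–amplitude (Poincaré-style) oscillator:

    dphi_i/dt = 2*pi/tau_i + k_i * L(t) * sin(phi_target(t) - phi_i)
                + g_i * sin(Phi(t) - phi_i)

where ``L(t)`` is the schedule's light state, ``phi_target`` is the phase
locked to that day's lights-on (cells peak shortly before dawn), and
``Phi`` is a network/subgroup mean phase.  Amplitude relaxes toward its
set point under entrained days and decays exponentially in DD or LL.  The
emitted signal is ``b(t) + A_i(t) * (1 + cos(phi_i)) / 2`` plus shot-like
and additive Gaussian noise, sampled every 45 min, with an elevated
decaying baseline over the first ~12 h emulating the post-dissection
transient.  A TIM reporter option advances the emitted phase ~3 h and
scales amplitude down relative to PER.

The five circadian neuron subgroups differ in light coupling (the
CRY-expressing LNvs strong; DN3s light-blind with internal coupling only),
intrinsic-period spread, damping, and amplitude.  All constants are
phenomenological: they are calibrated to reproduce qualitative orderings
of the biology (entrainment within ~3 days, LL amplitude collapse, LNv
desynchrony under weekend light shifts, DN3 synchrony maintained or
increased), not measured rate constants.

Fly activity
------------
Per-minute Poisson counts with crepuscular (dawn/dusk) rate peaks locked
to the schedule, two-state wake/sleep bouts (longer at night) during which
the rate is forced to zero, and optional death times after which counts
stay zero, with the bout list returned as ground truth.

Image stacks
------------
Cells rendered as non-overlapping 2-D Gaussian spots over a dark-current
offset with optional Poisson noise, injected cosmic-ray streak frames and
single-frame hot pixels, plus matching ROI rectangles — the fixture for
the imaging chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .behavior import ActivityRecord
from .imaging import ROI, FrameStack, ROISet
from .light import DAY_H, LightSchedule, lights_on_times
from .traces import CellTrace, GroundTruth

__all__ = [
    "SubgroupParams",
    "CellSimConfig",
    "ActivityParams",
    "simulate_cell_ensemble",
    "simulate_activity",
    "simulate_frames",
    "default_cell_config",
]


@dataclass(frozen=True)
class SubgroupParams:
    n_cells: int = 3                # per brain
    tau_mean: float = 23.8          # intrinsic free-running period, h
    tau_sd: float = 0.3
    k: float = 0.8                  # light coupling, 1/h while lights on
    k_sd_frac: float = 0.3          # per-cell lognormal-ish spread of k
    g: float = 0.1                  # internal coupling toward mean phase, 1/h
    ingroup: bool = False           # couple to own subgroup rather than network
    g_desync_boost: float = 0.0     # extra in-group cohesion when the rest of
                                    # the network loses phase coherence
    lam_dd: float = 0.010           # amplitude decay in DD, 1/h
    lam_ll: float = 0.040           # amplitude decay in LL, 1/h
    lam_relax: float = 0.05         # relaxation toward A0 under entrained days
    light_amp_suppress: float = 0.0  # amplitude cost of light at the wrong
                                     # phase: dA/dt -= this * L * (1 - cos(dphi)) * A, 1/h
    phase_noise: float = 0.01        # rad/sqrt(h) at full amplitude; scales as
                                     # A0/A (phase is labile near the origin)
    amplitude: float = 30.0         # A0, photons/min
    amplitude_sd: float = 6.0
    baseline: float = 10.0          # b0, photons/min
    baseline_drift: float = -0.3    # photons/min per day
    init_phase_sd_h: float = 2.0    # dispersion at culture start


def default_cell_config() -> dict[str, SubgroupParams]:
    """Study-condition defaults for the five circadian neuron subgroups."""
    return {
        # CRY+ lateral neurons: heterogeneous light input that re-entrains
        # over ~1-2 days, weak network coupling, strong amplitude cost of
        # mistimed light -> first to desynchronize, last to resynchronize
        "s-LNv": SubgroupParams(n_cells=3, k=0.8, k_sd_frac=0.35, g=0.0,
                                light_amp_suppress=15.0, phase_noise=0.03,
                                lam_relax=0.02, amplitude=25.0, tau_sd=0.25, init_phase_sd_h=2.5),
        "l-LNv": SubgroupParams(n_cells=3, k=0.85, k_sd_frac=0.35, g=0.0,
                                light_amp_suppress=15.0, phase_noise=0.03,
                                lam_relax=0.02, amplitude=35.0, tau_sd=0.25, init_phase_sd_h=2.5),
        # LNd: half CRY+, faster shift tracking, moderate coupling
        "LNd":   SubgroupParams(n_cells=3, k=0.50, k_sd_frac=0.25, g=0.15,
                                light_amp_suppress=0.5, amplitude=30.0,
                                tau_sd=0.3, init_phase_sd_h=2.0),
        "DN1":   SubgroupParams(n_cells=5, k=0.45, k_sd_frac=0.25, g=0.15,
                                light_amp_suppress=0.3, amplitude=60.0,
                                tau_sd=0.3, init_phase_sd_h=1.5),
        # DN3: cell-autonomously light-blind; in-group coupling that tightens
        # when the rest of the network moves away (WLS-evoked synchrony gain)
        "DN3":   SubgroupParams(n_cells=5, k=0.0, g=0.015, ingroup=True,
                                g_desync_boost=80.0, amplitude=30.0,
                                amplitude_sd=6.0, tau_sd=0.6, init_phase_sd_h=2.0),
    }


@dataclass
class CellSimConfig:
    subgroups: dict[str, SubgroupParams] = field(default_factory=default_cell_config)
    n_brains: int = 6
    sampling_interval_h: float = 0.75
    dt_h: float = 0.05              # integration step (fixed explicit Euler)
    reporter: str = "PER"
    tim_phase_advance_h: float = 3.0
    tim_amp_scale: float = 0.6
    peak_lead_h: float = 1.0        # waveform peak this long before lights-on
    shot_scale: float = 0.3         # shot noise variance per unit signal
    sigma_add: float = 1.5          # additive Gaussian noise, photons/min
    wander_sd: float = 2.5          # slow baseline wander (OU), photons/min
    wander_tau_h: float = 16.0      # OU correlation time; overlaps the
                                    # circadian band so it survives detrending
    transient_scale: float = 2.0    # initial baseline transient, x amplitude
    transient_tau_h: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for name, p in self.subgroups.items():
            if p.n_cells < 1:
                raise ValueError(f"{name}: n_cells must be >= 1")
            if not 16 <= p.tau_mean <= 32:
                raise ValueError(f"{name}: tau_mean must lie in [16, 32] h")
            for attr in ("tau_sd", "k", "g", "lam_dd", "lam_ll", "lam_relax"):
                v = getattr(p, attr)
                if not np.isfinite(v) or v < 0:
                    raise ValueError(f"{name}: {attr} must be finite and >= 0")
        if self.sampling_interval_h <= 0 or self.dt_h <= 0:
            raise ValueError("sampling_interval_h and dt_h must be > 0")
        if self.reporter not in ("PER", "TIM"):
            raise ValueError("reporter must be PER or TIM")


def _day_modes(schedule: LightSchedule) -> list[str]:
    """Classify each day as LD (entrained), LL (light into the late night)
    or DD (no light)."""
    modes = []
    for d in range(schedule.n_days):
        lo = DAY_H * d
        lights = [iv for iv in schedule.light_intervals()
                  if iv.start_h < lo + DAY_H and iv.end_h > lo]
        if not lights:
            modes.append("DD")
        elif any(iv.end_h > lo + 18.0 for iv in lights):
            modes.append("LL")
        else:
            modes.append("LD")
    return modes


def _light_vector(schedule: LightSchedule, t: np.ndarray) -> np.ndarray:
    """Vectorized light state on a time grid (half-open interval convention)."""
    starts = np.array([iv.start_h for iv in schedule.intervals])
    states = np.array([iv.state == "light" for iv in schedule.intervals])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(states) - 1)
    return states[idx].astype(float)


def _circmean(phi: np.ndarray) -> float:
    return float(np.angle(np.mean(np.exp(1j * phi))))


def simulate_cell_ensemble(
    config: CellSimConfig, schedule: LightSchedule
) -> tuple[list[CellTrace], GroundTruth]:
    """Integrate the coupled oscillator ensemble under a light schedule.

    Returns the sampled noisy traces and the noiseless ground truth
    (unwrapped emitted phase, amplitude envelope, intrinsic periods).
    Identical config and schedule give bit-identical output.
    """
    config.validate()
    if schedule.total_duration_h < 2 * DAY_H:
        raise ValueError("schedule must span at least 2 days")
    rng = np.random.default_rng(config.seed)

    names, brains, groups = [], [], []
    tau, k, sup, g, a0, b0, drift, phi0 = [], [], [], [], [], [], [], []
    group_params: dict[str, SubgroupParams] = {}
    for sub, p in config.subgroups.items():
        group_params[sub] = p
        for b in range(config.n_brains):
            for c in range(p.n_cells):
                names.append(f"{sub}_b{b + 1}_c{c + 1}")
                brains.append(f"brain{b + 1}")
                groups.append(sub)
                tau.append(rng.normal(p.tau_mean, p.tau_sd))
                ki = (max(0.0, p.k * (1 + p.k_sd_frac * rng.standard_normal()))
                      if p.k > 0 else 0.0)
                k.append(ki)
                sup.append(p.light_amp_suppress if ki > 0 else 0.0)
                g.append(p.g)
                a0.append(max(1.0, rng.normal(p.amplitude, p.amplitude_sd)))
                b0.append(p.baseline)
                drift.append(p.baseline_drift)
                phi0.append(rng.normal(0.0, p.init_phase_sd_h) * 2 * np.pi / DAY_H)
    pnoise = np.array([config.subgroups[s].phase_noise for s in groups])
    tau = np.clip(np.array(tau), 16.0, 32.0)
    k, sup, g, a0 = np.array(k), np.array(sup), np.array(g), np.array(a0)
    b0, drift = np.array(b0), np.array(drift)
    n_cells = len(names)
    groups = np.array(groups)
    group_masks = {s: groups == s for s in group_params}

    dt = config.dt_h
    n_steps = int(round(schedule.total_duration_h / dt))
    t_grid = np.arange(n_steps) * dt
    L = _light_vector(schedule, t_grid)
    ons = np.array(lights_on_times(schedule))
    modes = _day_modes(schedule)
    day_idx = np.minimum((t_grid // DAY_H).astype(int), len(ons) - 1)
    # entrainment target: peak (phi = 0) peak_lead_h before that day's lights-on
    phi_target = 2 * np.pi * (t_grid - (ons[day_idx] - config.peak_lead_h)) / DAY_H

    sample_every = int(round(config.sampling_interval_h / dt))
    n_samp = n_steps // sample_every
    t_samp = t_grid[::sample_every][:n_samp]

    omega = 2 * np.pi / tau
    phi = phi_target[0] + np.array(phi0)
    amp = a0.copy()
    phi_rec = np.empty((n_samp, n_cells))
    amp_rec = np.empty((n_samp, n_cells))

    for i in range(n_steps):
        if i % sample_every == 0 and i // sample_every < n_samp:
            j = i // sample_every
            phi_rec[j] = phi
            amp_rec[j] = amp
        net_mean = _circmean(phi)
        dphi = omega.copy()
        if L[i]:
            mismatch = phi_target[i] - phi
            dphi += k * np.sin(mismatch)
            # mistimed light suppresses amplitude (limit-cycle resetting cost)
            amp = amp - dt * sup * (1 - np.cos(mismatch)) * amp
        for sub, p in group_params.items():
            m = group_masks[sub]
            if p.g == 0:
                continue
            if p.ingroup:
                grp_mean = _circmean(phi[m])
                # cohesion grows when the rest of the network loses coherence
                rest = np.abs(np.mean(np.exp(1j * phi[~m])))
                g_eff = p.g * (1 + p.g_desync_boost * max(0.0, (1 - rest) - 0.02))
                dphi[m] += g_eff * np.sin(grp_mean - phi[m])
            else:
                dphi[m] += p.g * np.sin(net_mean - phi[m])
        mode = modes[day_idx[i]]
        for sub, p in group_params.items():
            m = group_masks[sub]
            if mode == "LD":
                damp = p.lam_relax * (a0[m] - amp[m])
            elif mode == "DD":
                damp = -p.lam_dd * amp[m]
            else:
                damp = -p.lam_ll * amp[m]
            amp[m] = amp[m] + dt * damp
        phi = phi + dt * dphi
        if np.any(pnoise > 0):
            lability = np.clip(a0 / np.maximum(amp, 1e-6), 1.0, 10.0)
            phi = phi + pnoise * lability * np.sqrt(dt) * rng.standard_normal(n_cells)

    # emitted waveform; TIM reporter is phase-advanced and lower amplitude
    shift = 0.0
    amp_scale = 1.0
    if config.reporter == "TIM":
        shift = 2 * np.pi * config.tim_phase_advance_h / DAY_H
        amp_scale = config.tim_amp_scale
    phase_emit = phi_rec + shift
    amp_emit = amp_rec * amp_scale

    baseline = b0[None, :] + drift[None, :] * t_samp[:, None] / DAY_H
    transient = (config.transient_scale * a0)[None, :] * np.exp(
        -t_samp[:, None] / config.transient_tau_h
    )
    clean = baseline + transient + amp_emit * (1 + np.cos(phase_emit)) / 2
    shot_sd = np.sqrt(config.shot_scale * np.clip(clean, 0, None))
    noise = rng.standard_normal(clean.shape) * shot_sd
    noise += rng.standard_normal(clean.shape) * config.sigma_add
    if config.wander_sd > 0:
        # slow per-cell baseline wander (OU process on the sampling grid)
        rho_w = np.exp(-config.sampling_interval_h / config.wander_tau_h)
        innov = rng.standard_normal(clean.shape) * config.wander_sd * np.sqrt(1 - rho_w**2)
        wander = np.empty_like(clean)
        wander[0] = rng.standard_normal(n_cells) * config.wander_sd
        for j in range(1, len(t_samp)):
            wander[j] = rho_w * wander[j - 1] + innov[j]
        noise += wander
    y = clean + noise

    traces = [
        CellTrace(names[i], brains[i], groups[i], t_samp, y[:, i], config.reporter)
        for i in range(n_cells)
    ]
    truth = GroundTruth(
        t=t_samp,
        phase={names[i]: phase_emit[:, i] for i in range(n_cells)},
        amplitude={names[i]: amp_emit[:, i] for i in range(n_cells)},
        period={names[i]: float(tau[i]) for i in range(n_cells)},
        subgroup={names[i]: groups[i] for i in range(n_cells)},
    )
    return traces, truth


# ---------------------------------------------------------------------------
# Locomotor activity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivityParams:
    base_day: float = 2.5          # awake beam crossings per minute
    base_night: float = 0.2
    peak_rate: float = 5.0         # added crepuscular peak rate
    peak_sd_h: float = 1.2
    mean_wake_day_min: float = 200.0
    mean_wake_night_min: float = 30.0
    mean_sleep_day_min: float = 12.0
    mean_sleep_night_min: float = 90.0
    rhythmic: bool = True          # False: homogeneous Poisson, no forced bouts
    flat_rate: float = 1.0         # rate used when rhythmic=False


def _crepuscular_rate(minutes: np.ndarray, schedule: LightSchedule, p: ActivityParams) -> np.ndarray:
    t_h = minutes / 60.0
    ons = np.array(lights_on_times(schedule))
    day = np.minimum((t_h // DAY_H).astype(int), len(ons) - 1)
    dawn = ons[day]
    dusk = dawn + 12.0
    is_day = (t_h >= dawn) & (t_h < dusk)
    rate = np.where(is_day, p.base_day, p.base_night)
    rate = rate + p.peak_rate * np.exp(-0.5 * ((t_h - dawn) / p.peak_sd_h) ** 2)
    rate = rate + p.peak_rate * np.exp(-0.5 * ((t_h - dusk) / p.peak_sd_h) ** 2)
    return rate


def _sample_bouts(n_min: int, is_night: np.ndarray, p: ActivityParams, rng) -> list[tuple[int, int]]:
    """Alternating wake/sleep bouts; durations exponential with day/night
    means taken at bout onset.  Returns sleep intervals (start, end)."""
    bouts = []
    t = int(rng.integers(0, 30))
    asleep = False
    while t < n_min:
        night = is_night[min(t, n_min - 1)]
        if asleep:
            mean = p.mean_sleep_night_min if night else p.mean_sleep_day_min
            dur = max(1, int(round(rng.exponential(mean))))
            bouts.append((t, min(t + dur, n_min)))
        else:
            mean = p.mean_wake_night_min if night else p.mean_wake_day_min
            dur = max(1, int(round(rng.exponential(mean))))
        t += dur
        asleep = not asleep
    return bouts


def simulate_activity(
    n_flies: int,
    schedule: LightSchedule,
    params: ActivityParams | None = None,
    seed: int = 0,
    death_time_h: Optional[dict[int, float]] = None,
) -> tuple[list[ActivityRecord], dict[str, list[tuple[int, int]]]]:
    """Per-minute Poisson activity for ``n_flies`` under a light schedule.

    Returns the records plus ground-truth forced-sleep bout intervals per
    fly.  ``death_time_h`` maps fly index to the hour after which its counts
    are zero forever.
    """
    if n_flies < 1:
        raise ValueError("n_flies must be >= 1")
    p = params or ActivityParams()
    rng = np.random.default_rng(seed)
    n_min = int(schedule.total_duration_h * 60)
    minutes = np.arange(n_min)

    if p.rhythmic:
        rate = _crepuscular_rate(minutes, schedule, p)
        t_h = minutes / 60.0
        ons = np.array(lights_on_times(schedule))
        day = np.minimum((t_h // DAY_H).astype(int), len(ons) - 1)
        is_night = ~((t_h >= ons[day]) & (t_h < ons[day] + 12.0))
    else:
        rate = np.full(n_min, p.flat_rate)
        is_night = np.zeros(n_min, dtype=bool)

    records, truth = [], {}
    for f in range(n_flies):
        fly_id = f"fly{f + 1:03d}"
        counts = rng.poisson(rate)
        bouts: list[tuple[int, int]] = []
        if p.rhythmic:
            bouts = _sample_bouts(n_min, is_night, p, rng)
            for s, e in bouts:
                counts[s:e] = 0
        if death_time_h is not None and f in death_time_h:
            dm = int(death_time_h[f] * 60)
            counts[dm:] = 0
            bouts = [(s, e) for s, e in bouts if s < dm]
        records.append(ActivityRecord(fly_id, counts, channel=f + 1))
        truth[fly_id] = bouts
    return records, truth


# ---------------------------------------------------------------------------
# Image stacks
# ---------------------------------------------------------------------------

def simulate_frames(
    traces: Sequence[CellTrace],
    frame_shape: tuple[int, int] = (64, 96),
    spot_sigma: float = 1.5,
    roi_half: int = 4,
    dark_offset: float = 50.0,
    gain: float = 10.0,
    noise: str = "none",
    cosmic_ray_frames: Sequence[int] = (),
    cosmic_ray_value: float = 3000.0,
    hot_pixels: Sequence[tuple[int, int, int, float]] = (),
    seed: int = 0,
) -> tuple[FrameStack, ROISet]:
    """Render traces as Gaussian spots on a grid layout.

    Each cell's integrated spot intensity is proportional to its trace
    value at the frame time (scaled by ``gain``); pixel values add a
    dark-current offset and, with ``noise="poisson"``, Poisson counting
    noise.  ``cosmic_ray_frames`` get a bright streak; ``hot_pixels`` are
    (frame, row, col, value) single-frame transients.  A background ROI is
    reserved in the top-left corner.  Raises if the grid cannot hold all
    cells without ROI overlap.
    """
    if not traces:
        raise ValueError("no traces to render")
    rng = np.random.default_rng(seed)
    h, w = frame_shape
    t = traces[0].t
    for tr in traces:
        if not np.array_equal(tr.t, t):
            raise ValueError("all traces must share one time grid")

    pitch = 2 * roi_half + 2
    margin = pitch  # top-left margin row/col reserved for background ROI
    cols = (w - margin) // pitch
    rows = (h - margin) // pitch
    if cols * rows < len(traces):
        raise ValueError(f"frame {frame_shape} too small for {len(traces)} non-overlapping ROIs")

    yy, xx = np.mgrid[0:h, 0:w]
    rois, spots = [], []
    for i, tr in enumerate(traces):
        r, c = divmod(i, cols)
        cy = margin + r * pitch + roi_half
        cx = margin + c * pitch + roi_half
        spot = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * spot_sigma**2))
        spots.append(spot)
        rois.append(ROI(cx - roi_half, cy - roi_half, cx + roi_half, cy + roi_half,
                        tr.subgroup, tr.cell_id, tr.brain_id))
    background = ROI(0, 0, pitch - 1, pitch - 1, "background")

    spots = np.stack(spots)                      # (cells, h, w)
    vals = np.stack([tr.y for tr in traces])     # (cells, n_t)
    clean = dark_offset + np.einsum("ct,chw->thw", np.clip(vals, 0, None) * gain, spots)

    if noise == "poisson":
        frames = rng.poisson(np.clip(clean, 0, None)).astype(float)
    elif noise == "none":
        frames = clean
    else:
        raise ValueError("noise must be 'none' or 'poisson'")

    for j in cosmic_ray_frames:
        r0 = int(rng.integers(0, h))
        c0 = int(rng.integers(0, max(1, w - 12)))
        frames[j, r0, c0:c0 + 12] += cosmic_ray_value
    for (j, r, c, v) in hot_pixels:
        frames[j, r, c] += v

    stack = FrameStack(frames, t, exposure_min=15.0)
    return stack, ROISet(rois, background)
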
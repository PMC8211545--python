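import numpy as np
import pytest

from circasync.light import ProtocolSpec, WLSSpec, build_protocol
from circasync.rhythm import DetrendedTrace
from circasync.simulate import CellSimConfig, SubgroupParams, simulate_cell_ensemble
from circasync.traces import CellTrace


@pytest.fixture(scope="session")
def strobe_day():
    return build_protocol(ProtocolSpec("ld_strobe", 1, 15))


@pytest.fixture(scope="session")
def strobe_8d_dd3():
    return build_protocol(ProtocolSpec("ld_strobe", 8, 15, dd_tail_days=3))


@pytest.fixture(scope="session")
def wls_8d_dd3():
    return build_protocol(
        ProtocolSpec("ld_strobe", 8, 15, dd_tail_days=3, wls=WLSSpec(3.0, 2, 5))
    )


def cosine_trace(
    amp=5.0, period=24.0, phase_h=0.0, days=11, dt=0.75, noise_sd=0.0,
    baseline=0.0, trend=0.0, seed=0, cell_id="c1", subgroup="s-LNv",
):
    t = np.arange(0, days * 24, dt)
    y = baseline + trend * t + amp * np.cos(2 * np.pi * (t - phase_h) / period)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0, noise_sd, len(t))
    return CellTrace(cell_id, "b1", subgroup, t, y)


def detrended_cosine(amp=5.0, period=24.0, phase_h=0.0, days=4, dt=0.75,
                     noise_sd=0.0, sigma_noise=0.1, seed=0, cell_id="c1"):
    """A DetrendedTrace built directly from a cosine (bypasses the DWT)."""
    t = np.arange(0, days * 24, dt)
    x = amp * np.cos(2 * np.pi * (t - phase_h) / period)
    if noise_sd > 0:
        x = x + np.random.default_rng(seed).normal(0, noise_sd, len(t))
    x = x - x.mean()
    return DetrendedTrace(cell_id, "b1", "s-LNv", t, x, sigma_noise)


@pytest.fixture(scope="session")
def small_ensemble(strobe_8d_dd3):
    """Two-brain control-arm ensemble plus ground truth (shared, read-only)."""
    cfg = CellSimConfig(n_brains=2, seed=7)
    return simulate_cell_ensemble(cfg, strobe_8d_dd3)


def quiet_single_cell_config(**kw):
    """One noiseless, uncoupled cell for parameter-recovery oracles."""
    sub = {"s-LNv": SubgroupParams(
        n_cells=1, k=kw.pop("k", 0.0), k_sd_frac=0.0, g=0.0, tau_mean=kw.pop("tau", 24.0),
        tau_sd=0.0, phase_noise=0.0, light_amp_suppress=0.0, amplitude=20.0,
        amplitude_sd=0.0, baseline_drift=0.0, init_phase_sd_h=0.0,
    )}
    return CellSimConfig(
        subgroups=sub, n_brains=1, sigma_add=0.0, shot_scale=0.0,
        transient_scale=0.0, seed=kw.pop("seed", 0), **kw,
    )
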
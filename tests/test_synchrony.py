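import numpy as np
import pytest

from circasync.rhythm import DetrendedTrace, RhythmCall, SineFitWindow
from circasync.synchrony import (
    circular_summary,
    delta_r_bands,
    mean_phase_on_day,
    order_parameter,
    phase_ensemble_export,
    rayleigh_p,
)

from conftest import detrended_cosine

ONS = [0.0, 24.0, 48.0, 72.0]


def noise_cells(n, days=4, sd=1.0, seed=0, prefix="n"):
    rng = np.random.default_rng(seed)
    t = np.arange(0, days * 24, 0.75)
    return [
        DetrendedTrace(f"{prefix}{i}", "b", "g", t,
                       rng.normal(0, sd, len(t)), sd)
        for i in range(n)
    ]


class TestOrderParameter:
    def test_identical_traces_give_exactly_one(self):
        cells = [detrended_cosine(cell_id=f"c{i}") for i in range(5)]
        rs = order_parameter(cells, ONS)
        np.testing.assert_allclose(rs.r, 1.0, atol=1e-12)

    def test_antiphase_pair_gives_exactly_zero(self):
        a = detrended_cosine(phase_h=0.0, cell_id="a")
        b = detrended_cosine(phase_h=12.0, cell_id="b")
        rs = order_parameter([a, b], ONS)
        np.testing.assert_allclose(rs.r, 0.0, atol=1e-12)

    def test_independent_noise_scales_as_one_over_n(self):
        vals = []
        for seed in range(100):
            rs = order_parameter(noise_cells(20, seed=seed), ONS)
            vals.append(np.nanmean(rs.r))
        assert abs(np.mean(vals) - 1 / 20) < 0.2 * (1 / 20)

    def test_invariant_to_common_scaling(self):
        cells = [detrended_cosine(phase_h=i * 2.0, noise_sd=0.5, seed=i,
                                  cell_id=f"c{i}") for i in range(6)]
        scaled = [DetrendedTrace(c.cell_id, c.brain_id, c.subgroup, c.t,
                                 7.3 * c.x, c.sigma_noise) for c in cells]
        r1 = order_parameter(cells, ONS).r
        r2 = order_parameter(scaled, ONS).r
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_decreases_with_phase_jitter(self):
        """Expected R falls monotonically as i.i.d. phase jitter grows."""
        means = []
        for sd_h in [0.0, 1.0, 2.0, 4.0]:
            vals = []
            for seed in range(50):
                rng = np.random.default_rng(1000 * seed + int(sd_h * 10))
                cells = [
                    detrended_cosine(phase_h=rng.normal(0, sd_h), noise_sd=0.3,
                                     seed=seed * 100 + i, cell_id=f"c{i}")
                    for i in range(10)
                ]
                vals.append(np.nanmean(order_parameter(cells, ONS).r))
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2] > means[3]

    def test_flat_cell_excluded_from_denominator_only(self):
        cells = [detrended_cosine(cell_id="a"), detrended_cosine(cell_id="b")]
        t = cells[0].t
        flat = DetrendedTrace("flat", "b", "g", t, np.zeros(len(t)), 0.0)
        with pytest.warns(UserWarning):
            rs = order_parameter(cells + [flat], ONS)
        # mean waveform shrinks by 2/3 -> variance by 4/9, denominator unchanged
        np.testing.assert_allclose(rs.r, 4 / 9, atol=1e-12)

    def test_requires_two_cells(self):
        with pytest.raises(ValueError):
            order_parameter([detrended_cosine()], ONS)

    def test_segments_outside_traces_skipped(self):
        cells = [detrended_cosine(days=2, cell_id=f"c{i}") for i in range(3)]
        rs = order_parameter(cells, [0.0, 24.0, 48.0])
        assert len(rs.r) == 2  # the 48-72 h segment does not fit


class TestDeltaRBands:
    def test_bands_nested_and_finite(self):
        res = delta_r_bands(noise_cells(8, seed=1), noise_cells(8, seed=2),
                            ONS, n_rand=10, seed=0)
        lo95, hi95 = res.band95
        lo99, hi99 = res.band99
        assert (lo99 <= lo95).all() and (hi95 <= hi99).all()
        assert np.isfinite(res.observed).all()

    def test_label_swap_negates_observed(self):
        a, b = noise_cells(8, seed=3), noise_cells(8, seed=4, prefix="m")
        r1 = delta_r_bands(a, b, ONS, n_rand=10, seed=0)
        r2 = delta_r_bands(b, a, ONS, n_rand=10, seed=0)
        np.testing.assert_allclose(r1.observed, -r2.observed, atol=1e-12)

    def test_reproducible_under_seed(self):
        a, b = noise_cells(8, seed=5), noise_cells(8, seed=6, prefix="m")
        r1 = delta_r_bands(a, b, ONS, n_rand=50, seed=9)
        r2 = delta_r_bands(a, b, ONS, n_rand=50, seed=9)
        np.testing.assert_array_equal(r1.band95[0], r2.band95[0])

    def test_strong_desynchrony_detected(self):
        """A genuinely desynchronized group falls below the lower 95% band."""
        sync = [detrended_cosine(phase_h=0.1 * i, noise_sd=0.3, seed=i,
                                 cell_id=f"s{i}") for i in range(12)]
        rng = np.random.default_rng(0)
        desync = [detrended_cosine(phase_h=rng.uniform(0, 24), noise_sd=0.3,
                                   seed=100 + i, cell_id=f"d{i}")
                  for i in range(12)]
        res = delta_r_bands(sync, desync, ONS, n_rand=500, seed=1)
        assert (res.observed < res.band95[0]).all()

    def test_small_pool_rejected(self):
        with pytest.raises(ValueError):
            delta_r_bands(noise_cells(1), noise_cells(1), ONS)


class TestRayleigh:
    def test_identical_phases(self):
        assert rayleigh_p(1.0, 10) < 1e-4

    def test_uniform_phases_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(2)
        n = 100
        rejections = 0
        draws = 1000
        for _ in range(draws):
            theta = rng.uniform(0, 2 * np.pi, n)
            rho = np.abs(np.mean(np.exp(1j * theta)))
            if rayleigh_p(rho, n) < 0.05:
                rejections += 1
        assert abs(rejections / draws - 0.05) < 0.025

    def test_matches_numerical_oracle_at_n8(self):
        """p(rho >= 0.75 | uniform, n = 8) from brute-force simulation agrees
        with the series approximation within 10%."""
        rng = np.random.default_rng(3)
        theta = rng.uniform(0, 2 * np.pi, size=(200_000, 8))
        rho = np.abs(np.mean(np.exp(1j * theta), axis=1))
        oracle = np.mean(rho >= 0.75)
        approx = rayleigh_p(0.75, 8)
        assert abs(approx - oracle) / oracle < 0.10


def _fits_and_calls(phases_h, midpoint=36.0, period=24.0):
    fits, calls = {}, {}
    for i, ph in enumerate(phases_h):
        f = SineFitWindow(midpoint, period, 5.0, ph % period, 0.0, 0.95,
                          start_h=midpoint - 24.0)
        fits[f"c{i}"] = [f]
        calls[f"c{i}"] = [RhythmCall(True, frozenset())]
    return fits, calls


class TestCircularSummary:
    def test_identical_phases_full_resultant(self):
        fits, calls = _fits_and_calls([6.0] * 10)
        (s,) = circular_summary(fits, calls, reference_phase_h=0.0)
        assert s.rho == pytest.approx(1.0)
        assert s.rayleigh_p < 1e-4
        assert s.n == 10

    def test_rotation_equivariance(self):
        base = [2.0, 5.0, 7.5, 11.0]
        f1, c1 = _fits_and_calls(base)
        f2, c2 = _fits_and_calls([p + 3.0 for p in base])
        (s1,) = circular_summary(f1, c1, 0.0)
        (s2,) = circular_summary(f2, c2, 0.0)
        assert (s2.mean_phase_zt_h - s1.mean_phase_zt_h) % 24 == pytest.approx(3.0, abs=1e-9)
        assert s2.rho == pytest.approx(s1.rho)

    def test_non_rhythmic_windows_excluded_entirely(self):
        fits, calls = _fits_and_calls([6.0, 7.0])
        calls["c0"] = [RhythmCall(False, frozenset({"gof"}))]
        calls["c1"] = [RhythmCall(False, frozenset({"gof"}))]
        assert circular_summary(fits, calls, 0.0) == []

    def test_alpha_threshold_radius(self):
        fits, calls = _fits_and_calls([1.0] * 12)
        (s,) = circular_summary(fits, calls, 0.0, alpha=0.05)
        assert s.alpha_threshold_radius == pytest.approx(np.sqrt(-np.log(0.05) / 12))

    def test_reference_day_mean_phase(self):
        fits, _ = _fits_and_calls([6.0] * 4, midpoint=3 * 24 + 12.0)
        ref = mean_phase_on_day(fits, day=3)
        # peak at window start + 6 h -> absolute (60 + 6) % 24 = 18
        assert ref == pytest.approx(18.0)


class TestPhaseEnsembleExport:
    def test_synchronized_ensemble_zero_relative_angles(self):
        from circasync.rhythm import EmbeddedPhase
        t = np.arange(0, 48, 0.75)
        phase = 2 * np.pi * t / 24
        emb = {
            f"c{i}": EmbeddedPhase(t, phase.copy(), np.ones(len(t)),
                                   np.ones(len(t), bool))
            for i in range(4)
        }
        df = phase_ensemble_export(emb, {f"c{i}": "ctrl" for i in range(4)},
                                   control_ids=["c0", "c1"])
        np.testing.assert_allclose(df["rel_phase_rad"], 0.0, atol=1e-12)

    def test_damping_cell_radius_decreases(self):
        from circasync.rhythm import EmbeddedPhase
        t = np.arange(0, 48, 0.75)
        phase = 2 * np.pi * t / 24
        emb = {
            "ref": EmbeddedPhase(t, phase, np.ones(len(t)), np.ones(len(t), bool)),
            "damp": EmbeddedPhase(t, phase, np.exp(-t / 30), np.ones(len(t), bool)),
        }
        df = phase_ensemble_export(emb, {"ref": "ctrl", "damp": "wls"}, ["ref"])
        r = df.loc[df.cell_id == "damp", "radius_norm"].to_numpy()
        assert (np.diff(r) < 0).all()
        assert r.max() == pytest.approx(1.0)
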
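# circasync

Analysis pipeline for single-cell circadian oscillator ensembles and fly
behavior: from bioluminescence image stacks (or per-cell trace tables) and
locomotor event streams to per-subgroup rhythmicity, phase, waveform
synchrony, randomization confidence bands, and sleep statistics — together
with a synthetic-data generator that emulates the biology under
programmable light schedules, so every stage is testable against known
ground truth without any external data.

## Who this is for

Chronobiologists analyzing longitudinal luciferase-reporter recordings of
clock-protein cycling (PER/TIM) in cultured *Drosophila* brains at
single-cell resolution, and the accompanying *in vivo* locomotor/sleep
assays from DAM (Drosophila Activity Monitor) beam-crossing counts.  The
motivating question is what "weekend light shifts" (WLS) — a 3-h phase
delay on Friday evening held through the weekend, then a 3-h advance on
Monday morning — do to synchrony within and between the five circadian
neuron subgroups (s-LNv, l-LNv, LNd, DN1, DN3).

## The core quantities

**Order parameter R.**  For a set of cells with detrended circadian
waveforms x_i(t) over a 24-h segment bounded by the control schedule's
lights-on,

    R = Var_t( mean_i x_i(t) ) / mean_i( Var_t x_i(t) )

R = 1 for identical waveforms, 0 for perfect cancellation, and ≈ 1/N for N
independent noise traces.  It uses the entire waveform, not phase
estimates, so damping and desynchrony both lower it.  Group differences
ΔR = R_WLS − R_CTRL get empirical 95%/99% confidence bands from 5000
randomized re-partitions of the pooled cells into disjoint subsets the
size of the smaller group.

**Reliably rhythmic.**  Per 2-day sliding window of the wavelet-detrended
trace, a least-squares sinusoid gives period τ̂, amplitude Â, phase φ̂ and
goodness of sine fit (Pearson r of fit vs data).  A window is reliably
rhythmic iff 16 ≤ τ̂ ≤ 32 h, Â rises above the noise floor (the SD of the
sub-4-h wavelet detail), and gof ≥ 0.82.  Phases are reported only from
reliably rhythmic windows, summarized with circular statistics (Rayleigh
test) standardized to ZT0 = control mean phase on day 3; an independent
phase estimate from 6-h-lag time-delay embedding cross-validates the fits.

**Behavior.**  Chi-square (Sokolove–Bushell) periodogram rhythmicity on
15-min activity bins (rhythmic iff power ≥ 40, peak width ≥ 4 h, period
24 ± 8 h); sleep as any ≥ 5-min run of zero activity, totalled per hour,
with dead-fly removal and per-bin Wilcoxon rank-sum comparisons at
α = 0.01.

## Worked example

Simulate both arms of a weekend-light-shift experiment (six brains per
arm, 8 days of 15-min-light/45-min-dark "LD strobe" entrainment plus 3
days of constant darkness), then score s-LNv synchrony:

```python
from circasync.light import ProtocolSpec, WLSSpec, build_protocol, lights_on_times
from circasync.simulate import CellSimConfig, simulate_cell_ensemble
from circasync import rhythm, synchrony

ctrl_sched = build_protocol(ProtocolSpec("ld_strobe", n_days=8, dd_tail_days=3))
wls_sched = build_protocol(ProtocolSpec("ld_strobe", n_days=8, dd_tail_days=3,
                                        wls=WLSSpec(delay_h=3.0, delay_start_day=2,
                                                    advance_day=5)))
ons = lights_on_times(ctrl_sched)

ctrl, _ = simulate_cell_ensemble(CellSimConfig(n_brains=6, seed=0), ctrl_sched)
wls, _ = simulate_cell_ensemble(CellSimConfig(n_brains=6, seed=1), wls_sched)
det_c = [rhythm.dwt_detrend(t) for t in ctrl]
det_w = [rhythm.dwt_detrend(t) for t in wls]

slnv_c = [d for d in det_c if d.subgroup == "s-LNv"]
slnv_w = [d for d in det_w if d.subgroup == "s-LNv"]

r = synchrony.order_parameter(slnv_c, ons, group="s-LNv")
print("control s-LNv R per day:", " ".join(f"{v:.2f}" for v in r.r))

bands = synchrony.delta_r_bands(slnv_c, slnv_w, ons, n_rand=1000, seed=17)
print(bands.to_frame().round(3).to_string(index=False))
```

Output:

```
control s-LNv R per day: 0.82 0.80 0.79 0.83 0.77 0.76 0.79 0.80 0.67 0.41
 day_midpoint_h  delta_r   lo95  hi95   lo99  hi99  sig95  sig99
           36.0    0.018 -0.119 0.113 -0.144 0.136  False  False
           60.0    0.058 -0.136 0.135 -0.184 0.170  False  False
           84.0   -0.002 -0.146 0.133 -0.179 0.173  False  False
          108.0   -0.188 -0.176 0.168 -0.219 0.231   True  False
          132.0   -0.213 -0.179 0.185 -0.232 0.247   True  False
          156.0   -0.139 -0.195 0.196 -0.255 0.268  False  False
          180.0   -0.110 -0.156 0.151 -0.186 0.186  False  False
          204.0   -0.219 -0.207 0.202 -0.253 0.269   True  False
          228.0   -0.208 -0.316 0.332 -0.400 0.402  False  False
          252.0   -0.102 -0.315 0.327 -0.395 0.391  False  False
```

Control s-LNv synchrony holds near R ≈ 0.8 through entrained days and
falls in constant darkness (last two days).  The shifted arm loses
synchrony relative to control on the simulated Sunday (day midpoint
108 h), the post-shift Monday (132 h) and again late in the week
(`sig95=True`: the observed ΔR leaves the 95% null band), reproducing the
characteristic weekend-shift desynchrony of the lateral ventral neurons,
while the same analysis on the light-blind DN3 subgroup yields ΔR ≥ 0.

The same workflow is available from the shell:

```bash
circasync run-all --seed 1 --out runs/demo      # both arms, full report bundle
circasync preprocess --stack brain.tif --rois rois.csv --out traces.csv
circasync sleep --dam monitor.txt --ctrl-ids M1c01,M1c02 --wls-ids M1c17,M1c18 --out sleep
```

`run-all` writes trace tables, per-window sine fits, R series, ΔR bands,
circular phase summaries, sleep tables and a machine-readable
`summary.json`, all reproducible from the saved config and seed.

DAM monitor files are parsed as tab-separated lines with 10 metadata
fields (reading index, date, time, status, six auxiliary zeros) followed
by 32 integer channel counts.

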
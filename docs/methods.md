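# Methods

This note documents the models, estimators and numerical choices behind
`circasync`, in the spirit of a methods supplement: what is computed, under
which assumptions, and what the synthetic tests do and do not establish.

## Light schedules

A schedule is a contiguous list of half-open `[start, end)` light/dark
intervals in continuous hours from experiment start; day *d* is
`[24d, 24(d+1))`.  Five families are built from a `ProtocolSpec`:
standard 12/12 LD; *LD strobe* (each of the 12 daytime hours one
`pulse_min` light pulse, default 15 min, followed by darkness, then a
12-h night — daytime entrainment that leaves most of each hour dark for
bioluminescence capture); skeleton photoperiod (dawn pulse starting at
lights-on, dusk pulse ending at lights-off); LL (the pulse/dark cycle
continues through the night hours); and DD.  Querying uses the half-open
convention, with the record's final instant mapped to the last interval.

The weekend light shift (WLS) delays every light transition by `delay_h`
(default 3 h) from the dusk of `delay_start_day` until the morning of
`advance_day`, when the original phase snaps back.  The experiment's
timeline is: three unshifted weekdays, the delay on the evening of the
third recorded day (0-based day 2), two delayed weekend days, the advance
on the morning of the sixth day (day 5).  How the delay plays out on the
delay evening itself is underdetermined at minute resolution; the default
convention (`extend_evening=True`) repeats the final 3 h of the preceding
day-light pattern into the freed gap — "staying up late with the lights
on" — and then translates the rest of the schedule until the advance.
The alternative (darkness in the gap) is available.  Per-day lights-on
times are the start of each day's first light interval; DD days get
entries extrapolated at 24-h spacing from the last lit day (flagged),
which is what bounds the 24-h synchrony segments in constant darkness.

## Synthetic oscillator ensembles

Downstream estimators consume waveform phase, amplitude and period only,
so cells are simulated as damped phase–amplitude (Poincaré-style)
oscillators rather than molecular clock ODEs:

    dφ_i/dt = 2π/τ_i + k_i·L(t)·sin(φ_target(t) − φ_i) + g·sin(Φ(t) − φ_i)
    dA_i/dt = λ_relax(A0_i − A_i)          on entrained days
            = −λ_DD·A_i  /  −λ_LL·A_i      in DD / LL days
            − s·L(t)·(1 − cos(φ_target − φ_i))·A_i

with `L(t)` the schedule's light state, `φ_target` locked to the current
day's lights-on (waveform peak `peak_lead_h = 1 h` before dawn), and `Φ`
a network or within-subgroup circular mean phase.  Because light coupling
acts only while `L(t) = 1`, a 15-min strobe pulse delivers one quarter of
the phase pull of a fully lit hour, making strobe-vs-standard-LD
equivalence an emergent property rather than an assumption.

Two couplings beyond the textbook model are deliberate and
phenomenological:

* **Amplitude cost of mistimed light** (`light_amp_suppress`, `s` above):
  light falling at the wrong oscillator phase drives the limit cycle
  toward its origin.  This is what standard resetting theory predicts for
  strong type-0-ish stimuli, and it is the mechanism by which a simulated
  weekend shift suppresses reporter amplitude for days.
* **Amplitude-dependent phase lability** (`phase_noise`, scaled by
  `A0/A`, capped at 10×): phase is ill-defined near the origin, so
  suppressed cells random-walk in phase.  Together these make shift-evoked
  desynchrony persistent — cells that were pushed near the origin scatter
  and take days to re-herd — rather than a one-sample transient.

Emission is `y = b(t) + A_i(t)(1 + cos φ_i)/2 + noise`, sampled every
0.75 h.  Noise has three parts: shot-like Gaussian noise with variance
proportional to the clean signal (photons/min values are aggregated
counts), additive white noise, and a slow Ornstein–Uhlenbeck baseline
wander (SD 2.5 photons/min, correlation time 16 h).  The wander matters:
purely white noise is almost invisible to the 12–48-h analysis band, and
without an in-band noise floor the order parameter would be insensitive
to amplitude collapse in a way real photon-limited recordings are not.
The first ~12 h add a large decaying baseline transient (2× amplitude,
4-h time constant) emulating the post-dissection settling period, which
is exactly what the 12-h trim rule removes.  A TIM-reporter option
advances the emitted phase by 3 h and scales amplitude by 0.6 relative to
PER.  Integration is fixed-step explicit Euler at 0.05 h; with rates
≤ 0.4 h⁻¹ the step error is far below the sampling noise.  Identical
config and seed give bit-identical output.

### Subgroup defaults (the simulated study conditions)

Six brains per arm, with per-brain cell counts giving ≈ 114 cells/arm
across five subgroups.  Constants are calibrated to reproduce the
qualitative orderings of the biology — entrainment within ~3 days, rapid
LL amplitude collapse, lateral-ventral desynchrony during/after a
weekend shift with DN3 synchrony maintained or increased — and are not
measured rate constants:

| subgroup | cells/brain | k (1/h) | g (1/h) | A0 | notes |
|---|---|---|---|---|---|
| s-LNv | 3 | 0.80 ± 35% | 0 | 25 | strong CRY input; `s=15`, slow recovery (λ_relax 0.02) |
| l-LNv | 3 | 0.85 ± 35% | 0 | 35 | as s-LNv |
| LNd | 3 | 0.50 ± 25% | 0.15 | 30 | mixed CRY; mild suppression (`s=0.5`) |
| DN1 | 5 | 0.45 ± 25% | 0.15 | 60 | highest amplitude; maintains rhythmicity |
| DN3 | 5 | 0 | 0.015 in-group | 30 | light-blind; τ SD 0.6 h |

DN3 cells couple to their own subgroup mean with a cohesion that grows
when the rest of the network loses phase coherence
(`g_eff = g·(1 + 80·max(0, (1−ρ_rest) − 0.02))` with ρ_rest the resultant
length of all non-DN3 phases).  This encodes the observed phenomenon that
the light-blind DN3s *tighten* when the light-driven groups scatter — the
interpretation the source biology itself suggests (re-synchronization
enabled by the desynchrony of other groups) — as an explicit model term;
without it the DN3 response would be undirected sampling noise.

Activity is an inhomogeneous per-minute Poisson process: awake day rate
2.5 min⁻¹ (night 0.2) plus Gaussian crepuscular peaks (height 5, SD
1.2 h) locked to the schedule's dawn/dusk; alternating wake/sleep bouts
with exponential durations (day wake 200 min / nap 12 min; night wake
30 min / sleep 90 min) force the rate to zero while asleep, yielding
≈ 10–11 h of scored sleep per day.  These rates are chosen so that a
rhythmic fly's periodogram clears the classic power/width criteria the
way real rhythmic flies do.  Optional death times zero the record
permanently.  Image stacks render each cell as a 2-D Gaussian spot
(σ = 1.5 px) on a grid with a reserved background region, dark-current
offset, optional Poisson noise, seeded cosmic-ray streak frames, and
single-frame hot pixels.

## Imaging chain

Order matches acquisition practice: cosmic-ray frame rejection →
45-min binning → pairwise running minimum → ROI extraction → photons/min
conversion.  The rejection statistic per frame is the sum of pixel values
exceeding 800 (the per-pixel-threshold reading, which keeps the constant
scale-free; a total-sum mode exists behind a flag); a frame is rejected
when it exceeds the trailing mean by > 3 SD over the last 30 *accepted*
frames — using accepted frames only prevents one ray from inflating the
SD and masking the next — with the first 30 frames as an unrejectable
warm-up.  When all recent frames are identical the SD is zero and the
strict inequality correctly rejects nothing.  Binning is anchored at
t = 0 with half-open bins stamped at midpoints; empty bins propagate as
explicit missing values, never zeros.  The running minimum takes the
pixelwise min of consecutive frame pairs (length n−1), removing any
single-frame transient.  Cell values are ROI means minus the same frame's
background-ROI mean, so negative values are legitimate and retained.

## Rhythm metrics

**Detrending.**  A translation-invariant (maximal-overlap) wavelet
multiresolution decomposition with the least-asymmetric `sym8` filter, to
level 5 at the 45-min cadence.  The trace is reflection-padded to a
multiple of 2⁵ before the transform and cropped after.  Detail level *j*
has nominal period band `[2^j, 2^{j+1}] × 0.75 h`, so the circadian
signal is D4 + D5 (12–48 h), the noise floor σ_noise is the SD of D1
(1.5–3 h, entirely below 4 h; the 3–6-h level straddles the boundary and
is excluded), and the approximation (> 48 h trend) plus sub-circadian
details are discarded.  σ_noise is a single per-record value.  The first
12 h are excluded before analysis; gaps are linearly interpolated with a
logged mask.

**Sine fits.**  48-h windows sliding by 6 h (the reporting step is a
choice; midpoints are the report coordinate).  Per window the period is
grid-searched over 16–32 h at 0.1 h with amplitude/phase/intercept solved
in closed form per candidate, ties broken toward 24 h, then refined by
bounded scalar minimization.  Phase is the waveform-peak time after the
window start, in `[0, τ̂)`, also reported in radians.  Goodness of sine
fit is the Pearson correlation of fit and data (an R² variant of the same
information; the 0.82 threshold is applied to the correlation).  Windows
with > 25% interpolated samples are skipped; flat windows report zero
amplitude and gof with a degeneracy flag.

**Reliably rhythmic** ⇔ 16 ≤ τ̂ ≤ 32 (inclusive) AND Â > σ_noise
(strict) AND gof ≥ 0.82 (inclusive); failures are itemized per criterion.
The classification is monotone in gof and amplitude.

**Lomb–Scargle.**  Normalized periodogram over the 16–32-h band on
non-overlapping 4-day segments of the detrended trace; a segment is
rhythmic when its peak power beats a seeded permutation null
(default 200 shuffles) at false-alarm probability < 0.05.  The
permutation null sidesteps the independent-frequency-count guesswork of
analytic false-alarm formulas and is self-calibrating on the narrow band
used here.

**Embedding phases.**  Points `(x(t), x(t − 6 h))`, centered by a 24-h
running mean, circle the origin for a clean oscillator; for a 24-h signal
the 6-h lag is a quarter period and the polar angle equals the waveform
phase (zero at peak).  The angle is unwrapped; the radius, smoothed over
3 h, is the amplitude proxy, flagged invalid below σ_noise.  Embedding
and sine-fit peak-time estimates agree to well under half an hour median
circular difference on the synthetic ensemble, which is the package's
built-in cross-validation of the two phase pipelines.

## Synchrony

The order parameter `R = Var_t(mean_i x̃_i) / mean_i(Var_t x̃_i)` is
computed on entire detrended waveforms over 24-h segments bounded by the
*control* schedule's lights-on (both arms scored on identical segments;
DD segments use the extrapolated boundaries).  No cell is discarded;
zero-variance cells drop out of the denominator with a warning.  R is
exactly 1 for identical traces, exactly 0 for two equal-amplitude
antiphase cosines, ≈ 1/N for independent noise, and invariant under
common multiplicative scaling.  An amplitude-prenormalized variant was
considered and rejected as the default because the damping component of
desynchrony is part of what the statistic should see.

ΔR confidence bands: pool both groups, draw two *disjoint* random subsets
of size `min(n_ctrl, n_wls)` per replicate (disjointness gives a
symmetric null for a difference statistic), compute the per-day R
difference, and take empirical 2.5/97.5 and 0.5/99.5 percentiles over
5000 replicates (seeded; 1000 used in the scaled-down built-in
experiment).  Because the observed split is itself one such partition
under the null, the bands are calibrated by exchangeability; measured
per-day exceedance is ≈ 5–6% at n_rand = 1000.

Circular phase summaries use reliably rhythmic windows only: angles are
peak times mod 24 h relative to ZT0 (the circular mean phase of control
cells on day 3, when entrainment is most stable), with resultant length
ρ, Rayleigh p from the standard series approximation
`exp(−z)(1 + (2z − z²)/4n − (24z − 132z² + 76z³ − 9z⁴)/288n²)`, z = nρ²
(verified against brute-force simulation within 10% at n = 8), and the
α-threshold radius `sqrt(−ln α / n)` for plotting.  Windows with no
qualifying cells are omitted, not reported as zero.  The phase-ensemble
export table (time, cell, group, angle relative to the control mean,
per-cell max-normalized radius) is sufficient to re-render disk-style
phase animations; no rendering is done here.

## Behavior

The chi-square periodogram statistic at candidate period P (an integer
number of 15-min bins from 64 to 128, i.e. 16–32 h) is
`Qp = Σ_h n_h (M_h − M)² / Var(x)` over the P fold columns, distributed
χ²(P−1) under the null; the significance line is the 95% χ² quantile.
Conventions not printed anywhere authoritative are ours and configurable:
*power* is peak Qp minus the significance line at the peak (a criterion
like "power ≥ 40" only makes sense relative to a baseline), and *width*
is the contiguous period range around the peak that stays above the line.
A fly is rhythmic iff power ≥ 40, width ≥ 4 h and the peak lies in
24 ± 8 h.  Width is record-length-limited: the super-threshold peak of
even a perfect 24-h rhythm narrows as (period)²/record length, so
rhythmicity rates are evaluated on ~5-day segments, the length at which
the classic criteria behave as published for real flies; on 8-day records
the same flies fail the width criterion for purely spectral reasons.

Sleep is any maximal run of ≥ 5 consecutive zero-activity minutes — all
minutes of the run count, including the first five — summed per 60-min
bin, with runs crossing bin boundaries contributing their minutes to each
bin (so sleep + wake = 60 for complete bins).  Dead flies are removed by
an automated stand-in for manual curation: a terminal zero run of ≥ 24 h
reaching the record end.  Group comparisons use two-sided Wilcoxon
rank-sum tests per bin and per day at α = 0.01 (sleep minutes are bounded
at 0 and 60, so rank tests, not t-tests); the measured null
false-positive rate is ≈ 1%.  Actograms are per-day max-normalized
rasters, double-plotted as 48-h rows.

## Pipeline and reproducibility

`run_experiment` executes both arms end to end (simulate → detrend → sine
fits → rhythmicity → R series → ΔR bands → circular summaries → activity
→ sleep comparison) and writes CSVs plus one JSON summary.  One master
seed expands into per-stage child seeds through `SeedSequence`, so any
stage can be rerun in isolation; reruns are byte-identical.  The built-in
experiment is a scaled-down analog of an 11-day, six-brains-per-arm
study (~114 cells/arm, n_rand = 1000), sized so the full run plus its
statistics completes in well under a minute; n_rand and all thresholds
are configuration fields defaulting to the standard values quoted above.

## What the synthetic tests do and do not show

The generator reproduces the *structure* the estimators assume — damped
noisy oscillators with light-locked targets, shot-like plus slow-wander
noise, crepuscular Poisson activity with forced sleep bouts — and the
qualitative subgroup orderings under weekend shifts.  Passing tests
therefore establish correctness of the estimators and calibration of the
statistics under realistic signal/noise structure.  They do not validate
the generator's rate constants against biology (none are measured), do
not cover anatomically realistic spatial imaging (spots on a grid, ROIs
given, no segmentation or focus drift), and do not model non-photic
zeitgebers, waveform asymmetries of the TIM reporter beyond a phase/
amplitude adjustment, or inter-brain heterogeneity beyond independent
cell draws.  Real-data idiosyncrasies — contamination, focus loss,
culture death — are represented only by the specific artifacts the
pipeline claims to remove (cosmic rays, hot pixels, baseline transients,
dead flies).

## Known limitations

* The 3–6-h wavelet level belongs to neither the circadian band nor the
  noise floor; energy there is simply discarded.
* The period grid refinement assumes a single dominant sinusoid per
  window; bimodal waveforms fold into the nearest single-peak fit.
* ΔR bands inherit the exchangeability assumption; strong group
  differences widen the null (the bands are conservative exactly when
  the effect is large).
* The Wilcoxon per-bin tests are unadjusted for multiplicity, matching
  standard practice for per-bin sleep displays; day-level totals are the
  confirmatory statistic.
* Dead-fly removal by terminal silence cannot distinguish death from a
  genuinely immobile final day; the 24-h threshold is configurable.
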
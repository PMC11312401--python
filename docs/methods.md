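# Methods

## Beat model

A single isolated cilium (length 10 µm, anchored at one end) is described at
its scan-line crossing as a one-dimensional position `x(t)` on a 4 ms frame
grid (250 fps).  Each beat is a raised-cosine pulse: a smooth monotone rise
from baseline 0 to `amplitude` over the effective stroke `t_eff`, then a
smooth monotone fall back over the recovery stroke `t_rec`, with zero
velocity at both ends and at the peak.  The raised-cosine ramp is a modeling
choice: published measurements constrain the stroke *durations* and the
*amplitude* but not the intra-stroke velocity profile, and a smooth minimum-
jerk-like ramp is the least structured shape consistent with a smooth
filament.  Beats are separated by rest intervals drawn i.i.d. from a
lognormal law parameterized by its arithmetic mean `interval_mean` and
log-sd `interval_sigma_log = 0.45`; the lognormal with this spread matches
the reported interval range at pH 7.0 (observed 112–584 ms around a 234 ms
mean) while staying strictly nonnegative.

The beat train is started five expected cycles before the record opens, so a
finite record samples the stationary regime: the expected number of peaks in
a record of length `T` is `T / E[cycle]`.  Without this, a record that
always opens on a fresh rest interval systematically undercounts peaks by
5–15% at low beat rates.  Segment boundaries are carried in continuous time
and rounded to the frame grid only at the end, so quantization error never
accumulates; with zero interval variance the burn-in is an exact multiple of
the cycle and construction is fully deterministic.

### Two simulation modes

The reported per-condition beat frequencies are not equal to
`1/(t_eff + t_rec + mean interval)` computed from the same source's stroke
and interval components (e.g. at pH 8.0: 37 + 38 + 31 ms = 106 ms ⇒ 9.4 Hz,
versus a reported 15.4 Hz).  Rather than guess a reconciliation, both number
families are honored in the regime where each was measured:

- **rate_matched** — all three components are rescaled by one common factor
  so `E[cycle] = 1/target_cbf`.  Used for CBF, CBD and ratio work.
- **component_matched** — the component durations are used verbatim and the
  beat rate is whatever emerges (≈2.45 Hz at pH 7.0).  Used for
  stroke-duration and interval work.

### Condition presets

The bundled table (`ciliabeat/data/presets.yaml`) encodes, per condition,
the cohort size and the reported CBF (Hz), CBD amplitude (µm), `t_eff`,
`t_rec` and mean interval (ms).  Three values are interpolations or
compromises where no absolute number is available: `t_eff` at pH 7.2 (90 ms,
linear between 136 and 44 ms), and the absolute pH 7.4 CBF (8.8 Hz) and CBD
(0.98 µm), taken as the compromise of the two values implied by dividing the
endpoint measurements by the endpoint ratios.  ATP-only presets carry the
pH 7.4 stroke components (that series was measured at pH 7.4; no separate
components are reported for it) with the interval mean chosen so the
component sum matches the reported rate.  Null conditions (unstimulated,
ATPγS, PKI-pretreated) have `amplitude = 0` — no beat train — plus an
Ornstein–Uhlenbeck baseline fluctuation with stationary sd 0.08 µm and
correlation time 300 ms, a phenomenological stand-in for the sub-threshold
jiggling of an unreactivated cilium.  With the default 0.2 µm detection
prominence these traces read out at ~0.4 Hz mean "CBF" with occasional
0.2–0.3 µm spurious waves — matching the reported unstimulated values
(0.38 ± 0.40 Hz, 0.23 µm) — i.e. the null conditions are *nearly* but not
perfectly silent, as in the real assay.

## Rendering

Each frame is the line integral of the filament centerline convolved with a
Gaussian PSF on a constant background, with optional additive Gaussian and
Poisson noise, written as 16-bit multi-page TIFF with fps and pixel size in
the image description.  Optics defaults — 0.1 µm pixels, 0.15 µm PSF sd,
peak filament contrast ≈ 50 counts over background 100 with noise sd 3 —
keep the 100 nm filament sub-resolution and make 0.5–1.5 µm excursions span
5–15 pixels, comparable to real HSVM of cilia.  The renderer refuses
configurations sampling a beat cycle with fewer than 6 frames.

The bent pose is a clamped-smoothstep lateral offset in the base-pose frame:
the offset rises smoothly from 0 at the anchor to exactly the commanded
displacement at the rest-pose scan-line station (70% of arc length) and
stays there distally; the drawn arc length is held at the filament length by
truncation.  This guarantees that the filament's crossing of the fixed
perpendicular scan line equals the ground-truth displacement *exactly*,
which is what makes half-pixel parameter-recovery tests meaningful.  A
constant-curvature arc would displace the material point exactly but miss
the fixed image line by several tenths of a micron at large bends.

## Quantification

Intensity is sampled along the user-set scan line by bilinear interpolation
at half-pixel spacing.  The background profile is the elementwise minimum of
the temporal-median profile and each frame's spatial median along the line —
the temporal median alone embeds the filament whenever it dwells at one
position for most of the record (low-pH conditions rest >50% of the time),
and would erase a static filament entirely.  The crossing position is the
intensity-weighted centroid of the dominant background-subtracted peak;
per-frame quality is peak contrast over a robust noise scale estimated from
frame-to-frame flicker.  A stack whose profile is flat in every frame raises
an error rather than returning a silent zero trace.

Peaks are detected on a lightly smoothed copy (Savitzky–Golay, window 5,
order 2 — quadratic-preserving, so raised-cosine peak heights are not
attenuated) with topographic prominence ≥ 0.2 µm and separation ≥ 20 ms
(5 frames, below the shortest plausible ~65 ms cycle).  The prominence
default sits below the smallest stimulated amplitude (0.57 µm) and above the
typical null-fluctuation excursion.  CBF is the peak count divided by the
record duration (2 s by convention); a peak at the record edge counts.  CBD
is the mean peak-minus-preceding-trough excursion over the first 10 complete
waves; a wave whose preceding trough is clipped by the record start is
excluded, and zero complete waves yields NaN with `n_waves_used = 0`,
distinct from a genuine 0.

### Stroke segmentation

Segmentation runs on the *raw* trace so frame-exact boundaries survive.
For each detected peak, the effective start is found by walking back from
the frame of fastest rise while the per-frame rising speed stays above 10%
of that beat's maximum rising speed; a single sub-threshold frame is bridged
(the walk stops only at two consecutive sub-threshold frames), which keeps
measurement jitter on slow strokes (pH 7.0 rise speeds approach the noise
floor of the differentiated trace) from truncating the rise, while leaving
noise-free traces frame-exact.  The recovery end is the first frame after
the peak where the position has returned to within 10% of the beat amplitude
above the local baseline *and* the speed has fallen below 10% of the maximum
falling speed.  Durations are frame counts × 4 ms, never sub-frame
interpolated.  The interval after a beat is the gap from its recovery end to
the next effective start (rest phase only); beats whose recovery never
completes before the next beat are flagged as merged, not silently dropped.
The 10% velocity fraction is an operational stand-in for by-eye frame
counting; against generator ground truth it places boundaries within ±1
frame on noise-free renders, with a known −3% bias on raised-cosine stroke
durations (the velocity threshold is crossed slightly inside the stroke).

## Cohort analysis and statistics

Condition summaries are arithmetic means and sample SDs over cilia (SD = 0
flagged at n = 1); stroke durations are per-cilium means over up to 10 beats
before the cohort mean, and intervals are pooled across cilia.  Ratios
normalize to the pH 7.4 condition, simulated at its reported cohort size
(n = 11).  Welch's t (Satterthwaite df), the paired t and one-way ANOVA are
implemented from the standard formulas so degenerate inputs have defined
outputs (t = 0, p = 1 for zero-variance equal-mean groups, where library
routines return NaN); the scipy implementations serve as independent oracles
in the test suite.  No multiple-testing correction is applied, matching how
such condition contrasts are conventionally reported; this is a deliberate
omission.

## Problem sizes and protocols

Cohort CBF/CBD use one 2 s record per cilium at the reported cohort sizes
(4–11 cilia).  Sparse regimes — ATP-only and null conditions, where a 2 s
record holds only ~0–3 beats — observe each cilium over three consecutive
2 s records and average, keeping the per-cilium observation span within the
4–8 s used for interval measurements in the source protocol.  Pooled
interval statistics use 3 cilia with records long enough to pool ≥60 (pH
7.0) or ≥80 (pH 8.0) intervals.  Effective-stroke duration checks use
noise-free renders with zero interval variance, averaging 10 beats.  The
full `reproduce-paper` run (all presets, both modes, plots) completes in
about two minutes on one CPU.

## What the synthetic data does and does not show

The generator reproduces the *kinematic phenomenology* of reactivated
isolated cilia — stroke asymmetry, lognormal rest intervals, amplitude and
rate presets per condition, sub-threshold null fluctuation — under idealized
imaging (planar beat, no drift, no photobleaching, no neighboring
structures, known anchor and orientation).  Passing recovery tests therefore
demonstrates that the quantifier is unbiased and frame-accurate *given* the
model, and that the analysis chain reproduces the condition-level numbers
the presets encode; it cannot validate the biological model itself, scan-line
placement on cluttered real footage, or out-of-plane beat components, all of
which are explicitly out of scope.  Cohort SDs are emergent from counting
statistics and are not calibrated to the reported error bars.
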
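# Methods

Definitions and estimator choices for every stage of the `eegtel`
pipeline, in processing order.  Units: EEG/EMG traces are millivolts,
time is seconds, band powers are mV² (or normalized, below).

## Signals and conventions

A recording holds an EEG and an EMG channel at a common sampling rate
(500 Hz in all defaults), a per-minute locomotor activity count series
aligned to the recording start, a start clock hour, and a 12 h:12 h
light schedule with lights on at clock hour 6 (zeitgeber time ZT 0).
`Recording.is_light(t)` derives the light phase of any sample;
zeitgeber hour = (clock hour − 6) mod 24.

## Artifact masking

Any sample with |v| ≥ 2 mV (inclusive) is an artifact; each
supra-threshold sample is padded by 100 ms on both sides and
overlapping pads merge into intervals.  Masked samples are **excluded,
never interpolated**: downstream estimators skip masked windows rather
than operate on reconstructed data, so an artifact can only remove
evidence, not fabricate it.

## High-pass filtering

Both branches use a zero-phase FIR high-pass (Hamming-window design via
`scipy.signal.firwin`, applied with `filtfilt`): 0.5 Hz for the
spectral branch (removes DC drift without touching delta), 6.3 Hz for
the spike branch (removes slow waves that would otherwise ride under
spike excursions).  Zero-phase filtering preserves event timing, which
the ±25 ms spike-matching tolerance depends on.

## Spectral estimation

* **Windows.** Non-overlapping 500 ms segments (250 samples), giving
  2 Hz frequency resolution — the coarsest grid on which the band edges
  0.5/4/8/13/30/80 Hz still separate (0.5 Hz maps to the first nonzero
  bin).  The taper is a **boxcar**: with a boxcar, Parseval's theorem
  makes per-window band powers sum exactly to total signal power, and a
  pure tone concentrates in a single bin, so the "bands tile the
  spectrum" property holds to numerical precision.  A Hann taper is
  available as an option for users who prefer lower leakage over exact
  additivity.
* **Bins.** Each 10 s bin aggregates its 20 windows by the
  **per-frequency median**.  Medians are robust to a minority of
  contaminated windows (a residual transient affects ≤ 10 of 20 windows
  without moving the bin estimate).  A bin is valid only if > 50% of
  its windows are artifact-free; invalid bins are NaN.
* **Band powers.** Power in [low, high) per band, upper edge inclusive
  for gamma, so delta+theta+alpha+beta+gamma = total power in
  0.5–80 Hz exactly.
* **Minutes.** Per-minute band power is the mean over the minute's
  valid bins (NaN if none).

## Normalization

Absolute telemetry power depends on electrode impedance and amplifier
gain, so per-minute powers are divided by the **10th percentile (linear
interpolation) of the subject's per-minute total power** — a proxy for
each animal's quiet-wake floor.  By construction the normalized total
power's 10th percentile is exactly 1, and every normalized quantity is
invariant under rescaling the raw trace.  Percent-of-total
distributions are scale-free by definition and sum to 100.

## Circadian profiles and activity regressions

Hourly profiles average normalized minute powers within each ZT hour;
they are only defined for recordings covering ≥ 24 h.  Band–activity
coupling is quantified by ordinary least squares
(`scipy.stats.linregress`) of **raw** (un-normalized) per-minute band
power on the minute's activity count; the slope, its standard error, r,
and p are reported per band.  The regression is undefined (NaN) when
activity is constant.

## Quality control

A subject is excluded when either

1. the delta-vs-activity slope is **strictly positive** — physiological
   delta power falls during locomotion, so a rising slope indicates
   movement noise leaking into the low band; or
2. **≥ 5.0%** (inclusive) of 10 s epochs are artifact-contaminated.

Excluded subjects still appear in the cohort QC table (with reasons)
but are removed from all pooled cohort tables.

## Spike detection and classification

* **Baseline SD.** Robust SD of the 6.3 Hz-filtered trace:
  `1.4826 × MAD`, computed over unmasked samples, so spikes and
  artifacts themselves do not inflate the threshold.
* **Detection.** Contiguous runs with |v| ≥ 10 SD; runs separated by
  ≤ 10 ms merge into one event.  Event width = merged
  threshold-crossing extent; events outside **15–70 ms** are discarded
  (fast noise blips and slow high-amplitude events).
* **Feature measurement.** Classification features are read from a
  10 ms moving-average copy of the filtered trace (detection still uses
  the raw filtered trace).  The event's sign is taken at the
  threshold-crossing midpoint; amplitude is the largest same-sign
  excursion within the crossing relative to a local baseline (median of
  the smoothed trace over ±200 ms); half-decay is the time from the
  crossing midpoint until the excursion first stays below half the peak
  for ≥ 10 ms (within 300 ms).  Smoothing, local baselining, and the
  sustained-drop rule keep single-sample noise and filter-edge
  transients from flipping amplitudes across class boundaries or
  producing spuriously short decays on multimodal crests.
* **Classes.** A: amplitude ≥ 20 SD **and** half-decay ≤ 15 ms.
  C: amplitude < 12 SD **and** half-decay ≥ 30 ms.  B: everything else.
* **Rates.** Events per class per hour over the unmasked duration
  (total duration × (1 − masked fraction)).

## Sleep staging

10 s epochs are built from 1 s subepochs; each subepoch carries

* delta fraction and theta/delta ratio from the 500 ms-window spectra,
* EMG RMS z-scored against the recording's quiet floor (mean/SD of the
  quieter half of subepochs, i.e. those with RMS ≤ the median),
* the containing minute's activity count,
* the fraction of artifact-masked samples.

Subepoch rule, evaluated in order (first match wins):

1. **artifact** if ≥ 50% of samples masked, or spectra invalid;
2. **wake** if activity > 0 or EMG z ≥ 1.0;
3. **NREM** if delta fraction ≥ 0.4 and EMG z ≤ 0.5;
4. **REM** if theta/delta ≥ 1.5 and EMG z ≤ 0.5;
5. otherwise carry the previous subepoch's stage (wake at start).

The epoch stage is the majority over its 10 subepochs, ties broken by
the precedence artifact > wake > NREM > REM; an epoch is an artifact
epoch outright if ≥ 80% of its samples are masked.  By default only the
first 24 h of longer recordings are scored.  Sleep bouts are runs of
≥ 3 consecutive non-wake, non-artifact epochs.  Summaries report stage
percentages for the light period, dark period, and full day, bout count
and mean bout duration, and per-stage mean spectra.

## Synthetic telemetry (the oracle)

The simulator produces EDF-writable recordings with complete ground
truth so every estimator above can be tested against known answers:

* **Hypnogram.** Semi-Markov chain over wake/NREM/REM at 1 s
  resolution; REM is entered only from NREM; wake bout lengths depend
  on light phase, giving light-phase sleep dominance.
* **EEG.** Pink (1/f) background plus state-locked oscillations: 2 Hz
  in NREM (0.20 mV), 6 Hz in REM (0.10 mV), 40 Hz in wake (0.04 mV) —
  yielding delta-in-light / gamma-in-dark circadian contrast.
* **EMG.** White noise with state-dependent SD (wake ≫ NREM > REM).
* **Activity.** Poisson per minute, rate proportional to the minute's
  wake fraction, higher in the dark phase; exactly zero in fully-asleep
  minutes.
* **Spikes.** Biphasic raised-cosine templates per class, injected
  **pre-compensated** through the 6.3 Hz detection filter and scaled by
  the realized robust SD of the filtered background, so injected
  amplitudes are exact in detector units.  Injection times avoid
  artifacts and each other.  Decoy events (10 ms and 100 ms) fall
  outside the 15–70 ms width gate by design.
* **Artifacts.** 5 s, ±3 mV clipped segments at a configurable rate.
* **Failure mode.** `movement_artifact_mode` adds activity-scaled pink
  noise (0.3 mV × √count) to wake minutes, producing the
  delta-rises-with-activity signature the QC rule must catch.

All randomness flows from one `numpy.random.SeedSequence` spawned into
independent streams (hypnogram, background, oscillation phases, EMG,
activity, spikes, artifacts, movement noise), so identical seeds give
bit-identical recordings and changing one component's draw count cannot
perturb the others.

## File formats

Recordings are exchanged as 16-bit EDF (1 s records, physical units
mV) written by a minimal self-contained writer; the stored physical
range is rounded to what the 8-character EDF header field can hold
*before* scaling, so writer and reader use the identical scale factor
and the round trip is exact to quantization.  Reading uses
`mne.io.read_raw_edf`.  Activity is a two-column CSV (`minute,count`);
missing minutes load as NaN.
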
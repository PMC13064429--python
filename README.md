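# eegtel — rodent EEG/EMG telemetry analysis

`eegtel` is a tested, reusable implementation of a wireless-telemetry
analysis pipeline for rodent electrocorticography: spectral band power
across activity states and the circadian cycle, epileptiform spike
detection and morphological classification, quality-control-based subject
exclusion, and rule-based sleep staging.  A synthetic-telemetry generator
with full ground truth (hidden sleep-state sequence, injected spike times
and classes, injected artifact intervals, expected band powers) provides
an oracle for every stage, so the whole pipeline is validated end to end
without any animal data.

## The analysis

A recording is a continuous EEG + EMG pair sampled at 500 Hz, a
per-minute locomotor activity count series, and a 12 h light/dark
schedule.  Three branches run from the same raw trace:

**Spectral branch.**  Samples exceeding ±2 mV are masked as artifacts
(with a 100 ms guard pad) and never interpolated.  The trace is high-pass
filtered at 0.5 Hz (zero-phase FIR), cut into 500 ms FFT windows, and each
10 s bin's spectrum is the per-frequency *median* over its 20 windows —
robust to transients that contaminate a minority of windows.  Band powers
(delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–80 Hz — the
bands tile 0.5–80 Hz exactly) are averaged per minute, normalized to the
10th percentile of each subject's per-minute total power, and summarized
as zeitgeber-hour profiles, percent-of-total distributions, and per-band
ordinary-least-squares regressions of raw power on activity count.  A
subject whose delta power *rises* with locomotion fails QC (movement
noise masquerading as slow-wave power) and is excluded.

**Spike branch.**  The raw trace is high-pass filtered at 6.3 Hz
(zero-phase FIR).  Events are excursions ≥ 10× a robust (MAD-based)
baseline SD, merged across gaps ≤ 10 ms, and kept only if the
threshold-crossing width lies in 15–70 ms — a deterministic surrogate for
the manual screen that removes fast noise blips and slow large events.
Retained events are classified by peak amplitude (SD units) and
half-decay time: **A** high and fast (≥ 20 SD, ≤ 15 ms), **C** low and
slow (< 12 SD, ≥ 30 ms), **B** everything between.  Rates are reported
per class per hour over the unmasked recording time.

**Sleep branch.**  10 s epochs are staged wake/NREM/REM by an ordered
rule evaluated on 1 s subepochs (activity or high EMG ⇒ wake; high delta
fraction with low EMG ⇒ NREM; high theta/delta with low EMG ⇒ REM;
otherwise carry the previous stage), combined by majority with the tie
precedence artifact > wake > NREM > REM.  Recordings with ≥ 5% artifact
epochs are excluded.  Summaries include stage percentages by light
period, sleep bouts (≥ 3 consecutive non-wake epochs), and per-stage
spectra.

The simulator generates matched synthetic recordings: pink-noise EEG with
state-dependent oscillations (NREM delta, REM theta, wake gamma), a
semi-Markov hypnogram with light-phase-dependent wake bouts, EMG
variance tied to state, wake-gated Poisson activity counts, biphasic
spike templates pre-compensated through the 6.3 Hz filter so injected
amplitudes are exact in detector SD units, and high-amplitude artifact
intervals.  Identical seeds give bit-identical recordings.

## Worked example

Simulate six hours of telemetry, then run each stage from its EDF +
activity CSV exactly as one would on real exports:

```console
$ eegtel simulate --seed 7 --hours 6 --subject-id m1 --out-dir data/m1
wrote data/m1/recording.edf (6 h, seed 7)

$ eegtel spikes data/m1/recording.edf --out m1_spikes.csv
class A: 1.00/h
class B: 2.34/h
class C: 0.67/h
total: 4.01/h over 5.99 h analyzed

$ eegtel sleep data/m1/recording.edf --activity data/m1/activity.csv \
      --start-hour 6 --out m1_stages.csv
wake: 48.2%  nrem: 45.3%  rem: 6.2%

$ eegtel report data/m1/recording.edf --activity data/m1/activity.csv \
      --start-hour 6 --out-dir results/m1
m1: included
report written to results/m1
```

(The simulator injected spikes at 1 / 2 / 0.5 per hour for classes
A / B / C; the detected 1.00 / 2.34 / 0.67 per hour over 5.99 unmasked
hours recovers that, and the recording — first six light-phase hours —
is sleep-heavy as expected.)

The per-minute normalized band powers land in `results/m1/minutes.csv`:

```console
$ head -3 results/m1/minutes.csv
minute,delta,theta,alpha,beta,gamma,total,n_valid_frames,activity
0,0.101893194,0.07969198,0.059553836,0.076394595,0.68694705,1.0044806,6,5.0
1,0.081219144,0.07392762,0.06013736,0.0749018,0.68224615,0.9724321,6,4.0
```

and `results/m1/summary.json` carries the QC decision and headline
numbers:

```json
{
  "excluded": false,
  "spike_rate_per_class": {"A": 1.0019, "B": 2.3378, "C": 0.6680},
  "spike_total_rate": 4.0077,
  "sleep_bout_count": 15,
  "sleep_mean_bout_min": 12.37,
  "norm_divisor_mv2": 0.0013569
}
```

Whole cohorts run from one YAML config (`eegtel run-all --config
cohort.yaml --out-dir results/`); excluded subjects appear in the QC
table only, never in the pooled cohort tables.  The same pipeline is
available as a library:

```python
from eegtel import SimConfig, simulate_recording, run_pipeline

rec, truth = simulate_recording(SimConfig(rng_seed=7, duration_hours=6))
report = run_pipeline(rec)
print(report.spike_summary.rate_per_class)
```

## Repository layout

```
src/eegtel/        the package: simulate, preprocess, spectral, spikes,
                   sleep, pipeline, recording_io, bands, cli
tests/             unit/property tests + test_acceptance.py (one test per
                   acceptance criterion)
scripts/acceptance.py   seeded end-to-end run reporting headline metrics
analysis/          numbered driver scripts producing the cohort tables in
                   results/
docs/methods.md    methods note (definitions, estimator choices, edge rules)
```

## Reproduction

```sh
pip install --no-build-isolation --no-deps -e .
python -m pytest tests -q                  # full suite, ~1.5 min on 1 CPU
python scripts/acceptance.py --seed 1 --out results/acceptance.json
python analysis/01_run_cohort.py           # 2 groups x 3 subjects, 24 h each
python analysis/02_circadian_profiles.py
python analysis/03_spike_and_sleep_summary.py
```

Everything is deterministic given the seeds; the acceptance script takes
a single `--seed` and derives all sub-seeds from it.
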
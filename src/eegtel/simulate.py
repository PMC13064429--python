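"""Synthetic wireless-telemetry EEG/EMG generator with ground truth.

Emulates multi-day rodent telemetry recordings: a 1/f^alpha pink background
EEG with state-dependent band-limited oscillations (NREM delta, REM theta,
wake gamma), EMG whose variance follows the vigilance state, per-minute
locomotor activity counts tied to wake and the light schedule, injected
epileptiform spike waveforms of three morphologies, and injected
high-amplitude artifacts.  Every injected feature is returned as ground
truth so each downstream stage has an oracle.

The hidden sleep/wake sequence is a semi-Markov chain over
{wake, NREM, REM} on 10 s epochs: geometric dwell times, REM entered only
from NREM, and longer wake dwells in the dark phase so the recording has
the usual nocturnal activity rhythm.

Spike amplitudes are calibrated in multiples of the robust SD of the
simulated background *after* the pipeline's 6.3 Hz spike high-pass: each
template is passed through that filter once and the injection is scaled so
the post-filter peak equals the class amplitude target.  This makes the
ground-truth SNR agree with the SD units the detector measures in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .preprocess import SPIKE_HP_HZ, highpass
from .recording_io import TelemetryRecording

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SpikeTemplateSpec",
    "DEFAULT_SPIKE_CLASSES",
    "simulate_recording",
    "make_spike_template",
    "make_decoy_template",
    "inject_artifacts",
]

EPOCH_S = 10.0

# Oscillation carrier frequencies per band (Hz); chosen at gridpoints of the
# 2 Hz spectral resolution so band attribution is clean.
OSC_FREQS = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 40.0}


@dataclass(frozen=True)
class SpikeTemplateSpec:
    """Morphology of one spike class.

    The waveform is a sharp asymmetric lobe (half-cosine rise, flat top,
    half-cosine fall) followed by a shallow slow counter-lobe carrying
    ``counter_frac`` of the main lobe's area with opposite sign, the classic
    spike(-and-wave) silhouette.  ``peak`` is in multiples of the baseline
    SD of the 6.3 Hz high-passed background.
    """

    peak: float
    rise_ms: float
    flat_ms: float
    fall_ms: float
    counter_ms: float = 160.0
    counter_frac: float = 0.6

    @property
    def fwhm_ms(self) -> float:
        """Full width at half maximum of the main lobe."""
        return self.rise_ms / 2.0 + self.flat_ms + self.fall_ms / 2.0


# Class A: high amplitude, quick; B: lower amplitude, slower return to
# baseline; C: lowest admissible amplitude, slowest decay.  The paper-style
# amplitude bands are A >= 20x, B in [12, 20)x, C in [10, 12)x baseline SD.
DEFAULT_SPIKE_CLASSES: dict[str, SpikeTemplateSpec] = {
    "A": SpikeTemplateSpec(peak=24.0, rise_ms=10, flat_ms=4, fall_ms=18),
    "B": SpikeTemplateSpec(peak=15.5, rise_ms=8, flat_ms=14, fall_ms=36),
    "C": SpikeTemplateSpec(peak=10.8, rise_ms=8, flat_ms=16, fall_ms=80),
}


@dataclass
class SimConfig:
    """Study conditions for one simulated telemetry recording."""

    duration_hours: float = 24.0
    sampling_rate: float = 500.0
    start_clock_hour: float = 6.0
    light_onset_hour: float = 6.0
    light_offset_hour: float = 18.0

    # EEG background: pink noise, 1/f^alpha, total SD in mV
    spectral_background_exponent: float = 1.0
    noise_sd: float = 0.05

    # state-dependent oscillation amplitudes, mV, per state per band
    state_band_amplitudes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            "wake": {"gamma": 0.04},
            "nrem": {"delta": 0.20},
            "rem": {"theta": 0.10},
        })

    # EMG white-noise SD per state, mV
    emg_state_sd: Mapping[str, float] = field(
        default_factory=lambda: {"wake": 0.08, "nrem": 0.015, "rem": 0.008})

    # locomotor activity, counts/min while awake (scaled by wake fraction)
    activity_rate_light: float = 4.0
    activity_rate_dark: float = 8.0

    # hypnogram semi-Markov parameters (dwell means in 10 s epochs)
    wake_dwell_light: float = 48.0
    wake_dwell_dark: float = 144.0
    nrem_dwell: float = 30.0
    rem_dwell: float = 12.0
    p_nrem_to_rem: float = 0.83
    p_rem_to_nrem: float = 0.30

    # epileptiform spikes, events/h per class
    spike_rates: Mapping[str, float] = field(
        default_factory=lambda: {"A": 1.0, "B": 2.0, "C": 0.5})
    spike_classes: Mapping[str, SpikeTemplateSpec] = field(
        default_factory=lambda: dict(DEFAULT_SPIKE_CLASSES))
    spike_min_separation_s: float = 1.0

    # artifacts
    artifact_rate: float = 1.0  # events/h
    artifact_duration_s: float = 5.0
    artifact_amplitude: float = 3.0  # mV, must exceed the 2 mV cleaning cutoff

    # movement-artifact mode: pink noise scaling with activity, strong
    # enough that delta power rises with locomotion (a QC-failing mouse)
    movement_artifact_mode: bool = False
    movement_noise_sd: float = 0.3  # mV extra SD per sqrt(count)

    rng_seed: int = 0
    subject_id: str = "sim"
    group_label: str = "sim"

    def validate(self) -> None:
        if self.duration_hours * 3600.0 < 600.0:
            raise ValueError("duration must be at least 10 min (one staging cycle)")
        if self.sampling_rate <= 160.0:
            raise ValueError("sampling_rate must exceed 160 Hz to represent the 80 Hz band edge")
        if self.artifact_rate > 0 and self.artifact_amplitude <= 2.0:
            raise ValueError("artifact_amplitude must exceed the 2 mV cleaning cutoff")
        for name, r in {**dict(self.spike_rates), "artifact": self.artifact_rate}.items():
            if r < 0:
                raise ValueError(f"rate {name} must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    state_sequence: np.ndarray  # stage label per 10 s epoch
    spikes: pd.DataFrame  # columns: time_s, cls
    artifact_intervals: list[tuple[float, float]]
    band_power_expectation: dict[str, dict[str, float]]  # state -> band -> mV^2
    filtered_baseline_sd: float  # robust SD of 6.3 Hz-filtered background, mV


# ---------------------------------------------------------------------------
# building blocks

def make_spike_template(class_label: str, sampling_rate: float,
                        spec: SpikeTemplateSpec | None = None) -> np.ndarray:
    """Return the class waveform in units of the nominal baseline SD.

    The main lobe peaks at ``spec.peak`` nominal SD; the counter-lobe is
    scaled to ``counter_frac`` of the main lobe's area.
    """
    if spec is None:
        try:
            spec = DEFAULT_SPIKE_CLASSES[class_label]
        except KeyError:
            raise ValueError(f"unknown spike class {class_label!r}") from None
    fs = sampling_rate
    r = int(round(spec.rise_ms * fs / 1000.0))
    p = int(round(spec.flat_ms * fs / 1000.0))
    d = int(round(spec.fall_ms * fs / 1000.0))
    L = int(round(spec.counter_ms * fs / 1000.0))
    tr = np.arange(r) / max(r, 1)
    td = np.arange(d) / max(d, 1)
    pos = np.concatenate([
        spec.peak * (1 - np.cos(np.pi * tr)) / 2,
        np.full(p, spec.peak),
        spec.peak * (1 + np.cos(np.pi * td)) / 2,
    ])
    if L and spec.counter_frac > 0:
        c = np.sin(np.pi * np.arange(L) / L) ** 2
        counter = -spec.counter_frac * pos.sum() * c / c.sum()
    else:
        counter = np.zeros(0)
    return np.concatenate([pos, counter])


def make_decoy_template(kind: str, sampling_rate: float, peak: float = 15.0) -> np.ndarray:
    """Out-of-range decoy transients for testing the width filter.

    ``narrow``: a ~10 ms Gaussian blip (below the 15 ms floor).
    ``wide``: a ~110 ms 50 Hz burst (above the 70 ms ceiling).
    """
    fs = sampling_rate
    if kind == "narrow":
        t = (np.arange(int(0.02 * fs)) - 0.01 * fs) / fs
        return peak * np.exp(-0.5 * (t / 0.0015) ** 2)
    if kind == "wide":
        n = int(0.13 * fs)
        t = np.arange(n) / fs
        env = np.clip(np.minimum(t, t[-1] - t) / 0.01, 0, 1)  # 10 ms ramps
        return peak * env * np.cos(2 * np.pi * 50.0 * (t - t[n // 2]))
    raise ValueError(f"unknown decoy kind {kind!r}")


def inject_artifacts(eeg: np.ndarray, intervals: list[tuple[float, float]],
                     amplitude: float, sampling_rate: float) -> np.ndarray:
    """Replace samples in *intervals* with saturating excursions > 2 mV.

    The artifact is a slow alternating-sign oscillation whose magnitude
    stays strictly above the 2 mV cleaning cutoff and reaches *amplitude*.
    """
    if amplitude <= 2.0:
        raise ValueError("artifact amplitude must exceed 2 mV to be visible to cleaning")
    out = np.array(eeg, dtype=np.float32, copy=True)
    n = out.size
    floor = 2.0 + 0.025 * (amplitude - 2.0)
    for start_s, end_s in intervals:
        i0 = int(round(start_s * sampling_rate))
        i1 = int(round(end_s * sampling_rate))
        if i0 < 0 or i1 > n or i1 <= i0:
            raise ValueError(f"artifact interval ({start_s}, {end_s}) outside recording")
        t = np.arange(i1 - i0) / sampling_rate
        mag = floor + (amplitude - floor) * 0.5 * (1 + np.sin(2 * np.pi * 1.5 * t))
        sign = np.where((t // 0.5) % 2 == 0, 1.0, -1.0)
        out[i0:i1] = (mag * sign).astype(np.float32)
    return out


def _geometric_dwell(rng: np.random.Generator, mean_epochs: float) -> int:
    return int(rng.geometric(min(1.0, 1.0 / max(mean_epochs, 1.0))))


def _state_sequence(cfg: SimConfig, rng: np.random.Generator, n_epochs: int) -> np.ndarray:
    """Semi-Markov hypnogram: wake -> NREM -> (REM <-> NREM) -> wake."""
    seq = np.empty(n_epochs, dtype="<U4")
    epoch_h = EPOCH_S / 3600.0
    span = (cfg.light_offset_hour - cfg.light_onset_hour) % 24.0
    i = 0
    state = "wake"
    while i < n_epochs:
        if state == "wake":
            zt = ((cfg.start_clock_hour + i * epoch_h) - cfg.light_onset_hour) % 24.0
            mean = cfg.wake_dwell_light if zt < span else cfg.wake_dwell_dark
            nxt = "nrem"
        elif state == "nrem":
            mean = cfg.nrem_dwell
            nxt = "rem" if rng.random() < cfg.p_nrem_to_rem else "wake"
        else:  # rem
            mean = cfg.rem_dwell
            nxt = "nrem" if rng.random() < cfg.p_rem_to_nrem else "wake"
        dwell = _geometric_dwell(rng, mean)
        seq[i:i + dwell] = state
        i += dwell
        state = nxt
    return seq


def _pink_noise(rng: np.random.Generator, n: int, alpha: float, sd: float,
                fs: float, chunk_s: float = 3600.0) -> np.ndarray:
    """1/f^alpha noise of length *n*, generated in hourly chunks by FFT shaping."""
    out = np.empty(n, dtype=np.float32)
    chunk = int(chunk_s * fs)
    pos = 0
    while pos < n:
        m = min(chunk, n - pos)
        white = rng.standard_normal(m)
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(m, d=1.0 / fs)
        shape = np.zeros_like(f)
        shape[1:] = f[1:] ** (-alpha / 2.0)
        x = np.fft.irfft(spec * shape, n=m)
        s = x.std()
        out[pos:pos + m] = (x * (sd / s if s > 0 else 0.0)).astype(np.float32)
        pos += m
    return out


def _smooth_envelope(per_epoch: np.ndarray, samples_per_epoch: int, n: int,
                     fs: float) -> np.ndarray:
    """Per-epoch values upsampled to samples with 1 s cosine smoothing."""
    env = np.repeat(per_epoch, samples_per_epoch)[:n]
    if env.size < n:
        env = np.pad(env, (0, n - env.size), mode="edge")
    win = np.hanning(int(fs) + 1)
    win /= win.sum()
    from scipy.signal import oaconvolve
    return oaconvolve(env, win, mode="same").astype(np.float32)


def _noise_band_fraction(alpha: float, low: float, high: float,
                         f0: float, nyq: float) -> float:
    """Fraction of 1/f^alpha power in [low, high] out of [f0, nyq]."""
    def integral(a: float, b: float) -> float:
        if alpha == 1.0:
            return np.log(b / a)
        return (b ** (1 - alpha) - a ** (1 - alpha)) / (1 - alpha)
    return integral(low, high) / integral(f0, nyq)


# ---------------------------------------------------------------------------
# main entry point

def simulate_recording(config: SimConfig) -> tuple[TelemetryRecording, GroundTruth]:
    """Generate one telemetry recording and its ground truth.

    Identical configs (including the seed) give bit-identical output; each
    randomness source (hypnogram, EEG noise, EMG, activity, spikes,
    artifacts) has its own child seed so switching one feature off leaves
    the others unchanged.
    """
    cfg = config
    cfg.validate()
    fs = cfg.sampling_rate
    duration_s = cfg.duration_hours * 3600.0
    n = int(round(duration_s * fs))
    n_epochs = int(duration_s // EPOCH_S)
    spe = int(round(EPOCH_S * fs))  # samples per epoch
    n_min = int(np.ceil(duration_s / 60.0))

    ss = np.random.SeedSequence(cfg.rng_seed)
    r_state, r_noise, r_phase, r_emg, r_act, r_spk, r_art, r_move = (
        np.random.default_rng(s) for s in ss.spawn(8))

    states = _state_sequence(cfg, r_state, n_epochs)

    # --- EEG background -----------------------------------------------------
    eeg = _pink_noise(r_noise, n, cfg.spectral_background_exponent, cfg.noise_sd, fs)

    t = None
    for band in sorted({b for amps in cfg.state_band_amplitudes.values() for b in amps}):
        freq = OSC_FREQS[band]
        amp_by_state = {s: cfg.state_band_amplitudes.get(s, {}).get(band, 0.0)
                        for s in ("wake", "nrem", "rem")}
        per_epoch = np.array([amp_by_state[s] for s in states], dtype=np.float32)
        if not per_epoch.any():
            continue
        env = _smooth_envelope(per_epoch, spe, n, fs)
        if t is None:
            t = np.arange(n, dtype=np.float64) / fs
        phase = r_phase.uniform(0, 2 * np.pi)
        eeg += (env * np.sin(2 * np.pi * freq * t + phase)).astype(np.float32)

    # --- EMG ----------------------------------------------------------------
    sd_by_state = {s: cfg.emg_state_sd.get(s, 0.0) for s in ("wake", "nrem", "rem")}
    per_epoch_sd = np.array([sd_by_state[s] for s in states], dtype=np.float32)
    emg_env = _smooth_envelope(per_epoch_sd, spe, n, fs)
    emg = (r_emg.standard_normal(n).astype(np.float32) * emg_env)

    # --- activity -----------------------------------------------------------
    epoch_wake = (states == "wake").astype(float)
    activity = np.zeros(n_min)
    epoch_h = EPOCH_S / 3600.0
    span = (cfg.light_offset_hour - cfg.light_onset_hour) % 24.0
    for m in range(n_min):
        e0, e1 = m * 6, min((m + 1) * 6, n_epochs)
        if e1 <= e0:
            activity[m] = 0.0
            continue
        wf = epoch_wake[e0:e1].mean()
        zt = ((cfg.start_clock_hour + m / 60.0) - cfg.light_onset_hour) % 24.0
        rate = cfg.activity_rate_light if zt < span else cfg.activity_rate_dark
        activity[m] = r_act.poisson(rate * wf)

    # --- movement-artifact mode (QC-failing mouse) --------------------------
    if cfg.movement_artifact_mode:
        extra = _pink_noise(r_move, n, 1.0, 1.0, fs)
        per_min_sd = cfg.movement_noise_sd * np.sqrt(activity)
        env = np.repeat(per_min_sd, int(60 * fs))[:n].astype(np.float32)
        if env.size < n:
            env = np.pad(env, (0, n - env.size), mode="edge")
        eeg += extra * env

    # --- spike injection ----------------------------------------------------
    filtered_bg = highpass(eeg, SPIKE_HP_HZ, fs)
    sigma_ref = float(1.4826 * np.median(np.abs(filtered_bg - np.median(filtered_bg))))
    del filtered_bg

    hours = cfg.duration_hours
    spike_rows: list[tuple[float, str]] = []
    placed: list[float] = []
    art_margin = cfg.artifact_duration_s + 1.0

    # artifacts are drawn first so spikes can avoid them
    n_art = r_art.poisson(cfg.artifact_rate * hours)
    art_intervals: list[tuple[float, float]] = []
    for _ in range(n_art):
        for _try in range(200):
            s0 = r_art.uniform(1.0, duration_s - cfg.artifact_duration_s - 1.0)
            iv = (s0, s0 + cfg.artifact_duration_s)
            if all(iv[1] + 1.0 < a or iv[0] - 1.0 > b for a, b in art_intervals):
                art_intervals.append(iv)
                break
    art_intervals.sort()

    for cls, rate in cfg.spike_rates.items():
        if rate <= 0:
            continue
        spec = cfg.spike_classes[cls]
        n_spk = r_spk.poisson(rate * hours)
        for _ in range(n_spk):
            for _try in range(500):
                ts = r_spk.uniform(1.0, duration_s - 1.0)
                if any(abs(ts - p) < cfg.spike_min_separation_s for p in placed):
                    continue
                if any(a - 1.0 < ts < b + 1.0 for a, b in art_intervals):
                    continue
                placed.append(ts)
                spike_rows.append((ts, cls))
                break

    for cls in sorted(set(c for _, c in spike_rows)):
        spec = cfg.spike_classes[cls]
        w = make_spike_template(cls, fs, spec)
        wf = highpass(np.concatenate([np.zeros(2000), w, np.zeros(2000)]), SPIKE_HP_HZ, fs)
        pf = float(np.abs(wf).max())
        wave = (w * (spec.peak * sigma_ref / pf)).astype(np.float32)
        ipk = int(np.argmax(np.abs(w)))
        for ts, c in spike_rows:
            if c != cls:
                continue
            i0 = int(round(ts * fs)) - ipk
            j0, j1 = max(i0, 0), min(i0 + wave.size, n)
            eeg[j0:j1] += wave[j0 - i0:j1 - i0]

    # --- artifacts ----------------------------------------------------------
    if art_intervals:
        eeg = inject_artifacts(eeg, art_intervals, cfg.artifact_amplitude, fs)

    spikes = pd.DataFrame(sorted(spike_rows), columns=["time_s", "cls"])

    # --- expectations -------------------------------------------------------
    from .bands import DEFAULT_BANDS
    f0 = 1.0 / duration_s
    nyq = fs / 2.0
    alpha = cfg.spectral_background_exponent
    expectation: dict[str, dict[str, float]] = {}
    for state in ("wake", "nrem", "rem"):
        per_band: dict[str, float] = {}
        for b in DEFAULT_BANDS:
            noise_p = cfg.noise_sd ** 2 * _noise_band_fraction(alpha, b.low, b.high, f0, nyq)
            amp = cfg.state_band_amplitudes.get(state, {}).get(b.name, 0.0)
            per_band[b.name] = noise_p + amp ** 2 / 2.0
        expectation[state] = per_band

    rec = TelemetryRecording(
        eeg=eeg, emg=emg, activity=activity, sampling_rate=fs,
        start_clock_hour=cfg.start_clock_hour,
        light_onset_hour=cfg.light_onset_hour,
        light_offset_hour=cfg.light_offset_hour,
        subject_id=cfg.subject_id, group_label=cfg.group_label)
    truth = GroundTruth(
        state_sequence=states, spikes=spikes, artifact_intervals=art_intervals,
        band_power_expectation=expectation, filtered_baseline_sd=sigma_ref)
    return rec, truth
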
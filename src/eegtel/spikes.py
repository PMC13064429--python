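"""Epileptiform spike detection, width filtering, and A/B/C classification.

Detection runs on the 6.3 Hz high-passed EEG: candidates are contiguous
excursions with |v| >= k x SD of baseline (k = 10), merged across gaps of
up to 10 ms.  The baseline SD is a robust (median absolute deviation)
estimate over all unmasked samples, insensitive to the sparse spikes
themselves.  Candidates are kept only if their threshold-crossing width
lies in 15-70 ms — a deterministic surrogate for the manual screen that
discards both fast noise blips and slow large-amplitude events.

Each retained event is classified by peak amplitude (in SD units, measured
against a local median baseline) and half-decay time (time from the peak
until the signed excursion last exceeds half the peak):

* **A** — high amplitude (>= 20 SD) and fast decay (<= 15 ms)
* **C** — low amplitude (< 12 SD) and slow decay (>= 30 ms)
* **B** — everything in between

Artifact-masked stretches are excluded both from detection and from the
recording hours used as the rate denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MAD_TO_SD = 1.4826  # consistency factor for Gaussian data

__all__ = [
    "SpikeClassRule",
    "SpikeSummary",
    "estimate_baseline_sd",
    "detect_spikes",
    "filter_by_width",
    "classify_spike",
    "classify_events",
    "spike_rate",
    "match_events",
]


@dataclass(frozen=True)
class SpikeClassRule:
    """Thresholds separating the three spike morphologies."""

    amp_a: float = 20.0  # SD units, lower bound for class A
    amp_b: float = 12.0  # SD units, lower bound for class B
    fast_decay_ms: float = 15.0  # class A must decay at least this fast
    slow_decay_ms: float = 30.0  # class C must decay at least this slowly


@dataclass
class SpikeSummary:
    """Spikes per hour, per class and total, over the unmasked hours."""

    rate_per_class: dict[str, float]
    total_rate: float
    hours_analyzed: float
    n_events: int


def estimate_baseline_sd(filtered_eeg: np.ndarray,
                         mask: np.ndarray | None = None,
                         sampling_rate: float | None = None) -> float:
    """Robust baseline SD (scaled MAD) of the spike-filtered trace, in mV.

    Requires at least one minute of unmasked data when the sampling rate is
    given; raises on an all-masked or constant trace.
    """
    x = np.asarray(filtered_eeg)
    if mask is not None:
        x = x[~np.asarray(mask, dtype=bool)]
    if x.size == 0:
        raise ValueError("no unmasked samples to estimate baseline SD from")
    if sampling_rate is not None and x.size < 60 * sampling_rate:
        raise ValueError("need at least 1 min of unmasked data")
    sd = MAD_TO_SD * float(np.median(np.abs(x - np.median(x))))
    if sd <= 0:
        raise ValueError("degenerate (constant) trace: baseline SD is zero")
    return sd


def detect_spikes(filtered_eeg: np.ndarray, sampling_rate: float, sd: float,
                  k: float = 10.0, merge_gap_ms: float = 10.0,
                  mask: np.ndarray | None = None,
                  baseline_window_ms: float = 400.0,
                  decay_window_ms: float = 300.0,
                  feature_smooth_ms: float = 10.0) -> pd.DataFrame:
    """Threshold detection of spike candidates.

    Returns a DataFrame with one row per candidate: ``peak_time_s``,
    ``amplitude_sd`` (peak height over a local median baseline, in SD
    units), ``width_ms`` (duration of the merged |v| >= k*sd excursion) and
    ``half_decay_ms``.

    Detection (thresholding, merging, width) runs on the raw filtered
    trace; the waveform features used for classification (amplitude,
    half-decay) are measured on a lightly smoothed copy
    (``feature_smooth_ms`` moving average) so a single noise sample riding
    the peak cannot shift an event across a class boundary.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    x = np.asarray(filtered_eeg, dtype=np.float64)
    above = np.abs(x) >= k * sd
    if mask is not None:
        above &= ~np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(above)
    cols = ["peak_time_s", "amplitude_sd", "width_ms", "half_decay_ms", "peak_index"]
    if idx.size == 0:
        return pd.DataFrame(columns=cols)

    gap = max(1, int(round(merge_gap_ms / 1000.0 * sampling_rate)))
    brk = np.flatnonzero(np.diff(idx) > gap)
    segments = np.split(idx, brk + 1)

    n_sm = max(1, int(round(feature_smooth_ms / 1000.0 * sampling_rate)) | 1)
    if n_sm > 1:
        from scipy.signal import oaconvolve
        xs = oaconvolve(x, np.full(n_sm, 1.0 / n_sm), mode="same")
    else:
        xs = x

    half_bw = int(round(baseline_window_ms / 1000.0 * sampling_rate / 2))
    n_decay = int(round(decay_window_ms / 1000.0 * sampling_rate))
    rows = []
    for seg in segments:
        i0, i1 = int(seg[0]), int(seg[-1])
        mid = (i0 + i1) // 2
        w0, w1 = max(0, mid - half_bw), min(x.size, mid + half_bw)
        base = float(np.median(xs[w0:w1]))
        # sign of the event = sign at the crossing midpoint; amplitude and
        # peak are the largest excursion in that direction, so a brief
        # opposite-sign edge transient cannot hijack the measurement
        sgn = 1.0 if xs[mid] >= base else -1.0
        exc = sgn * (xs[i0:i1 + 1] - base)
        ipk = i0 + int(np.argmax(exc))
        amp_mv = sgn * float(exc.max())
        amp = abs(amp_mv) / sd
        rel = sgn * (xs[mid:min(x.size, mid + n_decay)] - base)
        below = rel < abs(amp_mv) / 2.0
        # half-decay: first sustained (>= smoothing span) drop below half-peak,
        # so momentary noise dips and late rebounds do not move the estimate
        runs = np.convolve(below.astype(np.int32), np.ones(n_sm, dtype=np.int32),
                           mode="valid")
        sustained = np.flatnonzero(runs == n_sm)
        hd_ms = (sustained[0] if sustained.size else below.size) \
            / sampling_rate * 1000.0
        rows.append(dict(
            peak_time_s=ipk / sampling_rate,
            amplitude_sd=amp,
            width_ms=(i1 - i0 + 1) / sampling_rate * 1000.0,
            half_decay_ms=hd_ms,
            peak_index=ipk))
    return pd.DataFrame(rows, columns=cols)


def filter_by_width(candidates: pd.DataFrame,
                    min_ms: float = 15.0, max_ms: float = 70.0) -> pd.DataFrame:
    """Keep only candidates whose threshold-crossing width is in [min, max] ms."""
    keep = (candidates["width_ms"] >= min_ms) & (candidates["width_ms"] <= max_ms)
    return candidates[keep].reset_index(drop=True)


def classify_spike(amplitude_sd: float, half_decay_ms: float,
                   rule: SpikeClassRule = SpikeClassRule()) -> str:
    """Assign one of the A/B/C morphological classes."""
    if amplitude_sd >= rule.amp_a and half_decay_ms <= rule.fast_decay_ms:
        return "A"
    if amplitude_sd < rule.amp_b and half_decay_ms >= rule.slow_decay_ms:
        return "C"
    return "B"


def classify_events(events: pd.DataFrame,
                    rule: SpikeClassRule = SpikeClassRule()) -> pd.DataFrame:
    """Vectorized classification; adds a ``cls`` column."""
    out = events.copy()
    out["cls"] = [classify_spike(a, h, rule)
                  for a, h in zip(events["amplitude_sd"], events["half_decay_ms"])]
    return out


def spike_rate(events: pd.DataFrame, analyzed_hours: float,
               masked_hours: float = 0.0,
               classes: tuple[str, ...] = ("A", "B", "C")) -> SpikeSummary:
    """Spikes per hour over the unmasked analyzed time."""
    hours = analyzed_hours - masked_hours
    if hours <= 0:
        raise ValueError("no unmasked recording time")
    per_class = {c: float((events["cls"] == c).sum()) / hours if "cls" in events else 0.0
                 for c in classes}
    return SpikeSummary(rate_per_class=per_class,
                        total_rate=float(len(events)) / hours,
                        hours_analyzed=hours, n_events=int(len(events)))


def match_events(detected_times: np.ndarray, truth_times: np.ndarray,
                 tol_s: float = 0.025) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of detected to true event times.

    Pairs are formed in order of increasing time difference; each detected
    and each true event is used at most once.  Returns (detected_idx,
    truth_idx) pairs.
    """
    det = np.asarray(detected_times, dtype=float)
    tru = np.asarray(truth_times, dtype=float)
    cand = [(abs(d - t), i, j) for i, d in enumerate(det)
            for j, t in enumerate(tru) if abs(d - t) <= tol_s]
    cand.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    pairs = []
    for _, i, j in cand:
        if i in used_d or j in used_t:
            continue
        used_d.add(i)
        used_t.add(j)
        pairs.append((i, j))
    return pairs
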
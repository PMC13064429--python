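"""Artifact rejection and high-pass filtering.

Two filtering regimes feed the downstream branches, always from the same
raw trace: a 0.5 Hz high-pass for the spectral branch and a 6.3 Hz
high-pass for the spike branch.  Both are zero-phase FIR filters (symmetric
impulse response applied with centred FFT convolution, so the linear phase
cancels exactly) — zero phase preserves spike timing and epoch alignment.

Artifact rejection masks every sample whose absolute voltage reaches the
cutoff (±2 mV by default), plus a symmetric pad to absorb filter ringing
around the clipped excursion.  Masked samples are *excluded* from
downstream aggregation, never interpolated or zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal

__all__ = [
    "ArtifactMask",
    "remove_artifacts",
    "highpass",
    "mask_to_intervals",
    "SPECTRAL_HP_HZ",
    "SPIKE_HP_HZ",
]

SPECTRAL_HP_HZ = 0.5
SPIKE_HP_HZ = 6.3


@dataclass
class ArtifactMask:
    """Per-sample artifact rejection mask (True = rejected)."""

    mask: np.ndarray  # bool, same length as the trace
    cutoff: float  # mV

    @property
    def fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


def remove_artifacts(eeg: np.ndarray, sampling_rate: float,
                     cutoff: float = 2.0,
                     pad_ms: float = 100.0) -> tuple[np.ndarray, ArtifactMask]:
    """Mask high-amplitude artifacts (|v| >= cutoff mV) with a symmetric pad.

    Returns the input trace unchanged (exclusion happens downstream via the
    mask) together with the ArtifactMask.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    eeg = np.asarray(eeg)
    if eeg.size == 0:
        return eeg, ArtifactMask(np.zeros(0, dtype=bool), cutoff)
    hit = np.abs(eeg) >= cutoff
    pad = int(round(pad_ms / 1000.0 * sampling_rate))
    if pad > 0 and hit.any():
        # dilate the hit mask by `pad` samples on each side
        kernel = np.ones(2 * pad + 1, dtype=np.uint8)
        mask = np.convolve(hit.astype(np.uint8), kernel, mode="same") > 0
    else:
        mask = hit
    return eeg, ArtifactMask(mask, cutoff)


@lru_cache(maxsize=16)
def _hp_taps(cutoff: float, sampling_rate: float) -> np.ndarray:
    """Design a linear-phase FIR high-pass (Hamming window method).

    The transition band is cutoff/2 .. cutoff so the stopband (>= 40 dB
    attenuation with a Hamming window) covers DC up to half the cutoff and
    the passband ripple above 2x the cutoff is well under 1 dB.
    """
    nyq = sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValueError(f"cutoff must lie in (0, {nyq}) Hz")
    transition = cutoff / 2.0  # Hz, from cutoff/2 to cutoff
    numtaps = int(np.ceil(3.3 * sampling_rate / transition))
    if numtaps % 2 == 0:
        numtaps += 1  # odd length -> Type I, valid high-pass
    return signal.firwin(numtaps, (cutoff / 2.0 + cutoff) / 2.0,
                         width=transition, pass_zero=False, fs=sampling_rate)


def highpass(x: np.ndarray, cutoff: float, sampling_rate: float) -> np.ndarray:
    """Zero-phase FIR high-pass of *x* at *cutoff* Hz.

    The symmetric FIR kernel is applied once with centred overlap-add FFT
    convolution; symmetry makes the result zero-phase without a
    forward-backward pass, which matters on multi-hour traces.
    """
    taps = _hp_taps(float(cutoff), float(sampling_rate))
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        return x.astype(np.float32)
    # reflect-pad so the edge transient does not wrap content
    half = len(taps) // 2
    pad = min(half, x.size - 1)
    if pad > 0:
        xp = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    else:
        xp = x
    y = signal.oaconvolve(xp, taps, mode="same")
    if pad > 0:
        y = y[pad:pad + x.size]
    return y.astype(np.float32)


def mask_to_intervals(mask: np.ndarray, sampling_rate: float) -> list[tuple[float, float]]:
    """Convert a boolean sample mask to a list of (start_s, end_s) intervals."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0 or not m.any():
        return []
    d = np.diff(m.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if m[0]:
        starts = np.r_[0, starts]
    if m[-1]:
        ends = np.r_[ends, m.size]
    return [(s / sampling_rate, e / sampling_rate) for s, e in zip(starts, ends)]
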
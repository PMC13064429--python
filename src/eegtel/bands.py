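"""Frequency band definitions for rodent cortical EEG.

The analysis range is 0.5–80 Hz and the named bands must tile it exactly
(contiguous, non-overlapping) so that per-band powers sum to the total and
percent-of-total contributions sum to 100.  Edges follow rodent EEG
convention: delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–80 Hz.
Each band is a half-open interval [low, high) except the last, which is
closed at the top so 80 Hz itself is counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["BandDefinition", "DEFAULT_BANDS", "validate_bands", "band_masks"]

FMIN = 0.5
FMAX = 80.0


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with [low, high) edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name!r}: low must be < high")


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
)


def validate_bands(bands: Sequence[BandDefinition],
                   fmin: float = FMIN, fmax: float = FMAX) -> None:
    """Check that *bands* tile [fmin, fmax] exactly.

    Raises ValueError on gaps, overlaps, or mismatched outer edges.
    """
    if not bands:
        raise ValueError("no bands given")
    ordered = sorted(bands, key=lambda b: b.low)
    if not np.isclose(ordered[0].low, fmin):
        raise ValueError(f"bands must start at {fmin} Hz, got {ordered[0].low}")
    if not np.isclose(ordered[-1].high, fmax):
        raise ValueError(f"bands must end at {fmax} Hz, got {ordered[-1].high}")
    for a, b in zip(ordered[:-1], ordered[1:]):
        if not np.isclose(a.high, b.low):
            raise ValueError(f"bands {a.name!r} and {b.name!r} do not abut")


def band_masks(freqs: np.ndarray,
               bands: Sequence[BandDefinition] = DEFAULT_BANDS,
               fmin: float = FMIN, fmax: float = FMAX) -> dict[str, np.ndarray]:
    """Boolean mask per band over frequency gridpoints.

    A gridpoint belongs to the band whose [low, high) interval contains it;
    the top edge of the last band is inclusive.  Gridpoints outside
    [fmin, fmax] belong to no band.
    """
    validate_bands(bands, fmin, fmax)
    ordered = sorted(bands, key=lambda b: b.low)
    masks: dict[str, np.ndarray] = {}
    for i, b in enumerate(ordered):
        m = (freqs >= b.low) & (freqs < b.high)
        if i == len(ordered) - 1:
            m |= np.isclose(freqs, b.high)
        masks[b.name] = m
    return masks
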
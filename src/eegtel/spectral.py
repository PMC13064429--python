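"""Spectral power pipeline.

The spectrogram is computed from the 0.5 Hz high-passed EEG in 10 s bins:
power spectra of consecutive 500 ms windows (20 per bin, non-overlapping,
rectangular taper by default) are reduced to the per-frequency *median*
across windows, which suppresses transient contamination affecting a
minority of windows.  Band powers integrate the median density over the
named bands (which tile 0.5-80 Hz, so band powers sum to the total by
construction), are averaged per minute, normalized to the 10th percentile
of each subject's per-minute total power, and summarized as circadian
hourly profiles, percent-of-total distributions, and per-band ordinary
least squares regressions of raw power on locomotor activity.  A positive
delta-vs-activity slope flags a quality-control failure (movement noise):
delta power should fall, not rise, with locomotion.

Windows containing any artifact-masked sample are excluded from the
median; a bin with more than 50% of its windows excluded is invalid, and a
minute with no valid bin is missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bands import DEFAULT_BANDS, FMAX, FMIN, BandDefinition, band_masks

__all__ = [
    "SpectralFrames",
    "window_band_psd",
    "spectrogram_median_bins",
    "minute_band_power",
    "normalize_to_tenth_percentile",
    "hourly_profile",
    "percent_total_power",
    "band_activity_regression",
    "activity_binned_power",
    "qc_delta_activity",
    "BAND_NAMES",
]

BAND_NAMES = [b.name for b in DEFAULT_BANDS]


@dataclass
class SpectralFrames:
    """Median power spectra in 10 s bins over the analysis range."""

    times: np.ndarray  # bin start, s
    freqs: np.ndarray  # Hz
    psd: np.ndarray  # (n_bins, n_freqs) median density, mV^2/Hz; NaN if invalid
    valid: np.ndarray  # bool per bin
    bin_s: float = 10.0

    @property
    def df_hz(self) -> float:
        return float(self.freqs[1] - self.freqs[0]) if self.freqs.size > 1 else 1.0


def window_band_psd(eeg: np.ndarray, sampling_rate: float,
                    window_ms: float = 500.0,
                    fmin: float = FMIN, fmax: float = FMAX,
                    taper: str = "boxcar",
                    mask: np.ndarray | None = None,
                    chunk_windows: int = 7200,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-sided PSD of consecutive non-overlapping windows.

    Returns ``(freqs, psd, valid)`` where ``psd`` is (n_windows, n_freqs)
    in mV^2/Hz restricted to [fmin, fmax] and ``valid`` marks windows free
    of masked samples.  The default taper is rectangular so that tones on
    the 1/window frequency grid do not leak into neighbouring bands; a
    Hann taper is available for off-grid content.
    """
    fs = sampling_rate
    nper = int(round(window_ms / 1000.0 * fs))
    if nper < 2:
        raise ValueError("window too short")
    if fmax >= fs / 2.0:
        raise ValueError("fmax must be below the Nyquist frequency")
    n_win = eeg.size // nper
    if n_win == 0:
        raise ValueError("recording shorter than one analysis window")

    freqs = np.fft.rfftfreq(nper, d=1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    freqs_out = freqs[sel]

    if taper == "boxcar":
        win = np.ones(nper)
    elif taper == "hann":
        win = np.hanning(nper)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    scale = 2.0 / (fs * (win ** 2).sum())

    psd = np.empty((n_win, freqs_out.size), dtype=np.float32)
    for c0 in range(0, n_win, chunk_windows):
        c1 = min(c0 + chunk_windows, n_win)
        block = np.asarray(eeg[c0 * nper:c1 * nper], dtype=np.float64)
        block = block.reshape(c1 - c0, nper) * win
        spec = np.fft.rfft(block, axis=1)
        p = (np.abs(spec) ** 2) * scale
        psd[c0:c1] = p[:, sel].astype(np.float32)

    if mask is not None:
        m = np.asarray(mask[:n_win * nper], dtype=bool).reshape(n_win, nper)
        valid = ~m.any(axis=1)
    else:
        valid = np.ones(n_win, dtype=bool)
    return freqs_out, psd, valid


def spectrogram_median_bins(eeg: np.ndarray, sampling_rate: float,
                            window_ms: float = 500.0, bin_s: float = 10.0,
                            fmin: float = FMIN, fmax: float = FMAX,
                            taper: str = "boxcar",
                            mask: np.ndarray | None = None) -> SpectralFrames:
    """Median-across-windows power spectrum per 10 s bin.

    A bin is invalid (NaN spectrum) when more than half of its windows
    contain artifact-masked samples.
    """
    win_per_bin = bin_s * 1000.0 / window_ms
    if abs(win_per_bin - round(win_per_bin)) > 1e-9 or win_per_bin < 2:
        raise ValueError("window must divide the bin at least 2 times")
    wpb = int(round(win_per_bin))
    freqs, psd, wvalid = window_band_psd(
        eeg, sampling_rate, window_ms, fmin, fmax, taper, mask)
    n_bins = psd.shape[0] // wpb
    if n_bins == 0:
        raise ValueError("recording shorter than one spectral bin")

    out = np.full((n_bins, freqs.size), np.nan, dtype=np.float32)
    valid = np.zeros(n_bins, dtype=bool)
    pb = psd[:n_bins * wpb].reshape(n_bins, wpb, freqs.size)
    vb = wvalid[:n_bins * wpb].reshape(n_bins, wpb)
    n_ok = vb.sum(axis=1)
    # fast path: bins with all windows valid
    full = n_ok == wpb
    if full.any():
        out[full] = np.median(pb[full], axis=1)
    partial = (~full) & (n_ok >= wpb / 2.0)
    for i in np.flatnonzero(partial):
        out[i] = np.median(pb[i][vb[i]], axis=0)
    valid = n_ok >= wpb / 2.0
    times = np.arange(n_bins) * bin_s
    return SpectralFrames(times=times, freqs=freqs, psd=out, valid=valid, bin_s=bin_s)


def _frame_band_powers(frames: SpectralFrames,
                       bands: Sequence[BandDefinition]) -> pd.DataFrame:
    masks = band_masks(frames.freqs, bands)
    df = pd.DataFrame({"time_s": frames.times})
    for name, m in masks.items():
        df[name] = frames.psd[:, m].sum(axis=1) * frames.df_hz
    df["total"] = sum(df[n] for n in masks)
    df.loc[~frames.valid, list(masks) + ["total"]] = np.nan
    return df


def minute_band_power(frames: SpectralFrames,
                      bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                      activity: np.ndarray | None = None) -> pd.DataFrame:
    """Per-minute band power (mV^2) paired with that minute's activity count.

    Band power integrates the median density over each band per frame; the
    minute value is the mean over its valid frames (nominally 6).  Minutes
    with no valid frame are missing (NaN).
    """
    per_frame = _frame_band_powers(frames, bands)
    minute = (per_frame["time_s"] // 60).astype(int)
    cols = [b.name for b in bands] + ["total"]
    g = per_frame.groupby(minute)[cols]
    out = g.mean()
    out["n_valid_frames"] = per_frame[cols[0]].notna().groupby(minute).sum()
    out.loc[out["n_valid_frames"] == 0, cols] = np.nan
    out.index.name = "minute"
    out = out.reset_index()
    if activity is not None:
        act = np.asarray(activity, dtype=float)
        out["activity"] = [act[m] if m < act.size else np.nan for m in out["minute"]]
    return out


def normalize_to_tenth_percentile(minutes: pd.DataFrame,
                                  bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                                  ) -> tuple[pd.DataFrame, float]:
    """Divide band and total power by the 10th percentile of total power.

    The percentile uses linear interpolation between order statistics.
    Returns the normalized table and the divisor.  After normalization the
    10th percentile of per-minute total power is exactly 1.
    """
    cols = [b.name for b in bands] + ["total"]
    tot = minutes["total"].dropna()
    if tot.size < 10:
        raise ValueError("need at least 10 non-missing minutes to normalize")
    q = float(np.percentile(tot, 10.0))
    if q <= 0:
        raise ValueError("10th percentile of total power is zero (degenerate recording)")
    out = minutes.copy()
    out[cols] = out[cols] / q
    return out, q


def hourly_profile(minutes: pd.DataFrame, start_clock_hour: float,
                   light_onset_hour: float,
                   bands: Sequence[BandDefinition] = DEFAULT_BANDS) -> pd.DataFrame:
    """Mean power per zeitgeber hour (ZT0 = light onset), averaged across days."""
    n_min = int(minutes["minute"].max()) + 1
    if n_min < 24 * 60:
        raise ValueError("hourly profile requires at least 24 h of data")
    cols = [b.name for b in bands] + ["total"]
    clock = (start_clock_hour + minutes["minute"] / 60.0) % 24.0
    zt = np.floor((clock - light_onset_hour) % 24.0).astype(int)
    prof = minutes[cols].groupby(zt).mean()
    prof.index.name = "zt_hour"
    return prof.reset_index()


def percent_total_power(minutes: pd.DataFrame,
                        bands: Sequence[BandDefinition] = DEFAULT_BANDS) -> pd.DataFrame:
    """Per-minute band power as percent of that minute's total (sums to 100)."""
    if minutes["total"].dropna().empty:
        raise ValueError("no non-missing minutes")
    out = minutes[["minute"]].copy()
    for b in bands:
        out[b.name] = minutes[b.name] / minutes["total"] * 100.0
    return out


def band_activity_regression(minutes: pd.DataFrame,
                             bands: Sequence[BandDefinition] = DEFAULT_BANDS,
                             ) -> pd.DataFrame:
    """OLS of per-minute raw band power on activity count, one row per band."""
    rows = []
    for b in bands:
        sub = minutes[[b.name, "activity"]].dropna()
        act = sub["activity"].to_numpy()
        ok = sub.shape[0] >= 2 and np.unique(act).size >= 2
        if ok:
            res = stats.linregress(act, sub[b.name].to_numpy())
            rows.append(dict(band=b.name, slope=res.slope, intercept=res.intercept,
                             r_squared=res.rvalue ** 2, n_minutes=sub.shape[0],
                             slope_se=res.stderr, defined=True))
        else:
            rows.append(dict(band=b.name, slope=np.nan, intercept=np.nan,
                             r_squared=np.nan, n_minutes=sub.shape[0],
                             slope_se=np.nan, defined=False))
    return pd.DataFrame(rows)


def activity_binned_power(minutes: pd.DataFrame, n_levels: int = 11,
                          bands: Sequence[BandDefinition] = DEFAULT_BANDS) -> pd.DataFrame:
    """Mean raw band power per integer activity level 0..n_levels-1.

    Counts at or above the top level are pooled there (level 10 holds all
    minutes with >= 10 counts by default).
    """
    if minutes.empty:
        raise ValueError("empty minute series")
    sub = minutes.dropna(subset=["activity", "total"])
    level = np.minimum(sub["activity"].astype(int), n_levels - 1)
    cols = [b.name for b in bands]
    out = sub[cols].groupby(level).mean()
    out.index.name = "activity_level"
    return out.reindex(range(n_levels)).reset_index()


def qc_delta_activity(regressions: pd.DataFrame) -> dict:
    """QC rule: exclude a subject whose delta power rises with activity."""
    row = regressions.set_index("band").loc["delta"]
    if not row["defined"]:
        return dict(excluded=False, delta_slope=np.nan,
                    reason="delta regression undefined (constant activity)")
    excluded = bool(row["slope"] > 0)
    return dict(excluded=excluded, delta_slope=float(row["slope"]),
                reason="delta power increases with activity" if excluded else "")
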
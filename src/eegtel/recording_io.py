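"""Telemetry recording container and file I/O.

A recording is a pair of synchronized voltage traces (EEG, EMG, in mV at a
common sampling rate), a per-minute locomotor activity count series, and a
clock/light schedule.  On disk a recording is an EDF file with one EEG and
one EMG channel plus a CSV of per-minute activity counts.

Reading goes through :mod:`mne`'s EDF reader.  Writing uses a minimal
EDF(+) writer implemented here (16-bit samples, 1 s data records), since no
EDF export library is available; the writer is cross-checked against the
mne reader in the test suite.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TelemetryRecording",
    "write_edf",
    "read_recording",
    "write_activity_csv",
    "read_activity_csv",
]


@dataclass
class TelemetryRecording:
    """One subject's synchronized EEG/EMG traces plus activity and schedule.

    Voltages are millivolts; ``activity`` holds one count per minute with
    NaN marking missing minutes (missing is not zero).  Clock times are
    hours; ``start_clock_hour`` is the wall-clock hour at sample 0, and
    lights are on in [light_onset_hour, light_offset_hour).
    """

    eeg: np.ndarray
    emg: np.ndarray
    activity: np.ndarray
    sampling_rate: float
    start_clock_hour: float = 6.0
    light_onset_hour: float = 6.0
    light_offset_hour: float = 18.0
    subject_id: str = "subject"
    group_label: str = ""

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float32)
        self.emg = np.asarray(self.emg, dtype=np.float32)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.eeg.shape != self.emg.shape:
            raise ValueError("eeg and emg must have equal length")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        n_min = int(np.ceil(self.eeg.size / self.sampling_rate / 60.0))
        if self.activity.size != n_min:
            raise ValueError(
                f"activity length {self.activity.size} != ceil(duration/60 s) = {n_min}")

    @property
    def duration_s(self) -> float:
        return self.eeg.size / self.sampling_rate

    @property
    def n_epochs(self) -> int:
        """Number of complete 10 s scoring epochs."""
        return int(self.duration_s // 10)

    def zt_hours(self, t_s: np.ndarray) -> np.ndarray:
        """Zeitgeber time (hours since light onset, mod 24) at seconds *t_s*."""
        clock = (self.start_clock_hour + np.asarray(t_s) / 3600.0) % 24.0
        return (clock - self.light_onset_hour) % 24.0

    def is_light(self, t_s: np.ndarray) -> np.ndarray:
        """True where the lights are on at seconds *t_s* from start."""
        span = (self.light_offset_hour - self.light_onset_hour) % 24.0
        return self.zt_hours(t_s) < span


# ---------------------------------------------------------------------------
# EDF writing (minimal EDF, 16-bit, 1 s data records)

def _pad(text: str, n: int) -> bytes:
    b = text.encode("ascii")[:n]
    return b + b" " * (n - len(b))


def write_edf(path: str | Path, rec: TelemetryRecording) -> None:
    """Write the EEG/EMG traces of *rec* as a two-channel EDF file.

    Samples are stored as 16-bit integers scaled to each channel's physical
    range; the physical dimension is mV.  The trace is truncated to a whole
    number of 1 s records (EDF requirement).
    """
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record per channel
    n_rec = int(rec.eeg.size // spr)
    if n_rec == 0:
        raise ValueError("recording shorter than one 1 s EDF record")

    chans = [("EEG", rec.eeg[:n_rec * spr]), ("EMG", rec.emg[:n_rec * spr])]
    ns = len(chans)
    header_bytes = 256 * (1 + ns)

    start_h = int(rec.start_clock_hour) % 24
    start_m = int(round((rec.start_clock_hour % 1.0) * 60)) % 60

    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(f"{rec.subject_id} {rec.group_label}".strip() or "X", 80))
        f.write(_pad("Startdate X", 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad(f"{start_h:02d}.{start_m:02d}.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("", 44))
        f.write(_pad(str(n_rec), 8))
        f.write(_pad("1", 8))  # record duration, s
        f.write(_pad(str(ns), 4))

        phys_min, phys_max, dig_min, dig_max = [], [], [], []
        scaled = []
        for _, x in chans:
            amax = float(np.abs(x).max()) if x.size else 1.0
            amax = max(amax, 1e-6) * 1.0001
            # round the range to what the 8-byte header field can hold and
            # scale with the *stored* value, so reader and writer agree
            for prec in range(6, 1, -1):
                s = f"{amax:.{prec}g}"
                if len(s) + 1 <= 8:
                    break
            amax = float(s)
            phys_min.append(-amax)
            phys_max.append(amax)
            dig_min.append(-32768)
            dig_max.append(32767)
            scaled.append(np.clip(np.round(x / amax * 32767), -32768, 32767)
                          .astype("<i2"))

        for name, _ in chans:
            f.write(_pad(name, 16))
        for _ in chans:
            f.write(_pad("telemetry", 80))
        for _ in chans:
            f.write(_pad("mV", 8))
        for v in phys_min:
            f.write(_pad(f"{v:.6g}", 8))
        for v in phys_max:
            f.write(_pad(f"{v:.6g}", 8))
        for v in dig_min:
            f.write(_pad(str(v), 8))
        for v in dig_max:
            f.write(_pad(str(v), 8))
        for _ in chans:
            f.write(_pad("", 80))  # prefiltering
        for _ in chans:
            f.write(_pad(str(spr), 8))
        for _ in chans:
            f.write(_pad("", 32))

        for r in range(n_rec):
            for x in scaled:
                f.write(x[r * spr:(r + 1) * spr].tobytes())


# ---------------------------------------------------------------------------
# Reading

def read_recording(edf_path: str | Path,
                   activity_path: str | Path | None = None,
                   eeg_channel: str = "EEG",
                   emg_channel: str = "EMG",
                   start_clock_hour: float | None = None,
                   light_onset_hour: float = 6.0,
                   light_offset_hour: float = 18.0,
                   subject_id: str | None = None,
                   group_label: str = "",
                   expected_sampling_rate: float | None = None,
                   ) -> TelemetryRecording:
    """Load an EDF (EEG + EMG) and optional activity CSV into a recording.

    Channel labels are configurable; a missing channel raises a ValueError
    naming it.  Voltages are coerced to mV regardless of the EDF's declared
    unit.  If *start_clock_hour* is None it is taken from the EDF start
    time.
    """
    import mne

    raw = mne.io.read_raw_edf(str(edf_path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if expected_sampling_rate is not None and not np.isclose(fs, expected_sampling_rate):
        raise ValueError(
            f"sampling rate {fs} Hz does not match configured {expected_sampling_rate} Hz")

    chan_map = {name.strip().upper(): name for name in raw.ch_names}
    traces = {}
    for want in (eeg_channel, emg_channel):
        key = want.strip().upper()
        if key not in chan_map:
            raise ValueError(
                f"channel {want!r} not found in {edf_path} (has {raw.ch_names})")
        data = raw.get_data(picks=[chan_map[key]])[0]
        traces[want] = data * 1e3  # mne returns volts -> mV

    if start_clock_hour is None:
        meas = raw.info.get("meas_date")
        start_clock_hour = (meas.hour + meas.minute / 60.0) if meas else 0.0

    n = traces[eeg_channel].size
    n_min = int(np.ceil(n / fs / 60.0))
    if activity_path is not None:
        activity = read_activity_csv(activity_path, n_min)
    else:
        activity = np.full(n_min, np.nan)

    return TelemetryRecording(
        eeg=traces[eeg_channel], emg=traces[emg_channel], activity=activity,
        sampling_rate=fs, start_clock_hour=float(start_clock_hour),
        light_onset_hour=light_onset_hour, light_offset_hour=light_offset_hour,
        subject_id=subject_id or Path(edf_path).stem, group_label=group_label)


def write_activity_csv(path: str | Path, activity: np.ndarray) -> None:
    """Write per-minute activity counts as a two-column CSV."""
    df = pd.DataFrame({"minute": np.arange(len(activity)),
                       "activity_count": activity})
    df.to_csv(path, index=False)


def read_activity_csv(path: str | Path, n_minutes: int) -> np.ndarray:
    """Read per-minute activity counts; minutes absent from the file are NaN."""
    df = pd.read_csv(path)
    if not {"minute", "activity_count"} <= set(df.columns):
        raise ValueError("activity CSV needs columns: minute, activity_count")
    out = np.full(n_minutes, np.nan)
    idx = df["minute"].to_numpy(dtype=int)
    ok = (idx >= 0) & (idx < n_minutes)
    out[idx[ok]] = df["activity_count"].to_numpy(dtype=float)[ok]
    return out
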
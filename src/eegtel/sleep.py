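"""Rule-based sleep staging on 10 s epochs.

A deterministic surrogate for manual wake/NREM/REM scoring.  The
qualitative scoring criteria map onto quantitative features: slow-wave
dominance becomes the delta fraction of EEG power, REM's medium-wave
activity becomes the theta/delta ratio, and muscle tone becomes the EMG
RMS z-scored against the recording's quiet (sleep-candidate) floor.  The
locomotor activity channel defines wake: any count in the containing
minute marks its epochs as awake.

Scoring runs at 1 s subepoch resolution and each 10 s epoch receives the
stage occupying most of its subepochs (ties broken by the precedence
artifact > wake > NREM > REM).  Per subepoch the ordered rule is:

1. artifact, if the artifact-masked fraction reaches 0.5 (0.8 for
   wake-candidate subepochs — only large artifacts are scored during wake);
2. wake, if activity > 0 or EMG z >= z_wake;
3. NREM, if delta fraction >= delta_min and EMG z <= z_sleep;
4. REM, if theta/delta >= ratio_min and EMG z <= z_sleep;
5. otherwise the previous subepoch's stage (wake at the start).

Recordings whose scored span contains >= 5% artifact epochs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bands import DEFAULT_BANDS, band_masks
from .recording_io import TelemetryRecording
from .spectral import window_band_psd

__all__ = [
    "StageThresholds",
    "SleepSummary",
    "subepoch_features",
    "epoch_features",
    "score_subepochs",
    "majority_stage",
    "stage_epochs",
    "artifact_exclusion",
    "sleep_summary",
]

EPOCH_S = 10
SUB_S = 1  # subepoch resolution, s
STAGE_PRECEDENCE = ("artifact", "wake", "nrem", "rem")


@dataclass(frozen=True)
class StageThresholds:
    """Decision thresholds of the staging rule (unitless features)."""

    delta_min: float = 0.4  # min delta fraction for NREM
    ratio_min: float = 1.5  # min theta/delta ratio for REM
    z_wake: float = 1.0  # EMG z at or above which a subepoch is wake
    z_sleep: float = 0.5  # max EMG z compatible with sleep
    artifact_sleep: float = 0.5  # artifact fraction labelling a sleep candidate
    artifact_wake: float = 0.8  # artifact fraction labelling a wake candidate


@dataclass
class SleepSummary:
    """Stage occupancy, bout structure, and per-stage spectra."""

    percent_time: pd.DataFrame  # rows: day/night/24h, columns: stages
    bout_count: int
    mean_bout_min: float
    artifact_fraction: float
    excluded: bool
    stage_spectra: pd.DataFrame  # mean PSD per stage (freq x stage)


def subepoch_features(recording: TelemetryRecording,
                      eeg_spectral: np.ndarray,
                      mask: np.ndarray | None = None) -> pd.DataFrame:
    """Per-1 s features: delta fraction, theta/delta, EMG z, activity, artifact.

    *eeg_spectral* is the 0.5 Hz high-passed EEG; band powers come from
    the same 500 ms window spectra the spectral branch uses (two windows
    per subepoch).  The EMG z-score is computed against the quiet floor:
    the mean and SD of subepoch RMS over the quietest half of the
    recording, so wake muscle tone stands far above zero while REM atonia
    sits at or below it.
    """
    fs = recording.sampling_rate
    freqs, psd, wvalid = window_band_psd(eeg_spectral, fs, mask=mask)
    wps = int(round(SUB_S / 0.5))  # windows per subepoch
    n_sub = psd.shape[0] // wps
    masks = band_masks(freqs, DEFAULT_BANDS)
    df_hz = float(freqs[1] - freqs[0])

    p = psd[:n_sub * wps].reshape(n_sub, wps, -1)
    v = wvalid[:n_sub * wps].reshape(n_sub, wps)
    with np.errstate(invalid="ignore"):
        mean_psd = p.mean(axis=1)
    delta = mean_psd[:, masks["delta"]].sum(axis=1) * df_hz
    theta = mean_psd[:, masks["theta"]].sum(axis=1) * df_hz
    total = mean_psd.sum(axis=1) * df_hz

    spb = int(round(SUB_S * fs))
    emg = np.asarray(recording.emg[:n_sub * spb], dtype=np.float64).reshape(n_sub, spb)
    emg_rms = np.sqrt((emg ** 2).mean(axis=1))
    quiet = emg_rms <= np.median(emg_rms)
    mu, sigma = emg_rms[quiet].mean(), emg_rms[quiet].std()
    sigma = sigma if sigma > 0 else max(mu, 1e-12)
    emg_z = (emg_rms - mu) / sigma

    minute = (np.arange(n_sub) * SUB_S) // 60
    act = np.asarray(recording.activity, dtype=float)
    sub_act = np.where(minute < act.size, np.nan_to_num(act[np.minimum(minute, act.size - 1)]), 0.0)

    if mask is not None:
        m = np.asarray(mask[:n_sub * spb], dtype=bool).reshape(n_sub, spb)
        art_frac = m.mean(axis=1)
    else:
        art_frac = np.zeros(n_sub)

    eps = np.finfo(float).tiny
    return pd.DataFrame({
        "sub_index": np.arange(n_sub),
        "delta_fraction": delta / np.maximum(total, eps),
        "theta_delta_ratio": theta / np.maximum(delta, eps),
        "emg_z": emg_z,
        "activity": sub_act,
        "artifact_fraction": art_frac,
        "spectra_valid": v.any(axis=1),
    })


def epoch_features(recording: TelemetryRecording, eeg_spectral: np.ndarray,
                   mask: np.ndarray | None = None) -> pd.DataFrame:
    """10 s epoch-level aggregate of the subepoch features."""
    sub = subepoch_features(recording, eeg_spectral, mask)
    epoch = sub["sub_index"] // (EPOCH_S // SUB_S)
    agg = sub.groupby(epoch).agg(
        delta_fraction=("delta_fraction", "mean"),
        theta_delta_ratio=("theta_delta_ratio", "mean"),
        emg_z=("emg_z", "mean"),
        activity=("activity", "max"),
        artifact_fraction=("artifact_fraction", "mean"))
    agg.index.name = "epoch"
    return agg.reset_index()


def score_subepochs(features: pd.DataFrame,
                    thresholds: StageThresholds = StageThresholds()) -> np.ndarray:
    """Apply the ordered staging rule per subepoch, carrying forward when
    no criterion fires."""
    th = thresholds
    n = len(features)
    stages = np.empty(n, dtype="<U8")
    prev = "wake"
    f = features
    for i in range(n):
        wake_cand = f["activity"].iat[i] > 0 or f["emg_z"].iat[i] >= th.z_wake
        art_lim = th.artifact_wake if wake_cand else th.artifact_sleep
        if f["artifact_fraction"].iat[i] >= art_lim or not f["spectra_valid"].iat[i]:
            s = "artifact"
        elif wake_cand:
            s = "wake"
        elif (f["delta_fraction"].iat[i] >= th.delta_min
              and f["emg_z"].iat[i] <= th.z_sleep):
            s = "nrem"
        elif (f["theta_delta_ratio"].iat[i] >= th.ratio_min
              and f["emg_z"].iat[i] <= th.z_sleep):
            s = "rem"
        else:
            s = prev
        stages[i] = s
        if s != "artifact":
            prev = s
    return stages


def majority_stage(subepoch_labels: np.ndarray) -> str:
    """Modal label; ties broken by artifact > wake > NREM > REM precedence."""
    labels = np.asarray(subepoch_labels)
    if labels.size == 0:
        raise ValueError("empty subepoch label sequence")
    uniq, counts = np.unique(labels, return_counts=True)
    best = counts.max()
    winners = set(uniq[counts == best])
    for s in STAGE_PRECEDENCE:
        if s in winners:
            return s
    return uniq[0]


def stage_epochs(recording: TelemetryRecording, eeg_spectral: np.ndarray,
                 mask: np.ndarray | None = None,
                 thresholds: StageThresholds = StageThresholds(),
                 first_24h: bool = True) -> pd.DataFrame:
    """Full staging pipeline: subepoch features -> rule -> 10 s majority.

    By default only the first 24 h cycle is scored (scoring convention);
    pass ``first_24h=False`` to score the whole recording.
    """
    sub = subepoch_features(recording, eeg_spectral, mask)
    if first_24h:
        sub = sub.iloc[:24 * 3600 // SUB_S]
    labels = score_subepochs(sub, thresholds)
    sps = EPOCH_S // SUB_S
    n_ep = len(labels) // sps
    stages = [majority_stage(labels[i * sps:(i + 1) * sps]) for i in range(n_ep)]
    return pd.DataFrame({"epoch": np.arange(n_ep), "stage": stages})


def artifact_exclusion(stages: pd.DataFrame) -> tuple[float, bool]:
    """Fraction of artifact epochs; excluded at or above 5% (inclusive)."""
    frac = float((stages["stage"] == "artifact").mean()) if len(stages) else 0.0
    return frac, frac >= 0.05


def _bouts(stage_arr: np.ndarray, min_epochs: int) -> list[int]:
    """Lengths (epochs) of maximal sleep (NREM/REM) runs of >= min_epochs."""
    sleep = np.isin(stage_arr, ("nrem", "rem")).astype(np.int8)
    d = np.diff(np.r_[0, sleep, 0])
    starts, ends = np.flatnonzero(d == 1), np.flatnonzero(d == -1)
    return [e - s for s, e in zip(starts, ends) if e - s >= min_epochs]


def sleep_summary(stages: pd.DataFrame, recording: TelemetryRecording,
                  frames=None, min_bout_epochs: int = 3) -> SleepSummary:
    """Stage percentages by light period, sleep bouts, per-stage spectra.

    Day = lights on, night = lights off.  A sleep bout is a maximal run of
    consecutive NREM/REM epochs lasting at least ``min_bout_epochs``.
    """
    arr = stages["stage"].to_numpy()
    t_s = stages["epoch"].to_numpy() * float(EPOCH_S)
    light = recording.is_light(t_s)

    rows = {}
    for name, sel in (("day", light), ("night", ~light), ("24h", np.ones_like(light, bool))):
        n = max(sel.sum(), 1)
        rows[name] = {s: float((arr[sel] == s).sum()) / n * 100.0
                      for s in STAGE_PRECEDENCE}
    percent = pd.DataFrame(rows).T
    percent.index.name = "period"

    bouts = _bouts(arr, min_bout_epochs)
    frac, excluded = artifact_exclusion(stages)

    if frames is not None:
        spec = {}
        n_ep = min(len(arr), frames.psd.shape[0])
        for s in ("wake", "nrem", "rem"):
            sel = (arr[:n_ep] == s) & frames.valid[:n_ep]
            spec[s] = frames.psd[:n_ep][sel].mean(axis=0) if sel.any() else \
                np.full(frames.freqs.size, np.nan)
        stage_spectra = pd.DataFrame(spec, index=pd.Index(frames.freqs, name="freq_hz"))
    else:
        stage_spectra = pd.DataFrame()

    return SleepSummary(
        percent_time=percent.reset_index(),
        bout_count=len(bouts),
        mean_bout_min=float(np.mean(bouts)) * EPOCH_S / 60.0 if bouts else 0.0,
        artifact_fraction=frac, excluded=excluded,
        stage_spectra=stage_spectra.reset_index() if len(stage_spectra) else stage_spectra)
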
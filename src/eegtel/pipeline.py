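"""End-to-end per-subject analysis pipeline and cohort table export.

``run_pipeline`` takes one :class:`~eegtel.recording_io.TelemetryRecording`
through the full chain — artifact cleaning, the two high-pass branches,
median-window spectral power with 10th-percentile normalization,
threshold spike detection with A/B/C classification, rule-based sleep
staging — and applies the two exclusion rules (positive delta-vs-activity
slope; >= 5% artifact epochs).  The result is a :class:`SubjectReport`
of plain DataFrames that ``write_report`` serializes as CSV/JSON.

Excluded subjects still get a quality-control report, but their analysis
tables are not meant to enter group comparisons; ``cohort_tables`` pools
only included subjects.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import preprocess, spectral, spikes as spk, sleep as slp
from .recording_io import TelemetryRecording
from .sleep import SleepSummary, StageThresholds
from .spikes import SpikeClassRule, SpikeSummary

__all__ = ["PipelineConfig", "SubjectReport", "run_pipeline",
           "write_report", "cohort_tables", "config_hash"]


@dataclass(frozen=True)
class PipelineConfig:
    """All analysis parameters in one place (hashable for provenance)."""

    artifact_cutoff_mv: float = 2.0
    artifact_pad_ms: float = 100.0
    spectral_hp_hz: float = preprocess.SPECTRAL_HP_HZ
    spike_hp_hz: float = preprocess.SPIKE_HP_HZ
    window_ms: float = 500.0
    bin_s: float = 10.0
    taper: str = "boxcar"
    spike_threshold_sd: float = 10.0
    spike_merge_gap_ms: float = 10.0
    spike_width_min_ms: float = 15.0
    spike_width_max_ms: float = 70.0
    spike_rule: SpikeClassRule = field(default_factory=SpikeClassRule)
    stage_thresholds: StageThresholds = field(default_factory=StageThresholds)
    stage_first_24h: bool = True


def config_hash(config: PipelineConfig) -> str:
    """Stable short hash of the configuration, for provenance stamping."""
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SubjectReport:
    """Everything the pipeline derives from one recording."""

    subject_id: str
    group_label: str
    config_digest: str
    artifact_fraction_samples: float
    minutes: pd.DataFrame  # normalized per-minute band powers + activity
    norm_divisor: float  # 10th percentile of per-minute total power, mV^2
    hourly: pd.DataFrame | None  # ZT profile (None for recordings < 24 h)
    percent_total: pd.DataFrame
    regressions: pd.DataFrame
    activity_binned: pd.DataFrame
    spike_events: pd.DataFrame
    spike_summary: SpikeSummary
    stages: pd.DataFrame
    sleep: SleepSummary
    qc: dict  # exclusion decision and reasons
    excluded: bool


def run_pipeline(recording: TelemetryRecording,
                 config: PipelineConfig = PipelineConfig()) -> SubjectReport:
    """Run the full analysis chain on one recording."""
    fs = recording.sampling_rate

    _, art = preprocess.remove_artifacts(
        recording.eeg, fs, cutoff=config.artifact_cutoff_mv,
        pad_ms=config.artifact_pad_ms)
    eeg_spec = preprocess.highpass(recording.eeg, config.spectral_hp_hz, fs)
    eeg_spike = preprocess.highpass(recording.eeg, config.spike_hp_hz, fs)

    # spectral branch
    frames = spectral.spectrogram_median_bins(
        eeg_spec, fs, window_ms=config.window_ms, bin_s=config.bin_s,
        taper=config.taper, mask=art.mask)
    minutes_raw = spectral.minute_band_power(frames, activity=recording.activity)
    minutes, divisor = spectral.normalize_to_tenth_percentile(minutes_raw)
    try:
        hourly = spectral.hourly_profile(
            minutes, recording.start_clock_hour, recording.light_onset_hour)
    except ValueError:
        hourly = None
    percent = spectral.percent_total_power(minutes)
    regressions = spectral.band_activity_regression(minutes_raw)
    binned = spectral.activity_binned_power(minutes_raw)
    qc_delta = spectral.qc_delta_activity(regressions)

    # spike branch
    sd = spk.estimate_baseline_sd(eeg_spike, mask=art.mask, sampling_rate=fs)
    cands = spk.detect_spikes(
        eeg_spike, fs, sd, k=config.spike_threshold_sd,
        merge_gap_ms=config.spike_merge_gap_ms, mask=art.mask)
    events = spk.classify_events(
        spk.filter_by_width(cands, config.spike_width_min_ms,
                            config.spike_width_max_ms),
        config.spike_rule)
    masked_hours = art.fraction * recording.duration_s / 3600.0
    summary = spk.spike_rate(events, recording.duration_s / 3600.0, masked_hours)

    # sleep branch
    stages = slp.stage_epochs(recording, eeg_spec, mask=art.mask,
                              thresholds=config.stage_thresholds,
                              first_24h=config.stage_first_24h)
    sleep = slp.sleep_summary(stages, recording, frames=frames)

    reasons = []
    if qc_delta["excluded"]:
        reasons.append(qc_delta["reason"])
    if sleep.excluded:
        reasons.append(
            f"artifact epochs {sleep.artifact_fraction:.1%} >= 5% of scored epochs")
    qc = dict(delta_slope=qc_delta["delta_slope"],
              artifact_epoch_fraction=sleep.artifact_fraction,
              artifact_sample_fraction=art.fraction,
              reasons=reasons)

    return SubjectReport(
        subject_id=recording.subject_id, group_label=recording.group_label,
        config_digest=config_hash(config),
        artifact_fraction_samples=art.fraction,
        minutes=minutes, norm_divisor=divisor, hourly=hourly,
        percent_total=percent, regressions=regressions, activity_binned=binned,
        spike_events=events, spike_summary=summary,
        stages=stages, sleep=sleep, qc=qc, excluded=bool(reasons))


def write_report(report: SubjectReport, out_dir: str | Path) -> Path:
    """Serialize one subject's report as CSVs plus a summary JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.minutes.to_csv(out / "minutes.csv", index=False)
    if report.hourly is not None:
        report.hourly.to_csv(out / "hourly_profile.csv", index=False)
    report.percent_total.to_csv(out / "percent_total.csv", index=False)
    report.regressions.to_csv(out / "activity_regressions.csv", index=False)
    report.activity_binned.to_csv(out / "activity_binned.csv", index=False)
    report.spike_events.to_csv(out / "spike_events.csv", index=False)
    report.stages.to_csv(out / "sleep_stages.csv", index=False)
    report.sleep.percent_time.to_csv(out / "sleep_percent.csv", index=False)
    if len(report.sleep.stage_spectra):
        report.sleep.stage_spectra.to_csv(out / "stage_spectra.csv", index=False)
    summary = dict(
        subject_id=report.subject_id, group_label=report.group_label,
        config_digest=report.config_digest,
        excluded=report.excluded, qc=report.qc,
        norm_divisor_mv2=report.norm_divisor,
        spike_rate_per_class=report.spike_summary.rate_per_class,
        spike_total_rate=report.spike_summary.total_rate,
        spike_hours_analyzed=report.spike_summary.hours_analyzed,
        sleep_bout_count=report.sleep.bout_count,
        sleep_mean_bout_min=report.sleep.mean_bout_min)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return out / "summary.json"


def cohort_tables(reports: list[SubjectReport]) -> dict[str, pd.DataFrame]:
    """Pool included subjects into per-cohort tables.

    Returns hourly band-power profiles, spike rates, and sleep percentages
    with one row per subject (long format), plus a QC table covering every
    subject including the excluded ones.
    """
    qc_rows, hourly_rows, spike_rows, sleep_rows = [], [], [], []
    for r in reports:
        qc_rows.append(dict(subject_id=r.subject_id, group=r.group_label,
                            excluded=r.excluded,
                            delta_slope=r.qc["delta_slope"],
                            artifact_epoch_fraction=r.qc["artifact_epoch_fraction"],
                            reasons="; ".join(r.qc["reasons"])))
        if r.excluded:
            continue
        if r.hourly is not None:
            h = r.hourly.copy()
            h.insert(0, "subject_id", r.subject_id)
            h.insert(1, "group", r.group_label)
            hourly_rows.append(h)
        spike_rows.append(dict(subject_id=r.subject_id, group=r.group_label,
                               total_rate=r.spike_summary.total_rate,
                               **{f"rate_{c}": v for c, v
                                  in r.spike_summary.rate_per_class.items()}))
        s = r.sleep.percent_time.copy()
        s.insert(0, "subject_id", r.subject_id)
        s.insert(1, "group", r.group_label)
        sleep_rows.append(s)
    return {
        "qc": pd.DataFrame(qc_rows),
        "hourly": pd.concat(hourly_rows, ignore_index=True) if hourly_rows else pd.DataFrame(),
        "spike_rates": pd.DataFrame(spike_rows),
        "sleep_percent": pd.concat(sleep_rows, ignore_index=True) if sleep_rows else pd.DataFrame(),
    }
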
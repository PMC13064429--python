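import numpy as np
import pandas as pd
import pytest

from eegtel.bands import DEFAULT_BANDS
from eegtel.spectral import (activity_binned_power, band_activity_regression,
                             hourly_profile, minute_band_power,
                             normalize_to_tenth_percentile,
                             percent_total_power, qc_delta_activity,
                             spectrogram_median_bins, window_band_psd)

FS = 500.0
BANDS = [b.name for b in DEFAULT_BANDS]


def _tone(freq, minutes=2, amp=1.0):
    t = np.arange(int(minutes * 60 * FS)) / FS
    return amp * np.sin(2 * np.pi * freq * t)


def test_tone_power_parseval():
    # a unit sine has power 1/2; the window PSD must integrate to it
    x = _tone(10.0)
    freqs, psd, valid = window_band_psd(x, FS)
    assert valid.all()
    total = psd.mean(axis=0).sum() * (freqs[1] - freqs[0])
    assert total == pytest.approx(0.5, rel=1e-3)


def test_median_bins_reject_contaminated_minority():
    x = _tone(10.0)
    # slam 4 of every 20 windows with a huge transient: the median must hold
    burst = x.copy()
    nper = int(0.5 * FS)
    for w in range(0, 40, 10):
        burst[w * nper:(w + 1) * nper] += 50.0
    clean = spectrogram_median_bins(x, FS)
    dirty = spectrogram_median_bins(burst, FS)
    assert np.allclose(dirty.psd[0], clean.psd[0], rtol=0.05)


def test_bin_invalid_when_over_half_windows_masked():
    x = _tone(10.0, minutes=1)
    mask = np.zeros(x.size, dtype=bool)
    nper = int(0.5 * FS)
    mask[:11 * nper] = True  # 11 of the first bin's 20 windows
    frames = spectrogram_median_bins(x, FS, mask=mask)
    assert not frames.valid[0]
    assert np.isnan(frames.psd[0]).all()
    assert frames.valid[1:].all()


def test_minute_power_missing_when_all_frames_invalid():
    x = _tone(10.0, minutes=3)
    mask = np.zeros(x.size, dtype=bool)
    mask[int(60 * FS):int(120 * FS)] = True  # second minute fully masked
    frames = spectrogram_median_bins(x, FS, mask=mask)
    minutes = minute_band_power(frames)
    assert np.isnan(minutes.loc[1, "total"])
    assert not np.isnan(minutes.loc[0, "total"])


def test_normalization_contract_and_divisor():
    rng = np.random.default_rng(3)
    minutes = pd.DataFrame({b: rng.uniform(1, 2, 60) for b in BANDS})
    minutes["total"] = minutes[BANDS].sum(axis=1)
    minutes.insert(0, "minute", np.arange(60))
    normed, q = normalize_to_tenth_percentile(minutes)
    assert q == pytest.approx(np.percentile(minutes["total"], 10))
    assert np.percentile(normed["total"], 10) == pytest.approx(1.0, abs=1e-9)


def test_normalization_needs_ten_minutes():
    minutes = pd.DataFrame({b: np.ones(5) for b in BANDS})
    minutes["total"] = 5.0
    minutes.insert(0, "minute", np.arange(5))
    with pytest.raises(ValueError):
        normalize_to_tenth_percentile(minutes)


def test_percent_total_sums_to_100():
    rng = np.random.default_rng(4)
    minutes = pd.DataFrame({b: rng.uniform(0.5, 3, 30) for b in BANDS})
    minutes["total"] = minutes[BANDS].sum(axis=1)
    minutes.insert(0, "minute", np.arange(30))
    pct = percent_total_power(minutes)
    assert np.allclose(pct[BANDS].sum(axis=1), 100.0)


def test_hourly_profile_requires_24h_and_maps_zt():
    rng = np.random.default_rng(5)
    n = 25 * 60
    minutes = pd.DataFrame({b: rng.uniform(1, 2, n) for b in BANDS})
    minutes["total"] = minutes[BANDS].sum(axis=1)
    minutes.insert(0, "minute", np.arange(n))
    prof = hourly_profile(minutes, start_clock_hour=6.0, light_onset_hour=6.0)
    assert list(prof["zt_hour"]) == list(range(24))
    short = minutes.iloc[:600]
    with pytest.raises(ValueError):
        hourly_profile(short, 6.0, 6.0)


def test_regression_slope_and_se_match_known_line(rng):
    act = rng.integers(0, 10, 500).astype(float)
    noise = rng.normal(0, 0.3, 500)
    minutes = pd.DataFrame({b: np.ones(500) for b in BANDS})
    minutes["delta"] = 5.0 - 0.5 * act + noise
    minutes["total"] = minutes[BANDS].sum(axis=1)
    minutes.insert(0, "minute", np.arange(500))
    minutes["activity"] = act
    res = band_activity_regression(minutes).set_index("band")
    assert abs(res.loc["delta", "slope"] - (-0.5)) < 3 * res.loc["delta", "slope_se"]
    assert res.loc["delta", "defined"]


def test_regression_undefined_for_constant_activity():
    minutes = pd.DataFrame({b: np.ones(20) for b in BANDS})
    minutes["total"] = 5.0
    minutes.insert(0, "minute", np.arange(20))
    minutes["activity"] = 0.0
    res = band_activity_regression(minutes)
    assert not res["defined"].any()
    qc = qc_delta_activity(res)
    assert not qc["excluded"] and "undefined" in qc["reason"]


def test_qc_rule_sign():
    def make(slope):
        return pd.DataFrame([dict(band="delta", slope=slope, intercept=0.0,
                                  r_squared=0.5, n_minutes=100, slope_se=0.1,
                                  defined=True)])
    assert qc_delta_activity(make(0.2))["excluded"]
    assert not qc_delta_activity(make(-0.2))["excluded"]
    assert not qc_delta_activity(make(0.0))["excluded"]  # strict inequality


def test_activity_binned_pools_top_level():
    minutes = pd.DataFrame({b: np.ones(30) for b in BANDS})
    minutes["total"] = 5.0
    minutes.insert(0, "minute", np.arange(30))
    minutes["activity"] = np.concatenate([np.zeros(10), np.full(10, 5),
                                          np.full(10, 25)])
    out = activity_binned_power(minutes)
    assert len(out) == 11
    assert not np.isnan(out.loc[out["activity_level"] == 10, "delta"]).any()


def test_window_psd_input_validation():
    with pytest.raises(ValueError):
        window_band_psd(np.zeros(10), FS)  # shorter than one window
    with pytest.raises(ValueError):
        window_band_psd(_tone(10, minutes=1), FS, fmax=250.0)
    with pytest.raises(ValueError):
        window_band_psd(_tone(10, minutes=1), FS, taper="hamming")
    with pytest.raises(ValueError):
        spectrogram_median_bins(_tone(10, minutes=1), FS, window_ms=7000.0)
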
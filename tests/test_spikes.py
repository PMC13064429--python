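import numpy as np
import pandas as pd
import pytest

from eegtel.spikes import (SpikeClassRule, classify_events, classify_spike,
                           detect_spikes, estimate_baseline_sd,
                           filter_by_width, match_events, spike_rate)

FS = 500.0


def _noise(seconds=3600, sd=0.05, seed=0):
    return np.random.default_rng(seed).normal(0, sd, int(seconds * FS))


def _transient(x, t_s, width_ms, peak):
    """Add a raised-cosine transient of given total width and peak."""
    n = int(width_ms / 1000 * FS)
    w = peak * 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / n))
    i0 = int(t_s * FS)
    x[i0:i0 + n] += w
    return t_s + (n // 2) / FS  # crest time


def test_baseline_sd_matches_gaussian_within_5pct():
    x = _noise(600, sd=0.05)
    assert estimate_baseline_sd(x, sampling_rate=FS) == pytest.approx(0.05, rel=0.05)


def test_baseline_sd_robust_to_sparse_spikes():
    x = _noise(600, sd=0.05, seed=1)
    clean = estimate_baseline_sd(x, sampling_rate=FS)
    spiked = x.copy()
    for k in range(10):  # 1 spike/min at 15x SD
        _transient(spiked, 30 + 60 * k, 30, 15 * 0.05)
    assert estimate_baseline_sd(spiked, sampling_rate=FS) == \
        pytest.approx(clean, rel=0.02)


def test_baseline_sd_errors():
    with pytest.raises(ValueError):
        estimate_baseline_sd(np.zeros(0))
    with pytest.raises(ValueError):
        estimate_baseline_sd(np.ones(int(120 * FS)), sampling_rate=FS)  # constant
    with pytest.raises(ValueError):
        estimate_baseline_sd(_noise(10), sampling_rate=FS)  # < 1 min


def test_pure_noise_has_at_most_one_false_candidate():
    x = _noise(3600, sd=0.05, seed=2)
    sd = estimate_baseline_sd(x, sampling_rate=FS)
    cands = detect_spikes(x, FS, sd)
    assert len(cands) <= 1


def test_injected_transient_found_at_its_time():
    x = _noise(600, sd=0.05, seed=3)
    sd = 0.05
    crest = _transient(x, 300.0, 30, 15 * sd)
    cands = detect_spikes(x, FS, sd)
    assert len(cands) == 1
    assert cands["peak_time_s"].iloc[0] == pytest.approx(crest, abs=0.005)


def test_below_threshold_not_detected():
    x = np.zeros(int(120 * FS))
    _transient(x, 60.0, 30, 9.5 * 0.05)
    cands = detect_spikes(x, FS, 0.05)
    assert len(cands) == 0


def test_merge_gap_joins_nearby_crossings():
    sd = 0.05
    i0 = int(60 * FS)
    # two 6 ms supra-threshold pulses with an 8 ms sub-threshold gap between
    # them -> merged into one candidate spanning both
    x = np.zeros(int(120 * FS))
    x[i0:i0 + 3] = 12 * sd
    x[i0 + 7:i0 + 10] = 12 * sd
    cands = detect_spikes(x, FS, sd)
    assert len(cands) == 1
    assert cands["width_ms"].iloc[0] == pytest.approx(20.0, abs=2.0)
    # 30 ms apart -> two candidates
    x2 = np.zeros(int(120 * FS))
    x2[i0:i0 + 3] = 12 * sd
    x2[i0 + 18:i0 + 21] = 12 * sd
    assert len(detect_spikes(x2, FS, sd)) == 2


def test_masked_stretch_excluded_from_detection():
    x = np.zeros(int(120 * FS))
    _transient(x, 60.0, 30, 15 * 0.05)
    mask = np.zeros(x.size, dtype=bool)
    mask[int(59 * FS):int(61 * FS)] = True
    assert len(detect_spikes(x, FS, 0.05, mask=mask)) == 0


def test_width_filter_bounds_inclusive():
    df = pd.DataFrame({"width_ms": [10.0, 15.0, 40.0, 70.0, 100.0]})
    kept = filter_by_width(df)
    assert list(kept["width_ms"]) == [15.0, 40.0, 70.0]


def test_classification_rule_examples():
    assert classify_spike(25.0, 10.0) == "A"
    assert classify_spike(11.0, 40.0) == "C"
    assert classify_spike(15.0, 20.0) == "B"
    assert classify_spike(25.0, 40.0) == "B"  # high but slow -> not A
    assert classify_spike(11.0, 10.0) == "B"  # low but fast -> not C
    rule = SpikeClassRule(amp_a=30.0)
    assert classify_spike(25.0, 10.0, rule) == "B"


def test_classify_events_adds_column():
    df = pd.DataFrame({"amplitude_sd": [25.0, 11.0], "half_decay_ms": [10.0, 40.0]})
    out = classify_events(df)
    assert list(out["cls"]) == ["A", "C"]
    assert "cls" not in df  # input untouched


def test_spike_rate_uses_unmasked_hours():
    events = pd.DataFrame({"cls": ["A", "A", "B"]})
    s = spike_rate(events, analyzed_hours=2.0, masked_hours=0.5)
    assert s.total_rate == pytest.approx(2.0)
    assert s.rate_per_class["A"] == pytest.approx(4.0 / 3.0)
    with pytest.raises(ValueError):
        spike_rate(events, analyzed_hours=1.0, masked_hours=1.0)


def test_match_events_is_one_to_one_and_tolerance_bound():
    det = np.array([1.000, 1.010, 5.0])
    tru = np.array([1.005, 9.0])
    pairs = match_events(det, tru, tol_s=0.025)
    assert pairs == [(0, 0)]  # closest detected wins; 5.0 and 9.0 unmatched
    assert match_events(np.array([1.0]), np.array([1.05]), tol_s=0.025) == []
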
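import numpy as np
import pytest

from eegtel.bands import DEFAULT_BANDS
from eegtel.simulate import (DEFAULT_SPIKE_CLASSES, SimConfig,
                             inject_artifacts, make_decoy_template,
                             make_spike_template, simulate_recording)

FS = 500.0


def test_same_seed_is_bit_identical():
    cfg = SimConfig(rng_seed=5, duration_hours=0.25)
    rec1, tr1 = simulate_recording(cfg)
    rec2, tr2 = simulate_recording(SimConfig(rng_seed=5, duration_hours=0.25))
    assert np.array_equal(rec1.eeg, rec2.eeg)
    assert np.array_equal(rec1.emg, rec2.emg)
    assert np.array_equal(rec1.activity, rec2.activity)
    assert (tr1.state_sequence == tr2.state_sequence).all()
    assert tr1.spikes.equals(tr2.spikes)


def test_different_seed_differs():
    rec1, _ = simulate_recording(SimConfig(rng_seed=5, duration_hours=0.25))
    rec2, _ = simulate_recording(SimConfig(rng_seed=6, duration_hours=0.25))
    assert not np.array_equal(rec1.eeg, rec2.eeg)


def test_zero_spike_rates_yield_no_spikes():
    cfg = SimConfig(rng_seed=1, duration_hours=0.25,
                    spike_rates={"A": 0.0, "B": 0.0, "C": 0.0})
    _, truth = simulate_recording(cfg)
    assert len(truth.spikes) == 0


def test_ground_truth_invariants(sim2h):
    rec, truth = sim2h
    assert len(truth.state_sequence) == rec.n_epochs
    assert set(truth.state_sequence) <= {"wake", "nrem", "rem"}
    # spikes inside the recording, sorted, respecting min separation
    t = truth.spikes["time_s"].to_numpy()
    assert ((t >= 0) & (t <= rec.duration_s)).all()
    assert (np.diff(np.sort(t)) >= 1.0 - 1e-9).all()
    # artifact intervals disjoint and in range
    ivals = sorted(truth.artifact_intervals)
    for (s0, e0), (s1, _) in zip(ivals, ivals[1:]):
        assert e0 <= s1
    for s, e in ivals:
        assert 0 <= s < e <= rec.duration_s
    # spikes do not lie inside artifact intervals
    for s, e in ivals:
        assert not ((t >= s) & (t <= e)).any()


def test_rem_entered_only_from_nrem(sim24h):
    _, truth = sim24h
    seq = truth.state_sequence
    prev_on_entry = [seq[i - 1] for i in range(1, len(seq))
                     if seq[i] == "rem" and seq[i - 1] != "rem"]
    assert prev_on_entry and all(p == "nrem" for p in prev_on_entry)


def test_activity_zero_during_fully_asleep_minutes(sim2h):
    rec, truth = sim2h
    seq = truth.state_sequence
    for m in range(rec.activity.size - 1):
        states = seq[m * 6:(m + 1) * 6]
        if len(states) == 6 and not (states == "wake").any():
            assert rec.activity[m] == 0


def test_band_power_expectation_structure(sim2h):
    _, truth = sim2h
    names = {b.name for b in DEFAULT_BANDS}
    assert set(truth.band_power_expectation) == {"wake", "nrem", "rem"}
    for state, bp in truth.band_power_expectation.items():
        assert set(bp) == names
        assert all(v >= 0 for v in bp.values())
    # the designed state signatures dominate their own band
    bp = truth.band_power_expectation
    assert bp["nrem"]["delta"] > bp["wake"]["delta"]
    assert bp["rem"]["theta"] > bp["nrem"]["theta"]
    assert bp["wake"]["gamma"] > bp["nrem"]["gamma"]


def test_config_validation_errors():
    with pytest.raises(ValueError):
        SimConfig(duration_hours=0.05).validate()
    with pytest.raises(ValueError):
        SimConfig(sampling_rate=100.0).validate()
    with pytest.raises(ValueError):
        SimConfig(artifact_amplitude=1.5).validate()
    with pytest.raises(ValueError):
        SimConfig(spike_rates={"A": -1.0}).validate()


def test_spike_template_widths_in_range():
    for label, spec in DEFAULT_SPIKE_CLASSES.items():
        w = make_spike_template(label, FS)
        assert np.abs(w).max() == pytest.approx(spec.peak, rel=1e-6)
        assert 15.0 <= spec.fwhm_ms <= 70.0, label


def test_decoy_templates_out_of_range():
    narrow = make_decoy_template("narrow", FS)
    wide = make_decoy_template("wide", FS)
    # full width at half maximum of the narrow blip < 15 ms
    half = np.abs(narrow) >= np.abs(narrow).max() / 2
    assert half.sum() / FS * 1000 < 15
    # wide burst envelope lasts > 70 ms
    on = np.abs(wide) >= np.abs(wide).max() / 10
    dur = (np.flatnonzero(on)[-1] - np.flatnonzero(on)[0]) / FS * 1000
    assert dur > 70
    with pytest.raises(ValueError):
        make_decoy_template("medium", FS)


def test_inject_artifacts_exceeds_cutoff_everywhere():
    x = np.zeros(int(30 * FS), dtype=np.float32)
    out = inject_artifacts(x, [(5.0, 10.0)], amplitude=3.0, sampling_rate=FS)
    seg = out[int(5 * FS):int(10 * FS)]
    assert (np.abs(seg) > 2.0).all()
    assert np.abs(seg).max() <= 3.0 + 1e-6
    assert (out[:int(5 * FS)] == 0).all()
    with pytest.raises(ValueError):
        inject_artifacts(x, [(5.0, 10.0)], amplitude=1.0, sampling_rate=FS)
    with pytest.raises(ValueError):
        inject_artifacts(x, [(25.0, 35.0)], amplitude=3.0, sampling_rate=FS)
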
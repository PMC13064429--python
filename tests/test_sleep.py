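import numpy as np
import pandas as pd
import pytest

from eegtel.preprocess import SPECTRAL_HP_HZ, highpass
from eegtel.sleep import (EPOCH_S, artifact_exclusion, majority_stage,
                          score_subepochs, sleep_summary, stage_epochs)


def _features(**overrides):
    """One benign sleep-candidate subepoch row, overridable per column."""
    row = dict(sub_index=0, delta_fraction=0.1, theta_delta_ratio=0.5,
               emg_z=0.0, activity=0.0, artifact_fraction=0.0,
               spectra_valid=True)
    row.update(overrides)
    return pd.DataFrame([row])


def test_rule_wake_on_activity_or_emg():
    assert score_subepochs(_features(activity=3.0))[0] == "wake"
    assert score_subepochs(_features(emg_z=1.5))[0] == "wake"


def test_rule_nrem_needs_delta_and_low_emg():
    assert score_subepochs(_features(delta_fraction=0.5))[0] == "nrem"
    assert score_subepochs(_features(delta_fraction=0.5, emg_z=0.8))[0] != "nrem"


def test_rule_rem_needs_theta_ratio_and_low_emg():
    assert score_subepochs(_features(theta_delta_ratio=2.0))[0] == "rem"
    # delta criterion is checked first
    assert score_subepochs(
        _features(theta_delta_ratio=2.0, delta_fraction=0.5))[0] == "nrem"


def test_rule_carries_previous_when_nothing_fires():
    rows = pd.concat([_features(delta_fraction=0.5),
                      _features(sub_index=1)], ignore_index=True)
    assert list(score_subepochs(rows)) == ["nrem", "nrem"]
    # at the very start the carry default is wake
    assert score_subepochs(_features())[0] == "wake"


def test_rule_artifact_thresholds_differ_by_wake_candidacy():
    # sleep candidate: 0.5 artifact fraction is enough
    assert score_subepochs(_features(artifact_fraction=0.5))[0] == "artifact"
    # wake candidate: 0.5 is not enough, 0.8 is
    assert score_subepochs(
        _features(artifact_fraction=0.5, activity=2.0))[0] == "wake"
    assert score_subepochs(
        _features(artifact_fraction=0.8, activity=2.0))[0] == "artifact"


def test_majority_and_tie_precedence():
    assert majority_stage(np.array(["nrem"] * 6 + ["wake"] * 4)) == "nrem"
    # 5-5 tie -> wake beats nrem; artifact beats everything
    assert majority_stage(np.array(["nrem"] * 5 + ["wake"] * 5)) == "wake"
    assert majority_stage(np.array(["artifact"] * 5 + ["rem"] * 5)) == "artifact"
    with pytest.raises(ValueError):
        majority_stage(np.array([]))


def test_artifact_exclusion_inclusive_bound():
    def stages(n_art, n=1000):
        return pd.DataFrame({"stage": ["artifact"] * n_art
                             + ["wake"] * (n - n_art)})
    frac, excluded = artifact_exclusion(stages(50))  # exactly 5.0%
    assert frac == pytest.approx(0.05) and excluded
    frac, excluded = artifact_exclusion(stages(49))
    assert not excluded


def test_stage_epochs_recovers_hypnogram(sim2h):
    rec, truth = sim2h
    hp = highpass(rec.eeg, SPECTRAL_HP_HZ, rec.sampling_rate)
    stages = stage_epochs(rec, hp)
    assert len(stages) == rec.n_epochs
    st = stages["stage"].to_numpy()
    gt = truth.state_sequence[:len(st)]
    ok = st != "artifact"
    assert (st[ok] == gt[ok]).mean() >= 0.9


def test_sleep_summary_bouts_and_percentages(sim2h):
    rec, _ = sim2h
    stages = pd.DataFrame({
        "epoch": np.arange(12),
        "stage": ["wake", "nrem", "nrem", "nrem", "wake", "nrem", "rem",
                  "nrem", "wake", "wake", "nrem", "nrem"]})
    # pad activity/light via the real recording's schedule (first 2 min)
    s = sleep_summary(stages, rec)
    # bouts >= 3 epochs: [1..3] and [5..7]; the trailing 2-epoch run is not one
    assert s.bout_count == 2
    assert s.mean_bout_min == pytest.approx(3 * EPOCH_S / 60.0)
    day = s.percent_time.set_index("period").loc["24h"]
    assert day[["wake", "nrem", "rem", "artifact"]].sum() == pytest.approx(100.0)


def test_first_24h_limit(sim2h):
    rec, _ = sim2h
    hp = highpass(rec.eeg, SPECTRAL_HP_HZ, rec.sampling_rate)
    assert len(stage_epochs(rec, hp, first_24h=True)) == rec.n_epochs  # < 24 h
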
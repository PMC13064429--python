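#!/usr/bin/env python
"""Group summaries of spike rates and sleep-stage percentages from the
cohort of 01_run_cohort.py; writes results/spike_rate_group_means.csv and
results/sleep_percent_group_means.csv."""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    spikes = pd.read_csv(ROOT / "cohort" / "cohort_spike_rates.csv")
    cols = [c for c in spikes.columns if c.startswith("rate_")] + ["total_rate"]
    sp = spikes.groupby("group")[cols].agg(["mean", "std"])
    sp.to_csv(ROOT / "spike_rate_group_means.csv")
    print(sp.round(3).to_string())

    sleep = pd.read_csv(ROOT / "cohort" / "cohort_sleep_percent.csv")
    stages = ["wake", "nrem", "rem", "artifact"]
    sl = sleep.groupby(["group", "period"])[stages].agg(["mean", "std"])
    sl.to_csv(ROOT / "sleep_percent_group_means.csv")
    print(sl.round(2).to_string())


if __name__ == "__main__":
    main()
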
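#!/usr/bin/env python
"""Group-mean circadian (ZT hourly) band-power profiles from the cohort of
01_run_cohort.py; writes results/hourly_group_means.csv."""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    hourly = pd.read_csv(ROOT / "cohort" / "cohort_hourly.csv")
    bands = [c for c in hourly.columns
             if c not in ("subject_id", "group", "zt_hour")]
    means = hourly.groupby(["group", "zt_hour"])[bands].mean().reset_index()
    out = ROOT / "hourly_group_means.csv"
    means.to_csv(out, index=False)
    print(f"wrote {out}")
    # quick directional readout: gamma dark vs light per group
    for g, sub in means.groupby("group"):
        light = sub["zt_hour"] < 12
        print(f"{g}: gamma dark-light = "
              f"{sub.loc[~light, 'gamma'].mean() - sub.loc[light, 'gamma'].mean():+.3f}, "
              f"delta light-dark = "
              f"{sub.loc[light, 'delta'].mean() - sub.loc[~light, 'delta'].mean():+.3f}")


if __name__ == "__main__":
    main()
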
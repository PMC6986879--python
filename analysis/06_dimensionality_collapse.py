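#!/usr/bin/env python
"""Does the PRP electrode space contract when the odorant arrives?

Summarizes the participation-ratio time courses from the pipeline runs:
baseline (pre-trial) dimensionality versus the odor-epoch mean,
normalized to baseline, per odorant and learning stage.  In the
proficient session a shared odor-driven gain dominates the electrode
covariance and the normalized dimensionality drops well below one.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for name in ("naive", "proficient"):
        path = ROOT / "results" / f"pipeline_{name}" / "dimensionality_timecourse.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing - run 03_run_pipeline.py first")
        frame = pd.read_csv(path)
        frame = frame[frame.stage == name]
        odor = frame[(frame.timebin_s >= 0.5) & (frame.timebin_s <= 2.5)]
        base = frame[(frame.timebin_s >= -1.0) & (frame.timebin_s < 0.0)]
        for (ref, odorant), sub in odor.groupby(["reference", "odorant"]):
            b = base[(base.reference == ref) & (base.odorant == odorant)]
            rows.append(
                {
                    "condition": name,
                    "reference": ref,
                    "odorant": odorant,
                    "baseline_dim": b.dim.mean(),
                    "odor_dim": sub.dim.mean(),
                    "odor_normalized_dim": sub.normalized_dim.mean(),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "results" / "dimensionality_summary.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
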
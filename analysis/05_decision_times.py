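#!/usr/bin/env python
"""When does the neural code diverge relative to the behavioral decision?

For the proficient session, the per-bin rank-sum p-value between S+ and
S- is tracked for (a) binary licks and (b) the LDA-predicted odorant
identity from peak- and trough-referenced PRP.  The decision time is the
first post-odor bin after which p stays below 0.05 through the end of
the odor epoch.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    path = ROOT / "results" / "pipeline_proficient" / "decision_times.csv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run 03_run_pipeline.py first")
    table = pd.read_csv(path)
    table.to_csv(ROOT / "results" / "decision_times_proficient.csv", index=False)
    print(table.to_string(index=False))
    lick = table.loc[table.source == "licks", "decision_time_s"].iloc[0]
    print(f"\nlick decision time: {lick:.2f} s after odor-valve diversion")
    for _, row in table[table.source != "licks"].iterrows():
        delta = row.decision_time_s - lick
        print(f"{row.source}: {row.decision_time_s:.2f} s ({delta:+.2f} s vs licks)")


if __name__ == "__main__":
    main()
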
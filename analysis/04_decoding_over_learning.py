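#!/usr/bin/env python
"""Compare decoding of odorant contextual identity before and after learning.

Reads the decoding tables produced by 03_run_pipeline.py and reports the
normalized AUC (0 = chance, 1 = perfect decoding during the odor epoch)
for peak- and trough-referenced high-gamma PRP in the naive and
proficient sessions, mirroring the learning effect: decodable only once
the animal discriminates, and better from peak than trough PRP.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rows = []
    for name in ("naive", "proficient"):
        path = ROOT / "results" / f"pipeline_{name}" / "auc.csv"
        if not path.exists():
            raise SystemExit(f"{path} missing - run 03_run_pipeline.py first")
        frame = pd.read_csv(path)
        frame.insert(0, "condition", name)
        rows.append(frame)
    table = pd.concat(rows, ignore_index=True)
    table.to_csv(ROOT / "results" / "auc_over_learning.csv", index=False)
    print(table.to_string(index=False))
    prof = table[table.condition == "proficient"].set_index("reference").auc
    naive = table[table.condition == "naive"].set_index("reference").auc
    print(f"\nproficient peak AUC {prof['peak']:.2f} vs naive {naive['peak']:.2f}")


if __name__ == "__main__":
    main()
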
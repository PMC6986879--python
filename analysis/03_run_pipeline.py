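#!/usr/bin/env python
"""Run the full analysis chain on the simulated sessions.

Behavior scoring, per-trial PAC, phase-referenced power, LDA decoding,
decision times, and dimensionality for the proficient and naive
sessions written by 01_simulate_sessions.py.  The full output bundle
(including the multi-megabyte long-format PRP tensor) lands under
scratch/pipeline_<name>/; compact summary tables are mirrored into
results/pipeline_<name>/.
"""

import shutil
from pathlib import Path

from prpdecode import AnalysisConfig, load_session, run_full

ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
COMPACT_MAX_BYTES = 60_000


def main() -> None:
    config = AnalysisConfig()
    for name in ("proficient", "naive"):
        path = SESSIONS / name
        if not path.exists():
            raise SystemExit(f"{path} missing - run 01_simulate_sessions.py first")
        session, table = load_session(path)
        stage = name if name in ("naive", "proficient") else None
        out = ROOT / "scratch" / f"pipeline_{name}"
        manifest = run_full(
            [(session, table)], out, config=config, stage_filter=stage, seed=7
        )
        mirror = ROOT / "results" / f"pipeline_{name}"
        mirror.mkdir(parents=True, exist_ok=True)
        kept = []
        for f in sorted(out.iterdir()):
            if f.name == "behavior.csv":  # summarized in session_behavior_summary.csv
                continue
            if f.stat().st_size <= COMPACT_MAX_BYTES:
                shutil.copy2(f, mirror / f.name)
                kept.append(f.name)
        timing = ", ".join(f"{k} {v:.1f}s" for k, v in manifest.timestamps.items())
        print(f"{name}: full bundle in {out} ({timing})")
        print(f"{name}: compact tables mirrored to {mirror}: {', '.join(kept)}")


if __name__ == "__main__":
    main()
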
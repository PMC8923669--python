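#!/usr/bin/env python
"""Relate per-block neural response size to freezing within animals.

For each session, averages the type 1 response area over the five
extinction blocks of seven tones and pairs it with block-mean freezing
(CS+ freezing for onset responses, inter-tone-interval freezing for
offset responses), then reports the repeated-measures correlation per
condition from the report of 02.  Writes results/rmcorr_blocks.csv with
the per-block pairs behind the correlations.
"""

from pathlib import Path

import pandas as pd

from fearpeth.behavior import per_trial_freezing
from fearpeth.pipeline import unit_block_areas
from fearpeth.session_io import read_session

ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
REPORT = ROOT / "results" / "report"
OUT = ROOT / "results" / "rmcorr_blocks.csv"


def main() -> None:
    frames = []
    for path in sorted(p for p in SESSIONS.iterdir() if p.is_dir()):
        bundle = read_session(path)
        areas = unit_block_areas(bundle, n_blocks=5)
        if areas is None:
            continue
        freeze = (
            per_trial_freezing(bundle.behavior, bundle.events)
            .groupby("block")[["freezing_cs", "freezing_iti"]]
            .mean()
        )
        merged = areas.join(freeze, on="block")
        merged.insert(1, "condition", bundle.condition)
        frames.append(merged)
    blocks = pd.concat(frames, ignore_index=True)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    blocks.to_csv(OUT, index=False)

    rm = pd.read_csv(REPORT / "rmcorr.csv")
    print("repeated-measures correlations (sessions as subjects):")
    print(rm.to_string(index=False))
    print(f"\nwrote per-block pairs to {OUT}")


if __name__ == "__main__":
    main()
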
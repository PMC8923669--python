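#!/usr/bin/env python
"""Simulate the study-style cohort and dump every session to disk.

Generates six control and four inactivation-like sessions (spike trains,
trial events, LFPs, freeze/move annotations, sorting features) from
`cohort_config.yaml` and writes them under scratch/sessions/ in the
plain-text session format.  Everything downstream (02-04) reads these
files, so the whole analysis is reproducible from this one seed.
"""

from pathlib import Path

from fearpeth.pipeline import simulate_cohort
from fearpeth.session_io import load_config, write_session

SEED = 20220315
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "scratch" / "sessions"


def main() -> None:
    config = load_config(Path(__file__).parent / "cohort_config.yaml")
    bundles = simulate_cohort(config, SEED)
    for bundle in bundles:
        write_session(bundle, OUT / bundle.session_id)
        n_units = len(bundle.spike_trains)
        print(
            f"{bundle.session_id}: {bundle.condition}, {n_units} units, "
            f"{len(bundle.events)} trials, {bundle.events.duration_s:.0f} s"
        )
    print(f"\nwrote {len(bundles)} sessions to {OUT}")


if __name__ == "__main__":
    main()
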
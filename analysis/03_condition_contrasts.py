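#!/usr/bin/env python
"""Contrast extinction phases and conditions on units, ERPs and behaviour.

From the report tables of 02: mean response area and peak z in early vs
late extinction per condition (extinction sensitivity of the excitatory
responses), offset peak counts and maximal-peak latencies (temporal
dispersion under inactivation), ERP peak-to-peak amplitudes, freezing
percentages, bout durations and extinction slopes.  Writes
results/condition_contrasts.csv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
REPORT = ROOT / "results" / "report"
OUT = ROOT / "results" / "condition_contrasts.csv"


def main() -> None:
    um = pd.read_csv(REPORT / "unit_metrics.csv")
    erp = pd.read_csv(REPORT / "erp_metrics.csv")
    beh = pd.read_csv(REPORT / "behavior_summary.csv")

    rows = []
    type1 = um[(um.unit_type == 1) & (~um.degenerate)]
    for cond, grp in type1.groupby("condition"):
        for phase in ("EE", "LE"):
            sel = grp[grp.phase == phase]
            rows.append({
                "condition": cond, "phase": phase, "n_units": len(sel),
                "mean_area_onset": sel.area_onset.mean(),
                "mean_area_offset": sel.area_offset.mean(),
                "mean_peak_z_onset": sel.peak_z_onset.mean(),
                "mean_n_peaks_offset": sel[~sel.excluded_late_peak].n_peaks_offset.mean(),
                "mean_offset_max_peak_bin": sel[~sel.excluded_late_peak]
                .max_peak_bin_offset.mean(),
            })
    contrasts = pd.DataFrame(rows)

    print("type 1 unit metrics by condition and extinction phase:")
    print(contrasts.to_string(index=False))

    print("\nERP peak-to-peak (offset alignment):")
    off = erp[erp["align"] == "tone_offset"]  # .align is a DataFrame method
    print(off.groupby(["condition", "phase"]).peak_to_peak_uV.mean().to_string())

    print("\nbehaviour (freezing % and freeze bout duration):")
    cols = ["freezing_cs_EE", "freezing_cs_LE", "freeze_epoch_EE_s",
            "freeze_epoch_LE_s", "extinction_slope_cs"]
    print(beh.groupby("condition")[cols].mean().to_string())

    OUT.parent.mkdir(parents=True, exist_ok=True)
    contrasts.to_csv(OUT, index=False)
    print(f"\nwrote {OUT}")


if __name__ == "__main__":
    main()
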
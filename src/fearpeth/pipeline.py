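"""End-to-end orchestration: simulate → analyze → report.

``run_pipeline(config, seed)`` generates (or loads) a cohort of sessions,
applies cluster-quality gating, computes per-unit PETH statistics on
all-trials / early-extinction / late-extinction subsets, ERP metrics on
the best channel, behavioural summaries and the repeated-measures
correlations between response area and freezing, and returns the full
results bundle.  Identical (config, seed) pairs produce identical
outputs; the manifest records the config hash, seed and package version
(no timestamp, so reports are byte-reproducible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from fearpeth import __version__, behavior as bhv, classify, cluster_quality as cq, erp as erp_mod
from fearpeth import peth as peth_mod
from fearpeth.core import SessionBundle, TrialEvents, ValidationError
from fearpeth.session_io import write_report, write_session
from fearpeth.synthetic import simulate_session

log = logging.getLogger("fearpeth")

PHASE_SUBSETS = ("all", "EE", "LE")


@dataclass
class PipelineResults:
    unit_metrics: pd.DataFrame
    cohort_summary: pd.DataFrame
    erp_metrics: pd.DataFrame
    behavior_summary: pd.DataFrame
    rmcorr: pd.DataFrame
    manifest: dict


def _session_seed(seed: int, group_idx: int, session_idx: int) -> int:
    return (int(seed) * 100_003 + group_idx * 1_009 + session_idx) % (2**31 - 1)


def simulate_cohort(config: dict, seed: int) -> list[SessionBundle]:
    """Generate every session described by a parsed config."""
    bundles = []
    for gi, group in enumerate(config["groups"]):
        for si in range(group["n_sessions"]):
            bundles.append(
                simulate_session(
                    session_id=f"{group['name']}_s{si:02d}",
                    condition=group["condition"],
                    protocol=config["protocol"],
                    unit_specs=group["units"],
                    behavior=group["behavior"],
                    lfp=group["lfp"],
                    cluster=group["cluster"],
                    seed=_session_seed(seed, gi, si),
                )
            )
    return bundles


# ---------------------------------------------------------------------------
# per-session unit analysis


def _accepted_units(bundle: SessionBundle) -> list:
    """Cluster-quality gating: unit i is gated by cluster label i+1 when
    features are present, otherwise all units pass."""
    if bundle.cluster_features is None:
        return list(bundle.spike_trains)
    trains = {i + 1: t for i, t in enumerate(bundle.spike_trains)}
    metrics = cq.session_quality(bundle.cluster_features, trains)
    accepted = []
    by_id = {m.cluster_id: m for m in metrics}
    for cid, train in trains.items():
        m = by_id.get(cid)
        if m is not None and m.accepted:
            accepted.append(train)
        else:
            reasons = "; ".join(m.rejection_reasons) if m else "no cluster metrics"
            log.info("session %s: unit %s rejected (%s)", bundle.session_id, train.unit_id, reasons)
    return accepted


def _unit_zpeths(train, events: TrialEvents, subset: str):
    """Onset- and offset-aligned z-scored PETHs for one trial subset.

    The offset-aligned histogram reuses the baseline statistics of the
    pre-tone-onset window of the same trials.
    """
    onset = peth_mod.bin_spikes(train, events, align="tone_onset", subset=subset)
    z_on = peth_mod.zscore_peth(onset)
    stats = (z_on.baseline_mean, z_on.baseline_sd)
    offset = peth_mod.bin_spikes(train, events, align="tone_offset", subset=subset)
    z_off = peth_mod.zscore_peth(offset, stats=stats)
    return z_on, z_off


def analyze_units(bundle: SessionBundle) -> pd.DataFrame:
    """Per-unit typing and phase-resolved response metrics.

    Units are typed from the all-trials detections and re-measured on EE
    and LE; units with a zero-variance baseline are flagged degenerate
    and excluded from response statistics.
    """
    rows = []
    units = _accepted_units(bundle)
    # first pass: z-scored PETHs per unit per subset
    per_unit: dict[str, dict[str, tuple]] = {}
    degenerate: set[str] = set()
    for train in units:
        per_unit[train.unit_id] = {}
        for subset in PHASE_SUBSETS:
            z_on, z_off = _unit_zpeths(train, bundle.events, subset)
            if z_on.degenerate:
                degenerate.add(train.unit_id)
                log.info(
                    "session %s: unit %s degenerate baseline (SD=0) in %s",
                    bundle.session_id, train.unit_id, subset,
                )
            per_unit[train.unit_id][subset] = (z_on, z_off)
    usable = [u for u in units if u.unit_id not in degenerate]
    # typing from all-trials detections
    types: dict[str, tuple] = {}
    for train in usable:
        z_on, z_off = per_unit[train.unit_id]["all"]
        det_on = classify.detect_response(z_on)
        det_off = classify.detect_response(z_off)
        types[train.unit_id] = (det_on, det_off, *classify.classify_unit(det_on, det_off))
    # cohort-average peak bin per subset/alignment over type 1 units
    group_peak: dict[tuple[str, str], Optional[int]] = {}
    for subset in PHASE_SUBSETS:
        for ai, align in enumerate(("onset", "offset")):
            zs = [
                per_unit[u.unit_id][subset][ai]
                for u in usable
                if types[u.unit_id][2] == 1
            ]
            if zs:
                mean, _ = peth_mod.average_peths(zs)
                n = classify._window_bins(zs[0], classify.DEFAULT_INTEGRATION_S)
                post = mean[zs[0].n_pre_bins:][:n]
                group_peak[(subset, align)] = int(np.argmax(post))
            else:
                group_peak[(subset, align)] = None
    for train in units:
        uid = train.unit_id
        if uid in degenerate:
            rows.append(
                {"session_id": bundle.session_id, "condition": bundle.condition, "unit_id": uid,
                 "phase": "all", "degenerate": True}
            )
            continue
        det_on, det_off, unit_type, subtype = types[uid]
        for subset in PHASE_SUBSETS:
            z_on, z_off = per_unit[uid][subset]
            rec: dict[str, Any] = {
                "session_id": bundle.session_id,
                "condition": bundle.condition,
                "unit_id": uid,
                "phase": subset,
                "degenerate": False,
                "unit_type": unit_type,
                "subtype": subtype,
                "onset_responsive": det_on.responsive,
                "offset_responsive": det_off.responsive,
            }
            late = False
            for align, zp in (("onset", z_on), ("offset", z_off)):
                area, peak = classify.response_metrics(
                    zp, group_peak_bin=group_peak[(subset, align)]
                )
                n_peaks, late_a = classify.count_peaks(zp)
                rec[f"area_{align}"] = area
                rec[f"peak_z_{align}"] = peak
                rec[f"n_peaks_{align}"] = n_peaks
                rec[f"max_peak_bin_{align}"] = classify.maximal_peak_bin(zp)
                late |= late_a
            rec["excluded_late_peak"] = late
            rows.append(rec)
    return pd.DataFrame(rows)


def cohort_table(unit_metrics: pd.DataFrame) -> pd.DataFrame:
    """Type/subtype counts and percentages per condition (all-trials typing)."""
    rows = []
    if not unit_metrics.empty:
        usable = unit_metrics[(unit_metrics.phase == "all") & (~unit_metrics.degenerate)]
        for condition, grp in usable.groupby("condition", sort=True):
            units = [
                classify.UnitResponse(
                    unit_id=r.unit_id, phase="all",
                    onset=classify.ResponseDetection(bool(r.onset_responsive), "none", None),
                    offset=classify.ResponseDetection(bool(r.offset_responsive), "none", None),
                    unit_type=int(r.unit_type), subtype=str(r.subtype),
                )
                for r in grp.itertuples()
            ]
            summary = classify.cohort_summary(units)
            for category, vals in summary.items():
                rows.append(
                    {"condition": condition, "category": category,
                     "count": int(vals["count"]), "percent": vals["percent"]}
                )
    return pd.DataFrame(rows, columns=["condition", "category", "count", "percent"])


# ---------------------------------------------------------------------------
# ERP and behaviour per session


def analyze_erps(bundle: SessionBundle) -> pd.DataFrame:
    """Band-pass, pick the best channel on EE onset p2p, measure per phase."""
    cols = ["session_id", "condition", "channel_id", "align", "phase",
            "onset_latency_ms", "peak_latency_ms", "peak_to_peak_uV"]
    if not bundle.lfps:
        return pd.DataFrame(columns=cols)
    filtered = [erp_mod.bandpass_lfp(t) for t in bundle.lfps]
    erps_ee = [
        erp_mod.average_erp(t, bundle.events, align="tone_onset", subset="EE") for t in filtered
    ]
    best = erp_mod.select_best_channel(erps_ee, [t.channel_id for t in filtered])
    trace = next(t for t in filtered if t.channel_id == best)
    rows = []
    for align in ("tone_onset", "tone_offset"):
        for subset in ("EE", "LE"):
            e = erp_mod.average_erp(trace, bundle.events, align=align, subset=subset)
            m = erp_mod.erp_metrics(e)
            rows.append(
                {"session_id": bundle.session_id, "condition": bundle.condition,
                 "channel_id": best, "align": align, "phase": subset,
                 "onset_latency_ms": m.onset_latency_ms, "peak_latency_ms": m.peak_latency_ms,
                 "peak_to_peak_uV": m.peak_to_peak_uV}
            )
    return pd.DataFrame(rows, columns=cols)


def analyze_behavior(bundle: SessionBundle) -> dict[str, Any]:
    """Session-level behaviour summary (freezing, epochs, slopes, counts)."""
    ann = bundle.behavior
    events = bundle.events
    per_trial = bhv.per_trial_freezing(ann, events)
    rec: dict[str, Any] = {"session_id": bundle.session_id, "condition": bundle.condition}
    for subset, trials in (("EE", range(1, 15)), ("LE", range(21, 36))):
        sel = per_trial[per_trial.trial_index.isin(trials)]
        rec[f"freezing_cs_{subset}"] = float(sel.freezing_cs.mean())
        rec[f"freezing_iti_{subset}"] = float(sel.freezing_iti.mean())
    rec["extinction_slope_cs"] = bhv.extinction_slope(per_trial.freezing_cs.to_numpy())
    rec["extinction_slope_iti"] = bhv.extinction_slope(per_trial.freezing_iti.to_numpy())
    for phase in ("baseline", "EE", "LE"):
        ep = bhv.epoch_durations(ann, events, phase)
        rec[f"freeze_epoch_{phase}_s"] = ep.freeze_mean_s
        rec[f"move_epoch_{phase}_s"] = ep.move_mean_s
        rec[f"epoch_shortfall_{phase}"] = ep.shortfall
    rears_cs = usvs_cs = rears_iti = usvs_iti = 0
    for row in events.select("extinction").itertuples():
        cs = (row.tone_on_s, row.tone_off_s)
        iti = bhv.iti_window(events, row)
        rears_cs += bhv.count_events(ann, cs, "rear")
        usvs_cs += bhv.count_events(ann, cs, "usv")
        rears_iti += bhv.count_events(ann, iti, "rear")
        usvs_iti += bhv.count_events(ann, iti, "usv")
    rec.update(rear_count_cs=rears_cs, rear_count_iti=rears_iti,
               usv_count_cs=usvs_cs, usv_count_iti=usvs_iti)
    return rec


def unit_block_areas(bundle: SessionBundle, n_blocks: int) -> Optional[pd.DataFrame]:
    """Per-block mean response area over the session's type 1 units."""
    units = _accepted_units(bundle)
    rows = []
    type1 = []
    for train in units:
        z_on, z_off = _unit_zpeths(train, bundle.events, "all")
        if z_on.degenerate:
            continue
        det_on = classify.detect_response(z_on)
        det_off = classify.detect_response(z_off)
        if classify.classify_unit(det_on, det_off)[0] == 1:
            type1.append(train)
    if not type1:
        return None
    for b in range(1, n_blocks + 1):
        areas_on, areas_off = [], []
        for train in type1:
            z_on, z_off = _unit_zpeths(train, bundle.events, f"block{b}")
            if z_on.degenerate:
                continue
            areas_on.append(classify.response_metrics(z_on)[0])
            areas_off.append(classify.response_metrics(z_off)[0])
        if areas_on:
            rows.append(
                {"session_id": bundle.session_id, "block": b,
                 "area_onset": float(np.mean(areas_on)), "area_offset": float(np.mean(areas_off))}
            )
    return pd.DataFrame(rows) if rows else None


def neural_behavior_rmcorr(bundles: Sequence[SessionBundle], n_blocks: int) -> pd.DataFrame:
    """rmcorr between per-block response area and freezing %, per condition.

    Onset areas pair with CS+ freezing, offset areas with ITI freezing,
    both averaged over blocks of seven tones; sessions are the subjects.
    """
    cols = ["condition", "pairing", "r_rm", "df", "p_value", "common_slope", "n_subjects"]
    rows = []
    by_cond: dict[str, list] = {}
    for bundle in bundles:
        block_areas = unit_block_areas(bundle, n_blocks)
        if block_areas is None:
            continue
        per_trial = bhv.per_trial_freezing(bundle.behavior, bundle.events)
        freeze = per_trial.groupby("block")[["freezing_cs", "freezing_iti"]].mean()
        merged = block_areas.join(freeze, on="block")
        by_cond.setdefault(bundle.condition, []).append(merged)
    for condition, frames in sorted(by_cond.items()):
        if len(frames) < 2:
            continue
        data = pd.concat(frames, ignore_index=True)
        for pairing, xcol, ycol in (
            ("onset_area~cs_freezing", "area_onset", "freezing_cs"),
            ("offset_area~iti_freezing", "area_offset", "freezing_iti"),
        ):
            try:
                res = bhv.rmcorr(data.session_id.to_numpy(), data[xcol], data[ycol])
            except ValidationError as err:
                log.warning("rmcorr %s/%s undefined: %s", condition, pairing, err)
                continue
            rows.append(
                {"condition": condition, "pairing": pairing, "r_rm": res.r_rm, "df": res.df,
                 "p_value": res.p_value, "common_slope": res.common_slope,
                 "n_subjects": data.session_id.nunique()}
            )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# top level


UNIT_COLUMNS = [
    "session_id", "condition", "unit_id", "phase", "degenerate", "unit_type", "subtype",
    "onset_responsive", "offset_responsive", "area_onset", "area_offset",
    "peak_z_onset", "peak_z_offset", "n_peaks_onset", "n_peaks_offset",
    "max_peak_bin_onset", "max_peak_bin_offset", "excluded_late_peak",
]

BEHAVIOR_COLUMNS = [
    "session_id", "condition",
    "freezing_cs_EE", "freezing_iti_EE", "freezing_cs_LE", "freezing_iti_LE",
    "extinction_slope_cs", "extinction_slope_iti",
    "freeze_epoch_baseline_s", "move_epoch_baseline_s", "epoch_shortfall_baseline",
    "freeze_epoch_EE_s", "move_epoch_EE_s", "epoch_shortfall_EE",
    "freeze_epoch_LE_s", "move_epoch_LE_s", "epoch_shortfall_LE",
    "rear_count_cs", "rear_count_iti", "usv_count_cs", "usv_count_iti",
]


def analyze_cohort(
    bundles: Sequence[SessionBundle], n_blocks: int = 5, keep_going: bool = False
) -> PipelineResults:
    """Run every analysis stage over a list of sessions."""
    unit_frames, erp_frames, behavior_rows = [], [], []
    for bundle in bundles:
        stages = (
            ("units", lambda b=bundle: unit_frames.append(analyze_units(b))),
            ("erp", lambda b=bundle: erp_frames.append(analyze_erps(b))),
            ("behavior", lambda b=bundle: behavior_rows.append(analyze_behavior(b))),
        )
        for stage, fn in stages:
            try:
                fn()
            except (ValidationError, FileNotFoundError) as err:
                if not keep_going:
                    raise ValidationError(f"[{stage}] session {bundle.session_id}: {err}") from err
                log.warning("[%s] session %s failed, continuing: %s", stage, bundle.session_id, err)
    unit_metrics = (
        pd.concat(unit_frames, ignore_index=True) if unit_frames else pd.DataFrame()
    )
    unit_metrics = unit_metrics.reindex(columns=UNIT_COLUMNS)
    erp_cols = ["session_id", "condition", "channel_id", "align", "phase",
                "onset_latency_ms", "peak_latency_ms", "peak_to_peak_uV"]
    erp_metrics = (
        pd.concat(erp_frames, ignore_index=True).reindex(columns=erp_cols)
        if erp_frames
        else pd.DataFrame(columns=erp_cols)
    )
    behavior_summary = pd.DataFrame(behavior_rows).reindex(columns=BEHAVIOR_COLUMNS)
    rm = neural_behavior_rmcorr(bundles, n_blocks)
    return PipelineResults(
        unit_metrics=unit_metrics,
        cohort_summary=cohort_table(unit_metrics),
        erp_metrics=erp_metrics,
        behavior_summary=behavior_summary,
        rmcorr=rm,
        manifest={},
    )


def run_pipeline(
    config: dict,
    seed: int,
    out_dir: Optional[str | Path] = None,
    keep_going: bool = False,
    write_sessions_dir: Optional[str | Path] = None,
) -> PipelineResults:
    """Simulate the configured cohort, analyze it and (optionally) write
    the report; a pure function of (config, seed)."""
    bundles = simulate_cohort(config, seed)
    if write_sessions_dir is not None:
        for b in bundles:
            write_session(b, Path(write_sessions_dir) / b.session_id)
    results = analyze_cohort(bundles, n_blocks=config["protocol"].n_blocks, keep_going=keep_going)
    results.manifest = {
        "config_hash": config.get("config_hash", "unhashed"),
        "seed": int(seed),
        "fearpeth_version": __version__,
        "n_sessions": len(bundles),
    }
    if out_dir is not None:
        write_report(results, out_dir)
    return results
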
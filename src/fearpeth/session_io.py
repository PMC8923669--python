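"""Plain-text session persistence, config parsing and report writing.

A session directory holds:

* ``meta.yaml``      — session id, condition, duration, unit/channel lists
* ``events.csv``     — the trial table (``TrialEvents`` columns)
* ``spikes.csv``     — long table of (unit_id, time_s)
* ``behavior_states.csv`` / ``behavior_events.csv``
* ``lfp_<channel>.csv``  — one sample column per channel
* ``features.csv``   — spike_id, cluster label, f1..fK (optional)

All files are comma-separated UTF-8 with "." decimals; times are seconds
on a session clock starting at 0.  Reading rejects, never repairs,
invariant violations, naming the offending file and rule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from fearpeth.core import (
    BehaviorAnnotation,
    ClusterFeatures,
    LfpTrace,
    SessionBundle,
    SpikeTrain,
    TrialEvents,
    ValidationError,
)
from fearpeth.specs import BehaviorSpec, ClusterSpec, LfpSpec, ProtocolSpec, UnitSpec

FORMAT_VERSION = 1


def _fail(path: Path, msg: str) -> None:
    raise ValidationError(f"{path.name}: {msg}")


def write_session(bundle: SessionBundle, path: str | Path) -> Path:
    """Write one session bundle to a directory (created if needed)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "format_version": FORMAT_VERSION,
        "session_id": bundle.session_id,
        "condition": bundle.condition,
        "duration_s": bundle.events.duration_s,
        "unit_ids": [t.unit_id for t in bundle.spike_trains],
        "lfp_channels": [
            {"channel_id": t.channel_id, "sample_rate_hz": t.sample_rate_hz} for t in bundle.lfps
        ],
        "has_features": bundle.cluster_features is not None,
    }
    (path / "meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False), encoding="utf-8")
    bundle.events.df.to_csv(path / "events.csv", index=False)
    spikes = pd.DataFrame(
        [(t.unit_id, x) for t in bundle.spike_trains for x in t.times_s],
        columns=["unit_id", "time_s"],
    )
    spikes.to_csv(path / "spikes.csv", index=False)
    bundle.behavior.states.to_csv(path / "behavior_states.csv", index=False)
    bundle.behavior.events.to_csv(path / "behavior_events.csv", index=False)
    for trace in bundle.lfps:
        pd.DataFrame({"sample_uV": trace.samples_uV}).to_csv(
            path / f"lfp_{trace.channel_id}.csv", index=False
        )
    if bundle.cluster_features is not None:
        feats = bundle.cluster_features
        cols = {"spike_id": np.arange(feats.features.shape[0]), "label": feats.labels}
        for j in range(feats.n_features):
            cols[f"f{j + 1}"] = feats.features[:, j]
        pd.DataFrame(cols).to_csv(path / "features.csv", index=False)
    return path


def _read_csv(path: Path, columns: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"missing session file: {path}")
    # round_trip parsing so written shortest-repr floats read back bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        _fail(path, f"missing columns {missing}")
    return df


def read_session(path: str | Path) -> SessionBundle:
    """Read and fully validate a session directory."""
    path = Path(path)
    meta_path = path / "meta.yaml"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing session file: {meta_path}")
    meta = yaml.safe_load(meta_path.read_text(encoding="utf-8"))
    duration = float(meta["duration_s"])

    events_df = _read_csv(path / "events.csv", list(TrialEvents.COLUMNS))
    try:
        events = TrialEvents(events_df, duration_s=duration)
    except ValidationError as err:
        _fail(path / "events.csv", str(err))

    spikes = _read_csv(path / "spikes.csv", ["unit_id", "time_s"])
    trains = []
    for unit_id in meta.get("unit_ids", sorted(spikes.unit_id.unique())):
        times = spikes.loc[spikes.unit_id == unit_id, "time_s"].to_numpy(float)
        try:
            trains.append(SpikeTrain(unit_id=str(unit_id), times_s=times))
        except ValidationError as err:
            _fail(path / "spikes.csv", str(err))

    states = _read_csv(path / "behavior_states.csv", ["start_s", "end_s", "state"])
    bev_path = path / "behavior_events.csv"
    bev = _read_csv(bev_path, ["time_s", "kind"]) if bev_path.exists() else pd.DataFrame(
        {"time_s": pd.Series(dtype=float), "kind": pd.Series(dtype=str)}
    )
    if bev.empty:
        bev = pd.DataFrame({"time_s": pd.Series(dtype=float), "kind": pd.Series(dtype=str)})
    try:
        behavior = BehaviorAnnotation(states, bev, duration_s=duration)
    except ValidationError as err:
        _fail(path / "behavior_states.csv", str(err))

    lfps = []
    for chan in meta.get("lfp_channels", []):
        cid = str(chan["channel_id"])
        df = _read_csv(path / f"lfp_{cid}.csv", ["sample_uV"])
        lfps.append(
            LfpTrace(
                channel_id=cid,
                sample_rate_hz=float(chan["sample_rate_hz"]),
                samples_uV=df.sample_uV.to_numpy(float),
            )
        )

    features = None
    if meta.get("has_features"):
        fdf = _read_csv(path / "features.csv", ["spike_id", "label"])
        fcols = [c for c in fdf.columns if c.startswith("f") and c[1:].isdigit()]
        features = ClusterFeatures(
            features=fdf[fcols].to_numpy(float), labels=fdf.label.to_numpy(int)
        )

    return SessionBundle(
        session_id=str(meta["session_id"]),
        condition=str(meta["condition"]),
        spike_trains=trains,
        events=events,
        lfps=lfps,
        behavior=behavior,
        cluster_features=features,
    )


# ---------------------------------------------------------------------------
# reports

REPORT_TABLES = (
    "unit_metrics",
    "cohort_summary",
    "erp_metrics",
    "behavior_summary",
    "rmcorr",
)


def write_report(results: Any, path: str | Path) -> Path:
    """Emit the fixed set of delimited result tables plus a run manifest.

    ``results`` is a :class:`fearpeth.pipeline.PipelineResults`; tables are
    written with a fixed column order so repeated runs are byte-identical.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for name in REPORT_TABLES:
        df = getattr(results, name)
        df.to_csv(path / f"{name}.csv", index=False)
    manifest = dict(results.manifest)
    (path / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return path


# ---------------------------------------------------------------------------
# configuration

_SPEC_CLASSES = {
    "protocol": ProtocolSpec,
    "behavior": BehaviorSpec,
    "lfp": LfpSpec,
    "cluster": ClusterSpec,
}


def _build_spec(cls, mapping: dict | None):
    mapping = dict(mapping or {})
    for key in ("iti_range_s", "onset_kernel", "offset_kernel", "channel_gains"):
        if key in mapping and mapping[key] is not None:
            mapping[key] = tuple(mapping[key])
    if cls is ClusterSpec:
        mapping["cluster_means"] = tuple(tuple(m) for m in mapping["cluster_means"])
        if mapping.get("cluster_sizes"):
            mapping["cluster_sizes"] = tuple(mapping["cluster_sizes"])
    return cls(**mapping)


def parse_config(cfg: dict) -> dict:
    """Turn a nested config mapping into spec objects.

    Expected layout::

        protocol: {...}                  # ProtocolSpec fields
        groups:
          - name: control
            condition: control
            n_sessions: 2
            units:                       # UnitSpec fields (+ optional count)
              - {template: type1_both, count: 3}
            behavior: {...}
            lfp: {...}                   # optional
            cluster: {...}               # optional
    """
    if "groups" not in cfg:
        raise ValidationError("config: missing 'groups' list")
    out: dict[str, Any] = {
        "protocol": _build_spec(ProtocolSpec, cfg.get("protocol")),
        "groups": [],
    }
    for g in cfg["groups"]:
        units = []
        for u in g.get("units", []):
            u = dict(u)
            count = int(u.pop("count", 1))
            units.extend([_build_spec(UnitSpec, u)] * count)
        out["groups"].append(
            {
                "name": str(g.get("name", g["condition"])),
                "condition": str(g["condition"]),
                "n_sessions": int(g.get("n_sessions", 1)),
                "units": units,
                "behavior": _build_spec(BehaviorSpec, g.get("behavior")),
                "lfp": _build_spec(LfpSpec, g["lfp"]) if g.get("lfp") else None,
                "cluster": _build_spec(ClusterSpec, g["cluster"]) if g.get("cluster") else None,
            }
        )
    return out


def load_config(path: str | Path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    parsed = parse_config(cfg)
    parsed["config_hash"] = config_hash(cfg)
    return parsed


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
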
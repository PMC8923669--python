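"""Shared domain containers and their invariants.

Every container validates itself on construction and raises
:class:`ValidationError` (never silently repairs) when an invariant is
broken.  All timelines share one session clock with origin 0 s and all
intervals are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

PHASES = ("habituation", "acquisition", "extinction")
STATES = ("freeze", "move")
EVENT_KINDS = ("rear", "usv")

#: extinction trial indices (1-based) defining early / late extinction
EE_TRIALS = range(1, 15)
LE_TRIALS = range(21, 36)


class ValidationError(ValueError):
    """An input violated a documented container or argument invariant."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times (seconds, session clock) for one unit."""

    unit_id: str
    times_s: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", times)
        _require(times.ndim == 1, f"unit {self.unit_id}: times must be 1-D")
        _require(np.all(np.isfinite(times)), f"unit {self.unit_id}: non-finite spike time")
        if times.size > 1:
            _require(
                bool(np.all(np.diff(times) >= 0)),
                f"unit {self.unit_id}: spike times must be non-decreasing",
            )

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)


class TrialEvents:
    """The conditioning protocol realised as timestamped trial events.

    One row per trial with 1-based ``trial_index`` (restarting per phase,
    matching the convention "trials 1-14" for early extinction), a phase
    label, the extinction block (1-based; 0 outside extinction), tone
    on/offset times and optional footshock (US) on/offset times.
    """

    COLUMNS = ("trial_index", "phase", "block", "tone_on_s", "tone_off_s", "us_on_s", "us_off_s")

    def __init__(self, df: pd.DataFrame, duration_s: float):
        df = df.reset_index(drop=True)
        for col in self.COLUMNS:
            _require(col in df.columns, f"events: missing column {col!r}")
        self.df = df[list(self.COLUMNS)].copy()
        self.duration_s = float(duration_s)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        _require(self.duration_s > 0, "events: session duration must be positive")
        for i, row in df.iterrows():
            _require(row.phase in PHASES, f"events row {i}: unknown phase {row.phase!r}")
            _require(
                row.tone_on_s < row.tone_off_s,
                f"events row {i}: tone_off_s must exceed tone_on_s",
            )
            has_us = not (pd.isna(row.us_on_s) and pd.isna(row.us_off_s))
            if has_us:
                _require(
                    row.phase == "acquisition",
                    f"events row {i}: US present outside acquisition",
                )
                _require(
                    row.us_on_s < row.us_off_s,
                    f"events row {i}: us_off_s must exceed us_on_s",
                )
        ends = df[["tone_off_s", "us_off_s"]].max(axis=1).to_numpy(float)
        starts = df["tone_on_s"].to_numpy(float)
        _require(bool(np.all(np.diff(starts) > 0)), "events: trials must be strictly ordered")
        _require(
            bool(np.all(starts[1:] >= ends[:-1])),
            "events: trials must not overlap",
        )
        _require(
            float(np.nanmax(ends, initial=0.0)) <= self.duration_s,
            "events: trial extends past the session duration",
        )
        for phase in PHASES:
            idx = df.loc[df.phase == phase, "trial_index"].to_numpy(int)
            if idx.size:
                _require(
                    bool(np.all(idx == np.arange(1, idx.size + 1))),
                    f"events: {phase} trial_index must run 1..n",
                )

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TrialEvents)
            and self.duration_s == other.duration_s
            and self.df.equals(other.df)
        )

    def select(self, phase: str, subset: str = "all") -> pd.DataFrame:
        """Rows of one phase; ``subset`` narrows extinction to "EE" / "LE"
        (trials 1-14 / 21-35) or a single block ("block1".."blockN")."""
        _require(phase in PHASES, f"unknown phase {phase!r}")
        rows = self.df[self.df.phase == phase]
        if subset == "all":
            return rows
        _require(phase == "extinction", "trial subsets apply to extinction only")
        if subset.startswith("block"):
            return rows[rows.block == int(subset[len("block"):])]
        trials = {"EE": EE_TRIALS, "LE": LE_TRIALS}[subset]
        return rows[rows.trial_index.isin(trials)]

    def align_times(self, rows: pd.DataFrame, align: str) -> np.ndarray:
        col = {"tone_onset": "tone_on_s", "tone_offset": "tone_off_s"}.get(align)
        _require(col is not None, f"unknown alignment {align!r}")
        return rows[col].to_numpy(float)


@dataclass(frozen=True)
class LfpTrace:
    """One channel of low-frequency field potential, regularly sampled."""

    channel_id: str
    sample_rate_hz: float
    samples_uV: np.ndarray

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples_uV, dtype=float)
        object.__setattr__(self, "samples_uV", samples)
        _require(self.sample_rate_hz > 0, f"lfp {self.channel_id}: sample rate must be > 0")
        _require(samples.ndim == 1, f"lfp {self.channel_id}: samples must be 1-D")
        _require(bool(np.all(np.isfinite(samples))), f"lfp {self.channel_id}: non-finite sample")

    @property
    def duration_s(self) -> float:
        return self.samples_uV.size / self.sample_rate_hz


class BehaviorAnnotation:
    """Freeze/move interval stream plus rear / USV point events.

    State intervals are half-open, ordered, non-overlapping and tile the
    session span ``[0, duration)`` with no gaps.
    """

    def __init__(self, states: pd.DataFrame, events: pd.DataFrame, duration_s: float):
        for col in ("start_s", "end_s", "state"):
            _require(col in states.columns, f"behavior states: missing column {col!r}")
        for col in ("time_s", "kind"):
            _require(col in events.columns, f"behavior events: missing column {col!r}")
        self.states = states[["start_s", "end_s", "state"]].reset_index(drop=True).copy()
        self.events = events[["time_s", "kind"]].reset_index(drop=True).copy()
        self.duration_s = float(duration_s)
        self._validate()

    def _validate(self) -> None:
        st = self.states
        _require(len(st) > 0, "behavior states: empty annotation")
        for i, row in st.iterrows():
            _require(row.state in STATES, f"behavior states row {i}: unknown state {row.state!r}")
            _require(row.start_s < row.end_s, f"behavior states row {i}: start must precede end")
        starts = st.start_s.to_numpy(float)
        ends = st.end_s.to_numpy(float)
        _require(starts[0] == 0.0, "behavior states: first interval must start at 0")
        _require(
            bool(np.allclose(starts[1:], ends[:-1])) and bool(np.all(starts[1:] >= ends[:-1] - 1e-9)),
            "behavior states: intervals must tile the session without gaps or overlaps",
        )
        _require(
            abs(ends[-1] - self.duration_s) < 1e-6,
            "behavior states: intervals must span the full session",
        )
        for i, row in self.events.iterrows():
            _require(row.kind in EVENT_KINDS, f"behavior events row {i}: unknown kind {row.kind!r}")
            _require(
                0 <= row.time_s < self.duration_s + 1e-9,
                f"behavior events row {i}: time outside session",
            )

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, BehaviorAnnotation)
            and self.duration_s == other.duration_s
            and self.states.equals(other.states)
            and self.events.equals(other.events)
        )

    def intervals(self, state: str) -> np.ndarray:
        """(n, 2) array of [start, end) intervals for one state."""
        _require(state in STATES, f"unknown state {state!r}")
        rows = self.states[self.states.state == state]
        return rows[["start_s", "end_s"]].to_numpy(float)


@dataclass(frozen=True)
class ClusterFeatures:
    """Per-spike feature vectors with cluster labels (0 = noise)."""

    features: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labels)
        _require(feats.ndim == 2, "cluster features must be a 2-D matrix")
        _require(labels.shape == (feats.shape[0],), "one label per feature row required")
        _require(bool(np.all(np.isfinite(feats))), "cluster features contain non-finite values")

    @property
    def n_features(self) -> int:
        return int(self.features.shape[1])

    def cluster_ids(self) -> list[int]:
        return sorted(int(c) for c in np.unique(self.labels) if c != 0)


@dataclass
class SessionBundle:
    """One animal-session: spikes + events + LFPs + behaviour + clusters."""

    session_id: str
    condition: str
    spike_trains: list[SpikeTrain]
    events: TrialEvents
    lfps: list[LfpTrace]
    behavior: BehaviorAnnotation
    cluster_features: Optional[ClusterFeatures] = None

    CONDITIONS = ("control", "muscimol_like", "dreadd_like")

    def __post_init__(self) -> None:
        _require(self.condition in self.CONDITIONS, f"unknown condition {self.condition!r}")
        unit_ids = [t.unit_id for t in self.spike_trains]
        _require(len(set(unit_ids)) == len(unit_ids), "duplicate unit_id in session")
        chan_ids = [t.channel_id for t in self.lfps]
        _require(len(set(chan_ids)) == len(chan_ids), "duplicate channel_id in session")
        dur = self.events.duration_s
        for train in self.spike_trains:
            if train.n_spikes:
                _require(
                    0 <= train.times_s[0] and train.times_s[-1] <= dur + 1e-9,
                    f"unit {train.unit_id}: spikes outside session span",
                )
        _require(
            abs(self.behavior.duration_s - dur) < 1e-6,
            "behavior annotation span must match the event timeline",
        )

    def unit(self, unit_id: str) -> SpikeTrain:
        for train in self.spike_trains:
            if train.unit_id == unit_id:
                return train
        raise KeyError(unit_id)
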
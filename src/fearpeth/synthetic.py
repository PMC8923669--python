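"""Synthetic session generator.

Every generator is a pure function of ``(spec, events, seed)``: the master
seed is split into fixed per-component sub-streams so that, e.g., adding a
unit never perturbs the behaviour stream.  The statistical structure
matches what the analysis assumes:

* spike trains are inhomogeneous Poisson — baseline rate with rectangular
  event-locked transients (excitatory: rate × (1 + gain); suppressive:
  rate × gain), per-trial latency jitter, multiplicative per-block
  extinction decay, and optional splitting of the tone-offset transient
  into separated sub-peaks;
* behaviour alternates freeze/move with exponential holding times whose
  hazards are modulated while the conditioned tone (and the interval that
  follows it) is "hot", decaying over extinction blocks;
* LFP traces are sums of event-locked single-cycle sine kernels plus
  Gaussian noise;
* spike-sorting features are Gaussian clusters over a broad background.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

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

# fixed sub-seed offsets: one independent stream per component
_OFF_PROTOCOL = 0
_OFF_BEHAVIOR = 1
_OFF_LFP = 2
_OFF_CLUSTERS = 3
_OFF_UNITS = 1000


def component_rng(seed: int, offset: int) -> np.random.Generator:
    """Deterministic per-component random stream from one master seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(offset,)))


# ---------------------------------------------------------------------------
# protocol


def make_protocol(spec: ProtocolSpec, seed: int) -> TrialEvents:
    """Realise the conditioning protocol as a timestamped trial table.

    Trials are laid out habituation → acquisition → extinction on one
    session clock, separated by ITIs drawn uniformly from
    ``spec.iti_range_s`` (one extra draw provides the pre-trial lead-in
    and the post-session tail).  In the delay paradigm the footshock
    starts at tone offset; in the trace paradigm it starts
    ``trace_interval_s`` later.
    """
    rng = component_rng(seed, _OFF_PROTOCOL)
    lo, hi = spec.iti_range_s
    rows = []
    t = float(rng.uniform(lo, hi))
    phase_plan = (
        ("habituation", spec.n_habituation_trials, False),
        ("acquisition", spec.n_acquisition_trials, True),
        ("extinction", spec.n_extinction_trials, False),
    )
    for phase, n_trials, with_us in phase_plan:
        for i in range(1, n_trials + 1):
            tone_on = t
            tone_off = tone_on + spec.tone_duration_s
            us_on = us_off = math.nan
            trial_end = tone_off
            if with_us:
                us_on = tone_off + spec.trace_interval_s
                us_off = us_on + spec.us_duration_s
                trial_end = us_off
            block = (i - 1) // spec.block_size + 1 if phase == "extinction" else 0
            rows.append((i, phase, block, tone_on, tone_off, us_on, us_off))
            t = trial_end + float(rng.uniform(lo, hi))
    df = pd.DataFrame(rows, columns=list(TrialEvents.COLUMNS))
    return TrialEvents(df, duration_s=t)


def _block_scale(phase: str, block: int, decay_per_block: float) -> float:
    if phase != "extinction" or block <= 1:
        return 1.0
    return (1.0 - decay_per_block) ** (block - 1)


# ---------------------------------------------------------------------------
# spike trains


def _transient_windows(
    spec: UnitSpec, events: TrialEvents, rng: np.random.Generator
) -> list[tuple[float, float, float, bool]]:
    """(start, end, gain, excitatory) rate-transient windows, trial by trial."""
    on_exc = spec.template in ("type1_onset", "type1_both", "type3_biphasic")
    on_sup = spec.template == "type4_onset_dec"
    off_exc = spec.template in ("type1_offset", "type1_both")
    off_sup = spec.template in ("type4_offset_dec", "type3_biphasic")
    windows: list[tuple[float, float, float, bool]] = []
    # sub-peaks separated by 1.5 widths of silence so they stay distinct
    # in the trial-averaged histogram
    spacing = 2.5 * spec.response_width_s
    for row in events.df.itertuples():
        scale = _block_scale(row.phase, row.block, spec.extinction_decay_per_block)
        if on_exc or on_sup:
            jit = rng.normal(0.0, spec.latency_jitter_sd_s) if spec.latency_jitter_sd_s else 0.0
            start = row.tone_on_s + spec.response_latency_s + jit
            gain = spec.onset_gain * scale if on_exc else spec.onset_gain
            windows.append((start, start + spec.response_width_s, gain, on_exc))
        if off_exc or off_sup:
            jit = rng.normal(0.0, spec.latency_jitter_sd_s) if spec.latency_jitter_sd_s else 0.0
            base = row.tone_off_s + spec.response_latency_s + jit
            n_sub = spec.n_subpeaks if off_exc else 1
            for k in range(n_sub):
                start = base + k * spacing
                gain = spec.offset_gain * scale if off_exc else spec.offset_gain
                windows.append((start, start + spec.response_width_s, gain, off_exc))
    return windows


def _simulate_unit_impl(
    spec: UnitSpec, events: TrialEvents, rng: np.random.Generator, unit_id: str
) -> SpikeTrain:
    T = events.duration_s
    n_base = rng.poisson(spec.baseline_rate_hz * T)
    base = np.sort(rng.uniform(0.0, T, size=n_base))
    windows = _transient_windows(spec, events, rng)
    keep = np.ones(base.size, dtype=bool)
    extra: list[np.ndarray] = []
    for start, end, gain, excitatory in windows:
        start, end = max(start, 0.0), min(end, T)
        if end <= start:
            continue
        if excitatory:
            n = rng.poisson(spec.baseline_rate_hz * gain * (end - start))
            extra.append(rng.uniform(start, end, size=n))
        else:
            lo, hi = np.searchsorted(base, [start, end])
            in_win = np.arange(lo, hi)
            keep[in_win] &= rng.uniform(size=in_win.size) < gain
    times = np.sort(np.concatenate([base[keep]] + extra)) if extra else base[keep]
    times = _enforce_refractory(np.sort(times), spec.refractory_s)
    return SpikeTrain(unit_id=unit_id, times_s=times)


def _enforce_refractory(times: np.ndarray, dead_time_s: float) -> np.ndarray:
    """Greedy dead-time pruning: drop any spike closer than ``dead_time_s``
    to the previously kept spike."""
    if dead_time_s <= 0 or times.size < 2:
        return times
    kept = np.ones(times.size, dtype=bool)
    last = times[0]
    for i in range(1, times.size):
        if times[i] - last < dead_time_s:
            kept[i] = False
        else:
            last = times[i]
    return times[kept]


def simulate_unit(spec: UnitSpec, events: TrialEvents, seed: int, unit_id: str = "u0") -> SpikeTrain:
    """Inhomogeneous-Poisson spike train for one unit.

    Baseline spikes are homogeneous Poisson over the whole session;
    excitatory transients superpose extra Poisson spikes at rate
    ``baseline × gain`` inside their window, suppressive transients thin
    baseline spikes down to ``baseline × gain``.  Both operations are
    exact for the rectangular transient shape.
    """
    rng = component_rng(seed, _OFF_UNITS)
    return _simulate_unit_impl(spec, events, rng, unit_id)


def simulate_units(
    specs: Sequence[UnitSpec], events: TrialEvents, seed: int, prefix: str = "u"
) -> list[SpikeTrain]:
    """Simulate a population, one independent sub-stream per unit."""
    trains = []
    for i, spec in enumerate(specs):
        rng = component_rng(seed, _OFF_UNITS + i)
        trains.append(_simulate_unit_impl(spec, events, rng, unit_id=f"{prefix}{i:03d}"))
    return trains


# ---------------------------------------------------------------------------
# behaviour


def _modulation_profile(spec: BehaviorSpec, events: TrialEvents) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-constant hazard modulation: edges and per-segment values.

    The modulation applies from each conditioned tone onset until the next
    trial begins (tone + following inter-tone interval), decaying per
    extinction block; habituation tones are unconditioned and unmodulated.
    """
    T = events.duration_s
    edges = [0.0]
    values = [1.0]
    df = events.df
    conditioned = df[df.phase.isin(["acquisition", "extinction"])].reset_index(drop=True)
    for i, row in conditioned.iterrows():
        m_eff = 1.0 + (spec.cs_freeze_modulation - 1.0) * _block_scale(
            row.phase, row.block, spec.modulation_decay_per_block
        )
        start = row.tone_on_s
        end = conditioned.tone_on_s.iloc[i + 1] if i + 1 < len(conditioned) else T
        if start > edges[-1]:
            edges.append(start)
            values.append(m_eff)
        else:  # contiguous with previous window
            values[-1] = m_eff
        edges.append(end)
        values.append(1.0)
    return np.asarray(edges), np.asarray(values)


def simulate_behavior(spec: BehaviorSpec, events: TrialEvents, seed: int) -> BehaviorAnnotation:
    """Alternating freeze/move intervals from a two-state semi-Markov
    process with piecewise-constant, CS-modulated hazards; rear and USV
    events as Poisson points restricted to movement intervals."""
    rng = component_rng(seed, _OFF_BEHAVIOR)
    T = events.duration_s
    edges, mods = _modulation_profile(spec, events)
    scale = spec.epoch_duration_scale

    def hazard(state: str, seg: int) -> float:
        m = mods[seg]
        if state == "move":  # hazard of entering freeze
            return spec.freeze_hazard_baseline * m / scale
        return spec.move_hazard_baseline / (m * scale) if m > 0 else math.inf

    records = []
    t = 0.0
    state = "move"
    seg = 0
    interval_start = 0.0
    while t < T:
        target = rng.exponential(1.0)  # unit-rate cumulative hazard to spend
        # integrate the piecewise-constant hazard until the target is reached
        cur = t
        cur_seg = int(np.searchsorted(edges, cur, side="right") - 1)
        cur_seg = min(cur_seg, len(mods) - 1)
        transition_at = None
        while cur < T:
            seg_end = edges[cur_seg + 1] if cur_seg + 1 < len(edges) else T
            seg_end = min(seg_end, T)
            h = hazard(state, cur_seg)
            if math.isinf(h):
                transition_at = cur
                break
            if h > 0:
                dt_needed = target / h
                if cur + dt_needed < seg_end:
                    transition_at = cur + dt_needed
                    break
                target -= h * (seg_end - cur)
            cur = seg_end
            cur_seg += 1
        if transition_at is None or transition_at >= T:
            break
        if transition_at > interval_start:
            records.append((interval_start, transition_at, state))
            interval_start = transition_at
        state = "freeze" if state == "move" else "move"
        t = transition_at
    if interval_start < T:
        records.append((interval_start, T, state))
    states = pd.DataFrame(records, columns=["start_s", "end_s", "state"])

    ev_rows = []
    move = states[states.state == "move"]
    for kind, rate in (("rear", spec.rear_rate_hz), ("usv", spec.usv_rate_hz)):
        if rate <= 0:
            continue
        for row in move.itertuples():
            n = rng.poisson(rate * (row.end_s - row.start_s))
            ev_rows.extend((float(x), kind) for x in rng.uniform(row.start_s, row.end_s, size=n))
    ev_rows.sort()
    events_df = pd.DataFrame(ev_rows, columns=["time_s", "kind"])
    if events_df.empty:
        events_df = pd.DataFrame({"time_s": pd.Series(dtype=float), "kind": pd.Series(dtype=str)})
    return BehaviorAnnotation(states, events_df, duration_s=T)


# ---------------------------------------------------------------------------
# LFP


def _kernel_samples(lat: float, peak: float, amp: float, fs: float) -> tuple[int, np.ndarray]:
    """Single-cycle sine kernel sampled at ``fs``; returns (offset, wave).

    The wave starts ``lat`` seconds after the event, peaks (positive) at
    ``peak`` and completes one full cycle, so peak-to-peak equals ``amp``.
    """
    period = 4.0 * (peak - lat)
    n = int(round(period * fs))
    k = np.arange(n + 1)
    wave = 0.5 * amp * np.sin(2.0 * math.pi * k / (period * fs))
    return int(round(lat * fs)), wave


def simulate_lfp(spec: LfpSpec, events: TrialEvents, seed: int) -> list[LfpTrace]:
    """Per-channel traces: event-locked kernels (scaled per extinction
    block) plus white Gaussian noise."""
    rng = component_rng(seed, _OFF_LFP)
    fs = spec.sample_rate_hz
    n_samples = int(math.ceil(events.duration_s * fs))
    clean = np.zeros(n_samples)
    for row in events.df.itertuples():
        scale = _block_scale(row.phase, row.block, spec.kernel_decay_per_block)
        for t_event, kern in ((row.tone_on_s, spec.onset_kernel), (row.tone_off_s, spec.offset_kernel)):
            lat, peak, amp = kern
            if amp <= 0:
                continue
            off, wave = _kernel_samples(lat, peak, amp * scale, fs)
            i0 = int(round(t_event * fs)) + off
            i1 = min(i0 + wave.size, n_samples)
            if i0 < n_samples:
                clean[i0:i1] += wave[: i1 - i0]
    gains = spec.channel_gains or tuple(1.0 for _ in range(spec.n_channels))
    traces = []
    for c in range(spec.n_channels):
        noise = rng.normal(0.0, spec.noise_sd_uV, size=n_samples) if spec.noise_sd_uV > 0 else 0.0
        traces.append(
            LfpTrace(channel_id=f"ch{c}", sample_rate_hz=fs, samples_uV=gains[c] * clean + noise)
        )
    return traces


# ---------------------------------------------------------------------------
# cluster features


def simulate_cluster_features(spec: ClusterSpec, seed: int) -> ClusterFeatures:
    """Gaussian clusters (labels 1..K) plus broad background spikes (label 0)."""
    rng = component_rng(seed, _OFF_CLUSTERS)
    feats = []
    labels = []
    for i, (mean, cov, size) in enumerate(
        zip(spec.cluster_means, spec.cluster_covariances, spec.cluster_sizes), start=1
    ):
        feats.append(rng.multivariate_normal(np.asarray(mean, float), cov, size=size))
        labels.append(np.full(size, i))
    if spec.n_noise_spikes:
        centre = np.mean(np.asarray(spec.cluster_means, float), axis=0)
        feats.append(
            rng.normal(centre, spec.noise_spread, size=(spec.n_noise_spikes, spec.n_features))
        )
        labels.append(np.zeros(spec.n_noise_spikes))
    return ClusterFeatures(features=np.vstack(feats), labels=np.concatenate(labels).astype(int))


# ---------------------------------------------------------------------------
# whole sessions


def simulate_session(
    session_id: str,
    condition: str,
    protocol: ProtocolSpec,
    unit_specs: Sequence[UnitSpec],
    behavior: BehaviorSpec,
    lfp: Optional[LfpSpec],
    cluster: Optional[ClusterSpec],
    seed: int,
) -> SessionBundle:
    """Generate one complete session bundle from a master seed."""
    events = make_protocol(protocol, seed)
    trains = simulate_units(unit_specs, events, seed)
    annotation = simulate_behavior(behavior, events, seed)
    lfps = simulate_lfp(lfp, events, seed) if lfp is not None else []
    feats = simulate_cluster_features(cluster, seed) if cluster is not None else None
    return SessionBundle(
        session_id=session_id,
        condition=condition,
        spike_trains=trains,
        events=events,
        lfps=lfps,
        behavior=annotation,
        cluster_features=feats,
    )
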
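"""Auditory event-related potential (ERP) extraction and metrics.

LFP traces are zero-phase band-pass filtered at 1–32 Hz, averaged across
trials aligned to tone onset or offset, and summarised by onset latency,
peak latency and peak-to-peak amplitude.  The onset-latency rule (first
time the mean departs from the pre-event baseline by ``k`` baseline SDs
for ``m`` consecutive samples, defaults k = 2, m = 5) is this module's
own construct; the source recordings' latency criterion is unreported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from fearpeth.core import LfpTrace, TrialEvents, ValidationError

DEFAULT_BAND_HZ = (1.0, 32.0)
DEFAULT_WINDOW_S = (0.2, 0.5)  # (pre, post) around the aligned event


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class ERPTrace:
    align: str
    sample_rate_hz: float
    window_s: tuple[float, float]
    mean_uV: np.ndarray
    sem_uV: np.ndarray
    n_trials: int

    @property
    def n_pre(self) -> int:
        return int(round(self.window_s[0] * self.sample_rate_hz))

    def times_s(self) -> np.ndarray:
        """Sample times relative to the aligned event."""
        return (np.arange(self.mean_uV.size) - self.n_pre) / self.sample_rate_hz


@dataclass(frozen=True)
class ERPMetrics:
    onset_latency_ms: Optional[float]
    peak_latency_ms: Optional[float]
    peak_to_peak_uV: float
    baseline_sd_uV: float

    @property
    def defined(self) -> bool:
        return self.onset_latency_ms is not None


def bandpass_lfp(
    trace: LfpTrace, low_hz: float = DEFAULT_BAND_HZ[0], high_hz: float = DEFAULT_BAND_HZ[1], order: int = 2
) -> LfpTrace:
    """Zero-phase Butterworth band-pass; output length equals input."""
    nyq = trace.sample_rate_hz / 2.0
    _require(0 < low_hz < high_hz < nyq, "band must satisfy 0 < low < high < Nyquist")
    sos = signal.butter(order, [low_hz, high_hz], btype="band", fs=trace.sample_rate_hz, output="sos")
    try:
        filtered = signal.sosfiltfilt(sos, trace.samples_uV)
    except ValueError as err:  # trace shorter than the filter's edge padding
        raise ValidationError(f"lfp {trace.channel_id}: trace too short to filter ({err})")
    return LfpTrace(
        channel_id=trace.channel_id, sample_rate_hz=trace.sample_rate_hz, samples_uV=filtered
    )


def average_erp(
    trace: LfpTrace,
    events: TrialEvents,
    align: str = "tone_onset",
    window_s: tuple[float, float] = DEFAULT_WINDOW_S,
    phase: str = "extinction",
    subset: str = "all",
) -> ERPTrace:
    """Per-sample mean and SEM across the selected trials."""
    pre, post = window_s
    _require(pre >= 0 and post > 0, "window must satisfy pre >= 0, post > 0")
    fs = trace.sample_rate_hz
    rows = events.select(phase, subset)
    _require(len(rows) > 0, f"no trials in phase={phase!r} subset={subset!r}")
    t0s = events.align_times(rows, align)
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    segments = []
    for t0 in t0s:
        i0 = int(round(t0 * fs)) - n_pre
        i1 = i0 + n_pre + n_post
        _require(i0 >= 0 and i1 <= trace.samples_uV.size, "trial window outside the trace")
        segments.append(trace.samples_uV[i0:i1])
    stack = np.vstack(segments)
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return ERPTrace(
        align=align, sample_rate_hz=fs, window_s=(float(pre), float(post)), mean_uV=mean,
        sem_uV=sem, n_trials=n,
    )


def erp_metrics(
    erp: ERPTrace,
    baseline_window_s: Optional[float] = None,
    threshold_sd: float = 2.0,
    min_consecutive_samples: int = 5,
) -> ERPMetrics:
    """Onset latency, peak latency and peak-to-peak amplitude of an ERP.

    Onset = first post-event time where |mean − baseline mean| exceeds
    ``threshold_sd`` × baseline SD for ``min_consecutive_samples``
    consecutive samples; peak = first local extremum of the deviation at
    or after onset; peak-to-peak = max − min of the post-event mean.
    When the baseline SD is zero (noiseless traces) any non-zero
    deviation counts.  If no crossing occurs the latency metrics are
    undefined (None) and only peak-to-peak is reported.
    """
    pre, _ = erp.window_s
    if baseline_window_s is None:
        baseline_window_s = pre
    _require(0 < baseline_window_s <= pre + 1e-12, "baseline window must precede the event")
    fs = erp.sample_rate_hz
    n_pre = erp.n_pre
    n_base = int(round(baseline_window_s * fs))
    base = erp.mean_uV[n_pre - n_base : n_pre]
    b_mean = float(base.mean())
    b_sd = float(base.std())
    post = erp.mean_uV[n_pre:]
    p2p = float(post.max() - post.min())
    dev = np.abs(post - b_mean)
    crossing = dev > threshold_sd * b_sd
    onset_idx = None
    run = 0
    for i, c in enumerate(crossing):
        run = run + 1 if c else 0
        if run >= min_consecutive_samples:
            onset_idx = i - min_consecutive_samples + 1
            break
    if onset_idx is None:
        return ERPMetrics(None, None, p2p, b_sd)
    onset_ms = 1000.0 * onset_idx / fs
    # first local extremum of the deviation at/after onset
    peak_idx = None
    for i in range(max(onset_idx, 1), dev.size - 1):
        if dev[i] >= dev[i - 1] and dev[i] > dev[i + 1]:
            peak_idx = i
            break
    if peak_idx is None:
        peak_idx = int(np.argmax(dev[onset_idx:])) + onset_idx
    peak_ms = 1000.0 * peak_idx / fs
    return ERPMetrics(onset_ms, peak_ms, p2p, b_sd)


def select_best_channel(erps: Sequence[ERPTrace], channel_ids: Sequence[str]) -> str:
    """Channel with the largest mean peak-to-peak response; ties go to the
    lowest list index (documented convention)."""
    _require(len(erps) > 0, "empty ERP list")
    _require(len(erps) == len(channel_ids), "one channel id per ERP required")
    first = erps[0]
    for e in erps:
        _require(
            e.window_s == first.window_s and e.sample_rate_hz == first.sample_rate_hz,
            "mixed ERP geometries",
        )
    p2ps = [float(e.mean_uV[e.n_pre:].max() - e.mean_uV[e.n_pre:].min()) for e in erps]
    return channel_ids[int(np.argmax(p2ps))]
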
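"""Event-aligned spike binning and baseline z-score normalisation.

Peri-event time histograms use 40 ms bins with the aligned event at time
0; bin k covers ``[t0 + kΔ, t0 + (k+1)Δ)``.  Each unit's trial-averaged
histogram is z-scored against the mean and population SD of its own
5 s pre-tone-onset baseline, so post-event bins read directly in baseline
SD units.  Offset-aligned histograms may reuse baseline statistics taken
from the pre-onset window of the same trials (``baseline_stats``), since
the 5 s immediately before tone offset lie inside the tone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from fearpeth.core import SpikeTrain, TrialEvents, ValidationError

DEFAULT_BIN_WIDTH_S = 0.04
DEFAULT_BASELINE_S = 5.0
#: analysis windows (pre, post) in seconds per alignment
DEFAULT_WINDOWS = {"tone_onset": (5.0, 10.0), "tone_offset": (5.0, 5.0)}


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _n_bins(span_s: float, bin_width_s: float) -> int:
    n = span_s / bin_width_s
    _require(abs(n - round(n)) < 1e-9, f"window span {span_s} s is not a multiple of the bin width")
    return int(round(n))


@dataclass(frozen=True)
class PETH:
    """Trial-averaged peri-event histogram (counts per bin)."""

    align: str
    bin_width_s: float
    window_s: tuple[float, float]
    mean_counts: np.ndarray
    n_trials: int

    @property
    def n_pre_bins(self) -> int:
        return _n_bins(self.window_s[0], self.bin_width_s)

    @property
    def n_post_bins(self) -> int:
        return _n_bins(self.window_s[1], self.bin_width_s)

    def bin_starts(self) -> np.ndarray:
        """Bin start times relative to the aligned event."""
        pre, _ = self.window_s
        return -pre + np.arange(self.mean_counts.size) * self.bin_width_s


@dataclass(frozen=True)
class ZScoredPETH:
    """Baseline-normalised PETH; ``degenerate`` flags a zero-variance
    baseline (z undefined, unit excluded from response analysis)."""

    align: str
    bin_width_s: float
    window_s: tuple[float, float]
    z: Optional[np.ndarray]
    baseline_mean: float
    baseline_sd: float
    baseline_window_s: float
    n_trials: int
    degenerate: bool

    @property
    def n_pre_bins(self) -> int:
        return _n_bins(self.window_s[0], self.bin_width_s)

    def post_z(self) -> np.ndarray:
        _require(not self.degenerate, "degenerate z-scored PETH has no z values")
        return self.z[self.n_pre_bins:]


def bin_spikes(
    train: SpikeTrain,
    events: TrialEvents,
    align: str = "tone_onset",
    window_s: Optional[tuple[float, float]] = None,
    bin_width_s: float = DEFAULT_BIN_WIDTH_S,
    phase: str = "extinction",
    subset: str = "all",
) -> PETH:
    """Trial-averaged spike counts aligned to tone onset or offset.

    ``phase``/``subset`` select the trials ("EE" = extinction trials 1-14,
    "LE" = 21-35).  ``window_s = (pre, post)`` must divide evenly into
    bins of ``bin_width_s``.
    """
    if window_s is None:
        window_s = DEFAULT_WINDOWS[align]
    pre, post = window_s
    _require(bin_width_s > 0, "bin_width_s must be > 0")
    _require(pre >= 0 and post > 0, "window must satisfy pre >= 0, post > 0")
    n_bins = _n_bins(pre + post, bin_width_s)
    rows = events.select(phase, subset)
    _require(len(rows) > 0, f"no trials in phase={phase!r} subset={subset!r}")
    t0s = events.align_times(rows, align)
    edges = -pre + np.arange(n_bins + 1) * bin_width_s
    counts = np.zeros(n_bins)
    for t0 in t0s:
        rel = train.times_s - t0
        # half-open bins [edge_k, edge_{k+1})
        idx = np.floor((rel + pre) / bin_width_s).astype(int)
        valid = (rel >= edges[0]) & (idx >= 0) & (idx < n_bins)
        counts += np.bincount(idx[valid], minlength=n_bins)
    return PETH(
        align=align,
        bin_width_s=bin_width_s,
        window_s=(float(pre), float(post)),
        mean_counts=counts / len(t0s),
        n_trials=len(t0s),
    )


def baseline_stats(peth: PETH, baseline_window_s: float = DEFAULT_BASELINE_S) -> tuple[float, float]:
    """Mean and population SD of the baseline bins of a PETH.

    The baseline is the ``baseline_window_s`` stretch ending at the
    aligned event (for onset-aligned PETHs: the pre-tone period).
    """
    pre, _ = peth.window_s
    _require(baseline_window_s > 0, "baseline window must be > 0")
    _require(baseline_window_s <= pre + 1e-12, "baseline window exceeds the pre-event span")
    n_base = _n_bins(baseline_window_s, peth.bin_width_s)
    n_pre = peth.n_pre_bins
    base = peth.mean_counts[n_pre - n_base : n_pre]
    return float(np.mean(base)), float(np.std(base))


def zscore_peth(
    peth: PETH,
    baseline_window_s: float = DEFAULT_BASELINE_S,
    stats: Optional[tuple[float, float]] = None,
) -> ZScoredPETH:
    """Z-score a PETH against its baseline bins (or supplied ``stats``).

    Passing ``stats`` supports offset-aligned histograms normalised to
    the pre-tone-onset baseline of the same trials.
    """
    if stats is None:
        mean, sd = baseline_stats(peth, baseline_window_s)
    else:
        mean, sd = float(stats[0]), float(stats[1])
    degenerate = sd == 0.0
    z = None if degenerate else (peth.mean_counts - mean) / sd
    return ZScoredPETH(
        align=peth.align,
        bin_width_s=peth.bin_width_s,
        window_s=peth.window_s,
        z=z,
        baseline_mean=mean,
        baseline_sd=sd,
        baseline_window_s=float(baseline_window_s),
        n_trials=peth.n_trials,
        degenerate=degenerate,
    )


def average_peths(zpeths: Sequence[ZScoredPETH]) -> tuple[np.ndarray, np.ndarray]:
    """Bin-wise group mean and SEM of z-scored PETHs (mean ± SEM plots)."""
    _require(len(zpeths) > 0, "need at least one z-scored PETH")
    first = zpeths[0]
    for zp in zpeths:
        _require(not zp.degenerate, "degenerate PETHs cannot be averaged")
        _require(
            zp.align == first.align
            and zp.bin_width_s == first.bin_width_s
            and zp.window_s == first.window_s,
            "mixed PETH geometries",
        )
    stack = np.vstack([zp.z for zp in zpeths])
    mean = stack.mean(axis=0)
    n = stack.shape[0]
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return mean, sem
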
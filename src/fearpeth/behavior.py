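"""Behavioural quantification and the repeated-measures correlation.

Freezing is quantified per trial as the percentage of the CS+ window (or
the following inter-tone interval) overlapped by freeze intervals; epoch
durations summarise bout structure around protocol anchors; the
extinction rate is the least-squares slope of freezing % over the first
21 extinction trials; rmcorr estimates the common within-subject slope
between two repeatedly measured variables (subject-specific intercepts,
shared slope) with an F test on the slope term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from fearpeth.core import BehaviorAnnotation, TrialEvents, ValidationError

EXTINCTION_SLOPE_TRIALS = 21  # the first three blocks of seven tones
DEFAULT_BLOCK_SIZE = 7
DEFAULT_N_EPOCHS = 5


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def overlap_s(intervals: np.ndarray, window: tuple[float, float]) -> float:
    """Total overlap (seconds) of half-open intervals with a half-open window."""
    if intervals.size == 0:
        return 0.0
    lo = np.maximum(intervals[:, 0], window[0])
    hi = np.minimum(intervals[:, 1], window[1])
    return float(np.clip(hi - lo, 0.0, None).sum())


def percent_freezing(annotation: BehaviorAnnotation, window: tuple[float, float]) -> float:
    """100 × (freeze-interval overlap with the window) / window length."""
    start, end = window
    _require(start < end, "window start must precede end")
    _require(0 <= start and end <= annotation.duration_s + 1e-9, "window outside session")
    return 100.0 * overlap_s(annotation.intervals("freeze"), window) / (end - start)


def iti_window(events: TrialEvents, row: pd.Series) -> tuple[float, float]:
    """Inter-tone interval after one trial: tone offset → next tone onset
    (or session end)."""
    later = events.df[events.df.tone_on_s > row.tone_on_s]
    end = float(later.tone_on_s.iloc[0]) if len(later) else events.duration_s
    return float(row.tone_off_s), end


def per_trial_freezing(
    annotation: BehaviorAnnotation, events: TrialEvents, phase: str = "extinction"
) -> pd.DataFrame:
    """Per-trial freezing % during the CS+ and the following ITI."""
    rows = events.select(phase)
    records = []
    for row in rows.itertuples():
        cs = percent_freezing(annotation, (row.tone_on_s, row.tone_off_s))
        iti = percent_freezing(annotation, iti_window(events, row))
        records.append((row.trial_index, row.block, cs, iti))
    return pd.DataFrame(records, columns=["trial_index", "block", "freezing_cs", "freezing_iti"])


@dataclass(frozen=True)
class EpochDurations:
    phase: str  # baseline | EE | LE
    freeze_mean_s: float
    move_mean_s: float
    n_freeze: int
    n_move: int
    shortfall: bool  # fewer than the requested epochs were available


def epoch_durations(
    annotation: BehaviorAnnotation,
    events: TrialEvents,
    phase: str,
    k: int = DEFAULT_N_EPOCHS,
) -> EpochDurations:
    """Mean freeze and move bout durations around a protocol anchor.

    baseline: the last ``k`` epochs of each state starting before the
    first extinction CS+ onset; EE: the first ``k`` starting at/after it;
    LE: the first ``k`` starting at/after the tone onset of extinction
    trial 22.  Epochs are attributed by start time and never split.
    """
    ext = events.select("extinction")
    _require(len(ext) > 0, "protocol has no extinction trials")
    first_cs = float(ext.tone_on_s.iloc[0])
    if phase == "baseline":
        pick = lambda starts: starts < first_cs
        take_last = True
    elif phase == "EE":
        pick = lambda starts: starts >= first_cs
        take_last = False
    elif phase == "LE":
        trial22 = ext[ext.trial_index == 22]
        _require(len(trial22) == 1, "LE epochs need extinction trial 22")
        anchor = float(trial22.tone_on_s.iloc[0])
        pick = lambda starts: starts >= anchor
        take_last = False
    else:
        raise ValidationError(f"unknown epoch phase {phase!r}")
    means = {}
    counts = {}
    shortfall = False
    for state in ("freeze", "move"):
        iv = annotation.intervals(state)
        sel = iv[pick(iv[:, 0])]
        sel = sel[-k:] if take_last else sel[:k]
        durations = sel[:, 1] - sel[:, 0]
        counts[state] = int(durations.size)
        shortfall |= durations.size < k
        means[state] = float(durations.mean()) if durations.size else float("nan")
    return EpochDurations(
        phase=phase,
        freeze_mean_s=means["freeze"],
        move_mean_s=means["move"],
        n_freeze=counts["freeze"],
        n_move=counts["move"],
        shortfall=shortfall,
    )


def extinction_slope(
    per_trial: Sequence[float], n_trials: int = EXTINCTION_SLOPE_TRIALS
) -> float:
    """OLS slope (% per trial) of freezing over extinction trials 1..n."""
    y = np.asarray(per_trial, dtype=float)[:n_trials]
    valid = np.isfinite(y)
    _require(int(valid.sum()) >= 2, "need at least two freezing values for a slope")
    x = np.arange(1, y.size + 1, dtype=float)[valid]
    return float(np.polyfit(x, y[valid], 1)[0])


def count_events(
    annotation: BehaviorAnnotation, window: tuple[float, float], kind: str
) -> int:
    """Point events of one kind inside a half-open window."""
    start, end = window
    _require(start < end, "window start must precede end")
    ev = annotation.events
    sel = (ev.kind == kind) & (ev.time_s >= start) & (ev.time_s < end)
    return int(sel.sum())


def block_average(
    per_trial: Sequence[float], block_size: int = DEFAULT_BLOCK_SIZE
) -> tuple[np.ndarray, bool]:
    """Mean per consecutive block; flags a trailing partial block."""
    y = np.asarray(per_trial, dtype=float)
    _require(y.size > 0, "empty per-trial series")
    n_full = y.size // block_size
    partial = y.size % block_size != 0
    means = y[: n_full * block_size].reshape(n_full, block_size).mean(axis=1)
    if partial:
        means = np.append(means, y[n_full * block_size :].mean())
    return means, partial


@dataclass(frozen=True)
class RmCorrResult:
    r_rm: float
    df: int
    p_value: float
    common_slope: float


def rmcorr(subjects: Sequence, x: Sequence[float], y: Sequence[float]) -> RmCorrResult:
    """Repeated-measures correlation (common within-subject association).

    Fits ``y = subject intercepts + common slope · x`` by least squares;
    ``r_rm = sign(slope)·sqrt(SS_slope / (SS_slope + SS_residual))`` with
    ``df = n_observations − n_subjects − 1`` and a p-value from the F
    statistic of the slope term on (1, df).
    """
    subjects = np.asarray(subjects)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _require(x.shape == y.shape == subjects.shape, "subjects, x, y must have equal length")
    ids, inverse = np.unique(subjects, return_inverse=True)
    n_subj = ids.size
    n_obs = x.size
    _require(n_subj >= 2, "need at least two subjects")
    counts = np.bincount(inverse)
    _require(bool(np.all(counts >= 2)), "every subject needs at least two observations")
    df = n_obs - n_subj - 1
    _require(df >= 1, "not enough observations for the error term")
    # within-subject centred x must vary somewhere
    x_centred = x - np.bincount(inverse, weights=x)[inverse] / counts[inverse]
    _require(float(np.sum(x_centred**2)) > 0, "zero within-subject x-variance")

    dummies = np.eye(n_subj)[inverse]
    design_full = np.column_stack([dummies, x])
    beta, *_ = np.linalg.lstsq(design_full, y, rcond=None)
    resid_full = y - design_full @ beta
    ss_res = float(resid_full @ resid_full)
    beta0, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    resid_red = y - dummies @ beta0
    ss_slope = float(resid_red @ resid_red) - ss_res
    ss_slope = max(ss_slope, 0.0)
    slope = float(beta[-1])
    denom = ss_slope + ss_res
    r = np.sqrt(ss_slope / denom) if denom > 0 else 0.0
    r_rm = float(np.sign(slope) * r) if slope != 0 else float(r)
    if ss_res <= 0:  # perfect within-subject fit
        p = 0.0
    else:
        f_stat = ss_slope / (ss_res / df)
        p = float(stats.f.sf(f_stat, 1, df))
    return RmCorrResult(r_rm=r_rm, df=int(df), p_value=p, common_slope=slope)
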
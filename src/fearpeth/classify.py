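"""Response detection, unit typing and response-size statistics.

A significant response is one or more consecutive 40 ms bins whose
z-score is at least 2 baseline SDs (either sign) within the first 500 ms
after the aligned event.  Units are typed from their onset/offset
detections: excitatory responses → type 1 (subtype onset_only /
offset_only / both), no response → type 2, mixed excitatory + inhibitory
→ type 3 (biphasic), inhibitory only → type 4.  Response size is the
trapezoidal integral of z over the first 1 s (arbitrary units); peak
counting and the 100 ms maximal-peak latency histogram follow the same
thresholded-run convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from fearpeth.core import ValidationError
from fearpeth.peth import ZScoredPETH

DEFAULT_SEARCH_WINDOW_S = 0.5
DEFAULT_THRESHOLD_SD = 2.0
DEFAULT_INTEGRATION_S = 1.0


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def round_pct(x: float, ndigits: int = 1) -> float:
    """Percentage rounding, half away from zero (reporting convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResponseDetection:
    responsive: bool
    direction: str  # increase | decrease | none
    first_bin_index: Optional[int]
    search_window_s: float = DEFAULT_SEARCH_WINDOW_S
    threshold_sd: float = DEFAULT_THRESHOLD_SD
    min_consecutive_bins: int = 1


def _window_bins(zpeth: ZScoredPETH, window_s: float) -> int:
    """Number of post-event bins whose start lies before ``window_s``."""
    n_post = zpeth.z.size - zpeth.n_pre_bins
    n = int(np.ceil(window_s / zpeth.bin_width_s - 1e-12))
    _require(n >= 1, "search window shorter than one bin")
    _require(n <= n_post, "search window exceeds the post-event span")
    return n


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    runs = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            runs.append((start, i - start))
            start = None
    if start is not None:
        runs.append((start, len(mask) - start))
    return runs


def detect_response(
    zpeth: ZScoredPETH,
    search_window_s: float = DEFAULT_SEARCH_WINDOW_S,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    min_consecutive_bins: int = 1,
) -> ResponseDetection:
    """Apply the consecutive-bin threshold criterion to one unit.

    Responsive iff at least ``min_consecutive_bins`` consecutive bins
    cross the threshold *in the same direction* (z >= threshold or
    z <= -threshold) within the search window; direction and
    ``first_bin_index`` come from the earliest qualifying run.
    """
    _require(not zpeth.degenerate, "degenerate z-scored PETH rejected")
    _require(min_consecutive_bins >= 1, "min_consecutive_bins must be >= 1")
    n = _window_bins(zpeth, search_window_s)
    z = zpeth.post_z()[:n]
    candidates = []
    for direction, mask in (("increase", z >= threshold_sd), ("decrease", z <= -threshold_sd)):
        for start, length in _runs(mask):
            if length >= min_consecutive_bins:
                candidates.append((start, direction))
    if candidates:
        start, direction = min(candidates)
        return ResponseDetection(
            True, direction, int(start), search_window_s, threshold_sd, min_consecutive_bins
        )
    return ResponseDetection(
        False, "none", None, search_window_s, threshold_sd, min_consecutive_bins
    )


def classify_unit(onset: ResponseDetection, offset: ResponseDetection) -> tuple[int, str]:
    """Type a unit from its onset and offset detections.

    Returns ``(unit_type, subtype)`` with type 1 = excitatory, 2 = no
    response, 3 = biphasic (both directions across the two alignments),
    4 = inhibitory only.  Subtype applies to type 1.
    """
    dirs = {d.direction for d in (onset, offset) if d.responsive}
    if not dirs:
        return 2, "none"
    if dirs == {"increase", "decrease"}:
        return 3, "both_directions"
    if dirs == {"decrease"}:
        return 4, "none"
    if onset.responsive and offset.responsive:
        return 1, "both"
    return (1, "onset_only") if onset.responsive else (1, "offset_only")


def response_metrics(
    zpeth: ZScoredPETH,
    integration_window_s: float = DEFAULT_INTEGRATION_S,
    group_peak_bin: Optional[int] = None,
) -> tuple[float, float]:
    """Response area and peak z over the first second after the event.

    Area is the trapezoidal integral of the post-event z values with unit
    spacing per bin (arbitrary units).  Peak z is the unit's z at
    ``group_peak_bin`` (the bin where the cohort-average response peaks)
    when given, else the unit's own largest-|z| bin in the window.
    """
    _require(not zpeth.degenerate, "degenerate z-scored PETH rejected")
    n = _window_bins(zpeth, integration_window_s)
    z = zpeth.post_z()[:n]
    area = float(np.trapezoid(z))
    if group_peak_bin is not None:
        _require(0 <= group_peak_bin < n, "group peak bin outside the integration window")
        peak = float(z[group_peak_bin])
    else:
        peak = float(z[np.argmax(np.abs(z))])
    return area, peak


def count_peaks(
    zpeth: ZScoredPETH,
    search_window_s: float = DEFAULT_SEARCH_WINDOW_S,
    threshold_sd: float = DEFAULT_THRESHOLD_SD,
    per_bin: bool = False,
    late_scan_window_s: float = DEFAULT_INTEGRATION_S,
) -> tuple[int, bool]:
    """Count significant peaks in the search window.

    A peak is a maximal run of consecutive supra-threshold (|z| >=
    threshold) bins; ``per_bin=True`` instead counts individual
    supra-threshold bins.  ``excluded_late_peak`` is set when any
    supra-threshold run starts after the window but inside the response
    analysis span (``late_scan_window_s``, the 1 s area window by
    default); such units are dropped from peak-count summaries.
    Scanning the full post-event span instead would exclude essentially
    every unit, since ±2 SD chance crossings occur in a few percent of
    bins.
    """
    _require(not zpeth.degenerate, "degenerate z-scored PETH rejected")
    n = _window_bins(zpeth, search_window_s)
    n_late = max(_window_bins(zpeth, late_scan_window_s), n)
    post = zpeth.post_z()
    mask = np.abs(post[:n_late]) >= threshold_sd
    runs_all = _runs(mask)
    inside = [r for r in runs_all if r[0] < n]
    late = any(r[0] >= n for r in runs_all)
    if per_bin:
        n_peaks = int(mask[:n].sum())
    else:
        n_peaks = len(inside)
    return n_peaks, late


def maximal_peak_bin(
    zpeth: ZScoredPETH,
    search_window_s: float = DEFAULT_SEARCH_WINDOW_S,
    hist_bin_s: float = 0.1,
) -> int:
    """100 ms bin index of the unit's maximal (most positive) peak."""
    _require(not zpeth.degenerate, "degenerate z-scored PETH rejected")
    n = _window_bins(zpeth, search_window_s)
    z = zpeth.post_z()[:n]
    k = int(np.argmax(z))
    t = k * zpeth.bin_width_s
    return int(t / hist_bin_s)


def max_peak_latency_hist(
    peak_bins: Sequence[int], search_window_s: float = DEFAULT_SEARCH_WINDOW_S, hist_bin_s: float = 0.1
) -> np.ndarray:
    """Proportion (%) of units whose maximal peak falls in each 100 ms bin."""
    _require(len(peak_bins) > 0, "no units with peaks")
    n_hist = int(round(search_window_s / hist_bin_s))
    counts = np.bincount(np.asarray(peak_bins, int), minlength=n_hist)[:n_hist]
    return 100.0 * counts / counts.sum()


@dataclass
class UnitResponse:
    """Detection outcomes and response metrics for one unit in one phase."""

    unit_id: str
    phase: str  # EE | LE | all
    onset: ResponseDetection
    offset: ResponseDetection
    unit_type: int
    subtype: str
    area_onset: float = float("nan")
    area_offset: float = float("nan")
    peak_z_onset: float = float("nan")
    peak_z_offset: float = float("nan")
    n_peaks_onset: int = 0
    n_peaks_offset: int = 0
    max_peak_bin_onset: Optional[int] = None
    max_peak_bin_offset: Optional[int] = None
    excluded_late_peak: bool = False


def cohort_summary(units: Sequence[UnitResponse]) -> dict[str, dict[str, float]]:
    """Counts and percentages per type and per type 1 subtype.

    Percentages are 100·count/total rounded to one decimal, half away
    from zero; subtype percentages are relative to the type 1 count.
    """
    _require(len(units) > 0, "empty unit list")
    total = len(units)
    out: dict[str, dict[str, float]] = {}
    for t in (1, 2, 3, 4):
        n = sum(1 for u in units if u.unit_type == t)
        out[f"type{t}"] = {"count": n, "percent": round_pct(100.0 * n / total)}
    type1 = [u for u in units if u.unit_type == 1]
    for sub in ("onset_only", "offset_only", "both"):
        n = sum(1 for u in type1 if u.subtype == sub)
        denom = len(type1)
        out[f"type1_{sub}"] = {
            "count": n,
            "percent": round_pct(100.0 * n / denom) if denom else float("nan"),
        }
    out["total"] = {"count": total, "percent": 100.0}
    return out
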
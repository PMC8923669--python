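"""Tetrode cluster-quality metrics and the single-unit acceptance gate.

A candidate cluster passes as a single unit when L-ratio < 0.35,
isolation distance > 15 and fewer than 1% of interspike intervals fall
inside a 2 ms refractory bound (all strict inequalities).  Both distance
metrics are built on the squared Mahalanobis distance of non-member
spikes to the cluster, using the cluster's own mean and (n−1)-normalised
covariance:

* ``L = Σ_noncluster (1 − CDF_{χ², df=n_features}(D²))`` and
  ``L-ratio = L / n_cluster``;
* isolation distance = the n_cluster-th smallest D² among non-members
  (undefined when there are fewer non-members than cluster members).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from fearpeth.core import ClusterFeatures, SpikeTrain, ValidationError

L_RATIO_MAX = 0.35
ISOLATION_DISTANCE_MIN = 15.0
ISI_VIOLATION_MAX = 0.01
DEFAULT_REFRACTORY_S = 0.002


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class QualityMetrics:
    cluster_id: int
    l_ratio: float
    isolation_distance: Optional[float]
    isi_violation_fraction: Optional[float]
    accepted: bool
    rejection_reasons: tuple[str, ...] = ()


def mahalanobis_sq(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of each row of ``points``."""
    diff = points - mean
    try:
        solved = np.linalg.solve(cov, diff.T)
    except np.linalg.LinAlgError as err:
        raise ValidationError("singular cluster covariance") from err
    return np.einsum("ij,ji->i", diff, solved)


def cluster_metrics(features: ClusterFeatures, cluster_id: int) -> tuple[float, Optional[float]]:
    """L-ratio and isolation distance of one cluster against all other spikes."""
    labels = features.labels
    member = labels == cluster_id
    other = ~member
    n_c = int(member.sum())
    d = features.n_features
    _require(n_c > d, f"cluster {cluster_id}: needs more members than features ({n_c} <= {d})")
    _require(int(other.sum()) > 0, f"cluster {cluster_id}: no non-member spikes")
    x = features.features[member]
    mean = x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    d2 = mahalanobis_sq(features.features[other], mean, cov)
    l_value = float(np.sum(stats.chi2.sf(d2, df=d)))
    l_ratio = l_value / n_c
    if d2.size >= n_c:
        isolation = float(np.sort(d2)[n_c - 1])
    else:
        isolation = None
    return l_ratio, isolation


def isi_violation_rate(train: SpikeTrain, refractory_s: float = DEFAULT_REFRACTORY_S) -> float:
    """Fraction of consecutive-spike intervals shorter than the refractory
    bound (contamination proxy)."""
    _require(train.n_spikes >= 2, f"unit {train.unit_id}: need >= 2 spikes for ISI statistics")
    isis = np.diff(train.times_s)
    return float(np.mean(isis < refractory_s))


def accept_unit(
    l_ratio: float,
    isolation_distance: Optional[float],
    isi_violation_fraction: Optional[float],
    cluster_id: int = 0,
) -> QualityMetrics:
    """Apply the three-way single-unit gate (strict inequalities)."""
    reasons = []
    if not l_ratio < L_RATIO_MAX:
        reasons.append(f"l_ratio {l_ratio:.4g} not < {L_RATIO_MAX}")
    if isolation_distance is None:
        reasons.append("isolation_distance undefined (too few non-member spikes)")
    elif not isolation_distance > ISOLATION_DISTANCE_MIN:
        reasons.append(f"isolation_distance {isolation_distance:.4g} not > {ISOLATION_DISTANCE_MIN}")
    if isi_violation_fraction is None:
        reasons.append("isi_violation_fraction undefined (too few spikes)")
    elif not isi_violation_fraction < ISI_VIOLATION_MAX:
        reasons.append(
            f"isi_violation_fraction {isi_violation_fraction:.4g} not < {ISI_VIOLATION_MAX}"
        )
    return QualityMetrics(
        cluster_id=cluster_id,
        l_ratio=l_ratio,
        isolation_distance=isolation_distance,
        isi_violation_fraction=isi_violation_fraction,
        accepted=not reasons,
        rejection_reasons=tuple(reasons),
    )


def session_quality(
    features: ClusterFeatures, trains: dict[int, SpikeTrain]
) -> list[QualityMetrics]:
    """Gate every labelled cluster; ``trains`` maps cluster id → spike train."""
    out = []
    for cid in features.cluster_ids():
        l_ratio, isolation = cluster_metrics(features, cid)
        train = trains.get(cid)
        isi = isi_violation_rate(train) if train is not None and train.n_spikes >= 2 else None
        out.append(accept_unit(l_ratio, isolation, isi, cluster_id=cid))
    return out
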
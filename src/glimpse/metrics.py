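"""Similarity and agreement measures between temporal salience signals.

All operations accept :class:`~glimpse.gaze.SalienceSeries` objects or plain
1D arrays of equal length. Metrics that are undefined for a given input
(zero-mass signals, constant signals) are reported as ``None`` rather than
silently coerced.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gaze import SalienceSeries

__all__ = [
    "ComparisonReport",
    "BinaryReference",
    "signal_distance",
    "signal_iou",
    "soft_precision_recall",
    "rank_correlations",
    "binary_reference_from_changepoints",
    "minmax_normalize",
    "compare",
]


def _values(s) -> np.ndarray:
    v = s.values if isinstance(s, SalienceSeries) else np.asarray(s, dtype=float)
    return np.asarray(v, dtype=float)


def _paired(s1, s2) -> tuple[np.ndarray, np.ndarray]:
    a, b = _values(s1), _values(s2)
    if a.shape != b.shape:
        raise ValueError(f"signals must have equal length, got {a.size} and {b.size}")
    return a, b


@dataclass(frozen=True)
class BinaryReference:
    """A binary reference signal r(t), e.g. scene-change indicator."""

    values: np.ndarray
    changepoints: tuple = ()
    tolerance: int = 0


@dataclass(frozen=True)
class ComparisonReport:
    """All pairwise metrics between two signals (None where undefined)."""

    d: float
    iou: float
    rho: float | None
    tau: float | None
    precision: float | None = None
    recall: float | None = None
    n_frames: int = 0


def signal_distance(s1, s2) -> float:
    """Length-normalized Euclidean distance between two equal-length signals.

    ``sqrt((1/T) * sum_t (s1(t) - s2(t))^2)``; 0 for identical signals and
    1 between the constant-0 and constant-1 signals.
    """
    a, b = _paired(s1, s2)
    if a.size == 0:
        raise ValueError("signals must be non-empty")
    return float(np.sqrt(np.mean(np.square(a - b))))


def signal_iou(s1, s2) -> float:
    """Mean pointwise Jaccard index min/max between nonnegative signals.

    Frames where both signals are exactly 0 agree perfectly and count as 1.
    """
    a, b = _paired(s1, s2)
    if (a < 0).any() or (b < 0).any():
        raise ValueError("IoU requires nonnegative signals")
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    ratio = np.ones_like(hi)
    nz = hi > 0
    ratio[nz] = lo[nz] / hi[nz]
    return float(ratio.mean())


def soft_precision_recall(s, r) -> tuple[float | None, float | None]:
    """Soft precision/recall of a nonnegative score against a reference.

    With ``I = sum_t min(s, r)``, ``S = sum_t s`` and ``R = sum_t r``:
    precision is ``I/S`` and recall ``I/R``. A zero-mass score or reference
    leaves the corresponding metric undefined (``None``).
    """
    a, b = _paired(s, r)
    if (a < 0).any():
        raise ValueError("score signal must be nonnegative")
    inter = float(np.minimum(a, b).sum())
    s_sum = float(a.sum())
    r_sum = float(b.sum())
    precision = inter / s_sum if s_sum > 0 else None
    recall = inter / r_sum if r_sum > 0 else None
    return precision, recall


def rank_correlations(s1, s2) -> tuple[float | None, float | None]:
    """Spearman's rho (average ranks on ties) and Kendall's tau-b.

    Constant signals have no rank ordering; both correlations are then
    undefined and reported as ``None``.
    """
    a, b = _paired(s1, s2)
    if a.size < 2:
        raise ValueError("rank correlations need at least 2 samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return None, None
    rho = stats.spearmanr(a, b).statistic
    tau = stats.kendalltau(a, b).statistic  # tau-b (tie-corrected)
    rho = None if math.isnan(rho) else float(rho)
    tau = None if math.isnan(tau) else float(tau)
    return rho, tau


def binary_reference_from_changepoints(
    changepoints, n_frames: int, tolerance: int
) -> BinaryReference:
    """r(t) = 1 on frames within ``tolerance`` frames of any changepoint."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    cps = tuple(int(c) for c in changepoints)
    for c in cps:
        if not 1 <= c <= n_frames:
            raise ValueError(f"changepoint {c} outside [1, {n_frames}]")
    values = np.zeros(n_frames, dtype=int)
    for c in cps:
        lo = max(1, c - tolerance)
        hi = min(n_frames, c + tolerance)
        values[lo - 1 : hi] = 1
    return BinaryReference(values=values, changepoints=cps, tolerance=int(tolerance))


def minmax_normalize(s) -> np.ndarray:
    """Affinely map a signal onto [0, 1]; a constant signal maps to 0."""
    a = _values(s)
    span = np.ptp(a)
    if span == 0:
        return np.zeros_like(a)
    return (a - a.min()) / span


def compare(s1, s2, reference: BinaryReference | None = None) -> ComparisonReport:
    """All pairwise metrics between two signals in one report.

    Soft precision/recall are computed against ``reference`` when given
    (precision of ``s1``, recall of ``s1``), otherwise left out.
    """
    a, b = _paired(s1, s2)
    rho, tau = rank_correlations(a, b)
    precision = recall = None
    if reference is not None:
        precision, recall = soft_precision_recall(a, reference.values)
    return ComparisonReport(
        d=signal_distance(a, b),
        iou=signal_iou(a, b),
        rho=rho,
        tau=tau,
        precision=precision,
        recall=recall,
        n_frames=a.size,
    )
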
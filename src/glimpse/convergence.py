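"""How many observers does a stable salience estimate need?

The full-panel score ``s_N(t)`` is the reference. For every subset size
``k``, salience is recomputed from sampled k-observer subsets and compared
with ``s_N`` via the length-normalized Euclidean distance; the decay of the
mean distance with ``k`` tells how quickly the estimate converges, i.e. how
few participants a new study could get away with.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .gaze import GazeDataset, GlimpseParams, temporal_salience
from .metrics import signal_distance

__all__ = [
    "ConvergenceResult",
    "count_observer_combinations",
    "sample_observer_subsets",
    "convergence_curve",
]


@dataclass(frozen=True)
class ConvergenceResult:
    """Mean distance to the full-panel score per observer-subset size."""

    ks: np.ndarray          # subset sizes 1..N
    p_of_k: np.ndarray      # subsets evaluated per k: min(pmax, C(N, k))
    mean_d: np.ndarray
    stderr_d: np.ndarray
    pmax: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"k": self.ks, "p_of_k": self.p_of_k, "mean_d": self.mean_d,
             "stderr_d": self.stderr_d}
        )


def count_observer_combinations(n: int, k: int) -> int:
    """Exact number of distinct k-observer subsets of n observers, C(n, k)."""
    if n < 0 or k < 0:
        raise ValueError("n and k must be nonnegative")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    return math.comb(n, k)


def sample_observer_subsets(n: int, k: int, pmax: int, seed: int) -> list[tuple[int, ...]]:
    """Distinct k-subsets of observers 0..n-1, capped at ``pmax`` draws.

    When C(n, k) <= pmax every subset is enumerated (no sampling noise);
    otherwise ``pmax`` distinct subsets are drawn uniformly, reproducibly
    for a given seed.
    """
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    if pmax < 1:
        raise ValueError("pmax must be >= 1")
    total = count_observer_combinations(n, k)
    if total <= pmax:
        return [tuple(c) for c in combinations(range(n), k)]
    rng = np.random.default_rng(seed)
    seen: set[tuple[int, ...]] = set()
    out: list[tuple[int, ...]] = []
    while len(out) < pmax:
        subset = tuple(sorted(rng.choice(n, size=k, replace=False).tolist()))
        if subset not in seen:
            seen.add(subset)
            out.append(subset)
    return out


def convergence_curve(
    dataset: GazeDataset,
    params: GlimpseParams | None = None,
    pmax: int = 400,
    seed: int = 0,
) -> ConvergenceResult:
    """Mean distance d(s_k, s_N) versus subset size k, with standard errors.

    For each k in 1..N, scores min(pmax, C(N, k)) sampled k-observer
    subsets and measures their distance to the full-panel score. At k = N
    the only subset is the full panel, so the distance is exactly 0.
    """
    params = params or GlimpseParams()
    n = dataset.n_observers
    if n < 2:
        raise ValueError("convergence analysis needs at least 2 observers")
    s_full = temporal_salience(dataset, params)
    ks = np.arange(1, n + 1)
    p_of_k = np.zeros(n, dtype=int)
    mean_d = np.zeros(n)
    stderr_d = np.zeros(n)
    for i, k in enumerate(ks):
        subsets = sample_observer_subsets(n, int(k), pmax, seed + int(k))
        dists = np.array(
            [
                signal_distance(temporal_salience(dataset.subset(sub), params), s_full)
                for sub in subsets
            ]
        )
        p_of_k[i] = len(subsets)
        mean_d[i] = dists.mean()
        stderr_d[i] = dists.std(ddof=1) / math.sqrt(len(dists)) if len(dists) > 1 else 0.0
    return ConvergenceResult(
        ks=ks, p_of_k=p_of_k, mean_d=mean_d, stderr_d=stderr_d, pmax=int(pmax), seed=int(seed)
    )
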
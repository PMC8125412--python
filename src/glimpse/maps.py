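"""Temporal salience estimated from spatial salience-map sequences.

When gaze data are unavailable, a per-frame spatial salience map
``S(x, y; t)`` (predicted by any computational model) can be reduced to a
temporal score ``s(t)`` by one of four heuristics:

- MutualInfo: average mutual information between the map at ``t`` and its
  temporal neighbours (consistency of the predicted attention over time);
- MaxValue: the global maximum of the (rescaled) map;
- Spread: concentration of the map mass around its intensity centroid,
  measured with a Gaussian kernel;
- Points: centroids of the thresholded map's connected components are
  treated as surrogate gaze points and fed to the pair-consistency measure.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .gaze import GlimpseParams, SalienceSeries, window_pair_scores

logger = logging.getLogger(__name__)

__all__ = [
    "SalienceMapSequence",
    "SpreadKernel",
    "ComponentSet",
    "ZeroMassError",
    "score_mutual_info",
    "score_max_value",
    "salience_centroid",
    "make_spread_kernel",
    "score_spread",
    "binarize_map",
    "component_centroids",
    "score_points",
]


class ZeroMassError(ValueError):
    """Raised when an operation needs a map with positive total mass."""


class SalienceMapSequence:
    """A sequence of T nonnegative grayscale maps of identical shape.

    Stored as a ``(T, H, W)`` float array. ``value_scale`` documents the
    nominal maximum of the encoding (1.0 for float maps, 255 for 8-bit).
    """

    def __init__(self, maps: np.ndarray, value_scale: float = 1.0) -> None:
        maps = np.asarray(maps, dtype=float)
        if maps.ndim != 3:
            raise ValueError(f"maps must have shape (T, H, W), got {maps.shape}")
        if not np.isfinite(maps).all():
            raise ValueError("maps must be finite")
        if (maps < 0).any():
            raise ValueError("maps must be nonnegative")
        if value_scale <= 0:
            raise ValueError("value_scale must be positive")
        self.maps = maps
        self.value_scale = float(value_scale)

    @property
    def n_frames(self) -> int:
        return self.maps.shape[0]

    @property
    def height(self) -> int:
        return self.maps.shape[1]

    @property
    def width(self) -> int:
        return self.maps.shape[2]

    def __len__(self) -> int:
        return self.n_frames


@dataclass(frozen=True)
class SpreadKernel:
    """Unnormalised 2D Gaussian used by the Spread scorer.

    ``peak`` is 1 at the centre by construction, so a map fully
    concentrated at one pixel scores exactly 1. ``side`` is the
    conventional odd window length ``2*ceil(2*sigma) + 1`` (kept as
    metadata; the kernel is evaluated over the whole map).
    """

    sigma: float
    side: int
    peak: float = 1.0

    def __call__(self, dx: np.ndarray, dy: np.ndarray) -> np.ndarray:
        return self.peak * np.exp(-(np.square(dx) + np.square(dy)) / (2.0 * self.sigma**2))


@dataclass(frozen=True)
class ComponentSet:
    """Connected components of a binarized map and their centroids.

    Centroids are in normalized [0, 1]^2 coordinates (x / W, y / H), one
    per 8-connected component, so they are directly comparable with
    normalized gaze points.
    """

    binary_map: np.ndarray
    centroids: np.ndarray  # (k, 2) normalized (x, y)
    threshold: float


def _digitize(seq: SalienceMapSequence, n_bins: int) -> np.ndarray | None:
    """Quantize all maps linearly over the sequence's global value range."""
    lo = float(seq.maps.min())
    hi = float(seq.maps.max())
    if hi == lo:
        return None
    edges = np.linspace(lo, hi, n_bins + 1)
    return np.clip(np.digitize(seq.maps, edges[1:-1]), 0, n_bins - 1)


def _mutual_information_bits(a: np.ndarray, b: np.ndarray, n_bins: int) -> float:
    """MI in bits between two equally quantized maps, via joint histogram."""
    joint = np.bincount(a.ravel() * n_bins + b.ravel(), minlength=n_bins * n_bins)
    joint = joint.reshape(n_bins, n_bins).astype(float)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = np.outer(px, py)
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def score_mutual_info(
    seq: SalienceMapSequence, theta_t: int = 5, n_bins: int = 64
) -> SalienceSeries:
    """Average mutual information between a map and its temporal neighbours.

    ``s(t)`` averages ``I(S(.;t), S(.;t+k))`` over ``k in [-theta_t, theta_t]``
    excluding the self-term ``k = 0``; neighbours past the sequence ends are
    skipped and the divisor shrinks accordingly. MI is estimated from a
    joint histogram with ``n_bins`` levels per map after linear quantization
    over the sequence's global value range. Units: bits, in
    ``[0, log2(n_bins)]``.
    """
    if theta_t < 1:
        raise ValueError("theta_t must be >= 1")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    t_total = seq.n_frames
    if t_total < 2:
        raise ValueError("need at least 2 frames for mutual information")
    digitized = _digitize(seq, n_bins)
    if digitized is None:
        # Single-valued sequence: zero-entropy marginals, MI identically 0.
        return SalienceSeries(
            np.zeros(t_total), label="mutualinfo", value_range=(0.0, math.log2(n_bins))
        )
    # Each |k| is used by two frames; cache pairwise MI by (frame, offset).
    cache: dict[tuple[int, int], float] = {}

    def pair_mi(f: int, g: int) -> float:
        key = (min(f, g), abs(f - g))
        if key not in cache:
            cache[key] = _mutual_information_bits(digitized[key[0]], digitized[key[0] + key[1]], n_bins)
        return cache[key]

    values = np.zeros(t_total)
    for t in range(t_total):
        acc, cnt = 0.0, 0
        for k in range(-theta_t, theta_t + 1):
            if k == 0 or not 0 <= t + k < t_total:
                continue
            acc += pair_mi(t, t + k)
            cnt += 1
        values[t] = acc / cnt if cnt else 0.0
    return SalienceSeries(values, label="mutualinfo", value_range=(0.0, math.log2(n_bins)))


def score_max_value(seq: SalienceMapSequence) -> SalienceSeries:
    """Global maximum of each map, rescaled to [0, 1] by the value scale."""
    values = seq.maps.max(axis=(1, 2)) / seq.value_scale
    return SalienceSeries(values, label="maxvalue", value_range=(0.0, 1.0))


def salience_centroid(map2d: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted mean pixel position ``(xc, yc)``, 0-based."""
    m = np.asarray(map2d, dtype=float)
    total = m.sum()
    if total <= 0:
        raise ZeroMassError("map has zero total mass; centroid undefined")
    h, w = m.shape
    xs = np.arange(w)
    ys = np.arange(h)
    xc = float((m.sum(axis=0) * xs).sum() / total)
    yc = float((m.sum(axis=1) * ys).sum() / total)
    return xc, yc


def make_spread_kernel(width: int, theta_s: float) -> SpreadKernel:
    """Gaussian kernel whose bandwidth tracks the map width.

    ``sigma = width * theta_s / 2`` translates the normalized spatial scale
    into pixels; the odd window side ``2*ceil(2*sigma) + 1`` follows the
    common computer-vision convention for Gaussian filters.
    """
    if width <= 0 or theta_s <= 0:
        raise ValueError("width and theta_s must be positive")
    sigma = width * theta_s / 2.0
    side = 2 * math.ceil(2 * sigma) + 1
    return SpreadKernel(sigma=sigma, side=side)


def score_spread(seq: SalienceMapSequence, theta_s: float = 0.1) -> SalienceSeries:
    """Concentration of map mass around its centroid.

    ``s(t)`` is the mass-weighted mean of a peak-1 Gaussian centred at the
    salience centroid: 1 when all mass sits at one pixel, small when mass
    is spread far beyond the kernel bandwidth. Zero-mass frames score 0.
    """
    kernel = make_spread_kernel(seq.width, theta_s)
    xs = np.arange(seq.width)
    ys = np.arange(seq.height)
    values = np.zeros(seq.n_frames)
    n_zero = 0
    for t, m in enumerate(seq.maps):
        total = m.sum()
        if total <= 0:
            n_zero += 1
            continue
        xc, yc = salience_centroid(m)
        g = kernel(xs[None, :] - xc, ys[:, None] - yc)
        values[t] = float((m * g).sum() / total)
    if n_zero:
        logger.warning("%d zero-mass maps scored 0 by Spread", n_zero)
    return SalienceSeries(values, label="spread", value_range=(0.0, 1.0))


def _parse_threshold_method(method: str) -> tuple[str, float | None]:
    if method == "otsu":
        return "otsu", None
    m = re.fullmatch(r"fixed:([0-9.]+)", method)
    if m:
        frac = float(m.group(1))
        if not 0.0 <= frac <= 1.0:
            raise ValueError("fixed threshold fraction must be in [0, 1]")
        return "fixed", frac
    raise ValueError(f"unknown threshold method {method!r} (use 'otsu' or 'fixed:<f>')")


def binarize_map(map2d: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Threshold a map to a boolean matrix ``B = S > threshold``.

    ``method`` is ``"otsu"`` (threshold minimising intra-class variance) or
    ``"fixed:<f>"`` (threshold at fraction ``f`` of the map maximum). A
    constant map has no Otsu threshold and yields an empty ``B``.
    """
    m = np.asarray(map2d, dtype=float)
    if (m < 0).any():
        raise ValueError("map must be nonnegative")
    kind, frac = _parse_threshold_method(method)
    if kind == "fixed":
        thresh = frac * float(m.max())
        if m.max() == 0:
            return np.zeros_like(m, dtype=bool)
    else:
        if m.min() == m.max():
            logger.warning("constant map: Otsu threshold undefined, empty binarization")
            return np.zeros_like(m, dtype=bool)
        thresh = float(threshold_otsu(m))
    return m > thresh


def component_centroids(binary_map: np.ndarray) -> ComponentSet:
    """Centroids of the 8-connected components, normalized to [0, 1]^2."""
    b = np.asarray(binary_map, dtype=bool)
    h, w = b.shape
    labelled = label(b, connectivity=2)
    cents = []
    for region in regionprops(labelled):
        yc, xc = region.centroid  # (row, col)
        cents.append((xc / w, yc / h))
    centroids = np.array(cents, dtype=float).reshape(-1, 2)
    return ComponentSet(binary_map=b, centroids=centroids, threshold=math.nan)


def score_points(
    seq: SalienceMapSequence,
    params: GlimpseParams | None = None,
    method: str = "otsu",
) -> SalienceSeries:
    """Pair-consistency of surrogate gaze points hallucinated from maps.

    Each frame's map is thresholded, the centroids of its connected
    components stand in for gaze points, and the windowed pair-consistency
    measure is applied to them unchanged. Noisy maps thereby provide the
    multi-point variability that real multi-observer gaze has naturally.
    """
    params = params or GlimpseParams()
    frame_points = [
        component_centroids(binarize_map(m, method=method)).centroids for m in seq.maps
    ]
    values = window_pair_scores(frame_points, params.theta_s, params.theta_t)
    return SalienceSeries(values, label="points", value_range=(0.0, 1.0))
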
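"""Core gaze containers and the temporal salience measure.

Temporal salience is computed from the observer-spatio-temporal consistency
of raw gaze points: for each frame, all gaze points of all observers within
a temporal window are pooled into an anonymous "bag of gaze points", and the
score is the fraction of point pairs closer than a spatial scale ``theta_s``
(a Ripley's-K-style aggregation statistic, normalised to [0, 1]).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

logger = logging.getLogger(__name__)

__all__ = [
    "GlimpseParams",
    "GazeDataset",
    "PointBag",
    "SalienceSeries",
    "normalize_gaze",
    "aggregate_to_frames",
    "collect_window_points",
    "pair_consistency",
    "temporal_salience",
    "constant_baseline",
]


@dataclass(frozen=True)
class GlimpseParams:
    """Hyperparameters of the measure.

    Parameters
    ----------
    theta_s : float
        Spatial scale: distance threshold in normalized (width/height
        divided) coordinates. Two gaze points closer than ``theta_s`` count
        as a consistent pair. Default 0.1.
    theta_t : int
        Temporal scale: half-window in frames; the bag at frame ``t`` pools
        frames ``[t - theta_t, t + theta_t]``. Default 5.
    """

    theta_s: float = 0.1
    theta_t: int = 5

    def __post_init__(self) -> None:
        if not (self.theta_s > 0):
            raise ValueError(f"theta_s must be > 0, got {self.theta_s}")
        if not (isinstance(self.theta_t, (int, np.integer)) and self.theta_t >= 0):
            raise ValueError(f"theta_t must be a nonnegative integer, got {self.theta_t}")


class GazeDataset:
    """Per-observer, per-frame gaze positions for one video.

    Positions are stored as an ``(N, T, 2)`` float array with NaN marking
    missing samples (blinks, tracking loss). Frames are 1-based in all
    public interfaces; observer rows are 0-based indices into the array.

    Parameters
    ----------
    positions : ndarray, shape (N, T, 2)
        ``positions[o, t - 1] = (x, y)`` for observer ``o`` at frame ``t``.
        Either both coordinates are finite or both are NaN (missing).
    width, height : float
        Source frame size in pixels.
    frame_rate : float
        Frames per second of the source video.
    normalized : bool
        Whether positions were already divided by ``(width, height)``.
    """

    def __init__(
        self,
        positions: np.ndarray,
        width: float,
        height: float,
        frame_rate: float = 25.0,
        normalized: bool = False,
    ) -> None:
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 3 or positions.shape[2] != 2:
            raise ValueError(f"positions must have shape (N, T, 2), got {positions.shape}")
        if positions.shape[0] < 1 or positions.shape[1] < 1:
            raise ValueError("dataset needs at least one observer and one frame")
        if width <= 0 or height <= 0:
            raise ValueError(f"invalid frame dimensions {width}x{height}")
        half_missing = np.isnan(positions).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("samples must have both coordinates or be fully missing")
        self.positions = positions
        self.width = float(width)
        self.height = float(height)
        self.frame_rate = float(frame_rate)
        self.normalized = bool(normalized)

    @property
    def n_observers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def n_missing(self) -> int:
        """Number of (observer, frame) cells with no valid position."""
        return int(np.isnan(self.positions[:, :, 0]).sum())

    def off_screen_mask(self) -> np.ndarray:
        """Boolean (N, T) mask of valid samples lying outside the frame."""
        if self.normalized:
            lo, hi = 0.0, 1.0
            x_hi = y_hi = hi
        else:
            lo, x_hi, y_hi = 0.0, self.width, self.height
        x, y = self.positions[:, :, 0], self.positions[:, :, 1]
        with np.errstate(invalid="ignore"):
            out = (x < lo) | (x > x_hi) | (y < lo) | (y > y_hi)
        return out & ~np.isnan(x)

    @property
    def n_off_screen(self) -> int:
        return int(self.off_screen_mask().sum())

    def subset(self, observers) -> "GazeDataset":
        """Dataset restricted to the given 0-based observer indices."""
        idx = np.asarray(list(observers), dtype=int)
        if idx.size == 0:
            raise ValueError("observer subset must be non-empty")
        return GazeDataset(
            self.positions[idx],
            self.width,
            self.height,
            frame_rate=self.frame_rate,
            normalized=self.normalized,
        )

    def drop_off_screen(self) -> "GazeDataset":
        """Copy with off-screen samples marked missing."""
        pos = self.positions.copy()
        pos[self.off_screen_mask()] = np.nan
        return GazeDataset(pos, self.width, self.height, self.frame_rate, self.normalized)

    def frame_points(self, t: int) -> np.ndarray:
        """Valid gaze points of 1-based frame ``t`` as an (n, 2) array."""
        if not 1 <= t <= self.n_frames:
            raise IndexError(f"frame {t} outside [1, {self.n_frames}]")
        pts = self.positions[:, t - 1]
        return pts[~np.isnan(pts[:, 0])]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format frame-aggregated table (observer, frame, x, y).

        Observer ids are 1-based, frames 1-based; missing samples keep
        their row with empty coordinates.
        """
        n, t = self.n_observers, self.n_frames
        obs = np.repeat(np.arange(1, n + 1), t)
        frames = np.tile(np.arange(1, t + 1), n)
        flat = self.positions.reshape(-1, 2)
        return pd.DataFrame({"observer": obs, "frame": frames, "x": flat[:, 0], "y": flat[:, 1]})


@dataclass(frozen=True)
class PointBag:
    """Anonymous multiset of gaze points pooled over a temporal window.

    Observer identity is deliberately discarded: the measure only looks at
    the spatial aggregation of the pooled points.
    """

    points: np.ndarray  # (n, 2)
    source_frame: int

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class SalienceSeries:
    """A per-frame scalar salience signal ``s(t)``, ``t = 1..T``.

    ``value_range`` documents the closed interval the values live in
    (``(0.0, 1.0)`` for the gaze measure); ``None`` leaves it unchecked.
    """

    values: np.ndarray
    label: str = ""
    value_range: tuple | None = (0.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("salience series must be one-dimensional")
        if self.value_range is not None and self.values.size:
            lo, hi = self.value_range
            if np.nanmin(self.values) < lo - 1e-9 or np.nanmax(self.values) > hi + 1e-9:
                raise ValueError(
                    f"values outside declared range [{lo}, {hi}] for series {self.label!r}"
                )

    def __len__(self) -> int:
        return self.values.size

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


def normalize_gaze(dataset: GazeDataset) -> GazeDataset:
    """Divide x by the frame width and y by the height, mapping to [0, 1].

    Off-screen samples (coordinates outside the frame) are retained — they
    can legitimately signal inconsistent attention — but counted and logged.
    Note the resulting metric is anisotropic for non-square frames: a
    normalized distance mixes width- and height-relative units.
    """
    if dataset.normalized:
        raise ValueError("dataset is already normalized")
    scale = np.array([dataset.width, dataset.height])
    out = GazeDataset(
        dataset.positions / scale,
        dataset.width,
        dataset.height,
        frame_rate=dataset.frame_rate,
        normalized=True,
    )
    n_off = out.n_off_screen
    if n_off:
        logger.warning("%d off-screen gaze samples retained after normalization", n_off)
    return out


def aggregate_to_frames(
    raw: pd.DataFrame,
    frame_rate: float,
    width: float,
    height: float,
    sampling_rate: float | None = None,
    n_frames: int | None = None,
) -> GazeDataset:
    """Average timestamped samples into one position per (observer, frame).

    ``raw`` has columns ``observer`` (ids), ``time`` (seconds, >= 0), ``x``,
    ``y`` (NaN marks invalid samples, e.g. blinks). Frame ``t`` (1-based)
    covers the half-open interval ``[(t-1)/frame_rate, t/frame_rate)``; an
    observer's valid samples inside it are averaged, and frames with no
    valid samples are marked missing for that observer.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    if sampling_rate is not None and sampling_rate < frame_rate:
        raise ValueError("sampling_rate must be at least frame_rate")
    if raw.empty:
        logger.warning("empty gaze stream: returning a single-frame all-missing dataset")
        return GazeDataset(
            np.full((1, n_frames or 1, 2), np.nan), width, height, frame_rate, normalized=False
        )
    if (raw["time"] < 0).any():
        raise ValueError("timestamps must be nonnegative")

    df = raw.copy()
    df["frame"] = np.floor(df["time"].to_numpy() * frame_rate).astype(int) + 1
    valid = df["x"].notna() & df["y"].notna()
    observers = np.sort(df["observer"].unique())
    t_max = n_frames or int(df["frame"].max())
    obs_index = {o: i for i, o in enumerate(observers)}

    positions = np.full((len(observers), t_max, 2), np.nan)
    means = df[valid].groupby(["observer", "frame"])[["x", "y"]].mean()
    for (o, t), row in means.iterrows():
        if 1 <= t <= t_max:
            positions[obs_index[o], t - 1] = (row["x"], row["y"])
    return GazeDataset(positions, width, height, frame_rate, normalized=False)


def _window_bounds(t: int, theta_t: int, n_frames: int) -> tuple[int, int]:
    """Inclusive 1-based bounds of the window at ``t``, clipped to [1, T]."""
    return max(1, t - theta_t), min(n_frames, t + theta_t)


def collect_window_points(dataset: GazeDataset, t: int, theta_t: int) -> PointBag:
    """Pool all valid gaze points in the clipped window around frame ``t``.

    The window spans ``2*theta_t + 1`` frames centred at ``t`` and is
    clipped at the video boundaries, so the bag is defined for every frame
    (with fewer points near the ends).
    """
    if not 1 <= t <= dataset.n_frames:
        raise IndexError(f"frame {t} outside [1, {dataset.n_frames}]")
    lo, hi = _window_bounds(t, theta_t, dataset.n_frames)
    pts = dataset.positions[:, lo - 1 : hi].reshape(-1, 2)
    pts = pts[~np.isnan(pts[:, 0])]
    return PointBag(points=pts, source_frame=t)


def pair_consistency(bag: PointBag | np.ndarray, theta_s: float) -> float:
    """Fraction of unordered point pairs strictly closer than ``theta_s``.

    This is the normalised pair count ``(2 / (n (n-1))) * sum 1[d_ij < theta_s]``
    over unordered pairs. Bags with fewer than two points carry no
    consistency evidence and score 0.
    """
    if theta_s <= 0:
        raise ValueError("theta_s must be positive")
    pts = bag.points if isinstance(bag, PointBag) else np.asarray(bag, dtype=float)
    n = pts.shape[0]
    if n < 2:
        return 0.0
    close = np.count_nonzero(pdist(pts) < theta_s)
    return 2.0 * close / (n * (n - 1))


def _close_pair_counts(frame_points: list[np.ndarray], theta_s: float, theta_t: int):
    """Cache of close-pair counts between frames at offsets 0..2*theta_t.

    ``same[f]`` counts unordered close pairs within frame ``f``;
    ``cross[f][d - 1]`` counts close pairs between frames ``f`` and ``f + d``.
    Lets every window score be assembled without re-measuring distances.
    """
    t_total = len(frame_points)
    span = 2 * theta_t
    same = np.zeros(t_total, dtype=np.int64)
    cross = np.zeros((t_total, span), dtype=np.int64)
    for f, pts in enumerate(frame_points):
        if pts.shape[0] >= 2:
            same[f] = np.count_nonzero(pdist(pts) < theta_s)
        for d in range(1, span + 1):
            g = f + d
            if g >= t_total:
                break
            other = frame_points[g]
            if pts.shape[0] and other.shape[0]:
                cross[f, d - 1] = np.count_nonzero(cdist(pts, other) < theta_s)
    return same, cross


def window_pair_scores(
    frame_points: list[np.ndarray], theta_s: float, theta_t: int
) -> np.ndarray:
    """Pair-consistency score of the clipped window around every frame.

    Shared engine for gaze-based scoring and the centroid-based Points
    scorer: any per-frame point sets can be fed in.
    """
    t_total = len(frame_points)
    counts = np.array([p.shape[0] for p in frame_points], dtype=np.int64)
    same, cross = _close_pair_counts(frame_points, theta_s, theta_t)
    scores = np.zeros(t_total)
    degenerate = 0
    for t in range(1, t_total + 1):
        lo, hi = _window_bounds(t, theta_t, t_total)
        n = int(counts[lo - 1 : hi].sum())
        if n < 2:
            degenerate += 1
            continue
        close = int(same[lo - 1 : hi].sum())
        for f in range(lo - 1, hi):
            dmax = min(hi - 1, f + 2 * theta_t) - f
            if dmax > 0:
                close += int(cross[f, :dmax].sum())
        scores[t - 1] = 2.0 * close / (n * (n - 1))
    if degenerate:
        logger.warning("%d windows had fewer than 2 points; scored 0", degenerate)
    return scores


def temporal_salience(
    dataset: GazeDataset, params: GlimpseParams | None = None
) -> SalienceSeries:
    """Gaze-based temporal salience ``s(t)`` for every frame of the video.

    For each frame, pools all observers' gaze points over the clipped
    temporal window of ``2*theta_t + 1`` frames and scores the fraction of
    point pairs closer than ``theta_s``. High values mean observers looked
    at the same place at the same time — the signature of an
    attention-grabbing moment.
    """
    params = params or GlimpseParams()
    if not dataset.normalized:
        raise ValueError("dataset must be normalized before scoring (see normalize_gaze)")
    frame_points = [dataset.frame_points(t) for t in range(1, dataset.n_frames + 1)]
    values = window_pair_scores(frame_points, params.theta_s, params.theta_t)
    return SalienceSeries(values, label="glimpse", value_range=(0.0, 1.0))


def constant_baseline(n_frames: int, lam: float) -> SalienceSeries:
    """Constant series ``s(t) = lam``, a content-blind baseline."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    return SalienceSeries(
        np.full(n_frames, float(lam)), label=f"baseline λ={lam:g}", value_range=(0.0, 1.0)
    )
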
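"""Reading and writing gaze tables, score series and map sequences.

Formats are deliberately plain: comma-delimited UTF-8 tables for gaze and
scores, per-frame grayscale PNGs (``frame_%06d.png``) or a single ``.npy``
array of shape (T, H, W) for salience maps, and a flat JSON file for
configuration.
"""

from __future__ import annotations

import json
import logging
import re
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .gaze import GazeDataset, SalienceSeries, aggregate_to_frames
from .maps import SalienceMapSequence

logger = logging.getLogger(__name__)

__all__ = [
    "GazeParseError",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_scores",
    "write_scores",
    "read_map_sequence",
    "write_map_sequence",
    "read_changepoints",
    "load_config",
]

_FRAME_FILE = re.compile(r"frame_(\d{6})\.png$")


class GazeParseError(ValueError):
    """Malformed gaze table; the message names the offending line."""


def _check_numeric(df: pd.DataFrame, columns, path) -> pd.DataFrame:
    out = df.copy()
    for col in columns:
        coerced = pd.to_numeric(out[col], errors="coerce")
        bad = coerced.isna() & out[col].notna() & (out[col].astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise GazeParseError(f"{path}: non-numeric value in column {col!r} at line {line}")
        out[col] = coerced
    return out


def read_gaze_csv(
    path,
    width: float,
    height: float,
    frame_rate: float = 25.0,
    normalized: bool = False,
) -> GazeDataset:
    """Load a gaze table into a dataset, validating as it goes.

    Two layouts are accepted, told apart by the header: frame-aggregated
    ``observer,frame,x,y`` (1-based frames, at most one row per
    (observer, frame)) and raw timestamped ``observer,time,x,y`` (seconds;
    averaged into frames here). Empty x/y cells mark missing samples.
    Validation errors name the offending line.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = list(df.columns)
    if cols[:1] != ["observer"] or cols[-2:] != ["x", "y"] or len(cols) != 4:
        raise GazeParseError(
            f"{path}: expected header 'observer,frame,x,y' or 'observer,time,x,y', got {cols}"
        )
    time_key = cols[1]
    if time_key not in ("frame", "time"):
        raise GazeParseError(f"{path}: second column must be 'frame' or 'time', got {time_key!r}")
    df = _check_numeric(df, ["observer", time_key, "x", "y"], path)
    if df["observer"].isna().any() or df[time_key].isna().any():
        line = int((df["observer"].isna() | df[time_key].isna()).idxmax()) + 2
        raise GazeParseError(f"{path}: missing observer/{time_key} at line {line}")

    if time_key == "time":
        dataset = aggregate_to_frames(
            df.rename(columns={"time": "time"}), frame_rate, width, height
        )
    else:
        frames = df["frame"].to_numpy()
        if not np.allclose(frames, np.round(frames)) or (frames < 1).any():
            line = int(np.argmax((frames < 1) | (frames != np.round(frames)))) + 2
            raise GazeParseError(f"{path}: frame must be a positive integer at line {line}")
        dup = df.duplicated(subset=["observer", "frame"], keep=False)
        if dup.any():
            line = int(dup[dup].index[1]) + 2
            raise GazeParseError(f"{path}: duplicate (observer, frame) row at line {line}")
        observers = np.sort(df["observer"].unique())
        obs_index = {o: i for i, o in enumerate(observers)}
        t_max = int(frames.max())
        positions = np.full((len(observers), t_max, 2), np.nan)
        half = df["x"].isna() != df["y"].isna()
        if half.any():
            line = int(half.idxmax()) + 2
            raise GazeParseError(f"{path}: only one of x,y given at line {line}")
        for row in df.itertuples(index=False):
            positions[obs_index[row.observer], int(row.frame) - 1] = (row.x, row.y)
        dataset = GazeDataset(positions, width, height, frame_rate, normalized=normalized)

    logger.info(
        "loaded %s: N=%d observers, T=%d frames, %d missing, %d off-screen",
        path, dataset.n_observers, dataset.n_frames, dataset.n_missing, dataset.n_off_screen,
    )
    return dataset


def write_gaze_csv(dataset: GazeDataset, path) -> None:
    """Write the frame-aggregated ``observer,frame,x,y`` layout."""
    df = dataset.to_dataframe()
    df.to_csv(path, index=False, float_format="%.6f", na_rep="")


def write_scores(series: SalienceSeries, path) -> None:
    """Write a ``frame,score`` table, 1-based frames, 6-decimal scores."""
    frames = np.arange(1, len(series) + 1)
    df = pd.DataFrame({"frame": frames, "score": np.asarray(series)})
    df.to_csv(path, index=False, float_format="%.6f")


def read_scores(path, label: str | None = None) -> SalienceSeries:
    """Read a ``frame,score`` table back into a series (range unchecked)."""
    df = pd.read_csv(path)
    if list(df.columns) != ["frame", "score"]:
        raise GazeParseError(f"{path}: expected header 'frame,score', got {list(df.columns)}")
    df = df.sort_values("frame")
    return SalienceSeries(
        df["score"].to_numpy(float), label=label or Path(path).stem, value_range=None
    )


def _to_grayscale(img: np.ndarray, path) -> np.ndarray:
    if img.ndim == 3:
        logger.warning("%s: RGB input converted to grayscale by luminance", path)
        img = img[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    return np.asarray(img, dtype=float)


def read_map_sequence(path, value_scale: float = 255.0) -> SalienceMapSequence:
    """Load maps from a PNG directory or a ``.npy`` array of shape (T, H, W).

    PNG directories must contain consecutively numbered ``frame_%06d.png``
    files (any starting index); gaps or shape mismatches are errors. RGB
    images are collapsed to luminance with a warning.
    """
    path = Path(path)
    if path.is_dir():
        indexed = {}
        for f in path.iterdir():
            m = _FRAME_FILE.search(f.name)
            if m:
                indexed[int(m.group(1))] = f
        if not indexed:
            raise FileNotFoundError(f"{path}: no frame_%06d.png files found")
        idxs = sorted(indexed)
        expected = list(range(idxs[0], idxs[0] + len(idxs)))
        if idxs != expected:
            missing = sorted(set(expected) - set(idxs))[0]
            raise GazeParseError(f"{path}: frame numbering gap at index {missing:06d}")
        frames = [_to_grayscale(iio.imread(indexed[i]), indexed[i]) for i in idxs]
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            raise GazeParseError(f"{path}: mixed frame shapes {sorted(shapes)}")
        maps = np.stack(frames)
    else:
        maps = np.load(path)
        if maps.ndim != 3:
            raise GazeParseError(f"{path}: expected a (T, H, W) array, got shape {maps.shape}")
    return SalienceMapSequence(maps, value_scale=value_scale)


def write_map_sequence(seq: SalienceMapSequence, directory, start_index: int = 1) -> None:
    """Write each map as an 8-bit grayscale ``frame_%06d.png``.

    Values are rescaled from the sequence's value scale to 0..255 and
    clipped; sub-8-bit precision is lost in this representation.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(seq.maps, start=start_index):
        img = np.clip(m / seq.value_scale * 255.0, 0, 255).astype(np.uint8)
        iio.imwrite(directory / f"frame_{i:06d}.png", img)


def read_changepoints(path) -> list[int]:
    """Read a changepoint list, one 1-based frame index per line."""
    out = []
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        raw = raw.strip()
        if not raw or raw.startswith("#"):
            continue
        try:
            out.append(int(raw))
        except ValueError as exc:
            raise GazeParseError(f"{path}: bad changepoint at line {ln}: {raw!r}") from exc
    return out


def load_config(path) -> dict:
    """Load a flat JSON config mirroring the CLI flags."""
    with open(path) as fh:
        cfg = json.load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a JSON object")
    return cfg
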
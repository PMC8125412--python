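"""Published facts about the SAVAM eye-tracking corpus.

SAVAM (Semiautomatic Visual-Attention Modeling) is a public benchmark of
FullHD videos watched by a large observer panel on a high-speed binocular
tracker. The corpus itself is not bundled; these constants describe it for
sanity checks, documentation and sizing (e.g. how many raw tracker samples
average into one frame).
"""

from __future__ import annotations

N_OBSERVERS = 58
N_VIDEOS = 41
FRAME_RATE = 25.0          # frames / second
TRACKER_RATE = 500.0       # gaze samples / second
WIDTH = 1920               # pixels
HEIGHT = 1080              # pixels
TOTAL_FRAMES = 19_760
REPORTED_MINUTES = 13      # corpus length as reported, rounded to minutes

__all__ = [
    "N_OBSERVERS",
    "N_VIDEOS",
    "FRAME_RATE",
    "TRACKER_RATE",
    "WIDTH",
    "HEIGHT",
    "TOTAL_FRAMES",
    "REPORTED_MINUTES",
    "total_duration_minutes",
    "samples_per_frame",
]


def total_duration_minutes(n_frames: int = TOTAL_FRAMES, frame_rate: float = FRAME_RATE) -> float:
    """Video duration in minutes implied by a frame count and frame rate."""
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    return n_frames / frame_rate / 60.0


def samples_per_frame(tracker_rate: float = TRACKER_RATE, frame_rate: float = FRAME_RATE) -> float:
    """Raw tracker samples averaged into each video frame."""
    if frame_rate <= 0 or tracker_rate <= 0:
        raise ValueError("rates must be positive")
    return tracker_rate / frame_rate
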
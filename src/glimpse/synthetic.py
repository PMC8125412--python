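"""Synthetic multi-observer gaze and matching salience-map sequences.

The generator emulates the structure the salience measure relies on: at
each frame a fraction of observers attends a scripted attractor location
(gaze = attractor + isotropic Gaussian jitter), the rest scatter uniformly
over the screen. Each observer's attending/not-attending state evolves as
a two-state Markov chain, giving the per-observer temporal autocorrelation
that real gaze exhibits. Matching map sequences place a Gaussian blob at
the attractor, scaled by the attending fraction, over nonnegative noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gaze import GazeDataset
from .maps import SalienceMapSequence

__all__ = [
    "Scenario",
    "lissajous_attractor",
    "generate_gaze",
    "generate_salience_maps",
    "uniform_pair_probability",
]


def lissajous_attractor(n_frames: int, cycles: float = 1.5) -> np.ndarray:
    """Smooth closed trajectory inside [0.2, 0.8]^2, one point per frame."""
    phase = np.linspace(0.0, 2.0 * math.pi * cycles, n_frames)
    x = 0.5 + 0.3 * np.sin(phase)
    y = 0.5 + 0.3 * np.sin(2.0 * phase + math.pi / 4)
    return np.column_stack([x, y])


@dataclass
class Scenario:
    """Parameters of one synthetic viewing experiment.

    Defaults describe a mid-sized eye-tracking study: 20 observers watching
    an 8-second clip at 25 fps, with 70% of observers on-target at any
    moment, gaze jitter of 0.03 normalized units around the target, and
    16:9 salience maps with a 4-pixel blob over mild background noise.
    """

    n_observers: int = 20
    n_frames: int = 200
    attractor: np.ndarray | None = None  # (T, 2) in [0,1]^2; default Lissajous
    alpha: float | np.ndarray = 0.7      # attending fraction per frame
    cluster_sd: float = 0.03             # attended gaze spread, normalized units
    switch_prob: float = 0.1             # per-frame chance to re-draw attending state
    map_size: tuple[int, int] = (96, 54)  # (W, H) pixels
    blob_sd: float = 4.0                 # map blob spread, pixels
    noise_sd: float = 0.05               # additive map noise (clipped at 0)
    frame_rate: float = 25.0
    clip_gaze: bool = True               # keep gaze on-screen, as with a fixed display
    seed: int = 0

    def attractor_track(self) -> np.ndarray:
        track = (
            lissajous_attractor(self.n_frames)
            if self.attractor is None
            else np.asarray(self.attractor, dtype=float)
        )
        if track.shape != (self.n_frames, 2):
            raise ValueError(f"attractor must have shape ({self.n_frames}, 2)")
        if (track < 0).any() or (track > 1).any():
            raise ValueError("attractor must stay inside [0, 1]^2")
        return track

    def alpha_track(self) -> np.ndarray:
        a = np.broadcast_to(np.asarray(self.alpha, dtype=float), (self.n_frames,)).copy()
        if (a < 0).any() or (a > 1).any():
            raise ValueError("alpha must be in [0, 1]")
        return a

    def __post_init__(self) -> None:
        if self.n_observers < 1 or self.n_frames < 1:
            raise ValueError("need at least one observer and one frame")
        if self.cluster_sd < 0 or self.blob_sd <= 0 or self.noise_sd < 0:
            raise ValueError("spreads must be nonnegative (blob_sd positive)")
        if not 0.0 <= self.switch_prob <= 1.0:
            raise ValueError("switch_prob must be in [0, 1]")


def generate_gaze(scenario: Scenario) -> GazeDataset:
    """Simulate normalized multi-observer gaze for a scenario.

    Per (observer, frame): an attending observer looks at the attractor
    plus isotropic Gaussian jitter (clipped on-screen unless disabled); a
    non-attending observer looks uniformly anywhere. Attending states
    persist between frames: with probability ``switch_prob`` the state is
    re-drawn as Bernoulli(alpha(t)), otherwise kept — a two-state Markov
    chain whose stationary attending fraction is alpha.
    """
    rng = np.random.default_rng(scenario.seed)
    n, t_total = scenario.n_observers, scenario.n_frames
    track = scenario.attractor_track()
    alpha = scenario.alpha_track()

    states = np.zeros((n, t_total), dtype=bool)
    states[:, 0] = rng.random(n) < alpha[0]
    for t in range(1, t_total):
        redraw = rng.random(n) < scenario.switch_prob
        fresh = rng.random(n) < alpha[t]
        states[:, t] = np.where(redraw, fresh, states[:, t - 1])

    jitter = rng.normal(0.0, scenario.cluster_sd or 0.0, size=(n, t_total, 2))
    attended = track[None, :, :] + jitter
    uniform = rng.uniform(0.0, 1.0, size=(n, t_total, 2))
    positions = np.where(states[:, :, None], attended, uniform)
    if scenario.clip_gaze:
        positions = np.clip(positions, 0.0, 1.0)

    w, h = scenario.map_size
    return GazeDataset(
        positions, width=w, height=h, frame_rate=scenario.frame_rate, normalized=True
    )


def generate_salience_maps(scenario: Scenario) -> SalienceMapSequence:
    """Map sequence matching the scenario's attention script.

    Frame ``t`` holds a peak-``alpha(t)`` isotropic Gaussian blob at the
    attractor position plus nonnegative (clipped) Gaussian noise, so an
    unattended frame with zero noise is an all-zero map.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    w, h = scenario.map_size
    track = scenario.attractor_track()
    alpha = scenario.alpha_track()
    xs = np.arange(w)[None, :]
    ys = np.arange(h)[:, None]
    maps = np.zeros((scenario.n_frames, h, w))
    for t in range(scenario.n_frames):
        cx = track[t, 0] * (w - 1)
        cy = track[t, 1] * (h - 1)
        blob = np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * scenario.blob_sd**2))
        maps[t] = alpha[t] * blob
    if scenario.noise_sd > 0:
        maps += np.clip(rng.normal(0.0, scenario.noise_sd, size=maps.shape), 0.0, None)
    return SalienceMapSequence(maps, value_scale=1.0)


def uniform_pair_probability(theta_s: float) -> float:
    """Probability two i.i.d. uniform points in the unit square fall closer
    than ``theta_s``.

    Closed form ``pi*t^2 - (8/3)*t^3 + t^4/2`` from the distance CDF of the
    square, valid for thresholds up to 1; the corner regime (1, sqrt(2)] is
    not implemented. This is the analytic no-attention floor of the gaze
    measure: with purely uniform gaze, the expected score equals it.
    """
    if theta_s < 0 or theta_s > math.sqrt(2):
        raise ValueError(f"theta_s must be in [0, sqrt(2)], got {theta_s}")
    if theta_s > 1:
        raise NotImplementedError("closed form implemented for theta_s <= 1 only")
    t = theta_s
    return math.pi * t**2 - (8.0 / 3.0) * t**3 + 0.5 * t**4
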
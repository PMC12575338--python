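"""Exogenous driver construction.

The shared input to both latent systems emulates the structure of a
movie stimulus: a piecewise-constant signal that takes one random value
per annotated scene, plus Gaussian noise and light temporal smoothing to
mimic fast fluctuations riding on the slow scene transitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "DriverSignal",
    "build_scene_signal",
    "add_fluctuations",
    "random_scene_boundaries",
    "read_scenes_csv",
    "write_scenes_csv",
    "write_driver_csv",
]


@dataclass
class DriverSignal:
    """The exogenous input v(t) on a uniform sampling grid."""

    times: np.ndarray
    values: np.ndarray
    scene_boundaries: np.ndarray  # interior scene-change times, seconds
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values):
            raise ValueError("times and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("driver values must be finite")
        b = np.asarray(self.scene_boundaries, dtype=float)
        if b.size and (b.min() < self.times[0] or b.max() > self.times[-1]):
            raise ValueError("scene boundaries must lie within the time grid")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.times[1] - self.times[0])


def build_scene_signal(
    scene_boundaries, fs: float, duration: float, seed: int = 0
) -> DriverSignal:
    """Piecewise-constant scene signal with one Uniform(0, 1) draw per scene.

    ``scene_boundaries`` are the interior scene-change times; an empty
    list yields a single-scene (constant) signal.
    """
    boundaries = np.asarray(scene_boundaries, dtype=float)
    if boundaries.size and np.any(np.diff(boundaries) <= 0):
        raise ValueError("scene boundaries must be sorted and strictly increasing")
    if boundaries.size and (boundaries.min() <= 0 or boundaries.max() >= duration):
        raise ValueError("scene boundaries must lie strictly inside (0, duration)")
    n = int(round(duration * fs))
    times = np.arange(n) / fs
    n_scenes = boundaries.size + 1
    rng = np.random.Generator(np.random.Philox(key=seed))
    levels = rng.uniform(0.0, 1.0, size=n_scenes)
    scene_idx = np.searchsorted(boundaries, times, side="right")
    values = levels[scene_idx]
    return DriverSignal(
        times=times,
        values=values,
        scene_boundaries=boundaries,
        meta={"kind": "scene", "fs": fs, "duration": duration, "seed": seed,
              "n_scenes": int(n_scenes)},
    )


def add_fluctuations(
    signal: DriverSignal, noise_sd: float = 0.1, smooth_width: float = 0.05,
    seed: int = 0,
) -> DriverSignal:
    """Add white Gaussian noise, then smooth with a Gaussian kernel.

    ``smooth_width`` is the kernel SD in seconds (default 50 ms — a
    light smoothing that leaves scene structure intact).  Boundary
    handling is reflective, which preserves constants exactly;
    ``noise_sd = smooth_width = 0`` is the identity.
    """
    if noise_sd < 0 or smooth_width < 0:
        raise ValueError("noise_sd and smooth_width must be non-negative")
    values = signal.values.copy()
    if noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(key=seed))
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    sigma_samples = smooth_width * signal.fs
    if sigma_samples > 0:
        values = gaussian_filter1d(values, sigma_samples, mode="reflect")
    meta = dict(signal.meta)
    meta.update({"noise_sd": noise_sd, "smooth_width": smooth_width,
                 "fluctuation_seed": seed})
    return DriverSignal(
        times=signal.times.copy(),
        values=values,
        scene_boundaries=signal.scene_boundaries.copy(),
        meta=meta,
    )


def random_scene_boundaries(
    n_scenes: int, duration: float, seed: int = 0, min_scene: float = 0.2
) -> np.ndarray:
    """Random interior boundaries giving ``n_scenes`` scenes of random length.

    Each scene is at least ``min_scene`` seconds long.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    if n_scenes * min_scene > duration:
        raise ValueError("duration too short for the requested scene count")
    if n_scenes == 1:
        return np.empty(0)
    rng = np.random.Generator(np.random.Philox(key=seed))
    raw = rng.uniform(size=n_scenes)
    lengths = min_scene + raw / raw.sum() * (duration - n_scenes * min_scene)
    return np.cumsum(lengths)[:-1]


def read_scenes_csv(path) -> np.ndarray:
    """Read a two-column scene-annotation CSV (scene_id, onset_seconds).

    Returns the interior boundaries (onsets after the first scene).
    """
    df = pd.read_csv(path)
    expected = ["scene_id", "onset_seconds"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    onsets = df["onset_seconds"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError(f"{path}: scene onsets must be strictly increasing")
    return onsets[1:] if onsets.size else np.empty(0)


def write_scenes_csv(path, scene_boundaries, duration: float | None = None) -> None:
    """Write scene annotations; the first scene is assumed to start at 0."""
    onsets = np.concatenate(([0.0], np.asarray(scene_boundaries, dtype=float)))
    df = pd.DataFrame(
        {"scene_id": np.arange(len(onsets)), "onset_seconds": onsets}
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")


def write_driver_csv(path, driver: DriverSignal) -> None:
    df = pd.DataFrame({"time": driver.times, "value": driver.values})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
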
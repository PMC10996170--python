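"""Five-landmark extraction from bladder contours.

The landmarks are defined on the segmented bladder boundary of each
frame: the maximum-length diameter of the contour gives the Left and
Right wall points and their midpoint is the Center; the vertical line
through the Center intersects the wall at the Top and Bottom points.
Landmark x/y coordinates are assembled into stride-sampled time series
per clip (default every 10th frame of a 24 fps recording, i.e. a
2.4 Hz effective sample rate).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .preprocess import Clip, SegmentationResult
from .synth_us import CHANNELS

__all__ = [
    "LandmarkError",
    "LandmarkSet",
    "LandmarkSeries",
    "max_diameter_chord",
    "vertical_extents",
    "landmarks_from_contour",
    "extract_series",
]


class LandmarkError(ValueError):
    """Landmark extraction failed for a frame (treated as a missing sample)."""


@dataclass(frozen=True)
class LandmarkSet:
    """The five landmarks of one frame, each as an (x, y) pair."""

    frame_index: int
    center: tuple[float, float]
    left: tuple[float, float]
    right: tuple[float, float]
    top: tuple[float, float]
    bottom: tuple[float, float]

    def as_row(self) -> np.ndarray:
        """Coordinates flattened in :data:`pfmus.synth_us.CHANNELS` order."""
        return np.array([
            *self.center, *self.left, *self.right, *self.top, *self.bottom,
        ])


def max_diameter_chord(
    contour: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Endpoints and midpoint of the longest chord between contour vertices.

    Exhaustive over all vertex pairs.  Left is the endpoint with the
    smaller x (smaller y on a tie); ties between equally long chords are
    broken by the lexicographically smallest (left, right) pair.
    """
    contour = np.asarray(contour, dtype=float)
    if contour.ndim != 2 or contour.shape[0] < 3 or contour.shape[1] != 2:
        raise ValueError("contour must be an (n >= 3, 2) array")
    d = squareform(pdist(contour))
    dmax = d.max()
    ii, jj = np.nonzero(d == dmax)
    best = None
    for i, j in zip(ii, jj):
        if i >= j:
            continue
        p, q = contour[i], contour[j]
        left, right = sorted((tuple(p), tuple(q)))
        key = (*left, *right)
        if best is None or key < best:
            best = key
    left = np.array(best[:2])
    right = np.array(best[2:])
    return left, right, (left + right) / 2.0


def vertical_extents(
    contour: np.ndarray, center_x: float
) -> tuple[np.ndarray, np.ndarray]:
    """Top and bottom crossings of the vertical line x = center_x.

    Intersections with each contour edge are found by linear
    interpolation; the global minimum-y crossing is Top and the global
    maximum-y crossing is Bottom (a concave wall may cross more than
    twice).  Raises :class:`LandmarkError` when the line misses the
    contour.
    """
    contour = np.asarray(contour, dtype=float)
    x = contour[:, 0]
    y = contour[:, 1]
    x2 = np.roll(x, -1)
    y2 = np.roll(y, -1)

    ys: list[float] = []
    dx = x2 - x
    # Vertical edges lying exactly on the line contribute both endpoints.
    on_line = (dx == 0) & (x == center_x)
    ys.extend(y[on_line])
    ys.extend(y2[on_line])
    # Regular crossings, endpoints included once via half-open interval.
    lo = np.minimum(x, x2)
    hi = np.maximum(x, x2)
    crossing = (dx != 0) & (lo <= center_x) & (center_x <= hi)
    if crossing.any():
        t = (center_x - x[crossing]) / dx[crossing]
        ys.extend(y[crossing] + t * (y2[crossing] - y[crossing]))
    if not ys:
        raise LandmarkError(f"vertical line x={center_x} misses the contour")
    return (
        np.array([center_x, min(ys)]),
        np.array([center_x, max(ys)]),
    )


def landmarks_from_contour(contour: np.ndarray, frame_index: int = 0) -> LandmarkSet:
    """All five landmarks of one contour."""
    left, right, center = max_diameter_chord(contour)
    top, bottom = vertical_extents(contour, center[0])
    return LandmarkSet(
        frame_index=frame_index,
        center=tuple(center),
        left=tuple(left),
        right=tuple(right),
        top=tuple(top),
        bottom=tuple(bottom),
    )


@dataclass
class LandmarkSeries:
    """Stride-sampled 10-channel landmark time series of one clip."""

    clip_id: str
    sample_times_s: np.ndarray        # (n,) seconds from clip start
    frame_indices: np.ndarray         # (n,) frame index within the recording
    values: np.ndarray                # (n, 10) in CHANNELS order, NaN if missing
    missing: np.ndarray               # (n,) bool
    fps: float
    stride: int

    @property
    def sample_rate_hz(self) -> float:
        return self.fps / self.stride

    @property
    def n_samples(self) -> int:
        return len(self.sample_times_s)

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, CHANNELS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(CHANNELS))
        df.insert(0, "clip_id", self.clip_id)
        df.insert(1, "sample_index", np.arange(self.n_samples))
        df.insert(2, "frame_index", self.frame_indices)
        df.insert(3, "missing", self.missing.astype(int))
        return df


def extract_series(
    clip: Clip,
    segmentation_results: Mapping[int, SegmentationResult],
    stride: int = 10,
) -> LandmarkSeries:
    """Landmark series sampled at frames 0, stride, 2·stride, … of a clip.

    Frames whose segmentation failed, or where landmark extraction
    itself fails, become missing samples; the series is emitted
    regardless (a fully failed clip yields an all-missing series).
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if clip.n_frames < 1:
        raise ValueError("clip has no frames")
    sample_frames = np.arange(0, clip.n_frames, stride)
    values = np.full((len(sample_frames), len(CHANNELS)), np.nan)
    missing = np.ones(len(sample_frames), dtype=bool)
    for s, f in enumerate(sample_frames):
        res = segmentation_results.get(f)
        if res is None or not res.ok:
            continue
        try:
            lms = landmarks_from_contour(res.contour, frame_index=f)
        except (LandmarkError, ValueError):
            continue
        values[s] = lms.as_row()
        missing[s] = False
    return LandmarkSeries(
        clip_id=clip.clip_id,
        sample_times_s=sample_frames / clip.fps,
        frame_indices=clip.start_frame + sample_frames,
        values=values,
        missing=missing,
        fps=clip.fps,
        stride=stride,
    )


def write_series_csv(series_list: list[LandmarkSeries], path: str | Path) -> None:
    """All clips' series as one CSV in the canonical column order."""
    frames = [s.to_frame() for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
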
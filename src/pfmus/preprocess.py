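"""Clip trimming and bladder segmentation.

Recordings are cut into per-contraction clips using the contract/rest
call log, and the bladder is segmented in each analysed frame to a
closed contour.  The segmenter is intentionally simple — automatic
bimodal thresholding, morphological closing, largest dark component,
traced outer boundary — which is adequate for the synthetic frames this
package analyses.  Failure is always explicit (``status="failed"``),
never a degenerate contour, so missing-value semantics propagate
cleanly downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import find_contours, label as label_components, regionprops
from skimage.morphology import closing as _closing, disk

from .synth_us import ContractionLabel, EventLog, FrameStack

__all__ = [
    "Clip",
    "SegmentationParams",
    "SegmentationResult",
    "trim_clips",
    "segment_bladder",
]


@dataclass
class Clip:
    """One per-contraction video clip, the unit of analysis."""

    clip_id: str
    recording_id: str
    participant_id: str
    frames: np.ndarray  # (T, H, W) slice of the parent recording
    fps: float
    label: ContractionLabel
    start_s: float
    end_s: float
    start_frame: int

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the dark-region bladder segmenter.

    ``min_area_frac`` — smallest acceptable component, as a fraction of
    the frame (default 1%).  ``smoothing_sigma`` — Gaussian speckle
    reduction (px) applied before thresholding; without it a variance
    threshold on raw speckle is unreliable when the bladder occupies a
    small frame fraction.  ``closing_radius`` — structuring-element
    radius in px for the morphological closing.  ``min_contrast`` and
    ``max_level_ratio`` guard against frames with no genuinely dark
    region (all-bright or occluded), where a bimodal threshold would
    otherwise split background speckle in half.
    """

    min_area_frac: float = 0.01
    smoothing_sigma: float = 1.5
    closing_radius: int = 2
    min_contrast: float = 20.0
    max_level_ratio: float = 0.5


@dataclass
class SegmentationResult:
    frame_index: int
    status: str  # "ok" | "failed"
    contour: np.ndarray | None = None  # (n, 2) of (x, y) when ok

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def trim_clips(
    stack: FrameStack,
    event_log: EventLog,
    labels: Sequence[ContractionLabel | str],
    padding_s: float = 0.5,
    recording_id: str = "rec0",
    participant_id: str = "p0",
) -> list[Clip]:
    """Cut a recording into one clip per contraction.

    The clip window is [contract call, rest call] extended by
    ``padding_s`` on each side and clamped to the recording bounds, so
    onset and release motion around the calls is retained.
    """
    intervals = event_log.contraction_intervals()
    labels = [ContractionLabel.coerce(l) for l in labels]
    if len(labels) != len(intervals):
        raise ValueError(
            f"{len(labels)} labels for {len(intervals)} contraction intervals"
        )
    n_total = stack.n_frames
    clips = []
    for k, ((t0, t1), lab) in enumerate(zip(intervals, labels)):
        start = max(0, int(round((t0 - padding_s) * stack.fps)))
        end = min(n_total, int(round((t1 + padding_s) * stack.fps)))
        if end <= start:
            raise ValueError(f"empty clip window for cycle {k}")
        clips.append(Clip(
            clip_id=f"{recording_id}_c{k}",
            recording_id=recording_id,
            participant_id=participant_id,
            frames=stack.frames[start:end],
            fps=stack.fps,
            label=lab,
            start_s=start / stack.fps,
            end_s=end / stack.fps,
            start_frame=start,
        ))
    return clips


def _shoelace_area(contour: np.ndarray) -> float:
    x, y = contour[:, 0], contour[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def _shoelace_area_rc(curve: np.ndarray) -> float:
    return _shoelace_area(curve[:, ::-1])


def segment_bladder(
    frame: np.ndarray,
    params: SegmentationParams | None = None,
    frame_index: int = 0,
) -> SegmentationResult:
    """Segment the bladder (dominant dark region) in one grayscale frame.

    Pipeline: automatic bimodal (Otsu) threshold → dark mask →
    morphological closing → largest connected component → traced outer
    boundary.  Returns ``status="failed"`` when no dark component of at
    least ``min_area_frac`` of the frame exists, or when the putative
    dark region is not actually dark relative to the background
    (occluded or empty frames).
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("segment_bladder expects a single grayscale frame")
    frame = frame.astype(float)
    failed = lambda: SegmentationResult(frame_index, "failed")

    mask, smoothed, thr = threshold_dark_mask(frame, params)
    if mask is None:
        return failed()
    # Guard: the "dark" side must be genuinely dark, not the lower half
    # of background speckle.
    dark_level = smoothed[mask].mean()
    bright_level = smoothed[~mask].mean()
    if bright_level <= 0 or dark_level / bright_level > params.max_level_ratio:
        return failed()

    mask = _closing(mask, disk(params.closing_radius))
    lab = label_components(mask)
    props = regionprops(lab)
    if not props:
        return failed()
    largest = max(props, key=lambda p: p.area)
    if largest.area < params.min_area_frac * frame.size:
        return failed()

    # Sub-pixel boundary: iso-contour of the smoothed image at the
    # threshold level (the level crossing of the blurred intensity step
    # sits on the true edge, unlike the half-pixel-dilated mask outline).
    # Bright padding guarantees a closed loop even at the frame edge.
    padded = np.pad(smoothed, 1, constant_values=float(smoothed.max()) + 1.0)
    curves = find_contours(padded, thr)
    closed = [
        c[:-1] for c in curves
        if len(c) >= 4 and np.allclose(c[0], c[-1])
    ]
    if not closed:
        return failed()
    boundary = max(closed, key=_shoelace_area_rc)
    contour = boundary[:, ::-1] - 1.0  # (row, col) -> (x, y), undo padding
    if len(contour) < 3 or _shoelace_area(contour) < params.min_area_frac * frame.size:
        return failed()
    return SegmentationResult(frame_index, "ok", contour)


def threshold_dark_mask(
    frame: np.ndarray, params: SegmentationParams | None = None
) -> tuple[np.ndarray | None, np.ndarray, float]:
    """Speckle-smoothed automatic dark/bright mask of one frame.

    Returns ``(mask, smoothed, threshold)`` where mask is True on dark
    pixels, or ``(None, smoothed, nan)`` when the frame has no usable
    bimodal contrast.
    """
    params = params or SegmentationParams()
    frame = np.asarray(frame, dtype=float)
    smoothed = (
        gaussian(frame, sigma=params.smoothing_sigma, preserve_range=True)
        if params.smoothing_sigma > 0 else frame
    )
    if smoothed.max() - smoothed.min() < params.min_contrast:
        return None, smoothed, float("nan")
    thr = float(threshold_otsu(smoothed))
    mask = smoothed < thr
    if not mask.any() or mask.all():
        return None, smoothed, float("nan")
    return mask, smoothed, thr


def segment_clip(
    clip: Clip,
    params: SegmentationParams | None = None,
    frame_indices: Sequence[int] | None = None,
) -> dict[int, SegmentationResult]:
    """Segment selected frames of a clip (all frames by default)."""
    if frame_indices is None:
        frame_indices = range(clip.n_frames)
    return {
        i: segment_bladder(clip.frames[i], params, frame_index=i)
        for i in frame_indices
    }


def write_clip_manifest(clips: Sequence[Clip], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["clip_id", "recording_id", "participant_id", "label", "start_s", "end_s"]
        )
        for c in clips:
            writer.writerow([
                c.clip_id, c.recording_id, c.participant_id,
                c.label.value, f"{c.start_s:.6f}", f"{c.end_s:.6f}",
            ])


def write_contours(results: dict[int, SegmentationResult], path: str | Path) -> None:
    """Contours as CSV rows ``frame_index,vertex_index,x,y`` (ok frames only)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame_index", "vertex_index", "x", "y"])
        for i in sorted(results):
            res = results[i]
            if res.ok:
                for j, (x, y) in enumerate(res.contour):
                    writer.writerow([i, j, f"{x:.3f}", f"{y:.3f}"])
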
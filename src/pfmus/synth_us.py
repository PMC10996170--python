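"""Synthetic transabdominal bladder-ultrasound video generator.

Transverse B-mode views of the bladder show the urine-filled lumen as a
dark (anechoic) region on a bright, speckled background.  During pelvic
floor muscle training (PFMT) a correct contraction elevates the bladder
base (the inferior wall moves cranially), whereas a contraction failure
produces whole-bladder rigid motion driven by abdominal straining and
breathing, with no differential base motion.  This module simulates
recordings of repeated contraction/rest cycles with per-cycle class
labels, an event log of the contraction and rest calls, and exact
ground-truth contours and landmark trajectories.

Image coordinates follow the raster convention: origin at the top-left,
x rightward, y downward.  "Elevation" of the bladder base therefore
means a *decrease* of the Bottom landmark's y coordinate.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
import yaml
from skimage.draw import polygon2mask

__all__ = [
    "CHANNELS",
    "ContractionLabel",
    "SimulationConfig",
    "EventLog",
    "FrameStack",
    "GroundTruth",
    "contour_at",
    "render_frame",
    "simulate_recording",
]

#: Landmark coordinate channel names, in canonical column order.
CHANNELS = (
    "Center_x", "Center_y",
    "Left_x", "Left_y",
    "Right_x", "Right_y",
    "Top_x", "Top_y",
    "Bottom_x", "Bottom_y",
)

# Rendering intensities (uint8 scale): anechoic lumen vs. echogenic
# background.  Levels leave headroom so multiplicative speckle rarely
# saturates at 255, keeping the intensity histogram bimodal.
_LUMEN_LEVEL = 25.0
_BACKGROUND_LEVEL = 160.0
_OCCLUSION_LEVEL = 210.0


class ContractionLabel(str, enum.Enum):
    """Expert classification of one contraction attempt."""

    UNDETERMINABLE = "undeterminable"
    CORRECT = "correct"
    FAILURE = "failure"
    NONE = "none"

    @classmethod
    def coerce(cls, value: "ContractionLabel | str") -> "ContractionLabel":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(f"unknown contraction label: {value!r}") from None


#: Fixed class order used for label columns and confusion matrices.
CLASS_ORDER = (
    ContractionLabel.UNDETERMINABLE,
    ContractionLabel.CORRECT,
    ContractionLabel.FAILURE,
    ContractionLabel.NONE,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording.

    Amplitudes are in pixels, durations in seconds, frequencies in Hz.
    ``semi_axis_x``/``semi_axis_y`` are the resting bladder half-widths;
    varying them across recordings emulates different urine volumes.
    """

    frame_width: int = 128
    frame_height: int = 128
    fps: float = 24.0
    n_contractions: int = 4
    contraction_s: float = 3.0
    rest_s: float = 3.0
    semi_axis_x: float = 30.0
    semi_axis_y: float = 18.0
    base_amplitude_px: float = 10.0
    translation_amplitude_px: float = 8.0
    breathing_freq_hz: float = 0.25
    jitter_px: float = 0.3
    speckle_var: float = 0.02
    dropout_prob: float = 0.6
    seed: int = 0
    n_vertices: int = 180

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.n_contractions < 1:
            raise ValueError("n_contractions must be >= 1")
        if self.semi_axis_x <= 0 or self.semi_axis_y <= 0:
            raise ValueError("semi-axes must be positive")
        if min(self.base_amplitude_px, self.translation_amplitude_px,
               self.jitter_px, self.speckle_var) < 0:
            raise ValueError("amplitudes and variances must be non-negative")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.contraction_s <= 0 or self.rest_s < 0:
            raise ValueError("contraction_s must be > 0 and rest_s >= 0")
        if self.n_vertices < 3:
            raise ValueError("n_vertices must be >= 3")

    @property
    def cycle_s(self) -> float:
        return self.contraction_s + self.rest_s

    @property
    def duration_s(self) -> float:
        return self.n_contractions * self.cycle_s

    @property
    def center(self) -> tuple[float, float]:
        """Resting bladder centre, at the middle of the frame."""
        return self.frame_width / 2.0, self.frame_height / 2.0

    def to_yaml(self, path: str | Path) -> None:
        data = {
            f.name: (v.item() if hasattr(v, "item") else v)
            for f in fields(self)
            for v in [getattr(self, f.name)]
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass(frozen=True)
class EventLog:
    """Ordered contraction/rest call times, alternating starting with contract."""

    events: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        times = [t for _, t in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be strictly increasing")
        for i, (kind, _) in enumerate(self.events):
            expected = "contract" if i % 2 == 0 else "rest"
            if kind != expected:
                raise ValueError(
                    f"event {i} has kind {kind!r}, expected {expected!r} "
                    "(events must alternate starting with contract)"
                )

    def contraction_intervals(self) -> list[tuple[float, float]]:
        """[k-th contract call, k-th rest call] pairs."""
        pairs = []
        for i in range(0, len(self.events) - 1, 2):
            pairs.append((self.events[i][1], self.events[i + 1][1]))
        return pairs

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["kind", "time_s"])
            for kind, t in self.events:
                writer.writerow([kind, f"{t:.6f}"])

    @classmethod
    def from_csv(cls, path: str | Path) -> "EventLog":
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        return cls(tuple((r["kind"], float(r["time_s"])) for r in rows))


@dataclass
class FrameStack:
    """Time-ordered grayscale frames of one recording."""

    frames: np.ndarray  # (T, H, W) uint8
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (T, H, W) array")
        if self.frames.min() < 0 or self.frames.max() > 255:
            raise ValueError("frame intensities must lie in [0, 255]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def save_tiff(self, path: str | Path) -> None:
        tifffile.imwrite(str(path), self.frames.astype(np.uint8))

    @classmethod
    def load_tiff(cls, path: str | Path, fps: float) -> "FrameStack":
        return cls(tifffile.imread(str(path)), fps)


@dataclass
class GroundTruth:
    """Exact geometry and labels underlying a simulated recording.

    ``contours`` are the jittered vertex sets actually rendered;
    ``landmarks`` are the noise-free positions from the motion model,
    as a (T, 10) array in :data:`CHANNELS` order.
    """

    labels: list[ContractionLabel]
    contours: list[np.ndarray]
    landmarks: np.ndarray
    corrupted: np.ndarray  # (T,) bool, frames with occlusion dropout

    def labels_to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["cycle_index", "label"])
            for i, lab in enumerate(self.labels):
                writer.writerow([i, lab.value])


def _raised_cosine(t: float, t0: float, t1: float) -> float:
    """Smooth bump: 0 at the interval ends, 1 at its midpoint, 0 outside."""
    if t < t0 or t > t1 or t1 <= t0:
        return 0.0
    u = (t - t0) / (t1 - t0)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * u))


def _motion_offsets(
    time_s: float,
    label: ContractionLabel,
    event_window: tuple[float, float],
    config: SimulationConfig,
) -> tuple[float, float, float]:
    """(dx, dy, base_lift) rigid offsets and differential base displacement."""
    s = _raised_cosine(time_s, *event_window)
    if label is ContractionLabel.CORRECT:
        return 0.0, 0.0, config.base_amplitude_px * s
    if label is ContractionLabel.FAILURE:
        dx = config.translation_amplitude_px * np.sin(
            2.0 * np.pi * config.breathing_freq_hz * time_s
        )
        dy = config.translation_amplitude_px * s
        return dx, dy, 0.0
    if label in (ContractionLabel.NONE, ContractionLabel.UNDETERMINABLE):
        return 0.0, 0.0, 0.0
    raise ValueError(f"unknown contraction label: {label!r}")


def contour_at(
    time_s: float,
    label: ContractionLabel | str,
    event_window: tuple[float, float],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Bladder contour at one instant, as an (n_vertices, 2) array of (x, y).

    The resting shape is an ellipse.  For a correct contraction the lower
    boundary is displaced upward (decreasing y) by ``base_amplitude_px``
    times a raised-cosine bump over the contraction interval, weighted by
    the downward component of the boundary normal so the deformation is
    continuous; the Bottom landmark moves by the full amplitude and the
    upper boundary stays put.  A failure translates the whole contour
    rigidly.  Isotropic vertex jitter with std ``jitter_px`` is added
    when ``rng`` is given.
    """
    label = ContractionLabel.coerce(label)
    cx, cy = config.center
    theta = np.linspace(0.0, 2.0 * np.pi, config.n_vertices, endpoint=False)
    x = cx + config.semi_axis_x * np.cos(theta)
    y = cy + config.semi_axis_y * np.sin(theta)

    dx, dy, lift = _motion_offsets(time_s, label, event_window, config)
    # sin(theta) > 0 is the lower (larger-y) half in raster coordinates.
    y = y - lift * np.maximum(np.sin(theta), 0.0)
    contour = np.column_stack([x + dx, y + dy])

    if rng is not None and config.jitter_px > 0:
        contour = contour + rng.normal(0.0, config.jitter_px, contour.shape)
    return contour


def true_landmarks_at(
    time_s: float,
    label: ContractionLabel | str,
    event_window: tuple[float, float],
    config: SimulationConfig,
) -> np.ndarray:
    """Noise-free landmark positions, closed form, in :data:`CHANNELS` order."""
    label = ContractionLabel.coerce(label)
    cx, cy = config.center
    a, b = config.semi_axis_x, config.semi_axis_y
    dx, dy, lift = _motion_offsets(time_s, label, event_window, config)
    return np.array([
        cx + dx, cy + dy,              # Center
        cx - a + dx, cy + dy,          # Left
        cx + a + dx, cy + dy,          # Right
        cx + dx, cy - b + dy,          # Top
        cx + dx, cy + b - lift + dy,   # Bottom
    ])


def render_frame(
    contour: np.ndarray,
    config: SimulationConfig,
    rng_state: np.random.Generator | int,
    corrupt: bool = False,
) -> np.ndarray:
    """Render one B-mode-like frame from a bladder contour.

    Pixels inside the contour are near-dark (anechoic lumen); outside
    pixels are bright with multiplicative speckle of variance
    ``speckle_var``.  With ``corrupt=True`` a large occluding bright band
    is laid over the bladder from just above its upper boundary down to
    the frame bottom, so downstream segmentation fails (used for
    UNDETERMINABLE clips).
    """
    rng = np.random.default_rng(rng_state) if isinstance(rng_state, int) else rng_state
    h, w = config.frame_height, config.frame_width
    contour = np.asarray(contour, dtype=float)
    if (contour[:, 0].min() < 0 or contour[:, 0].max() > w - 1
            or contour[:, 1].min() < 0 or contour[:, 1].max() > h - 1):
        raise ValueError("contour exceeds frame bounds")

    mask = polygon2mask((h, w), contour[:, ::-1])  # (row, col) = (y, x)
    img = np.where(mask, _LUMEN_LEVEL, _BACKGROUND_LEVEL)

    if corrupt:
        band_top = max(0, int(np.floor(contour[:, 1].min())) - 2)
        img[band_top:, :] = _OCCLUSION_LEVEL

    if config.speckle_var > 0:
        noise = rng.normal(0.0, np.sqrt(config.speckle_var), img.shape)
        img = img * (1.0 + noise)
    return np.clip(img, 0, 255).astype(np.uint8)


def simulate_recording(
    config: SimulationConfig,
    label_sequence: Sequence[ContractionLabel | str],
) -> tuple[FrameStack, EventLog, GroundTruth]:
    """Simulate one recording of repeated contraction/rest cycles.

    Each cycle occupies ``contraction_s + rest_s`` seconds; the contract
    call opens the cycle and the rest call follows ``contraction_s``
    later.  Fully reproducible from ``config.seed``.
    """
    labels = [ContractionLabel.coerce(l) for l in label_sequence]
    if len(labels) != config.n_contractions:
        raise ValueError(
            f"label_sequence has {len(labels)} entries, "
            f"expected n_contractions={config.n_contractions}"
        )
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.duration_s * config.fps))

    events = []
    for k in range(config.n_contractions):
        t0 = k * config.cycle_s
        events.append(("contract", t0))
        events.append(("rest", t0 + config.contraction_s))
    event_log = EventLog(tuple(events))
    windows = event_log.contraction_intervals()

    frames = np.empty((n_frames, config.frame_height, config.frame_width), np.uint8)
    contours: list[np.ndarray] = []
    landmarks = np.empty((n_frames, len(CHANNELS)))
    corrupted = np.zeros(n_frames, dtype=bool)

    for i in range(n_frames):
        t = i / config.fps
        k = min(int(t // config.cycle_s), config.n_contractions - 1)
        label = labels[k]
        contour = contour_at(t, label, windows[k], config, rng=rng)
        corrupt = (
            label is ContractionLabel.UNDETERMINABLE
            and rng.uniform() < config.dropout_prob
        )
        frames[i] = render_frame(contour, config, rng, corrupt=corrupt)
        contours.append(contour)
        landmarks[i] = true_landmarks_at(t, label, windows[k], config)
        corrupted[i] = corrupt

    stack = FrameStack(frames, config.fps)
    truth = GroundTruth(labels, contours, landmarks, corrupted)
    return stack, event_log, truth
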
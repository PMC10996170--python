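"""Per-clip feature engineering on landmark time series.

Two bespoke scalar features come straight from the clinical rationale:
the bladder-area surrogate (|Right_x − Left_x| · |Bottom_y − Top_y|,
a proxy for urine volume) and the bladder-base elevation
(max − min of Bottom_y over the clip, the hallmark of a correct
pelvic-floor contraction).  On top of these, a fixed, versioned
catalogue of generic time-series features — moments, change statistics,
peak counts and discrete-Fourier magnitudes — is computed for each of
the 10 coordinate channels plus the Area channel.

Missing samples (failed segmentations) propagate as NaN.  Moment-type
features are computed on the observed samples only; spectral features
require a gap-free series, since a DFT over a gapped sampling grid is
ill-defined.  After the table is assembled, every feature *column*
containing at least one missing value is excluded, mirroring how
feature counts shrink under missing-value exclusion in practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .landmarks import LandmarkSeries
from .synth_us import CHANNELS, ContractionLabel

__all__ = [
    "CATALOGUE_VERSION",
    "FeatureCatalogue",
    "FeatureTable",
    "default_catalogue",
    "area_series",
    "base_elevation",
    "compute_channel_features",
    "build_feature_table",
]

CATALOGUE_VERSION = "pfmus-catalogue-1.0"

#: Minimum number of observed samples for spectral features.
_MIN_SPECTRAL_SAMPLES = 4


# ---------------------------------------------------------------------------
# Individual feature definitions.  Each takes the observed (non-missing)
# samples ``x`` in temporal order; spectral features additionally receive the
# sample rate and are only called on gap-free series.

def _mean_abs_change(x: np.ndarray) -> float:
    return float(np.mean(np.abs(np.diff(x)))) if len(x) >= 2 else np.nan


def _count_above_mean(x: np.ndarray) -> float:
    return float(np.sum(x > x.mean()))


def _autocorrelation_lag1(x: np.ndarray) -> float:
    if len(x) < 2:
        return np.nan
    v = np.var(x)
    if v == 0:
        return np.nan
    xc = x - x.mean()
    return float(np.dot(xc[:-1], xc[1:]) / ((len(x) - 1) * v))


def _linear_trend_slope(x: np.ndarray, t: np.ndarray) -> float:
    """Least-squares slope against sample time in seconds."""
    if len(x) < 2 or np.ptp(t) == 0:
        return np.nan
    return float(stats.linregress(t, x).slope)


def number_of_peaks(x: np.ndarray, support: int) -> float:
    """Count samples strictly greater than their ``support`` neighbours
    on both sides (boundary samples cannot qualify)."""
    n = len(x)
    if n < 2 * support + 1:
        return 0.0
    count = 0
    for i in range(support, n - support):
        left = x[i - support:i]
        right = x[i + 1:i + support + 1]
        if (x[i] > left).all() and (x[i] > right).all():
            count += 1
    return float(count)


def _dft(x: np.ndarray) -> np.ndarray:
    """DFT of the mean-removed series."""
    return np.fft.fft(x - x.mean())


def _abs_fft_coefficient(x: np.ndarray, k: int) -> float:
    if k > len(x) // 2:
        return np.nan
    return float(np.abs(_dft(x)[k]))


def _dominant_frequency_hz(x: np.ndarray, sample_rate_hz: float) -> float:
    n = len(x)
    mags = np.abs(_dft(x))
    ks = np.arange(1, n // 2 + 1)
    k_star = ks[np.argmax(mags[ks])]
    return float(k_star * sample_rate_hz / n)


def _spectral_energy(x: np.ndarray) -> float:
    return float(np.sum(np.abs(_dft(x)) ** 2) / len(x))


@dataclass(frozen=True)
class FeatureCatalogue:
    """Fixed ordered list of named per-channel feature definitions."""

    version: str
    moment: tuple[tuple[str, Callable], ...]
    spectral: tuple[tuple[str, Callable], ...]

    @property
    def names(self) -> tuple[str, ...]:
        names = tuple(n for n, _ in self.moment) + tuple(n for n, _ in self.spectral)
        if len(set(names)) != len(names):
            raise ValueError("catalogue feature names must be unique")
        return names


def default_catalogue() -> FeatureCatalogue:
    """The versioned default catalogue (19 features per channel)."""
    moment = (
        ("mean", lambda x, t, sr: float(np.mean(x))),
        ("minimum", lambda x, t, sr: float(np.min(x))),
        ("maximum", lambda x, t, sr: float(np.max(x))),
        ("median", lambda x, t, sr: float(np.median(x))),
        ("standard_deviation", lambda x, t, sr: float(np.std(x))),
        ("variance", lambda x, t, sr: float(np.var(x))),
        ("range", lambda x, t, sr: float(np.ptp(x))),
        ("mean_abs_change", lambda x, t, sr: _mean_abs_change(x)),
        ("count_above_mean", lambda x, t, sr: _count_above_mean(x)),
        ("autocorrelation_lag1", lambda x, t, sr: _autocorrelation_lag1(x)),
        ("linear_trend_slope", lambda x, t, sr: _linear_trend_slope(x, t)),
        ("number_of_peaks_1", lambda x, t, sr: number_of_peaks(x, 1)),
        ("number_of_peaks_3", lambda x, t, sr: number_of_peaks(x, 3)),
    )
    spectral = tuple(
        (f"abs_fft_coefficient_{k}",
         lambda x, t, sr, k=k: _abs_fft_coefficient(x, k))
        for k in (1, 2, 3, 4)
    ) + (
        ("dominant_frequency_hz", lambda x, t, sr: _dominant_frequency_hz(x, sr)),
        ("spectral_energy", lambda x, t, sr: _spectral_energy(x)),
    )
    return FeatureCatalogue(CATALOGUE_VERSION, moment, spectral)


# ---------------------------------------------------------------------------
# Bespoke features

def area_series(series: LandmarkSeries) -> np.ndarray:
    """Bladder-area surrogate per sample: |Right_x − Left_x| · |Bottom_y − Top_y|.

    Units px²; a proxy for urine volume.  NaN where the sample is missing.
    """
    width = np.abs(series.channel("Right_x") - series.channel("Left_x"))
    height = np.abs(series.channel("Bottom_y") - series.channel("Top_y"))
    return width * height


def base_elevation(series: LandmarkSeries) -> float:
    """Bladder-base elevation: max − min of Bottom_y over observed samples.

    Requires at least two observed samples, else NaN (missing).
    """
    by = series.channel("Bottom_y")
    ok = ~np.isnan(by)
    if ok.sum() < 2:
        return np.nan
    return float(by[ok].max() - by[ok].min())


def compute_channel_features(
    series: np.ndarray,
    sample_rate_hz: float,
    catalogue: FeatureCatalogue | None = None,
) -> dict[str, float]:
    """All catalogue features of one 1-D channel (NaN marks missing samples).

    Moment-type features use the observed samples in temporal order
    (their true sample times enter the trend slope).  Spectral features
    are computed only when the series is gap-free and has at least
    ``4`` samples; otherwise they are NaN.
    """
    catalogue = catalogue or default_catalogue()
    x = np.asarray(series, dtype=float)
    ok = ~np.isnan(x)
    t = np.flatnonzero(ok) / sample_rate_hz
    xo = x[ok]

    out: dict[str, float] = {}
    for name, fn in catalogue.moment:
        out[name] = fn(xo, t, sample_rate_hz) if len(xo) >= 1 else np.nan
    gap_free = bool(ok.all()) and len(x) >= _MIN_SPECTRAL_SAMPLES
    for name, fn in catalogue.spectral:
        out[name] = fn(x, t, sample_rate_hz) if gap_free else np.nan
    return out


# ---------------------------------------------------------------------------
# Table assembly

#: Channels featurized per clip: the 10 landmark coordinates plus Area.
FEATURE_CHANNELS = CHANNELS + ("Area",)

_META_COLUMNS = ("clip_id", "recording_id", "participant_id", "label")


@dataclass
class FeatureTable:
    """Labelled per-clip feature matrix after missing-value exclusion."""

    data: pd.DataFrame
    catalogue_version: str
    sample_rate_hz: float
    dropped_columns: list[str]
    dropped_clips: list[str] = field(default_factory=list)
    n_features_before: int = 0

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.data.columns if c not in _META_COLUMNS]

    @property
    def labels(self) -> pd.Series:
        return self.data["label"]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)
        sidecar = Path(path).with_suffix(".meta.json")
        sidecar.write_text(json.dumps({
            "catalogue_version": self.catalogue_version,
            "sample_rate_hz": self.sample_rate_hz,
            "n_features_before_exclusion": self.n_features_before,
            "n_features_after_exclusion": len(self.feature_columns),
            "dropped_columns": self.dropped_columns,
            "dropped_clips": self.dropped_clips,
        }, indent=2))


def build_feature_table(
    landmark_series_list: Sequence[LandmarkSeries],
    labels: Sequence[ContractionLabel | str],
    catalogue: FeatureCatalogue | None = None,
    metadata: Sequence[dict] | None = None,
) -> FeatureTable:
    """Assemble the labelled feature table over all clips.

    Each clip contributes the catalogue features of the 10 coordinate
    channels and the Area channel, plus ``base_elevation``.  Clips with
    zero observed samples carry no information and are dropped as rows;
    afterwards every feature column containing at least one missing
    value is excluded dataset-wide.
    """
    if len(labels) != len(landmark_series_list):
        raise ValueError("one label per landmark series required")
    catalogue = catalogue or default_catalogue()
    labels = [ContractionLabel.coerce(l) for l in labels]

    rows = []
    dropped_clips = []
    sample_rate = np.nan
    for i, series in enumerate(landmark_series_list):
        sample_rate = series.sample_rate_hz
        if series.missing.all():
            dropped_clips.append(series.clip_id)
            continue
        meta = (metadata[i] if metadata is not None else {})
        row = {
            "clip_id": series.clip_id,
            "recording_id": meta.get("recording_id", ""),
            "participant_id": meta.get("participant_id", ""),
            "label": labels[i].value,
        }
        channels = {name: series.channel(name) for name in CHANNELS}
        channels["Area"] = area_series(series)
        for ch_name, ch in channels.items():
            feats = compute_channel_features(ch, series.sample_rate_hz, catalogue)
            for f_name, value in feats.items():
                row[f"{ch_name}__{f_name}"] = value
        row["base_elevation"] = base_elevation(series)
        rows.append(row)

    if not rows:
        raise ValueError("all clips had zero observed samples")
    df = pd.DataFrame(rows)
    feature_cols = [c for c in df.columns if c not in _META_COLUMNS]
    n_before = len(feature_cols)
    dropped = [c for c in feature_cols if df[c].isna().any()]
    if len(dropped) == n_before:
        raise ValueError("missing-value exclusion removed every feature column")
    df = df.drop(columns=dropped)
    return FeatureTable(
        data=df,
        catalogue_version=catalogue.version,
        sample_rate_hz=float(sample_rate),
        dropped_columns=dropped,
        dropped_clips=dropped_clips,
        n_features_before=n_before,
    )
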
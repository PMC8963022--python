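"""Accelerometer preprocessing: magnitude, windowing, time-domain features.

Raw tri-axial streams are reduced to the orientation-invariant Euclidean norm
sqrt(x² + y² + z²), segmented into non-overlapping windows, and summarized by
six time-domain statistics per window (mean, standard deviation, minimum,
maximum, median, range). Windows whose modal per-sample label is the null
class are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import FeatureDataset, TriaxialRecording

__all__ = [
    "WindowSpec",
    "FEATURE_NAMES",
    "magnitude",
    "segment",
    "extract_features",
    "features_from_recording",
]

#: Column order of the extracted feature vector.
FEATURE_NAMES = ("mean", "std", "min", "max", "median", "range")

#: Label treated as the unannotated/background class; its windows are dropped.
NULL_LABEL = "null"


@dataclass(frozen=True)
class WindowSpec:
    """Non-overlapping window of a fixed duration (overlap is fixed at zero)."""

    window_seconds: float

    def length_samples(self, sample_rate: float) -> int:
        n = int(np.floor(self.window_seconds * sample_rate))
        if n < 1:
            raise ValueError(
                f"window of {self.window_seconds}s at {sample_rate}Hz is shorter "
                "than one sample"
            )
        return n


def magnitude(rec: TriaxialRecording) -> np.ndarray:
    """Euclidean norm of the three axes, invariant under sensor rotation."""
    if rec.n_samples == 0:
        raise ValueError("recording is empty")
    return np.sqrt(rec.x**2 + rec.y**2 + rec.z**2)


def _modal_label(window_labels: np.ndarray, class_order: Sequence[str]) -> str:
    """Most frequent label; ties go to the earlier class in ``class_order``."""
    rank = {c: i for i, c in enumerate(class_order)}
    values, counts = np.unique(window_labels.astype(str), return_counts=True)
    best = max(zip(values, counts), key=lambda vc: (vc[1], -rank.get(vc[0], len(rank))))
    return best[0]


def segment(
    series: np.ndarray,
    labels: np.ndarray,
    spec: WindowSpec,
    sample_rate: float,
    class_order: Sequence[str] | None = None,
    null_label: str = NULL_LABEL,
) -> list[tuple[np.ndarray, str]]:
    """Cut a labeled series into disjoint windows with modal labels.

    The trailing partial window is discarded; windows whose modal label equals
    ``null_label`` are dropped. A series shorter than one window yields an
    empty list. ``class_order`` controls the modal tie-break (default: order
    of first appearance in ``labels``).
    """
    series = np.asarray(series, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if len(series) != len(labels):
        raise ValueError("series and labels must have equal length")
    wlen = spec.length_samples(sample_rate)
    if class_order is None:
        seen: dict[str, None] = {}
        for l in labels:
            seen.setdefault(str(l), None)
        class_order = list(seen)
    out: list[tuple[np.ndarray, str]] = []
    for start in range(0, len(series) - wlen + 1, wlen):
        win = series[start : start + wlen]
        lab = _modal_label(labels[start : start + wlen], class_order)
        if lab == null_label:
            continue
        out.append((win, lab))
    return out


def extract_features(window: np.ndarray) -> np.ndarray:
    """Six time-domain features of one window, in ``FEATURE_NAMES`` order.

    The standard deviation uses the population formula (divide by n); the
    median of an even-length window is the mean of the two central order
    statistics.
    """
    window = np.asarray(window, dtype=float)
    if window.size == 0:
        raise ValueError("window is empty")
    mn = float(window.min())
    mx = float(window.max())
    return np.array(
        [
            float(window.mean()),
            float(window.std()),  # population std (ddof=0)
            mn,
            mx,
            float(np.median(window)),
            mx - mn,
        ]
    )


def features_from_recording(
    rec: TriaxialRecording,
    window_seconds: float,
    class_order: Sequence[str] | None = None,
    null_label: str = NULL_LABEL,
) -> FeatureDataset:
    """Full chain: magnitude → non-overlapping windows → feature table."""
    mag = magnitude(rec)
    windows = segment(
        mag,
        rec.labels,
        WindowSpec(window_seconds),
        rec.sample_rate,
        class_order=class_order,
        null_label=null_label,
    )
    if not windows:
        raise ValueError("recording shorter than one window (or all windows null)")
    X = np.vstack([extract_features(w) for w, _ in windows])
    labels = [lab for _, lab in windows]
    order = class_order
    if order is not None:
        order = [c for c in order if c != null_label and c in set(labels)]
        order = order or None
    return FeatureDataset.from_labels(X, labels, class_names=order, feature_names=FEATURE_NAMES)
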
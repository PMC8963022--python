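"""Synthetic imbalanced activity data for testing every pipeline stage.

Two tiers:

* :func:`generate_recording` emulates a raw tri-axial accelerometer stream —
  per activity a quasi-periodic sinusoid (activity-specific amplitude and
  frequency, per-axis scaling and random phase) riding on a gravity offset,
  plus Gaussian sensor noise — so the preprocessing chain (magnitude →
  windows → features) can be exercised end to end.
* :func:`generate_feature_dataset` draws window-level feature vectors
  directly from class-specific spherical Gaussians with controlled mean
  separation and exact class counts, giving precise geometric control for
  the sampler oracles.

The default scenario is five activity classes with counts (100, 20, 12, 8, 5)
— a 20:1 majority:minority ratio — in d = 6 dimensions with class means
separated by 3 noise standard deviations (moderate overlap). Neither tier
models subject-level variability or biomechanically realistic gait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import FeatureDataset, TriaxialRecording, make_rng

__all__ = [
    "ActivitySpec",
    "ScenarioSpec",
    "default_scenario",
    "generate_recording",
    "generate_feature_dataset",
]

GRAVITY = 9.81  # m/s^2 offset carried on the z axis

#: Per-axis scaling of each activity's oscillation (arm movement is rarely
#: isotropic; fixed so magnitudes differ between axes deterministically).
_AXIS_SCALE = (1.0, 0.6, 0.3)


@dataclass(frozen=True)
class ActivitySpec:
    """One activity class: sample count (feature tier) or duration (raw tier)."""

    name: str
    count: int = 1  # feature rows (feature tier)
    duration_s: float | None = None  # segment length (raw tier)
    amplitude: float = 1.0  # oscillation amplitude, m/s^2
    frequency_hz: float = 1.0  # dominant movement frequency
    noise_sd: float = 0.3  # raw-signal Gaussian noise, m/s^2

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"{self.name}: count must be >= 1")
        if self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """A full scenario: activity list plus rates and feature-cloud geometry."""

    activities: tuple[ActivitySpec, ...]
    sample_rate: float = 50.0
    n_features: int = 6
    separation: float = 3.0  # class-mean distance in units of feature_noise_sd
    feature_noise_sd: float = 1.0

    def __post_init__(self):
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")
        if len(self.activities) < 1:
            raise ValueError("scenario needs at least one activity")

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.activities)


def default_scenario() -> ScenarioSpec:
    """Five activities, 20:1 imbalance, moderate class overlap."""
    return ScenarioSpec(
        activities=(
            ActivitySpec("walking", count=100, duration_s=60.0, amplitude=2.5, frequency_hz=1.8),
            ActivitySpec("standing", count=20, duration_s=12.0, amplitude=0.3, frequency_hz=0.4),
            ActivitySpec("sitting", count=12, duration_s=8.0, amplitude=0.2, frequency_hz=0.3),
            ActivitySpec("ascending_stairs", count=8, duration_s=5.0, amplitude=3.0, frequency_hz=1.4),
            ActivitySpec("descending_stairs", count=5, duration_s=4.0, amplitude=3.5, frequency_hz=1.6),
        )
    )


def generate_recording(spec: ScenarioSpec, rng) -> TriaxialRecording:
    """Concatenated labeled activity segments with per-axis sinusoids + noise.

    Each activity contributes ``floor(duration_s × sample_rate)`` samples
    (``count / sample_rate`` seconds when no duration is given, i.e. count
    samples). Deterministic under a fixed seed.
    """
    rng = make_rng(rng)
    xs, ys, zs, labs = [], [], [], []
    for act in spec.activities:
        n = int(np.floor((act.duration_s or act.count / spec.sample_rate) * spec.sample_rate))
        if n < 1:
            raise ValueError(f"{act.name}: segment shorter than one sample")
        t = np.arange(n) / spec.sample_rate
        phases = rng.uniform(0, 2 * np.pi, size=3)
        axes = []
        for axis, (scale, phase) in enumerate(zip(_AXIS_SCALE, phases)):
            signal = act.amplitude * scale * np.sin(2 * np.pi * act.frequency_hz * t + phase)
            signal = signal + rng.normal(0.0, act.noise_sd, size=n)
            if axis == 2:
                signal = signal + GRAVITY
            axes.append(signal)
        xs.append(axes[0])
        ys.append(axes[1])
        zs.append(axes[2])
        labs.extend([act.name] * n)
    return TriaxialRecording(
        sample_rate=spec.sample_rate,
        x=np.concatenate(xs),
        y=np.concatenate(ys),
        z=np.concatenate(zs),
        labels=np.array(labs, dtype=object),
    )


def _class_means(n_classes: int, d: int, separation: float, sd: float) -> np.ndarray:
    """Deterministic class means: scaled unit axes (wrapping past d)."""
    means = np.zeros((n_classes, d))
    for c in range(n_classes):
        axis = c % d
        means[c, axis] = separation * sd * (1 + c // d)
    return means


def generate_feature_dataset(spec: ScenarioSpec, rng) -> FeatureDataset:
    """Class-specific Gaussian feature clouds with exact class counts."""
    rng = make_rng(rng)
    d = spec.n_features
    means = _class_means(len(spec.activities), d, spec.separation, spec.feature_noise_sd)
    blocks, labels = [], []
    for c, act in enumerate(spec.activities):
        blocks.append(rng.normal(means[c], spec.feature_noise_sd, size=(act.count, d)))
        labels.extend([act.name] * act.count)
    return FeatureDataset.from_labels(
        np.vstack(blocks),
        labels,
        class_names=spec.class_names,
        feature_names=tuple(f"f{i}" for i in range(d)),
    )
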
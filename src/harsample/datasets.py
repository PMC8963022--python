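"""Core data model for imbalanced activity-recognition experiments.

The central container is :class:`FeatureDataset`: an ``(n, d)`` float matrix of
window-level features plus per-row activity labels. Labels are stored as
integer indices into an ordered ``class_names`` tuple so that class ordering
(used for majority tie-breaks, rank tables and score matrices) is stable.

A :class:`TriaxialRecording` holds a raw labeled accelerometer stream; the
``preprocessing`` module turns it into a :class:`FeatureDataset`.

All stochastic operations in the package take a ``numpy.random.Generator``
(created with :func:`make_rng`), threaded explicitly so that every repetition
of an experiment is reproducible from a single master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TriaxialRecording",
    "FeatureDataset",
    "SamplerSpec",
    "Provenance",
    "SyntheticBatch",
    "make_rng",
    "validate_dataset",
    "class_counts",
    "read_feature_csv",
    "write_feature_csv",
    "read_recording_csv",
    "write_recording_csv",
]

#: Sampler method identifiers accepted by SamplerSpec.
SINGLE_METHODS = (
    "smote",
    "random_smote",
    "smote_tomeklinks",
    "msmote",
    "cbso",
    "prowsyn",
)
HYBRID_METHODS = ("dbm", "ndbm", "cbm")
ALL_METHODS = SINGLE_METHODS + HYBRID_METHODS


def make_rng(seed: int | None | np.random.Generator) -> np.random.Generator:
    """Return a deterministic random generator.

    Accepts an integer seed, ``None`` (OS entropy) or an existing generator,
    which is passed through unchanged. Identical seeds yield identical draw
    sequences — the reproducibility contract every sampler relies on.
    """
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class TriaxialRecording:
    """A raw labeled 3-axis accelerometer stream at a fixed sample rate."""

    sample_rate: float
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    labels: np.ndarray  # per-sample activity identifiers (strings)

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "z", np.asarray(self.z, dtype=float))
        object.__setattr__(self, "labels", np.asarray(self.labels, dtype=object))
        n = len(self.x)
        if not (len(self.y) == len(self.z) == len(self.labels) == n):
            raise ValueError(
                "x, y, z and labels must have equal length; got "
                f"{n}, {len(self.y)}, {len(self.z)}, {len(self.labels)}"
            )
        if not self.sample_rate > 0:
            raise ValueError(f"sample_rate must be positive, got {self.sample_rate}")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate


@dataclass
class FeatureDataset:
    """Feature matrix + integer class labels; the unit samplers consume.

    Parameters
    ----------
    X : (n, d) float array.
    y : (n,) integer array; each value indexes into ``class_names``.
    class_names : ordered tuple of class identifiers.
    feature_names : optional ordered tuple of column names.
    """

    X: np.ndarray
    y: np.ndarray
    class_names: tuple[str, ...]
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-D, got shape {self.X.shape}")
        self.y = np.asarray(self.y, dtype=int)
        self.class_names = tuple(str(c) for c in self.class_names)
        if self.feature_names is not None:
            self.feature_names = tuple(self.feature_names)
        if len(self.y) != self.X.shape[0]:
            raise ValueError("X and y row counts differ")

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_labels(
        cls,
        X: np.ndarray,
        labels: Sequence,
        class_names: Sequence[str] | None = None,
        feature_names: Sequence[str] | None = None,
    ) -> "FeatureDataset":
        """Build a dataset from string labels.

        When ``class_names`` is omitted, classes are ordered by first
        appearance in ``labels`` (a deterministic ordering that downstream
        tie-breaks depend on).
        """
        labels = [str(l) for l in labels]
        if class_names is None:
            seen: dict[str, int] = {}
            for l in labels:
                if l not in seen:
                    seen[l] = len(seen)
            class_names = tuple(seen)
        else:
            class_names = tuple(str(c) for c in class_names)
        index = {c: i for i, c in enumerate(class_names)}
        unknown = sorted({l for l in labels if l not in index})
        if unknown:
            raise ValueError(f"labels not in class_names: {unknown}")
        y = np.array([index[l] for l in labels], dtype=int)
        return cls(np.asarray(X, dtype=float), y, class_names, feature_names)

    # -- views ------------------------------------------------------------
    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def label_strings(self) -> np.ndarray:
        return np.array([self.class_names[i] for i in self.y], dtype=object)

    def subset(self, idx) -> "FeatureDataset":
        idx = np.asarray(idx)
        return FeatureDataset(self.X[idx], self.y[idx], self.class_names, self.feature_names)

    def class_rows(self, class_index: int) -> np.ndarray:
        """Global row indices belonging to one class."""
        return np.flatnonzero(self.y == class_index)

    def to_frame(self) -> pd.DataFrame:
        cols = self.feature_names or tuple(f"f{i}" for i in range(self.n_features))
        df = pd.DataFrame(self.X, columns=list(cols))
        df["label"] = self.label_strings()
        return df


@dataclass(frozen=True)
class SamplerSpec:
    """Method identifier plus hyperparameters for one sampling run.

    ``alpha`` is the sampling percentage: the fraction of the gap between
    each minority count and the majority count that synthesis fills
    (1.0 = full balance, the "100%" convention).
    """

    method: str
    k_neighbors: int = 5
    alpha: float = 1.0
    max_levels: int = 5
    theta: float = 1.0
    cluster_threshold_factor: float = 3.0

    def __post_init__(self):
        m = self.method.lower()
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {ALL_METHODS}")
        object.__setattr__(self, "method", m)
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if not self.alpha > 0:
            raise ValueError("alpha must be > 0")
        if self.max_levels < 1:
            raise ValueError("max_levels must be >= 1")


@dataclass(frozen=True)
class Provenance:
    """Where one synthetic row came from.

    Indices refer to rows of the dataset the sampler ran on. ``neighbor_index``
    is −1 for pure duplications; ``partner_index`` is the second interpolation
    vertex used by Random_SMOTE triangles, −1 otherwise. ``draws`` are the
    uniform [0, 1) numbers consumed for this row, in order.
    """

    method: str
    seed_index: int
    neighbor_index: int = -1
    partner_index: int = -1
    draws: tuple[float, ...] = ()


@dataclass
class SyntheticBatch:
    """Generated minority rows plus their per-row provenance."""

    X_syn: np.ndarray
    y_syn: np.ndarray
    provenance: list[Provenance] = field(default_factory=list)

    def __post_init__(self):
        self.X_syn = np.asarray(self.X_syn, dtype=float)
        self.y_syn = np.asarray(self.y_syn, dtype=int)
        if self.X_syn.ndim != 2:
            self.X_syn = self.X_syn.reshape(len(self.y_syn), -1)
        if len(self.provenance) != len(self.y_syn):
            raise ValueError("provenance length must equal number of synthetic rows")

    @property
    def n(self) -> int:
        return len(self.y_syn)

    @classmethod
    def empty(cls, n_features: int) -> "SyntheticBatch":
        return cls(np.empty((0, n_features)), np.empty(0, dtype=int), [])

    @classmethod
    def concat(cls, batches: Iterable["SyntheticBatch"], n_features: int) -> "SyntheticBatch":
        batches = list(batches)
        if not batches:
            return cls.empty(n_features)
        X = np.vstack([b.X_syn for b in batches]) if batches else np.empty((0, n_features))
        y = np.concatenate([b.y_syn for b in batches])
        prov: list[Provenance] = []
        for b in batches:
            prov.extend(b.provenance)
        return cls(X, y, prov)

    def select(self, keep: np.ndarray) -> "SyntheticBatch":
        keep = np.asarray(keep)
        prov = [p for p, k in zip(self.provenance, keep) if k]
        return SyntheticBatch(self.X_syn[keep], self.y_syn[keep], prov)


# ---------------------------------------------------------------------------
# validation and counting
# ---------------------------------------------------------------------------

def validate_dataset(ds: FeatureDataset) -> FeatureDataset:
    """Check FeatureDataset invariants and return the dataset unchanged.

    Raises ``ValueError`` naming the first violated invariant: missing values
    (with the offending row), labels outside ``class_names``, empty classes,
    or an empty matrix.
    """
    if ds.n < 1:
        raise ValueError("dataset is empty (n = 0)")
    if ds.n_features < 1:
        raise ValueError("dataset has no feature columns (d = 0)")
    bad = ~np.isfinite(ds.X)
    if bad.any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        raise ValueError(f"missing/non-finite value in row {row}")
    if len(ds.class_names) == 0:
        raise ValueError("class_names is empty")
    if ds.y.min(initial=0) < 0 or ds.y.max(initial=0) >= len(ds.class_names):
        bad_rows = np.flatnonzero((ds.y < 0) | (ds.y >= len(ds.class_names)))
        raise ValueError(
            f"label index {int(ds.y[bad_rows[0]])} in row {int(bad_rows[0])} "
            "is not in class_names"
        )
    present = set(np.unique(ds.y).tolist())
    missing = [c for i, c in enumerate(ds.class_names) if i not in present]
    if missing:
        raise ValueError(f"empty class(es): {missing}")
    return ds


def class_counts(ds: FeatureDataset) -> tuple[dict[str, int], str]:
    """Per-class row counts and the majority class.

    Counts cover every name in ``class_names`` (zero for absent classes) and
    always sum to ``n``. Ties for the majority are broken by ``class_names``
    order, so the result is deterministic.
    """
    counts = np.bincount(ds.y, minlength=len(ds.class_names))
    majority = ds.class_names[int(np.argmax(counts))]  # argmax keeps first max
    return {c: int(k) for c, k in zip(ds.class_names, counts)}, majority


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------
# Feature tables: header row, feature columns, final `label` column, UTF-8,
# '.' decimal. Raw recordings: columns t,x,y,z,label.

def read_feature_csv(path, class_names: Sequence[str] | None = None) -> FeatureDataset:
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise ValueError(f"{path}: feature CSV must end with a 'label' column")
    feat_cols = [c for c in df.columns if c != "label"]
    return FeatureDataset.from_labels(
        df[feat_cols].to_numpy(dtype=float),
        df["label"].astype(str).tolist(),
        class_names=class_names,
        feature_names=tuple(feat_cols),
    )


def write_feature_csv(ds: FeatureDataset, path) -> None:
    ds.to_frame().to_csv(path, index=False)


def read_recording_csv(path, sample_rate: float | None = None) -> TriaxialRecording:
    """Read a `t,x,y,z,label` stream; sample rate inferred from t if omitted."""
    df = pd.read_csv(path)
    required = {"t", "x", "y", "z", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: recording CSV needs columns {sorted(required)}")
    if sample_rate is None:
        dt = np.median(np.diff(df["t"].to_numpy(dtype=float)))
        if not dt > 0:
            raise ValueError(f"{path}: cannot infer sample rate from t column")
        sample_rate = 1.0 / dt
    return TriaxialRecording(
        sample_rate=float(sample_rate),
        x=df["x"].to_numpy(dtype=float),
        y=df["y"].to_numpy(dtype=float),
        z=df["z"].to_numpy(dtype=float),
        labels=df["label"].astype(str).to_numpy(dtype=object),
    )


def write_recording_csv(rec: TriaxialRecording, path) -> None:
    t = np.arange(rec.n_samples) / rec.sample_rate
    pd.DataFrame(
        {"t": t, "x": rec.x, "y": rec.y, "z": rec.z, "label": rec.labels}
    ).to_csv(path, index=False)
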
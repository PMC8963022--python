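"""Hybrid oversampling combinators: DBM, NDBM and CBM.

Each hybrid runs two constituent samplers independently on the same training
split with the same sampling percentage α and concatenates their synthetic
outputs over a *single* shared copy of the original rows:

* DBM  (distance-based)        = SMOTE + Random_SMOTE
* NDBM (noise-detection-based) = SMOTE_TomekLinks + MSMOTE
* CBM  (cluster-based)         = ProWSyn + CBSO

Keeping one copy of the originals means that at α = 1 each minority class
receives the majority–minority gap twice and deliberately overshoots the
majority count; no rebalancing is applied. For NDBM, original rows deleted by
the Tomek cleaning step are removed from the shared copy; MSMOTE's noise rows
are merely unused as seeds, never deleted.

``leakage_guard`` audits a split: synthesis must derive only from training
rows, and no test row may enter the augmented training set (exact duplicates
explainable by training-side provenance are recorded as coincidences, not
failures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .datasets import FeatureDataset, SamplerSpec, SyntheticBatch, make_rng
from .samplers import generate_batch

__all__ = ["HYBRID_CONSTITUENTS", "HybridResult", "hybrid_oversample", "LeakageReport", "leakage_guard"]

HYBRID_CONSTITUENTS: dict[str, tuple[str, str]] = {
    "dbm": ("smote", "random_smote"),
    "ndbm": ("smote_tomeklinks", "msmote"),
    "cbm": ("prowsyn", "cbso"),
}


@dataclass
class HybridResult:
    """Output of one hybrid run.

    ``augmented_train`` = (original rows minus ``removed_rows``) followed by
    the rows of ``batches[0]`` then ``batches[1]``; each original row appears
    at most once.
    """

    method: str
    augmented_train: FeatureDataset
    batches: tuple[SyntheticBatch, SyntheticBatch]
    removed_rows: np.ndarray
    cleaning_log: dict
    class_counts: dict[str, int]


def hybrid_oversample(
    train: FeatureDataset,
    method: str,
    alpha: float = 1.0,
    rng=None,
    k_neighbors: int = 5,
    max_levels: int = 5,
    theta: float = 1.0,
    cluster_threshold_factor: float = 3.0,
) -> HybridResult:
    """Run both constituents of ``method`` and concatenate their synthetics.

    The constituents receive independent random substreams spawned from the
    master generator, so their draws are uncorrelated yet the whole run is
    reproducible from one seed. A failing constituent propagates with its
    name attached.
    """
    method = method.lower()
    if method not in HYBRID_CONSTITUENTS:
        raise ValueError(f"unknown hybrid {method!r}; expected one of {sorted(HYBRID_CONSTITUENTS)}")
    if len(np.unique(train.y)) < 2:
        raise ValueError("hybrid oversampling needs at least 2 classes in the training set")
    rng = make_rng(rng)
    sub_a, sub_b = rng.spawn(2)
    names = HYBRID_CONSTITUENTS[method]
    batches: list[SyntheticBatch] = []
    removed = np.array([], dtype=int)
    log: dict = {}
    for name, sub in zip(names, (sub_a, sub_b)):
        spec = SamplerSpec(
            name,
            k_neighbors=k_neighbors,
            alpha=alpha,
            max_levels=max_levels,
            theta=theta,
            cluster_threshold_factor=cluster_threshold_factor,
        )
        try:
            batch, rem, blog = generate_batch(train, spec, sub)
        except Exception as exc:  # noqa: BLE001 - constituent named on the way up
            raise RuntimeError(f"hybrid {method}: constituent {name!r} failed: {exc}") from exc
        batches.append(batch)
        if len(rem):
            removed = rem
            log = blog
    keep = np.ones(train.n, dtype=bool)
    keep[removed] = False
    X = np.vstack([train.X[keep], batches[0].X_syn, batches[1].X_syn])
    y = np.concatenate([train.y[keep], batches[0].y_syn, batches[1].y_syn])
    augmented = FeatureDataset(X, y, train.class_names, train.feature_names)
    counts = np.bincount(augmented.y, minlength=len(train.class_names))
    return HybridResult(
        method=method,
        augmented_train=augmented,
        batches=(batches[0], batches[1]),
        removed_rows=removed,
        cleaning_log=log,
        class_counts={c: int(k) for c, k in zip(train.class_names, counts)},
    )


# ---------------------------------------------------------------------------
# leakage guard
# ---------------------------------------------------------------------------

@dataclass
class LeakageReport:
    """Result of the train/test contamination audit (never raises)."""

    passed: bool
    failures: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _row_set(X: np.ndarray) -> set[bytes]:
    return {np.ascontiguousarray(row).tobytes() for row in X}


def leakage_guard(
    train: FeatureDataset,
    test: FeatureDataset,
    augmented: FeatureDataset,
    batches: Sequence[SyntheticBatch] = (),
) -> LeakageReport:
    """Verify that oversampling touched only the training split.

    Two checks: (1) every provenance index of every synthetic batch refers to
    a training row; (2) no test row appears in the augmented training set —
    unless the matching augmented row is a genuine training row or a
    synthetic with training-side provenance, in which case the exact
    duplicate is reported as a coincidence note.
    """
    failures: list[str] = []
    notes: list[str] = []
    n_train = train.n
    for b, batch in enumerate(batches):
        for r, p in enumerate(batch.provenance):
            for label, idx in (
                ("seed", p.seed_index),
                ("neighbor", p.neighbor_index),
                ("partner", p.partner_index),
            ):
                if idx >= n_train:
                    failures.append(
                        f"batch {b} row {r}: {label} index {idx} lies outside the "
                        f"training set (n_train = {n_train}) — synthetic derived "
                        "from a non-training row"
                    )
    train_rows = _row_set(train.X)
    legit_synth = _row_set(np.vstack([b.X_syn for b in batches])) if batches else set()
    test_rows = _row_set(test.X)
    for i, row in enumerate(augmented.X):
        key = np.ascontiguousarray(row).tobytes()
        if key not in test_rows:
            continue
        if key in train_rows:
            notes.append(
                f"augmented row {i} equals a test row but also a training row "
                "(exact duplicate across the split) — coincidence"
            )
        elif key in legit_synth:
            notes.append(
                f"augmented row {i} is a synthetic that coincides with a test row "
                "(training-side provenance) — coincidence"
            )
        else:
            failures.append(
                f"augmented row {i} equals a test row and has no training-side origin"
            )
    return LeakageReport(passed=not failures, failures=failures, notes=notes)
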
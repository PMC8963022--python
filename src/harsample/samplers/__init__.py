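"""Shared sampler interface.

``generate_batch`` returns the synthetic rows (plus any original-row removals
a cleaning method performed); ``oversample`` additionally assembles the
augmented dataset. Single methods at ``alpha = 1`` bring every class exactly
to the majority count, except SMOTE+Tomek cleaning whose deviation equals its
logged removals.
"""

from __future__ import annotations

import numpy as np

from ..datasets import FeatureDataset, SamplerSpec, SyntheticBatch, make_rng
from ._interp import synthesis_targets
from .cluster import (
    ClusterAssignment,
    ProximityPartition,
    allocate_counts,
    cbso_batch,
    cbso_cluster,
    prowsyn_batch,
    prowsyn_partition,
)
from .distance import (
    random_smote_batch,
    random_smote_generate,
    smote_batch,
    smote_generate,
)
from .noise import (
    MinorityTyping,
    find_tomek_links,
    msmote_batch,
    msmote_type,
    smote_tomeklinks_oversample,
)

__all__ = [
    "generate_batch",
    "oversample",
    "synthesis_targets",
    "smote_generate",
    "random_smote_generate",
    "smote_batch",
    "random_smote_batch",
    "find_tomek_links",
    "smote_tomeklinks_oversample",
    "msmote_type",
    "msmote_batch",
    "MinorityTyping",
    "cbso_cluster",
    "cbso_batch",
    "prowsyn_partition",
    "prowsyn_batch",
    "allocate_counts",
    "ClusterAssignment",
    "ProximityPartition",
]

_BATCH_FUNCS = {
    "smote": smote_batch,
    "random_smote": random_smote_batch,
    "msmote": msmote_batch,
    "cbso": cbso_batch,
    "prowsyn": prowsyn_batch,
}


def generate_batch(
    ds: FeatureDataset, spec: SamplerSpec, rng
) -> tuple[SyntheticBatch, np.ndarray, dict]:
    """Run one single sampling method.

    Returns ``(batch, removed_original_rows, cleaning_log)``. Only
    ``smote_tomeklinks`` ever removes rows; for every other method the removal
    array is empty and the log is ``{}``.
    """
    rng = make_rng(rng)
    if spec.method == "smote_tomeklinks":
        _, batch, log = smote_tomeklinks_oversample(ds, spec, rng)
        return batch, np.array(log["removed_original"], dtype=int), log
    if spec.method not in _BATCH_FUNCS:
        raise ValueError(f"{spec.method!r} is not a single sampling method")
    return _BATCH_FUNCS[spec.method](ds, spec, rng), np.array([], dtype=int), {}


def oversample(
    ds: FeatureDataset, spec: SamplerSpec, rng
) -> tuple[FeatureDataset, SyntheticBatch, dict]:
    """Augmented dataset = (originals minus removals) + synthetic batch."""
    batch, removed, log = generate_batch(ds, spec, rng)
    keep = np.ones(ds.n, dtype=bool)
    keep[removed] = False
    X = np.vstack([ds.X[keep], batch.X_syn]) if batch.n else ds.X[keep]
    y = np.concatenate([ds.y[keep], batch.y_syn]) if batch.n else ds.y[keep]
    return FeatureDataset(X, y, ds.class_names, ds.feature_names), batch, log
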
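"""Cluster-based samplers: CBSO and ProWSyn.

CBSO groups each minority class by average-linkage agglomerative clustering,
cut at a threshold proportional to the class's mean nearest-neighbor
distance. Seeds are drawn with probability proportional to a *border weight*
(the fraction of a row's k all-class nearest neighbors that belong to other
classes), and the interpolation partner comes from the seed's own cluster —
synthesis never crosses cluster boundaries.

ProWSyn partitions each minority class into proximity levels by iteratively
peeling off the rows that appear among the k nearest minority neighbors of
any opposite-class row; level 1 hugs the class boundary, higher levels lie
deeper inside the class. Levels get exponentially decaying weights
w(l) ∝ exp(−θ(l−1)) and synthetic rows are allocated to levels in proportion
to total level weight (largest-remainder rounding), then generated by
SMOTE-style interpolation within each level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist

from ..datasets import FeatureDataset, SamplerSpec, SyntheticBatch
from ._interp import interpolate_within_pool, nearest_within, synthesis_targets

__all__ = [
    "ClusterAssignment",
    "cbso_cluster",
    "cbso_batch",
    "ProximityPartition",
    "prowsyn_partition",
    "prowsyn_batch",
    "allocate_counts",
]


# ---------------------------------------------------------------------------
# CBSO
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Per-class minority clustering: cluster id for every minority row."""

    rows: dict[int, np.ndarray]  # class -> global row indices
    cluster_ids: dict[int, np.ndarray]  # class -> id per row (aligned with rows)
    thresholds: dict[int, float]  # class -> distance cut used


def _cluster_one_class(Xc: np.ndarray, factor: float) -> tuple[np.ndarray, float]:
    m = Xc.shape[0]
    if m == 1:
        return np.zeros(1, dtype=int), 0.0
    D = cdist(Xc, Xc)
    np.fill_diagonal(D, np.inf)
    threshold = factor * float(D.min(axis=1).mean())
    Z = linkage(Xc, method="average")
    ids = fcluster(Z, t=threshold, criterion="distance") - 1
    return ids.astype(int), threshold


def cbso_cluster(ds: FeatureDataset, spec: SamplerSpec) -> ClusterAssignment:
    """Average-linkage clustering of each minority class.

    The cut threshold is ``cluster_threshold_factor`` times the mean distance
    from each minority row to its nearest same-class neighbor; singleton
    clusters are permitted.
    """
    counts = np.bincount(ds.y, minlength=len(ds.class_names))
    majority = int(np.argmax(counts))
    rows: dict[int, np.ndarray] = {}
    ids: dict[int, np.ndarray] = {}
    thr: dict[int, float] = {}
    for c in range(len(ds.class_names)):
        if c == majority or counts[c] == 0:
            continue
        rows_c = ds.class_rows(c)
        ids_c, t = _cluster_one_class(ds.X[rows_c], spec.cluster_threshold_factor)
        rows[c], ids[c], thr[c] = rows_c, ids_c, t
    return ClusterAssignment(rows, ids, thr)


def _border_weights(ds: FeatureDataset, rows_c: np.ndarray, c: int, k: int) -> np.ndarray | None:
    """Majority fraction among each row's k all-class nearest neighbors.

    Returns normalized seed-selection probabilities, or ``None`` when every
    weight is zero (seeds then drawn uniformly).
    """
    k_eff = min(k, ds.n - 1)
    lists = nearest_within(ds.X, rows_c, np.arange(ds.n), k=k_eff)
    w = np.array([float(np.mean(ds.y[nbrs] != c)) for nbrs in lists])
    total = w.sum()
    if total <= 0:
        return None
    return w / total


def cbso_batch(ds: FeatureDataset, spec: SamplerSpec, rng: np.random.Generator) -> SyntheticBatch:
    """CBSO applied per minority class.

    Partner candidates are the seed's cluster mates (ordered by distance,
    chosen uniformly); a singleton cluster duplicates its seed.
    """
    assignment = cbso_cluster(ds, spec)
    targets = synthesis_targets(ds, spec.alpha)
    parts = []
    for c, n_synth in targets.items():
        rows_c = assignment.rows[c]
        ids_c = assignment.cluster_ids[c]
        weights = _border_weights(ds, rows_c, c, spec.k_neighbors)
        lists = []
        for j, row in enumerate(rows_c):
            mates = rows_c[ids_c == ids_c[j]]
            ordered = nearest_within(ds.X, np.array([row]), mates, k=None)[0]
            lists.append(ordered)
        parts.append(
            interpolate_within_pool(
                ds.X, rows_c, lists, n_synth, c, rng, "cbso", weights=weights
            )
        )
    return SyntheticBatch.concat(parts, ds.n_features)


# ---------------------------------------------------------------------------
# ProWSyn
# ---------------------------------------------------------------------------

@dataclass
class ProximityPartition:
    """Proximity levels for one minority class.

    ``level_of`` maps every minority row of the class to a level in
    1..max_levels; ``weights`` are the normalized per-level weights
    w(l) ∝ exp(−θ(l−1)) over non-empty levels.
    """

    rows: np.ndarray  # global row indices of the class
    level_of: dict[int, int]  # global row index -> level
    weights: dict[int, float]  # level -> normalized weight
    max_levels: int
    theta: float

    def level_rows(self, level: int) -> np.ndarray:
        return np.array([r for r in self.rows if self.level_of[int(r)] == level], dtype=int)

    @property
    def levels_present(self) -> list[int]:
        return sorted(set(self.level_of.values()))


def _partition_one_class(
    ds: FeatureDataset, rows_c: np.ndarray, c: int, k: int, max_levels: int, theta: float
) -> ProximityPartition:
    other_rows = np.flatnonzero(ds.y != c)
    unassigned = list(int(r) for r in rows_c)
    level_of: dict[int, int] = {}
    for level in range(1, max_levels):
        if not unassigned:
            break
        pool = np.array(unassigned, dtype=int)
        # k nearest unassigned minority rows of each opposite-class row
        D = cdist(ds.X[other_rows], ds.X[pool])
        k_eff = min(k, len(pool))
        hit: set[int] = set()
        for drow in D:
            order = np.argsort(drow, kind="stable")[:k_eff]
            hit.update(int(pool[o]) for o in order)
        for r in sorted(hit):
            level_of[r] = level
        unassigned = [r for r in unassigned if r not in hit]
    for r in unassigned:
        level_of[r] = max_levels
    present = sorted(set(level_of.values()))
    raw = {l: float(np.exp(-theta * (l - 1))) for l in present}
    total = sum(raw.values())
    weights = {l: v / total for l, v in raw.items()}
    return ProximityPartition(rows_c, level_of, weights, max_levels, theta)


def prowsyn_partition(ds: FeatureDataset, spec: SamplerSpec) -> dict[int, ProximityPartition]:
    """Proximity partition for every minority class (class index -> partition)."""
    counts = np.bincount(ds.y, minlength=len(ds.class_names))
    majority = int(np.argmax(counts))
    out: dict[int, ProximityPartition] = {}
    for c in range(len(ds.class_names)):
        if c == majority or counts[c] == 0:
            continue
        rows_c = ds.class_rows(c)
        out[c] = _partition_one_class(
            ds, rows_c, c, spec.k_neighbors, spec.max_levels, spec.theta
        )
    return out


def allocate_counts(sizes: dict[int, int], weights: dict[int, float], n_synth: int) -> dict[int, int]:
    """Split ``n_synth`` across levels ∝ (level size × level weight).

    Largest-remainder rounding guarantees the allocations sum to ``n_synth``
    exactly; remainder ties go to the lower (boundary-nearer) level.
    """
    levels = sorted(sizes)
    mass = np.array([sizes[l] * weights[l] for l in levels], dtype=float)
    total = mass.sum()
    if total <= 0:
        mass = np.array([sizes[l] for l in levels], dtype=float)
        total = mass.sum()
    shares = n_synth * mass / total
    base = np.floor(shares).astype(int)
    remainder = n_synth - int(base.sum())
    order = sorted(range(len(levels)), key=lambda i: (-(shares[i] - base[i]), levels[i]))
    for i in order[:remainder]:
        base[i] += 1
    return {l: int(b) for l, b in zip(levels, base)}


def prowsyn_batch(ds: FeatureDataset, spec: SamplerSpec, rng: np.random.Generator) -> SyntheticBatch:
    """ProWSyn applied per minority class.

    Each level generates its allocation by interpolation between members of
    the same level (k nearest same-level neighbors); a level of size 1
    duplicates its member.
    """
    partitions = prowsyn_partition(ds, spec)
    targets = synthesis_targets(ds, spec.alpha)
    parts = []
    for c, n_synth in targets.items():
        part = partitions[c]
        sizes = {l: len(part.level_rows(l)) for l in part.levels_present}
        alloc = allocate_counts(sizes, part.weights, n_synth)
        for level in sorted(alloc):
            count = alloc[level]
            if count == 0:
                continue
            pool = part.level_rows(level)
            k_eff = min(spec.k_neighbors, max(len(pool) - 1, 0))
            lists = nearest_within(ds.X, pool, pool, k=k_eff or None)
            parts.append(
                interpolate_within_pool(ds.X, pool, lists, count, c, rng, "prowsyn")
            )
    return SyntheticBatch.concat(parts, ds.n_features)
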
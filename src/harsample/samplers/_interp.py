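"""Shared neighbor-search and interpolation machinery for all samplers.

Every SMOTE-family method in this package reduces to the same inner loop:
pick a seed row from an eligible pool, pick an interpolation partner from the
seed's candidate list, draw u ~ U[0, 1) and emit ``seed + u * (partner −
seed)``. Keeping one implementation here guarantees that methods which
coincide on special cases (e.g. MSMOTE when every minority row is safe) are
bit-identical to plain SMOTE under a shared seed.

Neighbor searches use exact pairwise distances with a stable argsort rather
than a tree: datasets here are window-level feature tables (hundreds to a few
thousand rows), and stable ordering makes tie-breaks deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist

from ..datasets import Provenance, SyntheticBatch

__all__ = ["nearest_within", "interpolate_within_pool", "synthesis_targets"]


def nearest_within(
    X: np.ndarray,
    pool: np.ndarray,
    candidates: np.ndarray,
    k: int | None = None,
) -> list[np.ndarray]:
    """For each row index in ``pool``, its nearest rows among ``candidates``.

    Returns one array of global row indices per pool member, ordered by
    Euclidean distance (stable on ties), excluding the member itself (by
    index, so duplicate coordinates elsewhere are kept). ``k=None`` keeps all
    candidates. A member whose candidate list would be empty gets ``[itself]``
    — the documented degenerate case where synthesis duplicates the seed.
    """
    pool = np.asarray(pool, dtype=int)
    candidates = np.asarray(candidates, dtype=int)
    D = cdist(X[pool], X[candidates])
    lists: list[np.ndarray] = []
    for i, p in enumerate(pool):
        order = np.argsort(D[i], kind="stable")
        ordered = candidates[order]
        ordered = ordered[ordered != p]
        if k is not None:
            ordered = ordered[:k]
        if len(ordered) == 0:
            ordered = np.array([p], dtype=int)
        lists.append(ordered)
    return lists


def interpolate_within_pool(
    X: np.ndarray,
    pool: np.ndarray,
    neighbor_lists: list[np.ndarray],
    n_synth: int,
    class_index: int,
    rng: np.random.Generator,
    method: str,
    weights: np.ndarray | None = None,
) -> SyntheticBatch:
    """Generate ``n_synth`` rows by seed/partner linear interpolation.

    Seeds are drawn uniformly with replacement from ``pool`` (or with
    probability ``weights`` when given); the partner is uniform over the
    seed's ``neighbor_lists`` entry; u ~ U[0, 1). Each output row lies on the
    closed segment between its seed and partner, and its provenance records
    exactly which rows and draw produced it.
    """
    pool = np.asarray(pool, dtype=int)
    if len(pool) == 0:
        raise ValueError(f"{method}: no eligible seed rows")
    d = X.shape[1]
    rows = np.empty((n_synth, d))
    prov: list[Provenance] = []
    for t in range(n_synth):
        if weights is None:
            s = int(rng.integers(len(pool)))
        else:
            s = int(rng.choice(len(pool), p=weights))
        seed = int(pool[s])
        cands = neighbor_lists[s]
        nb = int(cands[rng.integers(len(cands))])
        u = float(rng.random())
        rows[t] = X[seed] + u * (X[nb] - X[seed])
        prov.append(
            Provenance(
                method=method,
                seed_index=seed,
                neighbor_index=nb if nb != seed else -1,
                draws=(u,),
            )
        )
    return SyntheticBatch(rows, np.full(n_synth, class_index, dtype=int), prov)


def synthesis_targets(ds, alpha: float) -> dict[int, int]:
    """Synthetic row counts per class: ``round(alpha * (majority − count))``.

    At alpha = 1 every class is brought exactly to the majority count (the
    "sampling percentage 100%" convention). Returns only classes with a
    positive target, in class_names order.
    """
    counts = np.bincount(ds.y, minlength=len(ds.class_names))
    majority = int(counts.max())
    out: dict[int, int] = {}
    for c, k in enumerate(counts):
        gap = majority - int(k)
        n_synth = int(round(alpha * gap))
        if n_synth > 0:
            out[c] = n_synth
    return out
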
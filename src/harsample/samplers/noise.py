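"""Noise-detection samplers: Tomek links, SMOTE+Tomek cleaning, and MSMOTE.

A Tomek link is a cross-class pair (a, b) that are each other's nearest
neighbors under the Euclidean metric — no third point z satisfies
d(a, z) < d(a, b) or d(b, z) < d(a, b). Such pairs sit on class boundaries or
mark label noise. ``smote_tomeklinks_oversample`` first oversamples with
SMOTE, then removes both endpoints of every link found in the augmented set.

MSMOTE types each minority row by the class composition of its k nearest
neighbors over the whole training set: *safe* when all k share its class,
*noise* when none do, *border* otherwise. Safe seeds interpolate toward a
uniformly chosen one of their k nearest same-class neighbors, border seeds
only toward their single nearest same-class neighbor, and noise rows neither
seed synthesis nor serve as interpolation partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ..datasets import FeatureDataset, SamplerSpec, SyntheticBatch
from ._interp import interpolate_within_pool, nearest_within, synthesis_targets
from .distance import smote_batch

__all__ = [
    "find_tomek_links",
    "smote_tomeklinks_oversample",
    "MinorityTyping",
    "msmote_type",
    "msmote_batch",
]

SAFE, BORDER, NOISE = "safe", "border", "noise"


def find_tomek_links(X: np.ndarray, y: np.ndarray) -> list[tuple[int, int]]:
    """All cross-class mutual-nearest-neighbor pairs, as sorted (a, b) tuples.

    Implements the definition verbatim: (a, b) is a link iff no z is strictly
    closer to a than b is, and none strictly closer to b than a is.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        return []
    D = cdist(X, X)
    np.fill_diagonal(D, np.inf)
    nd = D.min(axis=1)  # distance to each point's nearest other point
    cross = y[:, None] != y[None, :]
    mutual = (D <= nd[:, None]) & (D <= nd[None, :])
    a_idx, b_idx = np.nonzero(np.triu(cross & mutual, k=1))
    return [(int(a), int(b)) for a, b in zip(a_idx, b_idx)]


def smote_tomeklinks_oversample(
    ds: FeatureDataset, spec: SamplerSpec, rng: np.random.Generator
) -> tuple[FeatureDataset, SyntheticBatch, dict]:
    """SMOTE first, then remove both endpoints of every Tomek link.

    Links are searched in the augmented set (originals + synthetics), so both
    original and synthetic rows may be deleted; the returned batch contains
    only the surviving synthetics. The cleaning log records the link pairs and
    the removed original / synthetic row indices — the output may therefore
    sit slightly off perfect balance, by exactly the logged removals.
    """
    batch = smote_batch(ds, spec, rng)
    Xa = np.vstack([ds.X, batch.X_syn]) if batch.n else ds.X
    ya = np.concatenate([ds.y, batch.y_syn]) if batch.n else ds.y
    n = ds.n
    links = find_tomek_links(Xa, ya)
    removed = sorted({i for pair in links for i in pair})
    removed_original = [i for i in removed if i < n]
    removed_synthetic = [i - n for i in removed if i >= n]
    keep_orig = np.ones(n, dtype=bool)
    keep_orig[removed_original] = False
    keep_syn = np.ones(batch.n, dtype=bool)
    keep_syn[removed_synthetic] = False
    surviving = batch.select(keep_syn)
    X_out = np.vstack([ds.X[keep_orig], surviving.X_syn])
    y_out = np.concatenate([ds.y[keep_orig], surviving.y_syn])
    cleaned = FeatureDataset(X_out, y_out, ds.class_names, ds.feature_names)
    log = {
        "links": [list(p) for p in links],
        "removed_original": removed_original,
        "removed_synthetic": removed_synthetic,
    }
    return cleaned, surviving, log


@dataclass
class MinorityTyping:
    """Per-minority-row safe/border/noise type and the neighbor count used."""

    types: dict[int, str]  # global row index -> type
    k_requested: int
    k_used: int

    def rows_of(self, kind: str) -> list[int]:
        return [i for i, t in self.types.items() if t == kind]


def msmote_type(ds: FeatureDataset, k: int) -> MinorityTyping:
    """Type every non-majority row by its k nearest all-class neighbors.

    The query point is excluded from its own neighborhood; with fewer than k
    other points, k is clipped (and the clip recorded on the result).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = np.bincount(ds.y, minlength=len(ds.class_names))
    majority = int(np.argmax(counts))
    k_used = min(k, ds.n - 1)
    if k_used < 1:
        raise ValueError("dataset too small to type minority rows")
    all_rows = np.arange(ds.n)
    minority_rows = np.flatnonzero(ds.y != majority)
    lists = nearest_within(ds.X, minority_rows, all_rows, k=k_used)
    types: dict[int, str] = {}
    for row, nbrs in zip(minority_rows, lists):
        same = int(np.sum(ds.y[nbrs] == ds.y[row]))
        if same == len(nbrs):
            types[int(row)] = SAFE
        elif same == 0:
            types[int(row)] = NOISE
        else:
            types[int(row)] = BORDER
    return MinorityTyping(types, k_requested=k, k_used=k_used)


def msmote_batch(
    ds: FeatureDataset, spec: SamplerSpec, rng: np.random.Generator
) -> SyntheticBatch:
    """MSMOTE applied per minority class.

    Seeds come only from safe ∪ border rows; noise rows are also excluded
    from the interpolation-partner pool so synthesis never moves toward
    suspected label noise. A class whose minority rows are all noise raises
    ``no eligible seeds``.
    """
    typing = msmote_type(ds, spec.k_neighbors)
    targets = synthesis_targets(ds, spec.alpha)
    parts = []
    for c, n_synth in targets.items():
        rows_c = ds.class_rows(c)
        eligible = np.array([i for i in rows_c if typing.types[int(i)] != NOISE], dtype=int)
        if len(eligible) == 0:
            raise ValueError(
                f"msmote: no eligible seeds for class {ds.class_names[c]!r} "
                "(all minority rows typed as noise)"
            )
        candidates = eligible  # noise rows removed from the partner pool too
        k_eff = min(spec.k_neighbors, max(len(candidates) - 1, 0))
        safe_lists = nearest_within(ds.X, eligible, candidates, k=k_eff or None)
        border_lists = nearest_within(ds.X, eligible, candidates, k=1)
        lists = [
            safe_lists[j] if typing.types[int(seed)] == SAFE else border_lists[j]
            for j, seed in enumerate(eligible)
        ]
        parts.append(
            interpolate_within_pool(ds.X, eligible, lists, n_synth, c, rng, "msmote")
        )
    return SyntheticBatch.concat(parts, ds.n_features)
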
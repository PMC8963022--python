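"""Distance-based samplers: SMOTE and Random_SMOTE.

Both methods synthesize minority rows by linear interpolation. SMOTE draws a
minority seed x and one of its k nearest same-class neighbors x_k and emits
``x + u (x_k − x)`` with u ~ U[0, 1), so every synthetic row lies on the
segment between two real minority points. Random_SMOTE widens the region: two
further minority rows x1, x2 (both ≠ x) define a temporary point
``x_tmp = x1 + u1 (x2 − x1)`` and the output ``x + u2 (x_tmp − x)`` lies in
the closed triangle (x, x1, x2).

The componentwise form ``seed + u·(other − seed)`` is this module's reading of
the generation rule: synthetic samples lie along the line between the two
points, which a scalar-norm offset could not produce for d > 1.
"""

from __future__ import annotations

import numpy as np

from ..datasets import FeatureDataset, Provenance, SamplerSpec, SyntheticBatch
from ._interp import interpolate_within_pool, nearest_within, synthesis_targets

__all__ = ["smote_generate", "random_smote_generate", "smote_batch", "random_smote_batch"]


def smote_generate(
    minority_X: np.ndarray,
    k: int,
    n_synth: int,
    rng: np.random.Generator,
    index_map: np.ndarray | None = None,
    class_index: int = 0,
) -> SyntheticBatch:
    """SMOTE within one minority class.

    ``k`` is capped at (minority size − 1). A minority class of size 1 has no
    neighbors: synthetic rows duplicate the lone seed (documented degenerate
    behavior). ``index_map`` translates local minority row numbers to global
    dataset rows for provenance.
    """
    minority_X = np.asarray(minority_X, dtype=float)
    n = minority_X.shape[0]
    if n == 0:
        raise ValueError("smote: minority class is empty")
    if index_map is None:
        index_map = np.arange(n)
    index_map = np.asarray(index_map, dtype=int)
    # Work in global index space throughout so provenance is audit-ready.
    local_to_global = index_map
    pool = local_to_global
    k_eff = min(k, n - 1) if n > 1 else 0
    if k_eff == 0:
        lists = [np.array([g]) for g in pool]
    else:
        # distances computed on the minority block only (same-class search)
        lists = _same_class_knn(minority_X, local_to_global, k_eff)
    return interpolate_within_pool(
        _global_matrix(minority_X, local_to_global),
        pool,
        lists,
        n_synth,
        class_index,
        rng,
        "smote",
    )


def _global_matrix(minority_X: np.ndarray, index_map: np.ndarray) -> np.ndarray:
    """A sparse-ish global view: rows placed at their global indices."""
    size = int(index_map.max()) + 1 if len(index_map) else 0
    M = np.zeros((size, minority_X.shape[1]))
    M[index_map] = minority_X
    return M


def _same_class_knn(minority_X: np.ndarray, index_map: np.ndarray, k: int) -> list[np.ndarray]:
    M = _global_matrix(minority_X, index_map)
    return nearest_within(M, index_map, index_map, k=k)


def random_smote_generate(
    minority_X: np.ndarray,
    n_synth: int,
    rng: np.random.Generator,
    index_map: np.ndarray | None = None,
    class_index: int = 0,
) -> SyntheticBatch:
    """Random_SMOTE within one minority class.

    Needs at least 3 minority rows so that x1 and x2 can both differ from the
    seed x; smaller classes fall back to SMOTE with k = 1 (documented).
    Provenance records (x, x1, x2, u1, u2); the synthetic row always lies in
    the closed triangle spanned by those three rows.
    """
    minority_X = np.asarray(minority_X, dtype=float)
    n = minority_X.shape[0]
    if n == 0:
        raise ValueError("random_smote: minority class is empty")
    if index_map is None:
        index_map = np.arange(n)
    index_map = np.asarray(index_map, dtype=int)
    if n < 3:
        return smote_generate(minority_X, 1, n_synth, rng, index_map, class_index)
    d = minority_X.shape[1]
    rows = np.empty((n_synth, d))
    prov: list[Provenance] = []
    for t in range(n_synth):
        s = int(rng.integers(n))
        others = np.delete(np.arange(n), s)
        pick = rng.choice(n - 1, size=2, replace=False)
        i1, i2 = int(others[pick[0]]), int(others[pick[1]])
        u1 = float(rng.random())
        u2 = float(rng.random())
        x = minority_X[s]
        x_tmp = minority_X[i1] + u1 * (minority_X[i2] - minority_X[i1])
        rows[t] = x + u2 * (x_tmp - x)
        prov.append(
            Provenance(
                method="random_smote",
                seed_index=int(index_map[s]),
                neighbor_index=int(index_map[i1]),
                partner_index=int(index_map[i2]),
                draws=(u1, u2),
            )
        )
    return SyntheticBatch(rows, np.full(n_synth, class_index, dtype=int), prov)


# -- dataset-level wrappers (one batch covering every minority class) -------

def smote_batch(ds: FeatureDataset, spec: SamplerSpec, rng: np.random.Generator) -> SyntheticBatch:
    """SMOTE applied per minority class; targets set by ``spec.alpha``."""
    targets = synthesis_targets(ds, spec.alpha)
    parts = []
    for c, n_synth in targets.items():
        rows_c = ds.class_rows(c)
        parts.append(
            smote_generate(ds.X[rows_c], spec.k_neighbors, n_synth, rng, rows_c, c)
        )
    return SyntheticBatch.concat(parts, ds.n_features)


def random_smote_batch(
    ds: FeatureDataset, spec: SamplerSpec, rng: np.random.Generator
) -> SyntheticBatch:
    """Random_SMOTE applied per minority class."""
    targets = synthesis_targets(ds, spec.alpha)
    parts = []
    for c, n_synth in targets.items():
        rows_c = ds.class_rows(c)
        parts.append(random_smote_generate(ds.X[rows_c], n_synth, rng, rows_c, c))
    return SyntheticBatch.concat(parts, ds.n_features)
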
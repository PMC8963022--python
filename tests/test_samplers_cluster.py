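import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from harsample.datasets import FeatureDataset, SamplerSpec, make_rng
from harsample.samplers import (
    allocate_counts,
    cbso_batch,
    cbso_cluster,
    prowsyn_batch,
    prowsyn_partition,
    smote_batch,
)


def two_blob_minority_ds(seed=0):
    """Majority far away; minority split into two tight, distant blobs."""
    rng = np.random.default_rng(seed)
    maj = rng.normal([100, 100], 1.0, size=(30, 2))
    blob1 = rng.normal([0, 0], 0.2, size=(6, 2))
    blob2 = rng.normal([20, 0], 0.2, size=(6, 2))
    X = np.vstack([maj, blob1, blob2])
    y = np.array([0] * 30 + [1] * 12)
    return FeatureDataset(X, y, ("maj", "min"))


class TestCbsoCluster:
    def test_two_distant_blobs_give_two_clusters(self):
        ds = two_blob_minority_ds()
        assign = cbso_cluster(ds, SamplerSpec("cbso"))
        ids = assign.cluster_ids[1]
        assert len(set(ids[:6])) == 1 and len(set(ids[6:])) == 1
        assert ids[0] != ids[6]

    def test_identical_rows_form_one_cluster(self):
        X = np.vstack([np.zeros((5, 2)), np.full((10, 2), 9.0)])
        ds = FeatureDataset(X, np.array([0] * 5 + [1] * 10), ("min", "maj"))
        assign = cbso_cluster(ds, SamplerSpec("cbso"))
        assert len(set(assign.cluster_ids[0])) == 1

    def test_single_minority_row_is_singleton_cluster(self):
        X = np.vstack([np.zeros((1, 2)), np.full((5, 2), 9.0)])
        ds = FeatureDataset(X, np.array([1] + [0] * 5), ("min", "maj"))
        assign = cbso_cluster(ds, SamplerSpec("cbso"))
        assert list(assign.cluster_ids[1]) == [0]

    def test_matches_threshold_clustering_oracle(self):
        # brute force: connected components under single cut at the same T on
        # a geometry where average- and single-linkage cuts agree
        ds = two_blob_minority_ds(seed=3)
        assign = cbso_cluster(ds, SamplerSpec("cbso"))
        rows = assign.rows[1]
        Xm = ds.X[rows]
        ids = assign.cluster_ids[1]
        # oracle: two groups separated by >> threshold
        assert assign.thresholds[1] < 10.0
        for i in range(len(rows)):
            for j in range(len(rows)):
                same_blob = (i < 6) == (j < 6)
                assert (ids[i] == ids[j]) == same_blob


class TestCbsoGenerate:
    def test_synthetics_never_cross_clusters(self):
        ds = two_blob_minority_ds(seed=1)
        assign = cbso_cluster(ds, SamplerSpec("cbso"))
        rows = list(assign.rows[1])
        id_of = {int(r): int(c) for r, c in zip(assign.rows[1], assign.cluster_ids[1])}
        batch = cbso_batch(ds, SamplerSpec("cbso"), make_rng(2))
        assert batch.n == 18
        for p in batch.provenance:
            if p.neighbor_index >= 0:
                assert id_of[p.seed_index] == id_of[p.neighbor_index]

    def test_uniform_weights_single_cluster_bit_identical_to_full_k_smote(self):
        # majority so far away that every border weight is zero -> uniform seeds;
        # one cluster; SMOTE with k = minority-1 has the same candidate lists
        rng = np.random.default_rng(5)
        maj = rng.normal([1000, 1000], 1.0, size=(20, 2))
        mino = rng.normal([0, 0], 1.0, size=(8, 2))
        ds = FeatureDataset(np.vstack([maj, mino]), np.array([0] * 20 + [1] * 8), ("a", "b"))
        a = cbso_batch(ds, SamplerSpec("cbso", k_neighbors=5), make_rng(7))
        b = smote_batch(ds, SamplerSpec("smote", k_neighbors=7), make_rng(7))
        assert np.array_equal(a.X_syn, b.X_syn)

    def test_singleton_cluster_duplicates_seed(self):
        X = np.vstack([np.zeros((1, 2)), np.full((6, 2), 9.0)])
        ds = FeatureDataset(X, np.array([0] + [1] * 6), ("min", "maj"))
        batch = cbso_batch(ds, SamplerSpec("cbso"), make_rng(0))
        assert batch.n == 5
        assert np.allclose(batch.X_syn, 0.0)


class TestProwsynPartition:
    def one_d_fixture(self):
        # majority cluster near 0; minority at -1, -2, -3 (rows 4, 5, 6)
        X = np.array([[0.0], [0.1], [0.2], [0.3], [-1.0], [-2.0], [-3.0]])
        y = np.array([0, 0, 0, 0, 1, 1, 1])
        return FeatureDataset(X, y, ("maj", "min"))

    def test_peeling_levels_on_line(self):
        ds = self.one_d_fixture()
        part = prowsyn_partition(ds, SamplerSpec("prowsyn", k_neighbors=1, max_levels=3))[1]
        assert part.level_of == {4: 1, 5: 2, 6: 3}

    def test_exponential_weights_closed_form(self):
        ds = self.one_d_fixture()
        part = prowsyn_partition(ds, SamplerSpec("prowsyn", k_neighbors=1, max_levels=3, theta=1.0))[1]
        raw = np.exp(-np.array([0.0, 1.0, 2.0]))
        expected = raw / raw.sum()
        assert np.allclose([part.weights[1], part.weights[2], part.weights[3]], expected)

    def test_max_levels_one_puts_everything_at_level_one(self):
        ds = self.one_d_fixture()
        part = prowsyn_partition(ds, SamplerSpec("prowsyn", k_neighbors=1, max_levels=1))[1]
        assert set(part.level_of.values()) == {1}
        assert part.weights == {1: 1.0}

    def test_levels_cover_every_minority_row(self, make_blobs):
        ds = make_blobs([25, 11], seed=4, d=3)
        part = prowsyn_partition(ds, SamplerSpec("prowsyn"))[1]
        assert sorted(part.level_of) == sorted(int(i) for i in ds.class_rows(1))

    def test_weights_strictly_decreasing_in_level(self, make_blobs):
        ds = make_blobs([30, 12], seed=2, d=2, spread=2.0)
        part = prowsyn_partition(ds, SamplerSpec("prowsyn", theta=0.7, max_levels=4))[1]
        levels = sorted(part.weights)
        w = [part.weights[l] for l in levels]
        assert all(a > b for a, b in zip(w, w[1:]))


class TestAllocation:
    def test_worked_allocation(self):
        sizes = {1: 1, 2: 1, 3: 1}
        weights = {1: 0.6652, 2: 0.2447, 3: 0.0900}
        alloc = allocate_counts(sizes, weights, 10)
        assert alloc == {1: 7, 2: 2, 3: 1}

    @given(
        st.lists(st.integers(1, 9), min_size=1, max_size=5),
        st.integers(0, 50),
        st.floats(0.1, 3.0),
    )
    @settings(max_examples=60, deadline=None)
    def test_allocations_sum_exactly(self, sizes, n_synth, theta):
        sizes_d = {l + 1: s for l, s in enumerate(sizes)}
        raw = {l: np.exp(-theta * (l - 1)) for l in sizes_d}
        total = sum(raw.values())
        weights = {l: v / total for l, v in raw.items()}
        alloc = allocate_counts(sizes_d, weights, n_synth)
        assert sum(alloc.values()) == n_synth
        assert all(v >= 0 for v in alloc.values())


class TestProwsynGenerate:
    def test_single_level_bit_identical_to_smote(self, make_blobs):
        # minority far from majority with k covering the class -> all level max
        # (one level present) -> same interpolation loop as SMOTE
        ds = make_blobs([20, 8], seed=9, spread=0.4, centers=[[0, 0], [70, 0]])
        a = prowsyn_batch(ds, SamplerSpec("prowsyn", k_neighbors=5, max_levels=1), make_rng(13))
        b = smote_batch(ds, SamplerSpec("smote", k_neighbors=5), make_rng(13))
        assert np.array_equal(a.X_syn, b.X_syn)

    def test_theta_large_concentrates_on_level_one(self, make_blobs):
        ds = make_blobs([30, 10], seed=1, d=2, spread=2.5)
        spec = SamplerSpec("prowsyn", theta=50.0, max_levels=3, k_neighbors=2)
        part = prowsyn_partition(ds, spec)[1]
        level1 = set(int(r) for r in part.level_rows(1))
        assert len(level1) < 10  # several levels actually occupied
        batch = prowsyn_batch(ds, spec, make_rng(3))
        assert {p.seed_index for p in batch.provenance} <= level1

    def test_batch_size_matches_gap(self, make_blobs):
        ds = make_blobs([40, 15, 9], seed=8, d=3)
        batch = prowsyn_batch(ds, SamplerSpec("prowsyn"), make_rng(5))
        assert batch.n == (40 - 15) + (40 - 9)
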
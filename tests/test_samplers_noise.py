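import numpy as np
import pytest

from harsample.datasets import FeatureDataset, SamplerSpec, class_counts, make_rng
from harsample.samplers import (
    find_tomek_links,
    msmote_batch,
    msmote_type,
    smote_batch,
    smote_tomeklinks_oversample,
)


def tomek_links_oracle(X, y):
    """Verbatim O(n^2) check: (a,b) is a link iff no z is strictly closer."""
    n = len(y)
    links = set()
    for a in range(n):
        for b in range(a + 1, n):
            if y[a] == y[b]:
                continue
            d_ab = np.linalg.norm(X[a] - X[b])
            blocked = False
            for z in range(n):
                if z in (a, b):
                    continue
                if (np.linalg.norm(X[a] - X[z]) < d_ab
                        or np.linalg.norm(X[b] - X[z]) < d_ab):
                    blocked = True
                    break
            if not blocked:
                links.add((a, b))
    return links


class TestFindTomekLinks:
    def test_separated_clusters_have_no_links(self, make_blobs):
        ds = make_blobs([10, 10], seed=0, spread=0.2, centers=[[0, 0], [50, 50]])
        assert find_tomek_links(ds.X, ds.y) == []

    def test_one_dimensional_worked_example(self):
        X = np.array([[0.0], [1.0], [1.1], [5.0]])
        y = np.array([0, 0, 1, 1])
        assert find_tomek_links(X, y) == [(1, 2)]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_verbatim_oracle_on_random_points(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(30, 2))
        y = rng.integers(0, 3, size=30)
        assert set(find_tomek_links(X, y)) == tomek_links_oracle(X, y)

    def test_invariant_under_row_permutation(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 2))
        y = rng.integers(0, 2, size=20)
        perm = rng.permutation(20)
        orig = set(find_tomek_links(X, y))
        permuted = find_tomek_links(X[perm], y[perm])
        remapped = {tuple(sorted((perm[a], perm[b]))) for a, b in permuted}
        assert remapped == orig


class TestSmoteTomekLinks:
    def test_wide_margin_cleans_nothing(self, make_blobs):
        ds = make_blobs([20, 8], seed=1, spread=0.3, centers=[[0, 0], [30, 30]])
        cleaned, batch, log = smote_tomeklinks_oversample(ds, SamplerSpec("smote_tomeklinks"), make_rng(0))
        assert log["links"] == []
        counts, _ = class_counts(cleaned)
        assert counts == {"A": 20, "B": 20}

    def test_mislabeled_point_removed_with_its_partner(self):
        # balanced classes (no synthesis): a lone majority point sits 0.3 away
        # from minority row 4 on a unit-spaced minority grid -> mutual NN pair
        majority = np.column_stack([np.linspace(100, 109, 9), np.zeros(9)])
        intruder = np.array([[4.3, 0.0]])
        minority = np.column_stack([np.arange(10.0), np.zeros(10)])
        X = np.vstack([majority, intruder, minority])
        ds = FeatureDataset(X, np.array([0] * 10 + [1] * 10), ("maj", "min"))
        cleaned, _, log = smote_tomeklinks_oversample(ds, SamplerSpec("smote_tomeklinks"), make_rng(0))
        assert log["links"] == [[9, 14]]  # intruder row and minority point x=4
        assert log["removed_original"] == [9, 14]
        assert cleaned.n == ds.n - 2

    def test_balanced_input_without_links_is_identity(self, make_blobs):
        ds = make_blobs([10, 10], seed=2, spread=0.2, centers=[[0, 0], [40, 0]])
        cleaned, batch, log = smote_tomeklinks_oversample(ds, SamplerSpec("smote_tomeklinks"), make_rng(0))
        assert batch.n == 0
        assert np.array_equal(cleaned.X, ds.X)

    def test_no_links_remain_after_cleaning(self, make_blobs):
        ds = make_blobs([25, 9], seed=5, spread=1.0, centers=[[0, 0], [3, 0]])
        cleaned, _, _ = smote_tomeklinks_oversample(ds, SamplerSpec("smote_tomeklinks"), make_rng(1))
        assert find_tomek_links(cleaned.X, cleaned.y) == []


class TestMsmoteTyping:
    def make_typed_fixture(self):
        # minority pocket far from majority -> safe; lone minority row inside
        # the majority cloud -> noise; pocket edge near majority -> border
        maj = np.array([[10.0 + dx, dy] for dx in range(4) for dy in range(4)])
        safe_pocket = np.array([[0.0, 0.0], [0.1, 0.0], [0.0, 0.1], [0.1, 0.1],
                                [0.05, 0.05], [0.02, 0.08]])
        noise_row = np.array([[11.5, 1.5]])
        X = np.vstack([maj, safe_pocket, noise_row])
        y = np.array([0] * len(maj) + [1] * 7)
        return FeatureDataset(X, y, ("maj", "min"))

    def test_safe_border_noise_partition(self):
        ds = self.make_typed_fixture()
        typing = msmote_type(ds, k=5)
        minority_rows = np.flatnonzero(ds.y == 1)
        assert set(typing.types) == set(int(i) for i in minority_rows)
        assert typing.types[22] == "noise"  # the row inside the majority cloud
        assert all(typing.types[i] == "safe" for i in range(16, 22))

    def test_border_when_neighborhood_is_mixed(self):
        X = np.array([[0.0], [0.2], [0.4], [0.6], [0.8], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        typing = msmote_type(FeatureDataset(X, y, ("a", "b")), k=3)
        assert typing.types[3] == "border"  # neighbors 0.4 (a), 0.8, 1.0 (b)

    def test_types_partition_minority_exactly(self, make_blobs):
        ds = make_blobs([30, 10, 6], seed=6, d=3)
        typing = msmote_type(ds, k=5)
        n_minority = int(np.sum(ds.y != 0))
        assert len(typing.types) == n_minority

    def test_k_clipped_when_dataset_small(self):
        ds = FeatureDataset(np.arange(6.0).reshape(3, 2), np.array([0, 0, 1]), ("a", "b"))
        typing = msmote_type(ds, k=10)
        assert typing.k_used == 2


class TestMsmoteGenerate:
    def test_all_safe_bit_identical_to_smote(self, make_blobs):
        ds = make_blobs([20, 8], seed=7, spread=0.3, centers=[[0, 0], [60, 60]])
        spec = SamplerSpec("msmote", k_neighbors=5)
        a = msmote_batch(ds, spec, make_rng(42))
        b = smote_batch(ds, SamplerSpec("smote", k_neighbors=5), make_rng(42))
        assert np.array_equal(a.X_syn, b.X_syn)
        assert np.array_equal(a.y_syn, b.y_syn)

    def test_noise_rows_never_seed_or_receive_interpolation(self):
        fixture = TestMsmoteTyping().make_typed_fixture()
        spec = SamplerSpec("msmote", k_neighbors=5)
        typing = msmote_type(fixture, 5)
        noise_rows = {i for i, t in typing.types.items() if t == "noise"}
        batch = msmote_batch(fixture, spec, make_rng(3))
        for p in batch.provenance:
            assert p.seed_index not in noise_rows
            assert p.neighbor_index not in noise_rows

    def test_border_seed_interpolates_to_single_nearest_neighbor(self):
        X = np.array([[0.0], [0.2], [0.4], [0.6], [0.8], [1.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        ds = FeatureDataset(X, y, ("a", "b"))
        typing = msmote_type(ds, k=3)
        assert typing.types[3] == "border"
        batch = msmote_batch(ds, SamplerSpec("msmote", k_neighbors=3), make_rng(1))
        for p in batch.provenance:
            if p.seed_index == 3:
                assert p.neighbor_index == 4  # its single nearest minority neighbor

    def test_all_noise_minority_raises_no_eligible_seeds(self):
        rng = np.random.default_rng(0)
        maj = rng.normal(0, 1, size=(100, 2))
        # two minority rows engulfed by the majority cloud, far from each other
        lone = np.array([[0.8, 0.8], [-0.8, -0.8]])
        ds = FeatureDataset(np.vstack([maj, lone]), np.array([0] * 100 + [1, 1]), ("a", "b"))
        with pytest.raises(ValueError, match="no eligible seeds"):
            msmote_batch(ds, SamplerSpec("msmote", k_neighbors=5), make_rng(0))
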
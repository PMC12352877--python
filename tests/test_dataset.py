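"""Labels, standardization, flattening, splits and partitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epixpress.annotation import CANONICAL_FEATURES, BinSpec
from epixpress.dataset import (
    ColumnMap,
    PatientDataset,
    PooledFeatureScaler,
    expression_labels,
    flatten,
    load_dataset,
    partition_subsets,
    save_dataset,
    split_train_val,
    standardize,
    unflatten,
)


class TestExpressionLabels:
    def test_all_zero_counts_give_zero_labels(self):
        assert not expression_labels([0, 0, 0]).any()

    def test_single_gene_forces_tpm_of_one_million(self):
        (label,) = expression_labels([42])
        assert label == pytest.approx(np.log2(1e6 + 1), abs=1e-12)

    def test_three_one_split_matches_arbitrary_precision_oracle(self):
        # Frozen from Fraction-based evaluation: TPM = (750000, 250000),
        # labels = log2(750001), log2(250001).
        labels = expression_labels([3, 1])
        assert labels == pytest.approx([19.516532993637436, 17.931574340092796], abs=1e-12)

    def test_tpm_sums_to_one_million(self, rng):
        counts = rng.integers(0, 500, size=1000)
        labels = expression_labels(counts)
        tpm = 2.0 ** labels - 1
        assert tpm.sum() == pytest.approx(1e6, rel=1e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            expression_labels([1, -2])


class TestStandardization:
    def test_two_point_feature_maps_to_plus_minus_one(self):
        tensor = np.zeros((2, 2, 1))
        tensor[0, :, 0] = 0.0
        tensor[1, :, 0] = 2.0
        z, records = standardize(tensor, ["H3K27Ac"])
        assert set(np.unique(z)) == {-1.0, 1.0}
        assert records[0].mean == 1.0 and records[0].sd == 1.0

    def test_constant_feature_is_degenerate_and_zeroed(self):
        tensor = np.full((3, 4, 2), 5.0)
        tensor[:, :, 1] = np.arange(12).reshape(3, 4)
        z, records = standardize(tensor, ["A", "B"])
        assert records[0].degenerate and not records[1].degenerate
        assert not z[:, :, 0].any()

    def test_pooled_moments_after_standardization(self, rng):
        tensor = rng.gamma(2.0, 3.0, size=(50, 10, 4))
        z, _ = standardize(tensor)
        assert np.abs(z.mean(axis=(0, 1))).max() < 1e-8
        assert np.abs(z.std(axis=(0, 1)) - 1).max() < 1e-6

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PooledFeatureScaler().fit(np.zeros((0, 5, 2)))

    def test_scaler_is_sklearn_compatible(self, rng):
        scaler = PooledFeatureScaler(feature_names=list(CANONICAL_FEATURES))
        assert "feature_names" in scaler.get_params()
        X = rng.poisson(3.0, size=(10, 5, 4)).astype(float)
        z = scaler.fit_transform(X)
        assert z.shape == X.shape


class TestFlatten:
    def test_column_map_positions_match_tensor_entries(self, rng):
        tensor = rng.normal(size=(1, 50, 4))
        flat = flatten(tensor, CANONICAL_FEATURES)
        assert flat.matrix.shape == (1, 200)
        for f_idx, f in enumerate(CANONICAL_FEATURES):
            for b in (0, 17, 49):
                col = flat.column_map.column(f, b)
                assert flat.matrix[0, col] == tensor[0, b, f_idx]

    def test_feature_blocks_are_contiguous(self):
        cmap = ColumnMap(CANONICAL_FEATURES, 50)
        for i, f in enumerate(CANONICAL_FEATURES):
            block = cmap.block(f)
            assert (block.start, block.stop) == (i * 50, (i + 1) * 50)

    def test_column_map_partitions_every_column_once(self):
        cmap = ColumnMap(CANONICAL_FEATURES, 50)
        seen = [cmap.feature_of(c) for c in range(cmap.n_columns)]
        assert len(set(seen)) == cmap.n_columns == 200

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(3, 12), st.integers(2, 8), st.integers(1, 4))
    def test_flatten_unflatten_roundtrip(self, n_genes, n_bins, n_features):
        tensor = np.random.default_rng(0).normal(size=(n_genes, n_bins, n_features))
        names = [f"f{i}" for i in range(n_features)]
        assert np.array_equal(unflatten(flatten(tensor, names)), tensor)

    def test_restrict_keeps_named_blocks(self, rng):
        tensor = rng.normal(size=(3, 50, 4))
        flat = flatten(tensor, CANONICAL_FEATURES)
        sub = flat.restrict(["H3K27Ac"])
        assert sub.matrix.shape == (3, 50)
        assert np.array_equal(sub.matrix, tensor[:, :, 0])


def _toy_dataset(n=40, n_chroms=4, seed=0):
    rng = np.random.default_rng(seed)
    return PatientDataset(
        patient_id="T",
        gene_ids=np.array([f"g{i}" for i in range(n)]),
        tensor=rng.poisson(2.0, size=(n, 50, 4)),
        labels=rng.gamma(2.0, 2.0, size=n),
        chroms=np.array([f"chr{i % n_chroms}" for i in range(n)]),
    )


class TestSplits:
    def test_full_train_fraction_empty_validation(self):
        ds = _toy_dataset()
        train, val = split_train_val(ds, train_fraction=1.0)
        assert len(val) == 0 and len(train) == ds.n_genes

    @pytest.mark.parametrize("scheme", ["random_genes", "cross_chromosomal"])
    def test_split_is_disjoint_and_exhaustive(self, scheme):
        ds = _toy_dataset()
        train, val = split_train_val(ds, 0.7, scheme=scheme, seed=3)
        assert len(np.intersect1d(train, val)) == 0
        assert len(np.union1d(train, val)) == ds.n_genes

    def test_cross_chromosomal_never_splits_a_chromosome(self):
        ds = _toy_dataset(n=100, n_chroms=4, seed=5)
        train, val = split_train_val(ds, 0.7, scheme="cross_chromosomal", seed=2)
        assert not set(ds.chroms[train]) & set(ds.chroms[val])
        assert len(train) >= 0.7 * ds.n_genes

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            split_train_val(_toy_dataset(), train_fraction=0.0)


class TestSubsetPartition:
    @pytest.mark.parametrize(
        "n, k, head, tail",
        [
            (20_015, 10, 2_002, 1_997),
            (18_524, 10, 1_853, 1_847),
            (10, 10, 1, 1),
        ],
    )
    def test_ceiling_rule_sizes(self, n, k, head, tail):
        part = partition_subsets(n, k)
        assert part.part_sizes[:-1] == tuple([head] * (part.k - 1))
        assert part.part_sizes[-1] == tail
        assert sum(part.part_sizes) == n

    def test_parts_disjoint_and_cover(self):
        part = partition_subsets(103, 10)
        all_idx = np.concatenate([part.indices(i) for i in range(part.k)])
        assert len(all_idx) == 103 and len(np.unique(all_idx)) == 103

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            partition_subsets(5, 10)


class TestContainerIO:
    def test_hdf5_roundtrip(self, tmp_path):
        ds = _toy_dataset()
        path = tmp_path / "ds.h5"
        save_dataset(ds, str(path))
        back = load_dataset(str(path))
        assert back.patient_id == ds.patient_id
        assert np.array_equal(back.tensor, ds.tensor)
        assert np.array_equal(back.labels, ds.labels)
        assert list(back.gene_ids) == list(ds.gene_ids)
        assert back.feature_names == ds.feature_names
        assert back.bin_spec == ds.bin_spec
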
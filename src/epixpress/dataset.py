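"""Per-patient dataset assembly: tensors, labels, standardization, flattening.

The central container is :class:`PatientDataset`: for one patient, a
``genes × bins × features`` tensor of raw window counts plus a per-gene
expression label ``log2(TPM + 1)``.  Models consume a
:class:`FlatDesignMatrix` — the standardized tensor flattened to
``genes × (bins · features)`` with each feature's bins in one contiguous
column block, described exactly by a :class:`ColumnMap`.

Standardization is pooled z-scoring per feature *within one gene set*
(train, validation or test separately, after splitting, to avoid leakage):
mean and population standard deviation are taken over all genes × bins of
that feature, so the feature mean of the standardized values is 0.0 — the
value later used as the zero-fill for absent or perturbed features.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .annotation import CANONICAL_FEATURES, BinSpec


# ---------------------------------------------------------------------------
# expression labels


def expression_labels(
    per_gene_window_counts: Sequence[float] | np.ndarray,
    region_length_bases: int | None = None,
) -> np.ndarray:
    """log2(TPM + 1) labels from per-gene RNA counts summed over the TSS window.

    TPM_g = 1e6 · (c_g / L) / Σ_h (c_h / L); with the window length L constant
    across genes this reduces to 1e6 · c_g / Σ c.  An all-zero input yields
    all-zero labels (degenerate but defined).
    """
    counts = np.asarray(per_gene_window_counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("RNA window counts must be non-negative")
    if region_length_bases is not None and region_length_bases <= 0:
        raise ValueError("region length must be positive")
    total = counts.sum()
    if total == 0:
        return np.zeros_like(counts)
    tpm = 1e6 * counts / total
    return np.log2(tpm + 1.0)


# ---------------------------------------------------------------------------
# standardization


@dataclass(frozen=True)
class StandardizationRecord:
    """Pooled mean/sd used to z-score one feature within one gene set."""

    feature: str
    mean: float
    sd: float

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0


class PooledFeatureScaler(TransformerMixin, BaseEstimator):
    """Z-score each feature of a ``genes × bins × features`` tensor using
    statistics pooled over all genes × bins of that feature.

    Population (divide-by-n) standard deviation is used, fixed for
    reproducibility.  A constant feature (sd = 0) transforms to all zeros and
    is flagged via ``degenerate_``.

    Attributes
    ----------
    means_, sds_ : ndarray of shape (n_features,)
    degenerate_ : boolean ndarray of shape (n_features,)
    """

    def __init__(self, feature_names: Sequence[str] | None = None):
        self.feature_names = feature_names

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"expected a genes × bins × features tensor, got ndim={X.ndim}")
        if X.shape[0] == 0:
            raise ValueError("cannot standardize an empty gene set")
        self.means_ = X.mean(axis=(0, 1))
        self.sds_ = X.std(axis=(0, 1))  # population form (ddof=0)
        self.degenerate_ = self.sds_ == 0.0
        self.n_features_in_ = X.shape[2]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.n_features_in_:
            raise ValueError("tensor feature dimension does not match the fitted scaler")
        safe_sd = np.where(self.degenerate_, 1.0, self.sds_)
        z = (X - self.means_[None, None, :]) / safe_sd[None, None, :]
        z[:, :, self.degenerate_] = 0.0
        return z

    def records(self) -> list[StandardizationRecord]:
        names = (
            list(self.feature_names)
            if self.feature_names is not None
            else [f"feature_{i}" for i in range(self.n_features_in_)]
        )
        return [
            StandardizationRecord(feature=n, mean=float(m), sd=float(s))
            for n, m, s in zip(names, self.means_, self.sds_)
        ]


def standardize(tensor: np.ndarray, feature_names: Sequence[str] | None = None):
    """Functional wrapper: returns (standardized tensor, standardization records)."""
    scaler = PooledFeatureScaler(feature_names=feature_names).fit(tensor)
    return scaler.transform(tensor), scaler.records()


# ---------------------------------------------------------------------------
# flattening and the column map


@dataclass(frozen=True)
class ColumnMap:
    """Column index ↔ (feature, bin) mapping of a flat design matrix; each
    feature's bins occupy one contiguous block in the given feature order."""

    feature_names: tuple[str, ...]
    n_bins: int

    @property
    def n_columns(self) -> int:
        return len(self.feature_names) * self.n_bins

    def column(self, feature: str, bin_index: int) -> int:
        if not 0 <= bin_index < self.n_bins:
            raise ValueError(f"bin index {bin_index} outside [0, {self.n_bins})")
        return self.feature_names.index(feature) * self.n_bins + bin_index

    def feature_of(self, column: int) -> tuple[str, int]:
        if not 0 <= column < self.n_columns:
            raise ValueError(f"column {column} outside [0, {self.n_columns})")
        return self.feature_names[column // self.n_bins], column % self.n_bins

    def block(self, feature: str) -> slice:
        i = self.feature_names.index(feature)
        return slice(i * self.n_bins, (i + 1) * self.n_bins)

    def column_names(self) -> list[str]:
        return [f"{f}_bin{b:02d}" for f in self.feature_names for b in range(self.n_bins)]

    def digest(self) -> str:
        payload = json.dumps({"features": self.feature_names, "n_bins": self.n_bins})
        return hashlib.sha1(payload.encode()).hexdigest()

    def subset(self, features: Sequence[str]) -> "ColumnMap":
        unknown = [f for f in features if f not in self.feature_names]
        if unknown:
            raise ValueError(f"unknown features {unknown}; have {self.feature_names}")
        return ColumnMap(feature_names=tuple(features), n_bins=self.n_bins)


@dataclass
class FlatDesignMatrix:
    """``genes × (bins · features)`` matrix with its column map and row ids."""

    matrix: np.ndarray
    column_map: ColumnMap
    gene_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != self.column_map.n_columns:
            raise ValueError(
                f"matrix shape {self.matrix.shape} inconsistent with column map "
                f"({self.column_map.n_columns} columns)"
            )

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[0]

    def restrict(self, features: Sequence[str]) -> "FlatDesignMatrix":
        """Keep only the named feature blocks (order as given)."""
        sub = self.column_map.subset(features)
        cols = np.concatenate(
            [np.arange(self.column_map.n_columns)[self.column_map.block(f)] for f in features]
        )
        return FlatDesignMatrix(self.matrix[:, cols], sub, self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.column_map.column_names())
        if self.gene_ids is not None:
            df.insert(0, "gene_id", self.gene_ids)
        return df


def flatten(
    tensor: np.ndarray,
    feature_names: Sequence[str] = CANONICAL_FEATURES,
    gene_ids: np.ndarray | None = None,
) -> FlatDesignMatrix:
    """Flatten ``genes × bins × features`` to ``genes × (bins · features)``.

    Row g holds the feature blocks in the given order with bins in gene
    orientation inside each block; ``unflatten(flatten(x)) == x``.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.ndim != 3:
        raise ValueError("expected a genes × bins × features tensor")
    n_genes, n_bins, n_features = tensor.shape
    if n_features != len(feature_names):
        raise ValueError("feature_names length does not match tensor")
    # (genes, bins, features) -> (genes, features, bins) -> contiguous blocks
    matrix = tensor.transpose(0, 2, 1).reshape(n_genes, n_features * n_bins)
    cmap = ColumnMap(feature_names=tuple(feature_names), n_bins=n_bins)
    return FlatDesignMatrix(matrix, cmap, gene_ids)


def unflatten(flat: FlatDesignMatrix) -> np.ndarray:
    """Inverse of :func:`flatten`."""
    n_features = len(flat.column_map.feature_names)
    n_bins = flat.column_map.n_bins
    return flat.matrix.reshape(flat.n_genes, n_features, n_bins).transpose(0, 2, 1)


# ---------------------------------------------------------------------------
# the per-patient container


@dataclass
class PatientDataset:
    """One patient's genes × bins × features raw-count tensor and labels."""

    patient_id: str
    gene_ids: np.ndarray
    tensor: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] = CANONICAL_FEATURES
    chroms: np.ndarray | None = None
    bin_spec: BinSpec = field(default_factory=BinSpec)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids)
        self.tensor = np.asarray(self.tensor)
        self.labels = np.asarray(self.labels, dtype=float)
        self.feature_names = tuple(self.feature_names)
        n_genes = len(self.gene_ids)
        expected = (n_genes, self.bin_spec.n_bins, len(self.feature_names))
        if self.tensor.shape != expected:
            raise ValueError(f"tensor shape {self.tensor.shape}, expected {expected}")
        if self.labels.shape != (n_genes,):
            raise ValueError("labels misaligned with gene_ids")
        if np.any(self.labels < 0):
            raise ValueError("labels must be non-negative")
        if np.any(np.asarray(self.tensor) < 0):
            raise ValueError("tensor entries must be non-negative")
        if self.chroms is not None:
            self.chroms = np.asarray(self.chroms)
            if self.chroms.shape != (n_genes,):
                raise ValueError("chroms misaligned with gene_ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def subset(self, idx: np.ndarray) -> "PatientDataset":
        idx = np.asarray(idx)
        return PatientDataset(
            patient_id=self.patient_id,
            gene_ids=self.gene_ids[idx],
            tensor=self.tensor[idx],
            labels=self.labels[idx],
            feature_names=self.feature_names,
            chroms=None if self.chroms is None else self.chroms[idx],
            bin_spec=self.bin_spec,
            meta=dict(self.meta),
        )

    def standardized(self):
        """(standardized tensor, records) using this set's own pooled statistics."""
        return standardize(self.tensor, self.feature_names)

    def design_matrix(self, standardized: bool = True) -> FlatDesignMatrix:
        tensor = self.standardized()[0] if standardized else self.tensor.astype(float)
        return flatten(tensor, self.feature_names, self.gene_ids)


# ---------------------------------------------------------------------------
# splits and subset partitions


def split_train_val(
    dataset: PatientDataset,
    train_fraction: float = 0.7,
    scheme: str = "random_genes",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint (train, validation) gene-index arrays covering all genes.

    ``random_genes`` shuffles genes under the seed.  ``cross_chromosomal``
    assigns whole chromosomes to the training side, largest remaining first
    (ties shuffled under the seed), until the train gene count first reaches
    ``train_fraction · n``; no chromosome spans both sets.
    """
    if not 0 < train_fraction <= 1:
        raise ValueError(f"train_fraction must lie in (0, 1], got {train_fraction}")
    n = dataset.n_genes
    target = train_fraction * n
    if scheme == "random_genes":
        order = np.random.default_rng(seed).permutation(n)
        n_train = int(np.ceil(target))
        return np.sort(order[:n_train]), np.sort(order[n_train:])
    if scheme == "cross_chromosomal":
        if dataset.chroms is None:
            raise ValueError("cross_chromosomal split requires chromosome metadata")
        rng = np.random.default_rng(seed)
        chroms, counts = np.unique(dataset.chroms, return_counts=True)
        order = rng.permutation(len(chroms))  # seed-shuffled tie-break
        chroms, counts = chroms[order], counts[order]
        by_size = np.argsort(-counts, kind="stable")  # largest remaining first
        train_chroms, got = [], 0
        for i in by_size:
            if got >= target:
                break
            train_chroms.append(chroms[i])
            got += counts[i]
        mask = np.isin(dataset.chroms, train_chroms)
        return np.flatnonzero(mask), np.flatnonzero(~mask)
    raise ValueError(f"unknown split scheme {scheme!r}")


@dataclass(frozen=True)
class SubsetPartition:
    """k contiguous, non-overlapping gene-index ranges covering all genes;
    parts 1..k−1 have size ⌈n/k⌉ and part k takes the remainder."""

    n_genes: int
    k: int
    part_sizes: tuple[int, ...]
    part_index_ranges: tuple[tuple[int, int], ...]

    def indices(self, part: int) -> np.ndarray:
        start, end = self.part_index_ranges[part]
        return np.arange(start, end)


def partition_subsets(n_genes: int, k: int = 10) -> SubsetPartition:
    """Split ``n_genes`` (in stored order) into k contiguous disjoint parts."""
    if not 1 <= k <= n_genes:
        raise ValueError(f"k must lie in [1, {n_genes}], got {k}")
    head = int(np.ceil(n_genes / k))
    sizes = [head] * (k - 1) + [n_genes - (k - 1) * head]
    if sizes[-1] <= 0:
        # degenerate when ⌈n/k⌉·(k−1) ≥ n; shrink trailing parts to keep cover
        sizes = [head] * (n_genes // head) + ([n_genes % head] if n_genes % head else [])
        sizes += [0] * (k - len(sizes))
        sizes = [s for s in sizes if s > 0]
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    ranges = tuple((int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]))
    return SubsetPartition(
        n_genes=n_genes, k=len(sizes), part_sizes=tuple(int(s) for s in sizes),
        part_index_ranges=ranges,
    )


# ---------------------------------------------------------------------------
# container I/O


def save_dataset(dataset: PatientDataset, path: str) -> None:
    """Write a PatientDataset to HDF5 (groups /tensor, /labels, /gene_ids,
    /feature_names, /meta)."""
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("tensor", data=dataset.tensor)
        h5.create_dataset("labels", data=dataset.labels)
        str_dt = h5py.string_dtype(encoding="utf-8")

        def _strings(values) -> np.ndarray:
            return np.asarray([str(v) for v in values], dtype=object)

        h5.create_dataset("gene_ids", data=_strings(dataset.gene_ids), dtype=str_dt)
        h5.create_dataset("feature_names", data=_strings(dataset.feature_names), dtype=str_dt)
        if dataset.chroms is not None:
            h5.create_dataset("chroms", data=_strings(dataset.chroms), dtype=str_dt)
        meta = h5.create_group("meta")
        meta.attrs["patient_id"] = dataset.patient_id
        meta.attrs["half_width"] = dataset.bin_spec.half_width
        meta.attrs["bin_width"] = dataset.bin_spec.bin_width
        meta.attrs["extra"] = json.dumps(dataset.meta, default=str)


def load_dataset(path: str) -> PatientDataset:
    """Read a PatientDataset written by :func:`save_dataset`."""
    import h5py

    with h5py.File(path, "r") as h5:
        spec = BinSpec(
            half_width=int(h5["meta"].attrs["half_width"]),
            bin_width=int(h5["meta"].attrs["bin_width"]),
        )
        return PatientDataset(
            patient_id=str(h5["meta"].attrs["patient_id"]),
            gene_ids=h5["gene_ids"].asstr()[:],
            tensor=h5["tensor"][:],
            labels=h5["labels"][:],
            feature_names=tuple(h5["feature_names"].asstr()[:]),
            chroms=h5["chroms"].asstr()[:] if "chroms" in h5 else None,
            bin_spec=spec,
            meta=json.loads(h5["meta"].attrs["extra"]),
        )


def export_tsv(dataset: PatientDataset, path: str) -> None:
    """Flat TSV export: gene_id, label, then the standardized columns
    FEATURE_binNN in canonical block order."""
    flat = dataset.design_matrix(standardized=True)
    df = flat.to_frame()
    df.insert(1, "label", dataset.labels)
    df.to_csv(path, sep="\t", index=False)
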
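"""Expression-stratified bin-wise signal landscapes.

For a chosen feature (typically H3K27Ac) the landscape is the per-bin mean of
standardized counts pooled over a gene stratum defined on the true labels.
Default strata follow the expression categories used throughout the
evaluation: high = [10, ∞) and low = (0, 5] on log2(TPM+1); exact zeros and
(5, 10) fall in "other".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import PatientDataset, standardize


@dataclass(frozen=True)
class StratumSpec:
    """Half-open/closed interval on labels; infinite bounds allowed."""

    name: str
    lower: float = float("-inf")
    upper: float = float("inf")
    lower_inclusive: bool = True
    upper_inclusive: bool = True

    def __post_init__(self) -> None:
        if np.isfinite(self.lower) and np.isfinite(self.upper) and not self.lower < self.upper:
            raise ValueError(f"stratum {self.name!r}: lower must be < upper")

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = x >= self.lower if self.lower_inclusive else x > self.lower
        hi = x <= self.upper if self.upper_inclusive else x < self.upper
        return lo & hi


#: The evaluation's expression categories.
DEFAULT_STRATA = (
    StratumSpec("high", lower=10.0, lower_inclusive=True),
    StratumSpec("low", lower=0.0, lower_inclusive=False, upper=5.0, upper_inclusive=True),
)


def stratify(labels, specs: Sequence[StratumSpec] = DEFAULT_STRATA) -> np.ndarray:
    """Assign each gene to at most one stratum; unmatched genes get "other".

    Overlapping specs raise, so the assignment is unambiguous.
    """
    labels = np.asarray(labels, dtype=float)
    assigned = np.full(labels.shape, "other", dtype=object)
    claimed = np.zeros(labels.shape, dtype=bool)
    for spec in specs:
        m = spec.contains(labels)
        if np.any(m & claimed):
            raise ValueError(f"stratum {spec.name!r} overlaps an earlier stratum")
        assigned[m] = spec.name
        claimed |= m
    return assigned.astype(str)


@dataclass
class LandscapeProfile:
    """Per-bin mean of standardized counts over one gene subset."""

    feature: str
    stratum: str
    means: np.ndarray
    n_genes: int


def mean_bin_profile(
    dataset: PatientDataset,
    feature: str,
    gene_subset: np.ndarray | None = None,
    stratum_name: str = "all",
    standardized: bool = True,
) -> LandscapeProfile:
    """Arithmetic per-bin mean of a feature's (standardized) counts over a
    gene subset.  Standardization statistics are pooled over the *whole*
    dataset so stratum profiles share one scale and recombine exactly."""
    if feature not in dataset.feature_names:
        raise ValueError(f"unknown feature {feature!r}; have {dataset.feature_names}")
    j = list(dataset.feature_names).index(feature)
    tensor = standardize(dataset.tensor, dataset.feature_names)[0] if standardized else (
        dataset.tensor.astype(float)
    )
    if gene_subset is None:
        gene_subset = np.arange(dataset.n_genes)
    gene_subset = np.asarray(gene_subset)
    if gene_subset.dtype == bool:
        gene_subset = np.flatnonzero(gene_subset)
    if gene_subset.size == 0:
        raise ValueError(f"empty gene subset for stratum {stratum_name!r}")
    return LandscapeProfile(
        feature=feature,
        stratum=stratum_name,
        means=tensor[gene_subset, :, j].mean(axis=0),
        n_genes=int(gene_subset.size),
    )


def stratified_profiles(
    dataset: PatientDataset,
    feature: str,
    specs: Sequence[StratumSpec] = DEFAULT_STRATA,
    standardized: bool = True,
    include_all: bool = True,
) -> list[LandscapeProfile]:
    """Landscape profiles for each stratum (skipping empty ones) plus,
    optionally, the all-gene profile."""
    assignment = stratify(dataset.labels, specs)
    out = []
    if include_all:
        out.append(mean_bin_profile(dataset, feature, None, "all", standardized))
    names = [s.name for s in specs] + ["other"]
    for name in names:
        idx = np.flatnonzero(assignment == name)
        if idx.size:
            out.append(mean_bin_profile(dataset, feature, idx, name, standardized))
    return out


def profiles_to_frame(
    profiles: Sequence[LandscapeProfile], dataset_id: str = ""
) -> pd.DataFrame:
    """Long-format table (dataset, feature, stratum, bin, mean, n_genes) for
    TSV export / plotting."""
    rows = []
    for p in profiles:
        for b, m in enumerate(p.means):
            rows.append(
                {
                    "dataset": dataset_id,
                    "feature": p.feature,
                    "stratum": p.stratum,
                    "bin": b,
                    "mean": float(m),
                    "n_genes": p.n_genes,
                }
            )
    return pd.DataFrame(rows)
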
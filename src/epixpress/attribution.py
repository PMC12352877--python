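"""Per-feature contribution: importance aggregation and zero-fill perturbation.

Two complementary views of what drives the prediction:

* **Importance aggregation** — a tree ensemble's per-column split-gain
  importances (normalized to sum to 1) are rolled up over each feature's
  contiguous 50-column block, giving one share per epigenetic feature.
* **Zero-fill perturbation** — one feature's standardized columns are
  replaced by 0.0 (the feature mean under pooled z-scoring) across all test
  genes, and the drop in cross-patient PCC is measured.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import ColumnMap, FlatDesignMatrix, PatientDataset
from .evaluation import _resolve_seeds, metrics, standardized_test_matrix
from .models import TREE_FAMILIES, ExpressionRegressor


@dataclass
class ImportanceProfile:
    """Normalized per-column importances with their (feature, bin) roll-up.

    ``feature_sums`` are exact block sums of ``per_column``; after
    normalization the columns sum to 1, so the feature sums partition the
    total importance mass.
    """

    per_column: np.ndarray
    column_map: ColumnMap
    normalization: str = "split gain, normalized to sum to 1"

    @property
    def table(self) -> pd.DataFrame:
        feats, bins = zip(*(self.column_map.feature_of(c) for c in range(len(self.per_column))))
        return pd.DataFrame(
            {"feature": feats, "bin": bins, "importance": self.per_column}
        )

    @property
    def feature_sums(self) -> dict[str, float]:
        return {
            f: float(self.per_column[self.column_map.block(f)].sum())
            for f in self.column_map.feature_names
        }


def aggregate_importance(
    model: ExpressionRegressor, column_map: ColumnMap
) -> ImportanceProfile:
    """Roll a tree ensemble's split-gain importances up to per-feature sums."""
    if model.family not in TREE_FAMILIES:
        raise ValueError(
            f"importance aggregation needs a tree-ensemble family, got {model.family!r}"
        )
    imp = np.asarray(model.feature_importances_, dtype=float)
    if imp.shape[0] != column_map.n_columns:
        raise ValueError(
            f"model has {imp.shape[0]} columns, column map has {column_map.n_columns}"
        )
    if np.any(imp < 0):
        raise ValueError("negative importance value")
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return ImportanceProfile(per_column=imp, column_map=column_map)


def perturb_feature(X: FlatDesignMatrix, feature: str) -> FlatDesignMatrix:
    """Return a copy of a standardized design matrix with one feature's
    columns set to exactly 0.0; all other entries are unchanged bitwise, and
    the operation is idempotent."""
    if feature not in X.column_map.feature_names:
        raise ValueError(
            f"unknown feature {feature!r}; have {X.column_map.feature_names}"
        )
    matrix = X.matrix.copy()
    matrix[:, X.column_map.block(feature)] = 0.0
    return FlatDesignMatrix(matrix, X.column_map, X.gene_ids)


@dataclass
class PerturbationResult:
    """Baseline vs zero-filled PCC for one perturbed feature (delta =
    baseline − perturbed, recomputable from the stored per-seed values)."""

    feature: str
    seeds: tuple[int, ...]
    baseline_pcc: tuple[float, ...]
    perturbed_pcc: tuple[float, ...]

    @property
    def baseline_mean(self) -> float:
        return float(np.mean(self.baseline_pcc))

    @property
    def perturbed_mean(self) -> float:
        return float(np.mean(self.perturbed_pcc))

    @property
    def delta(self) -> float:
        return self.baseline_mean - self.perturbed_mean

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "seeds": list(self.seeds),
            "baseline_pcc": list(self.baseline_pcc),
            "perturbed_pcc": list(self.perturbed_pcc),
            "baseline_mean": self.baseline_mean,
            "perturbed_mean": self.perturbed_mean,
            "delta": self.delta,
        }


def perturbation_experiment(
    train: PatientDataset,
    test: PatientDataset,
    family: str = "gradient_boosted_trees",
    hyperparams: dict | None = None,
    n_seeds: int = 10,
    seeds: Sequence[int] | None = None,
    features: Sequence[str] | None = None,
) -> list[PerturbationResult]:
    """Zero-fill each feature of the test matrix in turn and measure the PCC
    drop against the unperturbed baseline, across seeds.

    One model is fitted per seed on the full training matrix and evaluated on
    the baseline plus every perturbed variant of the test matrix.
    """
    from .dataset import flatten, standardize

    seeds = _resolve_seeds(n_seeds, seeds)
    features = list(features if features is not None else train.feature_names)
    order = list(train.feature_names)

    z_train, _ = standardize(train.tensor, order)
    X_train = flatten(z_train, order, train.gene_ids)
    X_test = standardized_test_matrix(test, order)
    perturbed = {f: perturb_feature(X_test, f) for f in features}

    baseline: list[float] = []
    per_feature: dict[str, list[float]] = {f: [] for f in features}
    for seed in seeds:
        model = ExpressionRegressor(family, hyperparams, random_state=seed)
        model.fit(X_train, train.labels)
        baseline.append(metrics(test.labels, model.predict(X_test)).pcc)
        for f in features:
            per_feature[f].append(metrics(test.labels, model.predict(perturbed[f])).pcc)
    return [
        PerturbationResult(
            feature=f,
            seeds=seeds,
            baseline_pcc=tuple(baseline),
            perturbed_pcc=tuple(per_feature[f]),
        )
        for f in features
    ]
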
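"""Metrics and the cross-patient experiment harness.

The primary evaluation metric is the Pearson correlation (PCC) between true
and predicted log2(TPM+1) labels, with Spearman correlation (SCC) and mean
squared error MSE = (1/n) Σ (y_i − ŷ_i)² alongside.  Experiments follow the
cross-patient protocol: fit on 100 % of the training patient's genes,
standardize every dataset with its own pooled statistics (after splitting,
never across sets), and evaluate on other patients without refitting,
repeated over a list of seeds (0..n_seeds−1 by default).

A test patient missing some features (e.g. an H3K27Ac-only cohort evaluated
under a four-feature model) has the absent feature blocks filled with 0.0 in
the standardized matrix — exactly the feature mean under pooled z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import (
    FlatDesignMatrix,
    PatientDataset,
    SubsetPartition,
    flatten,
    standardize,
)
from .models import ExpressionRegressor

#: Expression strata on true labels: high ≥ 10; low in (0, 5]; the rest
#: (exact zeros and (5, 10)) fall in "other".
HIGH_THRESHOLD = 10.0
LOW_UPPER = 5.0


@dataclass
class EvalResult:
    """Metrics of one (y, ŷ) comparison.  Correlations on a constant vector
    are undefined and flagged rather than coerced to 0."""

    pcc: float
    scc: float
    mse: float
    n: int
    predictions: np.ndarray | None = None
    pcc_defined: bool = True
    scc_defined: bool = True


def metrics(y, yhat, keep_predictions: bool = False) -> EvalResult:
    """Pearson, Spearman (average ranks for ties) and MSE for equal-length vectors."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: y has {y.size}, yhat has {yhat.size}")
    if y.size == 0:
        raise ValueError("empty vectors")
    mse = float(np.mean((y - yhat) ** 2))
    const = np.ptp(y) == 0 or np.ptp(yhat) == 0
    if const or y.size < 2:
        return EvalResult(
            pcc=float("nan"), scc=float("nan"), mse=mse, n=y.size,
            predictions=yhat if keep_predictions else None,
            pcc_defined=False, scc_defined=False,
        )
    pcc = float(stats.pearsonr(y, yhat)[0])
    scc = float(stats.spearmanr(y, yhat)[0])
    return EvalResult(
        pcc=pcc, scc=scc, mse=mse, n=y.size,
        predictions=yhat if keep_predictions else None,
    )


@dataclass
class MultiSeedSummary:
    """Per-seed results plus their mean/sd (population sd, recomputable
    exactly from the stored per-seed values)."""

    seeds: tuple[int, ...]
    results: tuple[EvalResult, ...]

    def _vals(self, attr: str) -> np.ndarray:
        return np.array([getattr(r, attr) for r in self.results], dtype=float)

    @property
    def mean_pcc(self) -> float:
        return float(np.mean(self._vals("pcc")))

    @property
    def sd_pcc(self) -> float:
        return float(np.std(self._vals("pcc")))

    @property
    def mean_scc(self) -> float:
        return float(np.mean(self._vals("scc")))

    @property
    def sd_scc(self) -> float:
        return float(np.std(self._vals("scc")))

    @property
    def mean_mse(self) -> float:
        return float(np.mean(self._vals("mse")))

    @property
    def sd_mse(self) -> float:
        return float(np.std(self._vals("mse")))

    def to_dict(self) -> dict:
        return {
            "seeds": list(self.seeds),
            "per_seed_pcc": self._vals("pcc").tolist(),
            "per_seed_scc": self._vals("scc").tolist(),
            "per_seed_mse": self._vals("mse").tolist(),
            "mean_pcc": self.mean_pcc, "sd_pcc": self.sd_pcc,
            "mean_scc": self.mean_scc, "sd_scc": self.sd_scc,
            "mean_mse": self.mean_mse, "sd_mse": self.sd_mse,
        }


def _resolve_seeds(n_seeds: int, seeds: Sequence[int] | None) -> tuple[int, ...]:
    return tuple(seeds) if seeds is not None else tuple(range(n_seeds))


def standardized_test_matrix(
    test: PatientDataset,
    feature_order: Sequence[str],
    stats_from: PatientDataset | None = None,
) -> FlatDesignMatrix:
    """Standardized flat matrix of a test patient in the training feature order.

    Features absent from the test dataset are filled with 0.0 (the feature
    mean post-standardization).  By default each dataset uses its own pooled
    statistics; pass ``stats_from`` to reuse another dataset's statistics
    instead (the conventional train-statistics alternative).
    """
    present = list(test.feature_names)
    if stats_from is None:
        z_present, _ = standardize(test.tensor, present)
    else:
        src = stats_from
        idx = [list(src.feature_names).index(f) for f in present]
        from .dataset import PooledFeatureScaler

        scaler = PooledFeatureScaler(feature_names=[src.feature_names[i] for i in idx])
        scaler.fit(src.tensor[:, :, idx])
        z_present = scaler.transform(test.tensor)
    n_bins = test.bin_spec.n_bins
    z = np.zeros((test.n_genes, n_bins, len(feature_order)))
    for j, f in enumerate(feature_order):
        if f in present:
            z[:, :, j] = z_present[:, :, present.index(f)]
    return flatten(z, feature_order, test.gene_ids)


def _check_compatible(train: PatientDataset, test: PatientDataset) -> None:
    if train.bin_spec != test.bin_spec:
        raise ValueError(
            f"bin spec mismatch: {train.patient_id} has {train.bin_spec}, "
            f"{test.patient_id} has {test.bin_spec}"
        )


def run_cross_patient(
    train: PatientDataset,
    tests: Sequence[PatientDataset],
    family: str = "gradient_boosted_trees",
    hyperparams: dict | None = None,
    n_seeds: int = 10,
    seeds: Sequence[int] | None = None,
    feature_subset: Sequence[str] | None = None,
    test_stats: str = "self",
) -> dict[str, MultiSeedSummary]:
    """Train on 100 % of one patient's genes, evaluate on other patients.

    For each seed the training tensor is standardized with its own pooled
    statistics, the model is fitted, each test dataset is standardized (its
    own statistics by default, the training statistics when
    ``test_stats="train"``), absent features are zero-filled, and metrics are
    computed.  ``feature_subset`` restricts both training and test matrices
    to those feature blocks before fitting.
    """
    if feature_subset is not None:
        unknown = [f for f in feature_subset if f not in train.feature_names]
        if unknown:
            raise ValueError(f"unknown features in subset: {unknown}")
    for t in tests:
        _check_compatible(train, t)
    seeds = _resolve_seeds(n_seeds, seeds)
    order = list(train.feature_names)

    z_train, _ = standardize(train.tensor, order)
    X_train = flatten(z_train, order, train.gene_ids)
    test_mats = [
        standardized_test_matrix(t, order, stats_from=train if test_stats == "train" else None)
        for t in tests
    ]
    if feature_subset is not None:
        X_train = X_train.restrict(feature_subset)
        test_mats = [m.restrict(feature_subset) for m in test_mats]

    per_test: dict[str, list[EvalResult]] = {t.patient_id: [] for t in tests}
    for seed in seeds:
        model = ExpressionRegressor(family, hyperparams, random_state=seed)
        model.fit(X_train, train.labels)
        for t, X_t in zip(tests, test_mats):
            per_test[t.patient_id].append(metrics(t.labels, model.predict(X_t)))
    return {
        pid: MultiSeedSummary(seeds=seeds, results=tuple(res))
        for pid, res in per_test.items()
    }


def evaluate_subsets(
    model: ExpressionRegressor,
    test: PatientDataset,
    partition: SubsetPartition,
    seeds: Sequence[int] | None = None,
    feature_subset: Sequence[str] | None = None,
) -> tuple[list[EvalResult], MultiSeedSummary]:
    """Evaluate a trained model on each contiguous part of a test dataset.

    Parts cover every gene exactly once; the summary aggregates over parts
    (one nominal seed per part, mirroring the per-part protocol).
    """
    if partition.n_genes != test.n_genes:
        raise ValueError(
            f"partition built for {partition.n_genes} genes, dataset has {test.n_genes}"
        )
    X = standardized_test_matrix(test, test.feature_names)
    if feature_subset is not None:
        X = X.restrict(feature_subset)
    seeds = _resolve_seeds(partition.k, seeds)
    results = []
    for part in range(partition.k):
        idx = partition.indices(part)
        part_mat = FlatDesignMatrix(X.matrix[idx], X.column_map, X.gene_ids[idx])
        results.append(metrics(test.labels[idx], model.predict(part_mat)))
    return results, MultiSeedSummary(seeds=tuple(seeds[: partition.k]), results=tuple(results))


def correlate_features_with_expression(dataset: PatientDataset) -> dict[str, float]:
    """Pearson correlation between each feature's per-gene summed raw window
    counts and the expression labels (NaN marker when the sum is constant)."""
    sums = dataset.tensor.sum(axis=1)  # genes × features
    out = {}
    for j, f in enumerate(dataset.feature_names):
        s = sums[:, j].astype(float)
        if np.ptp(s) == 0 or np.ptp(dataset.labels) == 0:
            out[f] = float("nan")
        else:
            out[f] = float(stats.pearsonr(s, dataset.labels)[0])
    return out


@dataclass
class TransferStudy:
    """Bundle of the full cross-patient study on one train/test pair.

    Holds the multi-seed baseline transfer, per-feature importance shares
    (mean over seeds), zero-fill perturbation results, the causal-feature-only
    retraining arm (train and test restricted to one feature), the linear
    baseline, and the four-feature model evaluated on a test patient that
    carries only the causal feature (absent blocks zero-filled).
    """

    baseline: MultiSeedSummary
    importance_shares: dict[str, float]
    per_seed_importance: list[dict[str, float]]
    perturbation: list
    single_feature: MultiSeedSummary
    zero_filled_full_model: MultiSeedSummary
    linear_baseline: MultiSeedSummary


def run_transfer_study(
    train: PatientDataset,
    test: PatientDataset,
    family: str = "gradient_boosted_trees",
    hyperparams: dict | None = None,
    n_seeds: int = 10,
    seeds: Sequence[int] | None = None,
    causal_feature: str = "H3K27Ac",
) -> TransferStudy:
    """Run the complete cross-patient protocol on one train/test pair.

    One model per seed is fitted on the full training matrix and reused for
    the baseline metrics, the importance profile and every perturbation arm;
    separate per-seed fits cover the single-feature retraining and the linear
    least-squares baseline.
    """
    from .attribution import PerturbationResult, aggregate_importance, perturb_feature

    _check_compatible(train, test)
    seeds = _resolve_seeds(n_seeds, seeds)
    order = list(train.feature_names)
    features = list(train.feature_names)

    z_train, _ = standardize(train.tensor, order)
    X_train = flatten(z_train, order, train.gene_ids)
    X_test = standardized_test_matrix(test, order)
    perturbed = {f: perturb_feature(X_test, f) for f in features}

    # test patient carrying only the causal feature (others zero-filled)
    causal_idx = order.index(causal_feature)
    test_causal_only = PatientDataset(
        patient_id=test.patient_id + "_single",
        gene_ids=test.gene_ids,
        tensor=test.tensor[:, :, [causal_idx]],
        labels=test.labels,
        feature_names=(causal_feature,),
        chroms=test.chroms,
        bin_spec=test.bin_spec,
    )
    X_test_zero_filled = standardized_test_matrix(test_causal_only, order)
    X_train_single = X_train.restrict([causal_feature])
    X_test_single = standardized_test_matrix(test_causal_only, [causal_feature])

    baseline, zero_filled = [], []
    per_seed_importance: list[dict[str, float]] = []
    pert_pcc: dict[str, list[float]] = {f: [] for f in features}
    single, linear = [], []
    for seed in seeds:
        model = ExpressionRegressor(family, hyperparams, random_state=seed)
        model.fit(X_train, train.labels)
        baseline.append(metrics(test.labels, model.predict(X_test)))
        zero_filled.append(metrics(test.labels, model.predict(X_test_zero_filled)))
        per_seed_importance.append(
            aggregate_importance(model, X_train.column_map).feature_sums
        )
        for f in features:
            pert_pcc[f].append(metrics(test.labels, model.predict(perturbed[f])).pcc)

        single_model = ExpressionRegressor(family, hyperparams, random_state=seed)
        single_model.fit(X_train_single, train.labels)
        single.append(metrics(test.labels, single_model.predict(X_test_single)))

        lin = ExpressionRegressor("linear_least_squares", random_state=seed)
        lin.fit(X_train, train.labels)
        linear.append(metrics(test.labels, lin.predict(X_test)))

    baseline_pcc = tuple(r.pcc for r in baseline)
    perturbation = [
        PerturbationResult(
            feature=f, seeds=seeds, baseline_pcc=baseline_pcc,
            perturbed_pcc=tuple(pert_pcc[f]),
        )
        for f in features
    ]
    shares = {
        f: float(np.mean([imp[f] for imp in per_seed_importance])) for f in features
    }
    return TransferStudy(
        baseline=MultiSeedSummary(seeds=seeds, results=tuple(baseline)),
        importance_shares=shares,
        per_seed_importance=per_seed_importance,
        perturbation=perturbation,
        single_feature=MultiSeedSummary(seeds=seeds, results=tuple(single)),
        zero_filled_full_model=MultiSeedSummary(seeds=seeds, results=tuple(zero_filled)),
        linear_baseline=MultiSeedSummary(seeds=seeds, results=tuple(linear)),
    )


@dataclass
class CategoryErrorReport:
    """Gene counts and MSE per expression stratum of the true labels."""

    counts: dict[str, int]
    mse: dict[str, float]
    overall_mse: float
    n: int


def category_error(y, yhat) -> CategoryErrorReport:
    """Stratified MSE: high (y ≥ 10), low (0 < y ≤ 5), other (y = 0 or 5 < y < 10)."""
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("length mismatch between y and yhat")
    masks = {
        "high": y >= HIGH_THRESHOLD,
        "low": (y > 0) & (y <= LOW_UPPER),
    }
    masks["other"] = ~(masks["high"] | masks["low"])
    sq = (y - yhat) ** 2
    counts = {k: int(m.sum()) for k, m in masks.items()}
    mse = {k: (float(sq[m].mean()) if m.any() else float("nan")) for k, m in masks.items()}
    return CategoryErrorReport(counts=counts, mse=mse, overall_mse=float(sq.mean()), n=y.size)
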
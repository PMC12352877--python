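"""Metrics, cross-patient harness, subset evaluation, category errors."""

import numpy as np
import pytest

from epixpress.annotation import BinSpec
from epixpress.dataset import PatientDataset, partition_subsets, flatten, standardize
from epixpress.evaluation import (
    category_error,
    correlate_features_with_expression,
    evaluate_subsets,
    metrics,
    run_cross_patient,
    standardized_test_matrix,
)
from epixpress.models import ExpressionRegressor


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0, 3.0])
        r = metrics(y, y)
        assert (r.pcc, r.scc, r.mse) == (1.0, 1.0, 0.0)

    def test_closed_form_example(self):
        # PCC by direct product-moment arithmetic; SCC = 1 − 6·Σd²/(n(n²−1))
        # with one swapped pair (Σd² = 2, n = 4) → both exactly 0.8.
        r = metrics([1, 2, 3, 4], [1, 3, 2, 4])
        assert r.pcc == pytest.approx(0.8, abs=1e-12)
        assert r.scc == pytest.approx(0.8, abs=1e-12)

    def test_random_pair_matches_textbook_oracle(self, rng):
        y = rng.normal(size=200)
        yhat = y + rng.normal(size=200)
        r = metrics(y, yhat)
        # brute-force product-moment form
        pcc = ((y - y.mean()) * (yhat - yhat.mean())).sum() / (
            np.sqrt(((y - y.mean()) ** 2).sum()) * np.sqrt(((yhat - yhat.mean()) ** 2).sum())
        )
        ranks = lambda v: np.argsort(np.argsort(v)).astype(float)  # noqa: E731 (no ties)
        ry, rh = ranks(y), ranks(yhat)
        scc = ((ry - ry.mean()) * (rh - rh.mean())).sum() / (
            np.sqrt(((ry - ry.mean()) ** 2).sum()) * np.sqrt(((rh - rh.mean()) ** 2).sum())
        )
        assert r.pcc == pytest.approx(pcc, abs=1e-12)
        assert r.scc == pytest.approx(scc, abs=1e-12)
        assert r.mse == pytest.approx(np.mean((y - yhat) ** 2), abs=1e-12)

    def test_constant_input_flagged_undefined_mse_still_computed(self):
        r = metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert not r.pcc_defined and np.isnan(r.pcc)
        assert r.mse == pytest.approx(2.0 / 3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            metrics([1, 2], [1, 2, 3])


class TestCrossPatient:
    def test_self_test_matches_training_set_metrics(self, small_cohort):
        A, _ = small_cohort
        res = run_cross_patient(A, [A], n_seeds=1,
                                hyperparams={"n_estimators": 50})["P1"]
        z, _ = standardize(A.tensor, A.feature_names)
        X = flatten(z, A.feature_names, A.gene_ids)
        model = ExpressionRegressor(hyperparams={"n_estimators": 50},
                                    random_state=0).fit(X, A.labels)
        direct = metrics(A.labels, model.predict(X))
        assert res.results[0].pcc == pytest.approx(direct.pcc, abs=1e-12)

    def test_absent_features_are_exactly_zero_after_standardization(self, small_cohort):
        A, B = small_cohort
        B_only_h3 = PatientDataset(
            patient_id="B1", gene_ids=B.gene_ids, tensor=B.tensor[:, :, [0]],
            labels=B.labels, feature_names=("H3K27Ac",), bin_spec=B.bin_spec,
        )
        X = standardized_test_matrix(B_only_h3, A.feature_names)
        for f in ("RNAPII", "ATAC", "CTCF"):
            block = X.matrix[:, X.column_map.block(f)]
            assert not block.any()
        assert X.matrix[:, X.column_map.block("H3K27Ac")].std() > 0

    def test_multi_seed_summary_recomputable(self, small_cohort):
        A, B = small_cohort
        res = run_cross_patient(A, [B], n_seeds=2,
                                hyperparams={"n_estimators": 40})["P2"]
        pccs = np.array([r.pcc for r in res.results])
        assert res.mean_pcc == pytest.approx(pccs.mean(), abs=0)
        assert res.sd_pcc == pytest.approx(pccs.std(), abs=0)

    def test_unknown_feature_subset_rejected(self, small_cohort):
        A, B = small_cohort
        with pytest.raises(ValueError, match="unknown features"):
            run_cross_patient(A, [B], feature_subset=["H3K9me3"], n_seeds=1)

    def test_bin_spec_mismatch_rejected(self, small_cohort):
        A, B = small_cohort
        other = PatientDataset(
            patient_id="odd", gene_ids=B.gene_ids[:5],
            tensor=B.tensor[:5, ::2, :], labels=B.labels[:5],
            bin_spec=BinSpec(half_width=2500, bin_width=200),
        )
        with pytest.raises(ValueError, match="bin spec"):
            run_cross_patient(A, [other], n_seeds=1)


@pytest.fixture(scope="module")
def fitted(small_cohort):
    A, B = small_cohort
    z, _ = standardize(A.tensor, A.feature_names)
    X = flatten(z, A.feature_names, A.gene_ids)
    model = ExpressionRegressor(hyperparams={"n_estimators": 60},
                                random_state=0).fit(X, A.labels)
    return model, A, B


class TestEvaluateSubsets:
    def test_k1_matches_whole_dataset_evaluation(self, fitted):
        model, A, B = fitted
        results, summary = evaluate_subsets(model, B, partition_subsets(B.n_genes, 1))
        whole = metrics(B.labels, model.predict(standardized_test_matrix(B, A.feature_names)))
        assert results[0].pcc == pytest.approx(whole.pcc, abs=1e-12)

    def test_parts_cover_each_gene_once(self, fitted):
        model, A, B = fitted
        part = partition_subsets(B.n_genes, 10)
        results, _ = evaluate_subsets(model, B, part)
        assert sum(r.n for r in results) == B.n_genes

    def test_per_part_sd_exceeds_whole_dataset_seed_sd(self, fitted, small_cohort):
        """Subset evaluation shows more spread than seed-to-seed variation on
        the full test set."""
        model, A, B = fitted
        _, per_part = evaluate_subsets(model, B, partition_subsets(B.n_genes, 10))
        whole = run_cross_patient(A, [B], n_seeds=3,
                                  hyperparams={"n_estimators": 60})["P2"]
        assert per_part.sd_pcc > whole.sd_pcc

    def test_partition_size_mismatch_rejected(self, fitted):
        model, A, B = fitted
        with pytest.raises(ValueError, match="partition"):
            evaluate_subsets(model, B, partition_subsets(B.n_genes - 1, 10))


class TestCorrelations:
    def test_feature_equal_to_label_sum_gives_unit_correlation(self):
        rng = np.random.default_rng(0)
        labels = rng.gamma(2.0, 2.0, size=50)
        tensor = np.zeros((50, 10, 2))
        tensor[:, 0, 0] = labels  # feature sum == label
        tensor[:, :, 1] = rng.poisson(3.0, size=(50, 10))
        ds = PatientDataset(
            patient_id="T", gene_ids=np.arange(50).astype(str), tensor=tensor,
            labels=labels, feature_names=("A", "B"),
            bin_spec=BinSpec(half_width=500, bin_width=100),
        )
        corr = correlate_features_with_expression(ds)
        assert corr["A"] == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_feature_has_negligible_correlation(self):
        rng = np.random.default_rng(1)
        n = 5000
        labels = rng.gamma(2.0, 2.0, size=n)
        tensor = rng.poisson(3.0, size=(n, 10, 1)).astype(float)
        ds = PatientDataset(
            patient_id="T", gene_ids=np.arange(n).astype(str), tensor=tensor,
            labels=labels, feature_names=("noise",),
            bin_spec=BinSpec(half_width=500, bin_width=100),
        )
        assert abs(correlate_features_with_expression(ds)["noise"]) < 0.05

    def test_default_cohort_ranks_h3k27ac_first(self, default_cohort):
        A, _ = default_cohort
        corr = correlate_features_with_expression(A)
        assert corr["H3K27Ac"] == max(corr.values())


class TestCategoryError:
    @pytest.mark.parametrize(
        "label, stratum",
        [(10.0, "high"), (5.0, "low"), (7.3, "other"), (0.0, "other"), (12.0, "high")],
    )
    def test_threshold_assignment(self, label, stratum):
        rep = category_error([label], [0.0])
        assert rep.counts[stratum] == 1

    def test_perfect_prediction_zero_everywhere(self):
        y = np.array([0.0, 3.0, 7.0, 11.0])
        rep = category_error(y, y)
        assert all(m == 0 for m in rep.mse.values())

    def test_strata_mse_recombines_to_overall(self, rng):
        y = rng.uniform(0, 14, size=500)
        yhat = y + rng.normal(size=500)
        rep = category_error(y, yhat)
        assert sum(rep.counts.values()) == 500
        weighted = sum(rep.counts[k] * rep.mse[k] for k in rep.counts if rep.counts[k])
        assert weighted / 500 == pytest.approx(rep.overall_mse, rel=1e-12)
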
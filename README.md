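# epixpress

Cross-patient prediction of gene expression from binned epigenetic signal
around transcription start sites.

## The problem

Glioblastoma stem cells (GSCs) are transcriptomically heterogeneous across
patients, yet their active-enhancer landscape — marked by H3K27Ac — appears
broadly shared. If that landscape really acts as a blueprint for
transcription, a regression model trained on **one** patient's epigenome
should predict gene expression in **other** patients without retraining.
`epixpress` implements that analysis end to end for anyone working with
matched ChIP-seq / ATAC-seq / RNA-seq patient cohorts:

1. **Binning** — for every gene, counts of four signals (H3K27Ac, RNAPII,
   ATAC, CTCF) are summarized over the ±2.5 kb window flanking the TSS in 50
   bins of 100 bp, giving a `genes × 50 × 4` tensor per patient. Expression
   labels are `log2(TPM + 1)` of RNA counts in the same window.
2. **Standardization** — each feature is z-scored with statistics pooled over
   all genes × bins of that feature, separately per gene set (after
   splitting, to avoid leakage). The feature mean is therefore exactly 0.0
   post-standardization.
3. **Regression** — the tensor is flattened to `genes × 200` with each
   feature's bins in one contiguous column block, and a regressor
   (gradient-boosted trees by default; classic gradient boosting, linear
   least squares, SVR and an MLP are also available) is fitted to minimize
   `MSE = (1/n) Σ (yᵢ − ŷᵢ)²`. Performance is reported as Pearson (PCC) and
   Spearman (SCC) correlation between true and predicted labels, over 10
   random seeds.
4. **Attribution** — per-column split-gain importances are summed over each
   feature's block (the four sums partition a total of 1.0), and each
   feature is ablated in turn by replacing its standardized columns with 0.0
   (its mean) at test time, measuring the PCC drop. A test patient that only
   has H3K27Ac data is handled the same way: the absent blocks are zero.
5. **Landscapes** — bin-wise mean standardized H3K27Ac profiles are pooled
   over expression strata (high: label ≥ 10; low: 0 < label ≤ 5) to
   visualize the two enhancer peaks flanking the TSS and the dip at the TSS
   bin.

Because real patient sequencing data cannot ship with the package, a fully
parameterized generative model (`epixpress.simulate`) produces synthetic
multi-patient cohorts with the structure the analysis assumes: a shared
per-gene latent expression level, a two-peak H3K27Ac template whose
amplitude saturates with expression, weaker and partly redundant
RNAPII/ATAC coupling, mostly expression-independent CTCF, patient-level
scale variation, and negative-binomial counts. Every pipeline stage is
tested against it.

## Worked example

```python
from epixpress import SyntheticConfig, generate_cohort, run_cross_patient
from epixpress.attribution import aggregate_importance
from epixpress.dataset import standardize, flatten
from epixpress.models import ExpressionRegressor

cohort = generate_cohort(SyntheticConfig(n_genes=2000, n_patients=2, seed=5))
train, test = cohort
summary = run_cross_patient(train, [test], n_seeds=3)["P2"]
print(f"P1 -> P2: PCC {summary.mean_pcc:.3f} +/- {summary.sd_pcc:.4f}, "
      f"SCC {summary.mean_scc:.3f}, MSE {summary.mean_mse:.3f}")

z, _ = standardize(train.tensor, train.feature_names)
X = flatten(z, train.feature_names, train.gene_ids)
model = ExpressionRegressor(random_state=0).fit(X, train.labels)
shares = aggregate_importance(model, X.column_map).feature_sums
print({f: round(s, 3) for f, s in shares.items()})
```

prints

```
P1 -> P2: PCC 0.910 +/- 0.0000, SCC 0.894, MSE 2.137
{'H3K27Ac': 0.834, 'RNAPII': 0.086, 'ATAC': 0.043, 'CTCF': 0.037}
```

The model trained on patient 1 transfers to patient 2 with PCC ≈ 0.91 (the
seed-to-seed spread is zero because the default boosted-tree settings are
deterministic), and H3K27Ac carries over 80 % of the total split-gain
importance — the enhancer mark dominates the prediction, as expected from
the generative model's coupling strengths.

The same pipeline runs from the shell on real track files (BAM, bigWig,
bedGraph + BED/GTF annotations):

```bash
epixpress simulate --n-genes 2000 --n-patients 2 --seed 5 --out-dir cohort/
epixpress evaluate --train-dataset cohort/P1.h5 --test-dataset cohort/P2.h5 \
    --n-seeds 10 --out-dir results/
epixpress attribute --train-dataset cohort/P1.h5 --test-dataset cohort/P2.h5 \
    --out-dir attribution/
epixpress landscape --dataset cohort/P1.h5 --dataset cohort/P2.h5 --out-dir landscape/
```

## Layout

| module | contents |
| --- | --- |
| `epixpress.annotation` | BED/GTF parsing, TSS conventions, window/bin geometry |
| `epixpress.signal` | signal-track backends (BAM, bigWig, bedGraph, in-memory) and binning |
| `epixpress.dataset` | labels, pooled standardization, flattening/column map, splits, HDF5 container |
| `epixpress.models` | `ExpressionRegressor` families, grid search, (de)serialization |
| `epixpress.evaluation` | metrics, cross-patient harness, subset evaluation, category errors |
| `epixpress.attribution` | importance aggregation, zero-fill perturbation |
| `epixpress.landscape` | expression-stratified bin profiles |
| `epixpress.simulate` | the generative cohort model |
| `epixpress.cli` | `epixpress` command-line entry point |

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
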
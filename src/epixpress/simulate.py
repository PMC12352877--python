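"""Synthetic multi-patient cohort generator.

The generator produces cohorts with the statistical structure the
cross-patient analysis assumes, so every pipeline stage is testable without
external sequencing data:

* A shared per-gene latent expression level ``e_g`` (zero for a silent
  fraction of genes, lognormal otherwise) common to all patients — the
  "shared landscape" that makes cross-patient transfer learnable.
* An H3K27Ac bin template with two peaks flanking the TSS (bins 20 and 30 at
  defaults) and a dip at the central bin, whose amplitude scales with a
  saturating function ``s(e) = e^0.7`` of expression.
* RNAPII and ATAC share a single narrow TSS-centred peak template — genuine
  but largely redundant signal; CTCF is mostly expression-independent,
  driven by a per-gene site strength.
* Patient-level lognormal scale factors around the shared gene-level
  landscape, and negative-binomial (overdispersed) counts for both the
  epigenetic bins and the RNA window, from which log2(TPM+1) labels are
  computed.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .annotation import CANONICAL_FEATURES, BinSpec
from .dataset import PatientDataset, expression_labels


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the generative cohort model.

    Coupling strengths α order the features' association with expression
    (H3K27Ac strongest, CTCF weakest); background rates β and dispersions
    set each feature's noise floor so the induced signal/label correlations
    echo the ordering seen in patient data.
    """

    n_genes: int = 5000
    n_patients: int = 2
    seed: int = 0
    bin_spec: BinSpec = field(default_factory=BinSpec)
    #: fraction of silent genes (e_g = 0)
    silent_fraction: float = 0.15
    #: lognormal parameters of nonzero latent expression
    expression_log_mean: float = 1.5
    expression_log_sd: float = 1.8
    #: two-peak H3K27Ac template
    peak_centers: tuple[int, int] = (20, 30)
    peak_width: float = 3.0
    template_floor: float = 0.05
    #: single TSS-proximal peak shared by RNAPII/ATAC, and the CTCF site shape
    tss_peak_width: float = 2.0
    ctcf_peak_width: float = 5.0
    #: per-feature coupling strengths α (signal per unit s(e))
    coupling: Mapping[str, float] = field(
        default_factory=lambda: {"H3K27Ac": 3.0, "RNAPII": 1.2, "ATAC": 0.8, "CTCF": 0.2}
    )
    #: saturating link s(e) = e ** saturation
    saturation: float = 0.7
    #: per-feature lognormal sd of gene-level regulatory noise multiplying the
    #: expression-coupled signal (shared across patients; models gene-specific
    #: context the expression level does not explain — larger sd, weaker
    #: signal/label correlation)
    gene_noise_log_sd: Mapping[str, float] = field(
        default_factory=lambda: {"H3K27Ac": 0.9, "RNAPII": 1.1, "ATAC": 1.8, "CTCF": 2.5}
    )
    #: per-feature background rates β (counts per bin independent of expression)
    background: Mapping[str, float] = field(
        default_factory=lambda: {"H3K27Ac": 0.5, "RNAPII": 1.5, "ATAC": 4.0, "CTCF": 3.0}
    )
    #: per-feature negative-binomial dispersion (gamma shape; larger = less noise)
    count_dispersion: Mapping[str, float] = field(
        default_factory=lambda: {"H3K27Ac": 8.0, "RNAPII": 4.0, "ATAC": 2.0, "CTCF": 2.0}
    )
    #: patient scale variation: per-patient, per-feature lognormal(0, σ_p)
    patient_log_sd: float = 0.2
    #: expression-independent CTCF site strength: lognormal(0, σ_c), coupling κ
    ctcf_site_log_sd: float = 1.0
    ctcf_site_coupling: float = 1.5
    #: RNA window counts: NB with mean depth · rna_depth_per_unit · e_g
    rna_depth_per_unit: float = 50.0
    rna_dispersion: float = 10.0

    def validate(self) -> None:
        problems = []
        if not 0 <= self.silent_fraction < 1:
            problems.append("silent_fraction must lie in [0, 1)")
        if self.n_genes <= 0 or self.n_patients <= 0:
            problems.append("n_genes and n_patients must be positive")
        for name in ("peak_width", "tss_peak_width", "ctcf_peak_width",
                     "expression_log_sd", "rna_depth_per_unit", "rna_dispersion"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be > 0")
        n_bins = self.bin_spec.n_bins
        if not all(0 <= c < n_bins for c in self.peak_centers):
            problems.append(f"peak_centers must lie in [0, {n_bins})")
        for f in CANONICAL_FEATURES:
            if self.count_dispersion[f] <= 0:
                problems.append(f"count_dispersion[{f}] must be > 0")
            if self.gene_noise_log_sd[f] < 0:
                problems.append(f"gene_noise_log_sd[{f}] must be >= 0")
            if self.background[f] < 0:
                problems.append(f"background[{f}] must be >= 0")
            if self.coupling[f] < 0:
                problems.append(f"coupling[{f}] must be >= 0")
        if problems:
            raise ValueError("invalid SyntheticConfig: " + "; ".join(problems))


@dataclass(frozen=True)
class GeneLatents:
    """Per-gene quantities shared across all patients of a cohort."""

    expression: np.ndarray  # e_g ≥ 0, zero for silent genes
    ctcf_site: np.ndarray   # expression-independent site strength
    chroms: np.ndarray      # synthetic chromosome labels (contiguous blocks)


def template_profile(
    spec: BinSpec,
    centers: Sequence[float],
    width: float,
    floor: float,
) -> np.ndarray:
    """Sum of Gaussian bumps plus a floor, rescaled to maximum 1.

    Symmetric centers about the middle bin give equal peak heights and a
    strict local minimum midway between them.
    """
    if width <= 0:
        raise ValueError("peak width must be > 0")
    n_bins = spec.n_bins
    if not all(0 <= c < n_bins for c in centers):
        raise ValueError(f"centers must lie in [0, {n_bins})")
    b = np.arange(n_bins, dtype=float)
    w = np.full(n_bins, float(floor))
    for c in centers:
        w += np.exp(-((b - c) ** 2) / (2.0 * width**2))
    return w / w.max()


def sample_gene_latents(config: SyntheticConfig, rng: np.random.Generator) -> GeneLatents:
    """Draw the shared per-gene latents: e_g = 0 with probability
    ``silent_fraction``, else exp(Normal(μ_e, σ_e)); a lognormal CTCF site
    strength; and contiguous synthetic chromosome labels."""
    n = config.n_genes
    silent = rng.random(n) < config.silent_fraction
    e = np.exp(rng.normal(config.expression_log_mean, config.expression_log_sd, n))
    e[silent] = 0.0
    ctcf = np.exp(rng.normal(0.0, config.ctcf_site_log_sd, n))
    n_chroms = min(20, n)
    chroms = np.array([f"chr{1 + (g * n_chroms) // n}" for g in range(n)])
    return GeneLatents(expression=e, ctcf_site=ctcf, chroms=chroms)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts via the gamma–Poisson mixture (mean ``mean``,
    gamma shape ``dispersion``); a zero mean yields a zero count."""
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 0.0) / dispersion)
    return rng.poisson(lam)


def feature_templates(config: SyntheticConfig) -> dict[str, np.ndarray]:
    """Bin-shape template per feature: two flanking peaks for H3K27Ac, a
    single narrow TSS peak for RNAPII/ATAC, a broader peak for CTCF."""
    spec = config.bin_spec
    mid = (spec.n_bins - 1) / 2.0 + 0.5  # centre bin index (25 at defaults)
    two_peak = template_profile(spec, config.peak_centers, config.peak_width,
                                config.template_floor)
    tss_peak = template_profile(spec, [mid], config.tss_peak_width, config.template_floor)
    ctcf_peak = template_profile(spec, [mid], config.ctcf_peak_width, config.template_floor)
    return {"H3K27Ac": two_peak, "RNAPII": tss_peak, "ATAC": tss_peak, "CTCF": ctcf_peak}


def generate_cohort(config: SyntheticConfig | None = None) -> list[PatientDataset]:
    """Generate ``n_patients`` datasets around one shared gene-level landscape.

    Per patient p and feature f the bin intensity is
    ``λ[g, b] = γ[p, f] · (α_f · s(e_g) · w_f[b] + β_f)`` (CTCF adds the
    expression-independent site term ``κ · c_g · w_CTCF[b]``), with counts
    drawn negative-binomially around λ.  RNA window counts are
    negative-binomial with mean proportional to patient depth × e_g, and
    labels are log2(TPM+1) of those counts.  Fully deterministic under
    ``config.seed``.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    latents = sample_gene_latents(config, rng)
    templates = feature_templates(config)
    s = latents.expression**config.saturation
    n_bins = config.bin_spec.n_bins
    # gene-level regulatory noise on the expression-coupled signal, shared
    # across patients (part of the common landscape)
    coupled = {
        f: s * np.exp(rng.normal(0.0, config.gene_noise_log_sd[f], config.n_genes))
        for f in CANONICAL_FEATURES
    }

    patients = []
    for p in range(config.n_patients):
        gammas = {
            f: float(np.exp(rng.normal(0.0, config.patient_log_sd)))
            for f in CANONICAL_FEATURES
        }
        depth = float(np.exp(rng.normal(0.0, config.patient_log_sd)))
        tensor = np.zeros((config.n_genes, n_bins, len(CANONICAL_FEATURES)), dtype=np.int64)
        for j, f in enumerate(CANONICAL_FEATURES):
            w = templates[f]
            lam = config.coupling[f] * coupled[f][:, None] * w[None, :]
            if f == "CTCF":
                lam = lam + config.ctcf_site_coupling * latents.ctcf_site[:, None] * w[None, :]
            lam = gammas[f] * (lam + config.background[f])
            tensor[:, :, j] = _nb_counts(rng, lam, config.count_dispersion[f])
        rna_mean = depth * config.rna_depth_per_unit * latents.expression
        rna_counts = _nb_counts(rng, rna_mean, config.rna_dispersion)
        labels = expression_labels(rna_counts, config.bin_spec.window_length)
        patients.append(
            PatientDataset(
                patient_id=f"P{p + 1}",
                gene_ids=np.array([f"G{g:05d}" for g in range(config.n_genes)]),
                tensor=tensor,
                labels=labels,
                feature_names=CANONICAL_FEATURES,
                chroms=latents.chroms,
                bin_spec=config.bin_spec,
                meta={
                    "synthetic": True,
                    "seed": config.seed,
                    "patient_index": p,
                    "rna_window_counts": rna_counts.tolist() if config.n_genes <= 100 else None,
                },
            )
        )
    return patients


def write_cohort_tracks(
    dataset: PatientDataset,
    out_dir: str,
    gene_spacing: int | None = None,
) -> dict[str, str]:
    """Emit a synthetic cohort patient as plain-text inputs for the build
    pipeline: a BED6 annotation plus one bedGraph per feature and for RNA.

    Genes are laid out on their synthetic chromosomes, all on the "+" strand,
    spaced so windows never overlap.  Each bin's count c is written as a
    constant per-base value c / bin_width over the bin, so base-coverage
    binning reproduces the tensor exactly (up to float rounding).
    Returns a dict of the written paths.
    """
    import os

    spec = dataset.bin_spec
    spacing = gene_spacing or 3 * spec.window_length
    os.makedirs(out_dir, exist_ok=True)
    chroms = (
        dataset.chroms if dataset.chroms is not None else np.array(["chr1"] * dataset.n_genes)
    )
    # per-chromosome running offset for TSS placement
    tss = np.zeros(dataset.n_genes, dtype=np.int64)
    offsets: dict[str, int] = {}
    for g in range(dataset.n_genes):
        c = str(chroms[g])
        offsets[c] = offsets.get(c, spec.half_width + 1000) + spacing
        tss[g] = offsets[c]

    paths: dict[str, str] = {}
    bed_path = os.path.join(out_dir, "genes.bed")
    with open(bed_path, "w") as fh:
        for g in range(dataset.n_genes):
            fh.write(
                f"{chroms[g]}\t{tss[g]}\t{tss[g] + 1000}\t{dataset.gene_ids[g]}\t0\t+\n"
            )
    paths["annotation"] = bed_path

    def _write_track(name: str, per_gene_bins: np.ndarray) -> str:
        path = os.path.join(out_dir, f"{name}.bedgraph")
        with open(path, "w") as fh:
            for g in range(dataset.n_genes):
                start = tss[g] - spec.half_width
                for b in range(spec.n_bins):
                    v = per_gene_bins[g, b]
                    if v:
                        fh.write(
                            f"{chroms[g]}\t{start + b * spec.bin_width}\t"
                            f"{start + (b + 1) * spec.bin_width}\t{v / spec.bin_width}\n"
                        )
        return path

    for j, f in enumerate(dataset.feature_names):
        paths[f] = _write_track(f, dataset.tensor[:, :, j])
    rna = dataset.meta.get("rna_window_counts")
    if rna is not None:
        rna_bins = np.zeros((dataset.n_genes, spec.n_bins))
        rna_bins[:, 0] = np.asarray(rna, dtype=float)
        paths["RNA"] = _write_track("RNA", rna_bins)
    return paths
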
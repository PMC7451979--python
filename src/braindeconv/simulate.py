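"""Synthetic data generation for the whole pipeline.

This module emulates the data the deconvolution workflow consumes, without
any external download:

- a labelled single-cell population with planted type-specific marker genes
  (a stand-in for an annotated brain single-nucleus dataset),
- pseudo-bulk "artificial mixtures" built by drawing cells with replacement
  and averaging their counts, with the realised cell-type fractions kept as
  ground truth,
- negative-binomial read-count noise (variance = mu + phi * mu^2) with a
  dispersion that can be re-estimated from any count matrix,
- IHC-like noisy proportion measurements whose per-sample sums scatter
  around one (each cell type is "stained and counted" independently),
- phenotypes confounded by cell composition, and
- genotype dosages with planted genotype-by-cell-type interaction effects
  on expression.

Defaults follow the evaluation setting of the benchmark study this package
reproduces: five cell types, 100 markers per type, 70 pseudo-bulk samples.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    NoiseModel,
    ProportionMatrix,
    ReferenceDataset,
    SimulationTruth,
    SingleCellPopulation,
    warn_once,
)

__all__ = [
    "generate_population",
    "make_pseudobulk",
    "estimate_dispersion",
    "add_nb_noise",
    "simulate_ihc",
    "simulate_phenotype",
    "simulate_genotypes",
    "reference_from_population",
    "derive_seed",
]

#: fixed per-stage offsets used to derive operation seeds from a master seed
_STAGE_OFFSETS = {
    "population": 11,
    "pseudobulk": 23,
    "noise": 37,
    "ihc": 41,
    "phenotype": 53,
    "genotypes": 61,
    "reference": 71,
}


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed from a single master seed.

    Deterministic and collision-free across the pipeline's stages, and kept
    below 2**31 so the result is portable across RNG backends.
    """
    if stage not in _STAGE_OFFSETS:
        raise KeyError(f"unknown pipeline stage {stage!r}")
    return (int(master_seed) * 1009 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


def _default_frequencies(n_types: int) -> np.ndarray:
    # geometric decay: one dominant type (neuron-like) down to a rare one
    # (endothelial-like); for 5 types: 0.40, 0.26, 0.16, 0.11, 0.07
    w = 0.65 ** np.arange(n_types)
    return w / w.sum()


def generate_population(
    n_genes: int,
    cell_types: Sequence[str],
    markers_per_type: int = 100,
    fold_change: float = 8.0,
    seed: int = 0,
    *,
    n_cells: int = 1576,
    type_frequencies: Sequence[float] | None = None,
    baseline_mean: float = 5.0,
    baseline_sigma: float = 1.0,
) -> SingleCellPopulation:
    """Generate a labelled single-cell count population with planted markers.

    Baseline per-gene means are drawn from a log-normal distribution
    (heavy-tailed positive, as real expression is); each planted marker of
    type k has its mean multiplied by ``fold_change`` in type k only, so the
    marker invariant mean_k >= fold_change * max(other means) holds by
    construction and marker sets are disjoint across types. Per-cell counts
    are Poisson draws around the type means.

    Parameters
    ----------
    n_genes : total number of genes.
    cell_types : distinct cell-type names (>= 2).
    markers_per_type : planted markers per type; the product with the number
        of types must not exceed ``n_genes``.
    fold_change : marker over-expression factor (> 1).
    n_cells : population size; the default mirrors the 1576-nucleus
        reference population the artificial-mixture design is modelled on.
    type_frequencies : population frequency per type; defaults to a
        geometric profile with one dominant and one rare type.
    """
    cell_types = list(cell_types)
    if n_genes <= 0 or markers_per_type <= 0 or n_cells <= 0:
        raise ValueError("n_genes, markers_per_type and n_cells must be positive")
    if len(cell_types) < 2:
        raise ValueError("need at least 2 cell types")
    if len(set(cell_types)) != len(cell_types):
        raise ValueError("duplicate cell-type names")
    if fold_change <= 1:
        raise ValueError("fold_change must be > 1")
    if markers_per_type * len(cell_types) > n_genes:
        raise ValueError("markers_per_type * n_types exceeds n_genes")

    if type_frequencies is None:
        freq = _default_frequencies(len(cell_types))
    else:
        freq = np.asarray(type_frequencies, dtype=float)
        if len(freq) != len(cell_types) or (freq <= 0).any():
            raise ValueError("type_frequencies must be positive, one per type")
        freq = freq / freq.sum()

    rng = np.random.default_rng(seed)
    genes = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene")

    mu = np.log(baseline_mean) - 0.5 * baseline_sigma**2  # unit-median-ish baseline
    baseline = rng.lognormal(mean=mu, sigma=baseline_sigma, size=n_genes)
    type_means = np.tile(baseline[:, None], (1, len(cell_types)))

    marker_truth: dict[str, list[str]] = {}
    for k, ct in enumerate(cell_types):
        lo, hi = k * markers_per_type, (k + 1) * markers_per_type
        type_means[lo:hi, k] *= fold_change
        marker_truth[ct] = list(genes[lo:hi])

    # cell labels: round expected counts, then fix the remainder to n_cells
    expected = freq * n_cells
    counts_per_type = np.floor(expected).astype(int)
    remainder = n_cells - counts_per_type.sum()
    order = np.argsort(expected - counts_per_type)[::-1]
    counts_per_type[order[:remainder]] += 1
    labels = np.repeat(np.arange(len(cell_types)), counts_per_type)
    rng.shuffle(labels)

    counts = rng.poisson(type_means[:, labels])
    cells = pd.Index([f"c{i:05d}" for i in range(n_cells)], name="cell")

    return SingleCellPopulation(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        cell_labels=pd.Series([cell_types[k] for k in labels], index=cells),
        type_means=pd.DataFrame(type_means, index=genes, columns=cell_types),
        marker_truth=marker_truth,
    )


def make_pseudobulk(
    pop: SingleCellPopulation,
    n_samples: int = 70,
    cells_per_sample: int = 500,
    seed: int = 0,
    *,
    concentration: float = 10.0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Build artificial bulk mixtures by resampling cells and averaging.

    Each pseudo-bulk sample is the per-gene mean of ``cells_per_sample``
    cells drawn with replacement from the population. To create
    between-sample composition variability (required for correlation-based
    evaluation; uniform pool resampling alone would give near-constant
    truth), each sample first draws target type weights from a Dirichlet
    with parameter ``concentration * population frequency``, then samples
    cells type-by-type. The recorded truth is the *realised* fraction of
    drawn cells per type, which sums to one exactly.
    """
    if pop.n_cells == 0:
        raise ValueError("empty population")
    if n_samples <= 0 or cells_per_sample <= 0:
        raise ValueError("n_samples and cells_per_sample must be positive")

    rng = np.random.default_rng(seed)
    cell_types = pop.cell_types
    freq = pop.type_frequencies().to_numpy()
    present = freq > 0
    counts = pop.counts.to_numpy()
    cells_by_type = {
        ct: np.flatnonzero((pop.cell_labels == ct).to_numpy()) for ct in cell_types
    }

    samples = pd.Index([f"s{j:03d}" for j in range(n_samples)], name="sample")
    bulk = np.empty((counts.shape[0], n_samples))
    props = np.zeros((len(cell_types), n_samples))

    for j in range(n_samples):
        if present.sum() == 1:
            weights = present.astype(float)
        else:
            weights = np.zeros(len(cell_types))
            weights[present] = rng.dirichlet(concentration * freq[present])
        drawn_per_type = rng.multinomial(cells_per_sample, weights)
        chosen = np.concatenate(
            [
                rng.choice(cells_by_type[ct], size=m, replace=True)
                for ct, m in zip(cell_types, drawn_per_type)
                if m > 0
            ]
        )
        bulk[:, j] = counts[:, chosen].mean(axis=1)
        props[:, j] = drawn_per_type / cells_per_sample

    expr = ExpressionMatrix(
        pd.DataFrame(bulk, index=pop.counts.index, columns=samples), scale="linear"
    )
    truth = SimulationTruth(
        proportions=ProportionMatrix(
            pd.DataFrame(props, index=pd.Index(cell_types, name="cell_type"), columns=samples),
            kind="true",
        )
    )
    return expr, truth


def estimate_dispersion(
    counts: ExpressionMatrix, *, mean_threshold: float = 1.0
) -> NoiseModel:
    """Estimate a single negative-binomial dispersion from a count matrix.

    Per gene, the method-of-moments estimate phi_g = max(0, (var - mean) /
    mean^2) is computed across samples; genes with mean expression at or
    below ``mean_threshold`` are excluded (their moment ratio is dominated
    by Poisson noise). The common dispersion is the median of the per-gene
    estimates — robust to the heavy right tail of moment estimators.
    """
    if counts.is_log:
        raise ValueError("dispersion estimation requires count-scale input")
    x = counts.data.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 samples to estimate dispersion")
    means = x.mean(axis=1)
    keep = means > mean_threshold
    if not keep.any():
        raise ValueError("no genes above the mean threshold; cannot estimate dispersion")
    variances = x.var(axis=1, ddof=1)
    phi_g = np.maximum(0.0, (variances[keep] - means[keep]) / means[keep] ** 2)
    return NoiseModel(dispersion=float(np.median(phi_g)))


def add_nb_noise(
    means: ExpressionMatrix, model: NoiseModel, seed: int = 0
) -> ExpressionMatrix:
    """Resample integer read counts around the given means.

    Draws are negative binomial with E[count] = mean and Var = mu + phi *
    mu^2; a dispersion of zero takes the Poisson path exactly. Zero means
    always yield zero counts.
    """
    mu = means.data.to_numpy(dtype=float)
    if (mu < 0).any():
        raise ValueError("means must be non-negative")
    phi = model.dispersion
    rng = np.random.default_rng(seed)
    if phi == 0:
        draws = rng.poisson(mu)
    else:
        # numpy's NB(n, p): mean = n(1-p)/p, so n = 1/phi, p = 1/(1+phi*mu)
        n = 1.0 / phi
        p = 1.0 / (1.0 + phi * mu)
        draws = np.where(mu > 0, rng.negative_binomial(n, p), 0)
    return ExpressionMatrix(
        pd.DataFrame(draws, index=means.data.index, columns=means.data.columns),
        scale="counts",
    )


def simulate_ihc(
    truth: ProportionMatrix, cv: float = 0.2, seed: int = 0
) -> ProportionMatrix:
    """Corrupt true proportions into IHC-like independent measurements.

    Every entry is multiplied by an independent unit-mean log-normal factor
    with coefficient of variation ``cv``, mimicking per-cell-type staining
    and counting error. Columns are deliberately NOT renormalised, so the
    per-sample sums scatter around one — the signature of proportions
    measured one cell type at a time.
    """
    if cv < 0:
        raise ValueError("cv must be non-negative")
    values = truth.data.to_numpy(dtype=float)
    if cv == 0:
        noisy = values.copy()
    else:
        sigma2 = np.log1p(cv**2)
        rng = np.random.default_rng(seed)
        factors = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=values.shape)
        noisy = values * factors
    return ProportionMatrix(
        pd.DataFrame(noisy, index=truth.data.index, columns=truth.data.columns),
        kind="measured",
    )


def simulate_phenotype(
    expr: ExpressionMatrix,
    truth: ProportionMatrix,
    direct_genes: Sequence[str],
    mediated_celltype: str,
    effect: float = 1.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    direct_effect: float = 1.0,
) -> tuple[pd.Series, dict]:
    """Simulate a phenotype confounded by cell composition.

    phenotype = effect * z(proportion of ``mediated_celltype``)
              + direct_effect * sum over ``direct_genes`` of z(expression)
              + Gaussian noise,

    where z() standardises across samples. With ``direct_genes`` empty the
    phenotype is purely composition-driven: before composition adjustment,
    every marker gene of the mediated type will associate with it.

    Returns the phenotype vector and a record of its generating parameters
    (suitable for :attr:`SimulationTruth.phenotype_effects`).
    """
    if mediated_celltype not in truth.data.index:
        raise KeyError(f"unknown cell type {mediated_celltype!r}")
    missing = [g for g in direct_genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"direct genes absent from expression matrix: {missing[:5]}")
    samples = expr.data.columns
    if not samples.equals(truth.data.columns):
        raise ValueError("expression and truth proportions are sample-misaligned")

    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    rng = np.random.default_rng(seed)
    y = effect * _z(truth.data.loc[mediated_celltype].to_numpy(dtype=float))
    for g in direct_genes:
        y = y + direct_effect * _z(expr.data.loc[g].to_numpy(dtype=float))
    y = y + rng.normal(0.0, noise_sd, size=len(samples))

    params = {
        "mediated_celltype": mediated_celltype,
        "effect": effect,
        "direct_genes": list(direct_genes),
        "direct_effect": direct_effect,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return pd.Series(y, index=samples, name="phenotype"), params


def simulate_genotypes(
    n_samples: int,
    n_snps: int,
    maf: float,
    planted: Sequence[tuple[str, str, str, float]],
    truth: ProportionMatrix,
    expr: ExpressionMatrix,
    seed: int = 0,
    *,
    main_effect: float = 0.0,
) -> tuple[pd.DataFrame, ExpressionMatrix]:
    """Simulate additive SNP dosages and plant interaction eQTL effects.

    Dosages are Binomial(2, maf) per SNP and sample. For each planted
    effect (snp, gene, cell_type, gamma) the gene's expression row gains
    ``gamma * dosage * proportion`` (plus an optional genotype main effect,
    ``main_effect * dosage``); all other genes are returned unchanged.
    """
    if not (0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    if n_samples != expr.data.shape[1]:
        raise ValueError("n_samples must match the expression matrix")
    if not expr.data.columns.equals(truth.data.columns):
        raise ValueError("expression and truth proportions are sample-misaligned")

    rng = np.random.default_rng(seed)
    snps = pd.Index([f"snp{i:05d}" for i in range(n_snps)], name="snp")
    dosages = pd.DataFrame(
        rng.binomial(2, maf, size=(n_snps, n_samples)),
        index=snps,
        columns=expr.data.columns,
    )

    modified = expr.data.copy()
    for snp, gene, cell_type, gamma in planted:
        if snp not in dosages.index:
            raise KeyError(f"planted SNP {snp!r} not among simulated SNPs")
        if gene not in modified.index:
            raise KeyError(f"planted gene {gene!r} not in expression matrix")
        if cell_type not in truth.data.index:
            raise KeyError(f"planted cell type {cell_type!r} not in truth")
        g = dosages.loc[snp].to_numpy(dtype=float)
        c = truth.data.loc[cell_type].to_numpy(dtype=float)
        modified.loc[gene] = (
            modified.loc[gene].to_numpy(dtype=float) + gamma * g * c + main_effect * g
        )
    return dosages, ExpressionMatrix(modified, scale=expr.scale)


def reference_from_population(
    pop: SingleCellPopulation,
    replicates_per_type: int = 5,
    cells_per_replicate: int = 20,
    seed: int = 0,
) -> ReferenceDataset:
    """Build a reference dataset of pseudo-pure replicate profiles.

    For each cell type, ``replicates_per_type`` profiles are formed by
    averaging ``cells_per_replicate`` cells of that type drawn with
    replacement — emulating purified-population or cell-sorted reference
    samples used for marker derivation.
    """
    if replicates_per_type < 2:
        raise ValueError("need >= 2 replicates per type for downstream DE")
    rng = np.random.default_rng(seed)
    counts = pop.counts.to_numpy()
    cols: list[np.ndarray] = []
    names: list[str] = []
    labels: list[str] = []
    for ct in pop.cell_types:
        idx = np.flatnonzero((pop.cell_labels == ct).to_numpy())
        if len(idx) == 0:
            warn_once(f"cell type {ct!r} has no cells; skipped in reference")
            continue
        for r in range(replicates_per_type):
            chosen = rng.choice(idx, size=cells_per_replicate, replace=True)
            cols.append(counts[:, chosen].mean(axis=1))
            names.append(f"{ct}_rep{r}")
            labels.append(ct)
    data = pd.DataFrame(
        np.column_stack(cols), index=pop.counts.index, columns=pd.Index(names, name="sample")
    )
    return ReferenceDataset(data=data, labels=pd.Series(labels, index=names), scale="counts")
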
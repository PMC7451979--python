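"""Composition-aware downstream analyses.

Two applications of estimated cell-type proportions:

1. Phenotype association with and without proportion adjustment. Genes
   whose apparent phenotype association is explained away once cell-type
   proportions enter as covariates are likely composition-driven false
   positives.
2. Cell-type interaction eQTL scanning. Per (SNP, gene, cell type) the
   linear interaction model y = intercept + alpha*g + beta*c + gamma*(g*c)
   is fitted; a significant interaction gamma indicates a
   genotype-by-cell-type effect. Tests are combined under a global
   Benjamini-Hochberg FDR across all SNP-gene pairs and cell types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, ProportionMatrix, warn_once

__all__ = [
    "associate_phenotype",
    "proportion_phenotype_association",
    "enumerate_cis_pairs",
    "celltype_eqtl",
    "eqtl_scan",
    "EqtlFit",
]

_MAX_CONDITION = 1e6


def _signed_log10_p(coef: np.ndarray, p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.sign(coef) * (-np.log10(np.maximum(p, np.finfo(float).tiny)))


def _fit_gene_models(Y: np.ndarray, X: np.ndarray, coef_idx: int):
    """OLS of every row of Y on design X; t-test on column ``coef_idx``.

    Returns (coef, p) arrays, one entry per gene.
    """
    n, k = X.shape
    XtX = X.T @ X
    XtXi = np.linalg.inv(XtX)
    beta = Y @ X @ XtXi.T  # genes x k
    resid = Y - beta @ X.T
    dof = n - k
    sigma2 = (resid**2).sum(axis=1) / dof
    se = np.sqrt(np.maximum(sigma2 * XtXi[coef_idx, coef_idx], np.finfo(float).tiny))
    t = beta[:, coef_idx] / se
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return beta[:, coef_idx], p


def _covariate_design(props: ProportionMatrix) -> np.ndarray:
    """Proportion covariates with the largest-mean type dropped.

    Estimated proportions live on the simplex, so together with an
    intercept the full set is collinear; the dominant type serves as the
    reference category.
    """
    reference = props.data.mean(axis=1).idxmax()
    return props.data.drop(index=reference).to_numpy(dtype=float).T


def associate_phenotype(
    expr: ExpressionMatrix,
    phenotype: pd.Series,
    covariates: ProportionMatrix | None = None,
    *,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene phenotype association, unadjusted and proportion-adjusted.

    Fits expression ~ phenotype (the unadjusted model) and, when
    ``covariates`` is given, expression ~ phenotype + proportions (one
    reference cell type dropped). Reports signed log10 p-values —
    sign(coefficient) * (-log10 p) — for the phenotype term in each model
    and classifies every gene at the per-model Bonferroni threshold
    alpha / n_genes into ``both``, ``unadjusted_only``, ``adjusted_only``
    or ``neither``.
    """
    if not expr.data.columns.equals(phenotype.index):
        raise ValueError("expression samples and phenotype are misaligned")
    Y = expr.data.to_numpy(dtype=float)
    n = Y.shape[1]
    y = phenotype.to_numpy(dtype=float)

    X0 = np.column_stack([np.ones(n), y])
    coef0, p0 = _fit_gene_models(Y, X0, coef_idx=1)

    out = pd.DataFrame(index=expr.data.index)
    out["coef_unadjusted"] = coef0
    out["p_unadjusted"] = p0
    out["signed_log10p_unadjusted"] = _signed_log10_p(coef0, p0)

    bonferroni = alpha / Y.shape[0]
    sig0 = p0 < bonferroni

    if covariates is not None:
        if not expr.data.columns.equals(covariates.data.columns):
            raise ValueError("expression samples and covariates are misaligned")
        C = _covariate_design(covariates)
        X1 = np.column_stack([np.ones(n), y, C])
        if np.linalg.cond(X1) > _MAX_CONDITION:
            raise ValueError(
                f"covariate design condition number {np.linalg.cond(X1):.3g} "
                f"exceeds {_MAX_CONDITION:.0e}"
            )
        coef1, p1 = _fit_gene_models(Y, X1, coef_idx=1)
        out["coef_adjusted"] = coef1
        out["p_adjusted"] = p1
        out["signed_log10p_adjusted"] = _signed_log10_p(coef1, p1)
        sig1 = p1 < bonferroni
        out["class"] = np.select(
            [sig0 & sig1, sig0 & ~sig1, ~sig0 & sig1],
            ["both", "unadjusted_only", "adjusted_only"],
            default="neither",
        )
    else:
        out["class"] = np.where(sig0, "both", "neither")
    out.attrs["bonferroni_threshold"] = bonferroni
    return out


def proportion_phenotype_association(
    props: ProportionMatrix, phenotypes: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Signed log10 p for each (cell type, phenotype) univariate association."""
    if isinstance(phenotypes, pd.Series):
        phenotypes = phenotypes.to_frame()
    if not props.data.columns.equals(phenotypes.index):
        raise ValueError("proportions and phenotypes are misaligned")
    rows = []
    for ct in props.data.index:
        c = props.data.loc[ct].to_numpy(dtype=float)
        for name in phenotypes.columns:
            y = phenotypes[name].to_numpy(dtype=float)
            if np.ptp(c) == 0 or np.ptp(y) == 0:
                rows.append(
                    {"cell_type": ct, "phenotype": name, "coef": np.nan,
                     "p": np.nan, "signed_log10p": np.nan, "note": "zero variance"}
                )
                continue
            res = stats.linregress(c, y)
            rows.append(
                {"cell_type": ct, "phenotype": name, "coef": res.slope,
                 "p": res.pvalue,
                 "signed_log10p": float(np.sign(res.slope) * -np.log10(max(res.pvalue, np.finfo(float).tiny))),
                 "note": ""}
            )
    return pd.DataFrame(rows)


def enumerate_cis_pairs(
    snp_positions: pd.DataFrame,
    gene_tss: pd.DataFrame,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """All (SNP, gene) pairs with |SNP position - TSS| <= window, inclusive.

    ``snp_positions`` needs columns (chrom, pos, id); ``gene_tss`` needs
    (chrom, pos, id). Positions are 1-based; the window boundary is
    inclusive on both sides.
    """
    for name, table in (("snp_positions", snp_positions), ("gene_tss", gene_tss)):
        missing = {"chrom", "pos", "id"} - set(table.columns)
        if missing:
            raise ValueError(f"{name} lacks columns {sorted(missing)}")
    shared = set(snp_positions.chrom) & set(gene_tss.chrom)
    if not shared:
        raise ValueError(
            "no shared chromosome labels between SNPs "
            f"({sorted(set(snp_positions.chrom))[:3]}...) and genes "
            f"({sorted(set(gene_tss.chrom))[:3]}...)"
        )
    rows = []
    for chrom in sorted(shared):
        snps = snp_positions[snp_positions.chrom == chrom]
        genes = gene_tss[gene_tss.chrom == chrom]
        dist = snps.pos.to_numpy()[:, None] - genes.pos.to_numpy()[None, :]
        within = np.abs(dist) <= window
        si, gi = np.nonzero(within)
        for a, b in zip(si, gi):
            rows.append(
                {"snp": snps.id.iloc[a], "gene": genes.id.iloc[b],
                 "distance": int(dist[a, b])}
            )
    return pd.DataFrame(rows, columns=["snp", "gene", "distance"])


@dataclass
class EqtlFit:
    """One interaction-model fit: y = intercept + alpha*g + beta*c + gamma*(g*c)."""

    snp: str
    gene: str
    cell_type: str
    alpha: float
    beta: float
    gamma: float
    se_gamma: float
    p_interaction: float
    q: float = math.nan


def celltype_eqtl(
    y: np.ndarray,
    g: np.ndarray,
    c: np.ndarray,
    *,
    snp: str = "snp",
    gene: str = "gene",
    cell_type: str = "cell_type",
) -> EqtlFit:
    """Fit the genotype-by-proportion interaction model for one triple.

    The interaction p-value is the two-sided t-test on the gamma estimate.
    Monomorphic genotypes and zero-variance proportions are rejected.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    c = np.asarray(c, dtype=float)
    if np.isnan(y).any() or np.isnan(g).any() or np.isnan(c).any():
        raise ValueError("missing values must be dropped before fitting")
    if np.ptp(g) == 0:
        raise ValueError(f"monomorphic SNP {snp!r}")
    if np.ptp(c) == 0:
        raise ValueError(f"zero-variance proportion for {cell_type!r}")
    n = len(y)
    X = np.column_stack([np.ones(n), g, c, g * c])
    XtX = X.T @ X
    if np.linalg.cond(XtX) > 1 / np.finfo(float).eps:
        raise ValueError(f"degenerate design for ({snp}, {gene}, {cell_type})")
    XtXi = np.linalg.inv(XtX)
    beta = XtXi @ X.T @ y
    resid = y - X @ beta
    dof = n - 4
    sigma2 = float(resid @ resid) / dof
    se_gamma = math.sqrt(max(sigma2 * XtXi[3, 3], np.finfo(float).tiny))
    t = beta[3] / se_gamma
    p = 2.0 * float(stats.t.sf(abs(t), dof))
    return EqtlFit(
        snp=snp, gene=gene, cell_type=cell_type,
        alpha=float(beta[1]), beta=float(beta[2]), gamma=float(beta[3]),
        se_gamma=se_gamma, p_interaction=max(p, np.finfo(float).tiny),
    )


#: raw p-value grid for the threshold-count curve
_P_GRID = 10.0 ** np.arange(-1.0, -9.5, -0.5)


def eqtl_scan(
    expr: ExpressionMatrix,
    dosages: pd.DataFrame,
    props: ProportionMatrix,
    pairs: pd.DataFrame,
    fdr: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interaction-eQTL scan over (SNP, gene) pairs and all cell types.

    Every pair x cell type is fitted; Benjamini-Hochberg is applied jointly
    over all tests (the global-FDR convention) and rows with q <= ``fdr``
    are flagged significant. Per-test failures (monomorphic SNPs, flat
    proportions) are skipped with a warning, never aborting the scan. Also
    returns the count of raw p-values below each threshold of a log-spaced
    grid — the power-comparison curve.
    """
    if pairs.empty:
        raise ValueError("empty pair list")
    samples = expr.data.columns
    if not dosages.columns.equals(samples) or not props.data.columns.equals(samples):
        raise ValueError("expression, dosages and proportions are sample-misaligned")

    fits: list[EqtlFit] = []
    n_failed = 0
    for row in pairs.itertuples(index=False):
        if row.snp not in dosages.index or row.gene not in expr.data.index:
            n_failed += 1
            continue
        y = expr.data.loc[row.gene].to_numpy(dtype=float)
        g = dosages.loc[row.snp].to_numpy(dtype=float)
        for ct in props.data.index:
            c = props.data.loc[ct].to_numpy(dtype=float)
            try:
                fits.append(
                    celltype_eqtl(y, g, c, snp=row.snp, gene=row.gene, cell_type=ct)
                )
            except ValueError:
                n_failed += 1
    if n_failed:
        warn_once(f"eqtl_scan: {n_failed} tests skipped (degenerate inputs)")
    if not fits:
        raise ValueError("all eQTL tests failed")

    table = pd.DataFrame(
        [
            (f.snp, f.gene, f.cell_type, f.alpha, f.beta, f.gamma,
             f.se_gamma, f.p_interaction)
            for f in fits
        ],
        columns=["snp", "gene", "cell_type", "alpha", "beta", "gamma",
                 "se_gamma", "p_interaction"],
    )
    table["q"] = multipletests(table.p_interaction, method="fdr_bh")[1]
    table["significant"] = table.q <= fdr

    curve = pd.DataFrame(
        {
            "p_threshold": _P_GRID,
            "n_associations": [
                int((table.p_interaction < thr).sum()) for thr in _P_GRID
            ],
        }
    )
    return table, curve
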
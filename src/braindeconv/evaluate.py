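"""Accuracy evaluation of estimated cell-type proportions.

Estimates are scored against measured or true proportions per cell type
with (1) correlation across samples — sensitive to *relative* accuracy —
and (2) mean squared error with a permutation test — sensitive to
*absolute* accuracy. A companion regression quantifies how much of each
gene's expression variance the proportions explain (PVE).
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix, ProportionMatrix

__all__ = [
    "per_celltype_correlation",
    "critical_correlation",
    "mse_per_celltype",
    "mse_permutation_test",
    "pve_per_gene",
    "proportion_sum_check",
    "method_concordance",
]


def _align(pred: ProportionMatrix, truth: ProportionMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    types = pred.data.index.intersection(truth.data.index)
    samples = pred.data.columns.intersection(truth.data.columns)
    if len(samples) < 3:
        raise ValueError(f"need >= 3 shared samples, found {len(samples)}")
    if len(types) == 0:
        raise ValueError("no shared cell types between prediction and truth")
    return pred.data.loc[types, samples], truth.data.loc[types, samples]


def _corr_pvalue(r: float, n: int, sided: str) -> float:
    """t-approximation p-value for a correlation coefficient, n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    if sided == "two":
        return 2.0 * stats.t.sf(abs(t), n - 2)
    return stats.t.sf(t, n - 2)


def per_celltype_correlation(
    pred: ProportionMatrix,
    truth: ProportionMatrix,
    method: str = "spearman",
    *,
    sided: str = "two",
) -> pd.DataFrame:
    """Correlation across samples between predicted and reference proportions.

    Returns a table with one row per shared cell type: r, p-value (t
    approximation with n-2 degrees of freedom) and n. Zero-variance rows
    yield a missing r with the reason recorded.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError("method must be 'spearman' or 'pearson'")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    P, T = _align(pred, truth)
    n = P.shape[1]
    rows = []
    for ct in P.index:
        x = P.loc[ct].to_numpy(dtype=float)
        y = T.loc[ct].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"cell_type": ct, "r": np.nan, "p": np.nan, "n": n,
                         "note": "zero variance"})
            continue
        if method == "spearman":
            r = stats.spearmanr(x, y).statistic
        else:
            r = stats.pearsonr(x, y).statistic
        rows.append(
            {"cell_type": ct, "r": float(r), "p": _corr_pvalue(float(r), n, sided),
             "n": n, "note": ""}
        )
    return pd.DataFrame(rows).set_index("cell_type")


def critical_correlation(n: int, alpha: float = 0.05, sided: str = "one") -> float:
    """Smallest correlation significant at level alpha for sample size n.

    Inverts the t-approximation: r* = t* / sqrt(n - 2 + t*^2) with t* the
    upper-alpha (or alpha/2) quantile at n-2 degrees of freedom. At n = 70
    and one-sided alpha 0.05 this is ~0.198 — the usual "r > 0.2" rule of
    thumb for 70-sample cohorts.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    q = 1 - alpha if sided == "one" else 1 - alpha / 2
    t_star = stats.t.ppf(q, n - 2)
    return float(t_star / math.sqrt(n - 2 + t_star**2))


def mse_per_celltype(pred: ProportionMatrix, truth: ProportionMatrix) -> pd.Series:
    """Mean squared error between predicted and reference proportions, per type."""
    P, T = _align(pred, truth)
    return ((P - T) ** 2).mean(axis=1).rename("mse")


def mse_permutation_test(
    pred: ProportionMatrix,
    truth: ProportionMatrix,
    n_perm: int = 10000,
    seed: int = 0,
) -> pd.Series:
    """Permutation p-value for the per-type MSE being smaller than chance.

    The null shuffles the sample labels of the predicted row within each
    cell type (preserving each type's marginal distribution) and recomputes
    the MSE; p = (1 + #{null MSE <= observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    P, T = _align(pred, truth)
    rng = np.random.default_rng(seed)
    n = P.shape[1]
    out = {}
    for ct in P.index:
        x = P.loc[ct].to_numpy(dtype=float)
        y = T.loc[ct].to_numpy(dtype=float)
        observed = np.mean((x - y) ** 2)
        perms = rng.permuted(np.tile(x, (n_perm, 1)), axis=1)
        null = ((perms - y) ** 2).mean(axis=1)
        out[ct] = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    return pd.Series(out, name="perm_p").rename_axis("cell_type")


def pve_per_gene(
    expr: ExpressionMatrix, props: ProportionMatrix
) -> pd.DataFrame:
    """Per-gene variance explained by cell-type proportions (R^2 + F-test).

    Each gene's expression across samples is regressed on the proportion
    rows plus an intercept by ordinary least squares. Exact-simplex
    proportion tables make the intercept redundant; one reference type (the
    largest on average) is dropped in that case, which leaves the fitted
    subspace — hence R^2 — unchanged. Remaining rank deficiency is an
    error, reported with the design's condition number.
    """
    if not expr.data.columns.equals(props.data.columns):
        shared = expr.data.columns.intersection(props.data.columns)
        if len(shared) < props.data.shape[0] + 2:
            raise ValueError("too few shared samples for the PVE regression")
        expr = ExpressionMatrix(expr.data[shared], scale=expr.scale)
        props = ProportionMatrix(props.data[shared], kind=props.kind)

    C = props.data.copy()
    sums = C.sum(axis=0)
    if np.allclose(sums, 1.0, atol=1e-6):
        reference = C.mean(axis=1).idxmax()
        C = C.drop(index=reference)

    n = C.shape[1]
    X = np.column_stack([np.ones(n), C.to_numpy(dtype=float).T])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            "collinear proportion covariates; design condition number "
            f"{np.linalg.cond(X):.3g}"
        )
    if n < X.shape[1] + 1:
        raise ValueError("need at least K + 2 samples for K proportion covariates")

    Y = expr.data.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    fitted = (X @ beta).T
    ss_res = ((Y - fitted) ** 2).sum(axis=1)
    ss_tot = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
    r2 = np.clip(r2, 0.0, 1.0)
    df_model = rank - 1
    df_resid = n - rank
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (r2 / df_model) / np.maximum((1.0 - r2) / df_resid, np.finfo(float).tiny)
    p = stats.f.sf(f, df_model, df_resid)
    return pd.DataFrame({"r2": r2, "f_p": p}, index=expr.data.index)


def proportion_sum_check(
    props: ProportionMatrix, tolerance: float = 0.25
) -> pd.DataFrame:
    """Per-sample proportion sums with an |sum - 1| <= tolerance flag.

    Measured (IHC-like) tables stain each cell type independently, so sums
    only approximately reach one; sums far from one flag samples where a
    major population went uncounted or was double-counted.
    """
    sums = props.column_sums()
    ok = (sums - 1.0).abs() <= tolerance
    return pd.DataFrame({"sum": sums, "within_tolerance": ok})


def method_concordance(
    estimates: Mapping[str, ProportionMatrix]
) -> pd.DataFrame:
    """Pairwise per-cell-type Spearman correlation between methods' estimates."""
    names = list(estimates)
    if len(names) < 2:
        raise ValueError("need >= 2 estimates to compare")
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            corr = per_celltype_correlation(
                estimates[a], estimates[b], method="spearman"
            )
            for ct, row in corr.iterrows():
                rows.append(
                    {"method_a": a, "method_b": b, "cell_type": ct, "spearman_r": row.r}
                )
    return pd.DataFrame(rows)
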
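"""Cell-type proportion estimation from bulk expression.

Three marker-based estimators plus a single-gene baseline:

- ``deconvolve_dsa``: digital-sorting-style semi-supervised estimator. It
  needs only marker *identities*: per-type marker-average expression M is
  modelled as M = diag(s) P with P on the simplex, so the per-type scale
  factors satisfy sum_k (1/s_k) M[k, j] = 1 for every sample j. The
  reciprocal scales x = 1/s are recovered by non-negative least squares on
  that ones-vector system and P = diag(x) M, clipped and renormalised.
- ``deconvolve_nnls``: supervised signature regression. Each bulk sample is
  regressed on the per-type mean marker profiles (the signature matrix)
  under a non-negativity constraint; coefficients are normalised to sum 1.
- ``deconvolve_logmean``: a log-scale marker-mean estimator. Per-type mean
  log2 expression minus the pure-reference offset, exponentiated back and
  normalised. (A simplified relative of published log-scale estimators; no
  quantile-based offset tuning is attempted.)
- ``single_marker_proxy``: one gene per cell type (e.g. ENO2 for neurons,
  GFAP for astrocytes), returning raw expression rows as relative scores.

All matrix estimators operate on linear-scale expression; log-scale input
is detected and rejected with a message.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import (
    ExpressionMatrix,
    MarkerSet,
    ProportionMatrix,
    ReferenceDataset,
    warn_once,
)

__all__ = [
    "build_signature",
    "deconvolve_nnls",
    "deconvolve_dsa",
    "deconvolve_logmean",
    "single_marker_proxy",
]

#: linear-scale matrices whose maximum is below this look log-transformed
_LOG_SUSPECT_MAX = 30.0


def _require_linear(expr: ExpressionMatrix, op: str) -> pd.DataFrame:
    if expr.is_log:
        raise ValueError(
            f"{op} requires linear-scale expression; got log2cpm "
            "(use ExpressionMatrix.to_linear() first)"
        )
    if expr.data.to_numpy().max() < _LOG_SUSPECT_MAX:
        raise ValueError(
            f"{op}: expression maximum < {_LOG_SUSPECT_MAX} suggests log-scale "
            "input mislabelled as linear; unlog it or retag the scale"
        )
    return expr.data


def _marker_means(
    data: pd.DataFrame, markers: MarkerSet, op: str
) -> pd.DataFrame:
    """Cell-type x sample matrix of per-type mean marker expression."""
    rows = {}
    for ct, genes in markers.items():
        present = [g for g in genes if g in data.index]
        if not present:
            raise ValueError(f"{op}: cell type {ct!r} has no markers in the matrix")
        if len(present) < 0.5 * len(genes):
            warn_once(
                f"{op}: cell type {ct!r} lost {len(genes) - len(present)} of "
                f"{len(genes)} markers absent from the expression matrix"
            )
        rows[ct] = data.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def _to_simplex(raw: np.ndarray, cell_types, samples, method: str) -> ProportionMatrix:
    raw = np.maximum(raw, 0.0)
    sums = raw.sum(axis=0)
    degenerate = sums <= 0
    if degenerate.any():
        warn_once(f"{method}: all-zero estimates for some samples; set to uniform")
        raw[:, degenerate] = 1.0
        sums = raw.sum(axis=0)
    props = raw / sums
    return ProportionMatrix(
        pd.DataFrame(props, index=pd.Index(cell_types, name="cell_type"), columns=samples),
        kind="estimated",
    )


def build_signature(
    ref: ReferenceDataset, markers: MarkerSet, *, pseudo_count: float = 1.0
) -> pd.DataFrame:
    """Per-type mean expression of the marker genes, on linear scale.

    Rows are the union of all marker genes found in the reference (missing
    genes are dropped with a warning; more than half missing is an error),
    columns are cell types. This is the design matrix for signature
    regression.
    """
    data = ref.data
    if ref.scale == "log2cpm":
        data = np.maximum(np.exp2(data) - pseudo_count, 0.0)
    wanted = markers.all_genes()
    present = [g for g in wanted if g in data.index]
    if len(present) < 0.5 * len(wanted):
        raise ValueError(
            f"only {len(present)} of {len(wanted)} marker genes found in the reference"
        )
    if len(present) < len(wanted):
        warn_once(
            f"{len(wanted) - len(present)} marker genes absent from the reference; dropped"
        )
    sub = data.loc[present]
    sig = sub.T.groupby(ref.labels).mean().T  # gene x cell-type means
    return sig[[ct for ct in markers.cell_types if ct in sig.columns]]


def deconvolve_nnls(expr: ExpressionMatrix, sig: pd.DataFrame) -> ProportionMatrix:
    """Signature-regression deconvolution via non-negative least squares.

    Per sample j solves min || y_j - X b ||^2 subject to b >= 0 over the
    shared marker genes, then normalises b to the simplex.
    """
    data = _require_linear(expr, "deconvolve_nnls")
    shared = sig.index.intersection(data.index)
    if len(shared) == 0:
        raise ValueError("no shared marker genes between expression and signature")
    X = sig.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "signature matrix is rank-deficient (collinear cell-type profiles); "
            f"condition number {np.linalg.cond(X):.3g}"
        )
    Y = data.loc[shared].to_numpy(dtype=float)
    raw = np.column_stack([nnls(X, Y[:, j])[0] for j in range(Y.shape[1])])
    return _to_simplex(raw, sig.columns, data.columns, "deconvolve_nnls")


def deconvolve_dsa(expr: ExpressionMatrix, markers: MarkerSet) -> ProportionMatrix:
    """Digital-sorting-style deconvolution from marker identities alone.

    Forms M[k, j] = mean expression of type-k markers in sample j, solves
    the ones-vector system sum_k M[k, j] x_k = 1 (all j) for x >= 0 by
    non-negative least squares, and returns P = diag(x) M clipped to zero
    and renormalised per sample. x_k estimates the reciprocal of the
    per-type marker expression scale.
    """
    data = _require_linear(expr, "deconvolve_dsa")
    M = _marker_means(data, markers, "deconvolve_dsa")
    Mv = M.to_numpy(dtype=float)
    dead = ~(Mv > 0).any(axis=1)
    if dead.any():
        bad = [ct for ct, d in zip(M.index, dead) if d]
        raise ValueError(f"deconvolve_dsa: all-zero marker means for {bad}")
    if len(M) == 1:
        raw = np.ones_like(Mv)
    else:
        x, _ = nnls(Mv.T, np.ones(Mv.shape[1]))
        raw = x[:, None] * Mv
    return _to_simplex(raw, M.index, data.columns, "deconvolve_dsa")


def deconvolve_logmean(
    expr: ExpressionMatrix,
    ref: ReferenceDataset,
    markers: MarkerSet,
    *,
    pseudo_count: float = 1.0,
) -> ProportionMatrix:
    """Log-scale marker-mean deconvolution with pure-reference offsets.

    z[k, j] = mean over type-k markers of log2(expr + 1); the offset o_k is
    the same statistic computed on the pure type-k reference mean profile.
    The unnormalised proportion is 2^(z - o), normalised per sample.
    """
    data = _require_linear(expr, "deconvolve_logmean")
    log_bulk = np.log2(data + pseudo_count)

    ref_data = ref.data
    if ref.scale == "log2cpm":
        ref_data = np.maximum(np.exp2(ref_data) - pseudo_count, 0.0)
    pure_means = ref_data.T.groupby(ref.labels).mean().T  # gene x type

    rows = {}
    for ct, genes in markers.items():
        present = [g for g in genes if g in log_bulk.index and g in pure_means.index]
        if not present:
            raise ValueError(f"deconvolve_logmean: no usable markers for {ct!r}")
        if ct not in pure_means.columns:
            raise ValueError(f"deconvolve_logmean: {ct!r} missing from reference labels")
        z = log_bulk.loc[present].mean(axis=0)
        offset = float(np.log2(pure_means.loc[present, ct] + pseudo_count).mean())
        rows[ct] = np.exp2(z - offset)
    raw = pd.DataFrame(rows).T
    return _to_simplex(
        raw.to_numpy(dtype=float), raw.index, data.columns, "deconvolve_logmean"
    )


def single_marker_proxy(
    expr: ExpressionMatrix, gene_map: Mapping[str, str]
) -> pd.DataFrame:
    """Single-gene relative proxy for each cell type.

    Returns the named genes' expression rows as a cell-type x sample score
    matrix. Scores are deliberately NOT normalised to the simplex — a lone
    marker (ENO2, GFAP, CD68, CD34, OLIG2 in the classic brain panel) only
    tracks relative abundance across samples. The result carries
    ``attrs["is_proportion"] = False``.
    """
    missing = {ct: g for ct, g in gene_map.items() if g not in expr.data.index}
    if missing:
        named = ", ".join(f"{g} ({ct})" for ct, g in missing.items())
        raise KeyError(f"single-marker genes absent from the expression matrix: {named}")
    scores = pd.DataFrame(
        {ct: expr.data.loc[g] for ct, g in gene_map.items()}
    ).T
    scores.index.name = "cell_type"
    flat = [ct for ct in scores.index if np.ptp(scores.loc[ct].to_numpy()) == 0]
    if flat:
        warn_once(
            f"single-marker proxy rows with zero variance (useless for "
            f"correlation): {flat}"
        )
    scores.attrs["is_proportion"] = False
    return scores
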
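"""Marker-gene derivation from labelled reference profiles.

Markers are selected per cell type as the top-k genes by one-vs-rest log2
fold-change among genes passing a Benjamini-Hochberg FDR gate (default:
100 genes at FDR < 0.05). Differential expression uses Welch t-tests on
log2 CPM. Helper operations remove genes shared between marker lists and
filter neuronal-subtype markers down to those actually enriched in the
parent type.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MarkerSet, ReferenceDataset, warn_once

__all__ = [
    "normalize_reference",
    "select_markers",
    "remove_overlapping_markers",
    "filter_subtype_markers",
]


def normalize_reference(
    ref: ReferenceDataset, *, log: bool = True, pseudo_count: float = 1.0
) -> ReferenceDataset:
    """Library-size normalise a count-scale reference to (log2) CPM.

    Each sample is scaled to counts-per-million; when ``log`` is set the
    values are then transformed as log2(CPM + pseudo_count).
    """
    if ref.scale not in ("counts", "linear"):
        raise ValueError(f"expected count-scale reference, got {ref.scale!r}")
    totals = ref.data.sum(axis=0)
    zero = totals.index[totals <= 0]
    if len(zero):
        raise ValueError(f"reference samples with zero total counts: {list(zero)[:5]}")
    cpm = ref.data * (1e6 / totals)
    if log:
        return ReferenceDataset(np.log2(cpm + pseudo_count), ref.labels, scale="log2cpm")
    return ReferenceDataset(cpm, ref.labels, scale="cpm")


def _one_vs_rest_de(log_data: np.ndarray, in_type: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Welch t-test per gene, type samples vs pooled rest, on log2 values."""
    a = log_data[:, in_type]
    b = log_data[:, ~in_type]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    log_fc = a.mean(axis=1) - b.mean(axis=1)
    return log_fc, p


def select_markers(
    ref: ReferenceDataset,
    k: int = 100,
    fdr_max: float = 0.05,
    *,
    pseudo_count: float = 1.0,
) -> MarkerSet:
    """Select per-type marker genes: FDR gate, then top-k by fold-change.

    For each cell type a one-vs-rest Welch t-test is run per gene on log2
    CPM; p-values are BH-adjusted within the contrast. Genes with FDR below
    ``fdr_max`` and positive fold-change are ranked by descending log2
    fold-change (ties broken by smaller FDR, then gene identifier) and the
    top ``k`` are kept. A type yielding fewer than ``k`` markers is allowed
    with a warning.
    """
    counts = ref.replicate_counts()
    too_few = counts.index[counts < 2]
    if len(too_few):
        raise ValueError(f"cell types with <2 replicates: {list(too_few)}")

    if ref.scale != "log2cpm":
        ref = normalize_reference(ref, log=True, pseudo_count=pseudo_count)
    log_data = ref.data.to_numpy(dtype=float)
    genes = ref.data.index

    sets: dict[str, list[str]] = {}
    meta_rows: list[pd.DataFrame] = []
    for ct in ref.cell_types:
        in_type = (ref.labels == ct).to_numpy()
        log_fc, p = _one_vs_rest_de(log_data, in_type)
        fdr = multipletests(p, method="fdr_bh")[1]
        table = pd.DataFrame(
            {"cell_type": ct, "gene": genes, "log2_fc": log_fc, "fdr": fdr}
        )
        passing = table[(table.fdr < fdr_max) & (table.log2_fc > 0)]
        ranked = passing.sort_values(
            ["log2_fc", "fdr", "gene"], ascending=[False, True, True]
        )
        chosen = ranked.head(k)
        if len(chosen) < k:
            warn_once(
                f"cell type {ct!r}: only {len(chosen)} of {k} requested markers "
                f"pass FDR < {fdr_max}"
            )
        sets[ct] = chosen.gene.tolist()
        meta_rows.append(chosen)

    metadata = pd.concat(meta_rows, ignore_index=True) if meta_rows else None
    return MarkerSet(sets, metadata=metadata)


def remove_overlapping_markers(sets: MarkerSet) -> MarkerSet:
    """Drop every gene that appears in more than one cell type's list.

    The resulting lists are pairwise disjoint (order preserved); this is
    required before deconvolving fine-grained subtypes whose marker lists
    may share genes. Idempotent.
    """
    if len(sets) < 2:
        raise ValueError("need at least 2 marker lists")
    membership: dict[str, int] = {}
    for genes in sets.values():
        for g in genes:
            membership[g] = membership.get(g, 0) + 1
    cleaned = {
        ct: [g for g in genes if membership[g] == 1] for ct, genes in sets.items()
    }
    empty = [ct for ct, genes in cleaned.items() if not genes]
    if empty:
        warn_once(f"cell types left without markers after overlap removal: {empty}")
    return MarkerSet(cleaned, metadata=sets.metadata)


def filter_subtype_markers(
    subtype_sets: MarkerSet,
    parent_ref: ReferenceDataset,
    parent_type: str,
    min_fold: float = 2.0,
) -> MarkerSet:
    """Keep only subtype markers genuinely enriched in the parent cell type.

    Subtype marker lists (e.g. excitatory/inhibitory neurons) derived from
    one dataset may contain genes that are in fact highest in a different
    major cell type. A subtype marker is retained only if its mean
    expression in ``parent_type`` (within ``parent_ref``, linear scale)
    exceeds ``min_fold`` times the maximum mean over the other major types.
    """
    if parent_type not in parent_ref.cell_types:
        raise KeyError(f"unknown parent type {parent_type!r}")
    if parent_ref.scale == "log2cpm":
        raise ValueError("parent reference must be on a linear scale")

    means = parent_ref.data.T.groupby(parent_ref.labels).mean().T  # gene x type
    parent_mean = means[parent_type]
    other_max = means.drop(columns=parent_type).max(axis=1)

    filtered: dict[str, list[str]] = {}
    for ct, genes in subtype_sets.items():
        kept = []
        for g in genes:
            if g not in means.index:
                continue
            if parent_mean[g] > min_fold * other_max[g]:
                kept.append(g)
        filtered[ct] = kept
    return MarkerSet(filtered, metadata=subtype_sets.metadata)
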
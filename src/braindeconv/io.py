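"""Readers and writers for the pipeline's tabular formats.

Matrices travel as TSV/CSV with a header row of sample identifiers and a
first column of feature identifiers (delimiter chosen from the extension).
Marker sets are serialised as GMT (one line per cell type) or two-column
TSV; proportion tables carry a ``# key=value`` comment header recording the
producing method and seed. A YAML manifest records every generation
parameter of a simulated dataset.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .containers import (
    ExpressionMatrix,
    MarkerSet,
    ProportionMatrix,
    ReferenceDataset,
)

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_proportions",
    "write_proportions",
    "read_markers",
    "write_markers_gmt",
    "write_markers_tsv",
    "read_labels",
    "write_manifest",
    "read_manifest",
]

_LOG_SUSPECT_MAX = 30.0


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def _read_frame(path: str | Path, what: str) -> pd.DataFrame:
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), index_col=0, comment="#")
    if frame.empty:
        raise ValueError(f"{what} at {path} is empty")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{what} at {path}: duplicate identifiers {dups[:5]}")
    try:
        frame = frame.astype(float)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{what} at {path}: non-numeric cells ({err})") from None
    return frame


def read_matrix(path: str | Path, kind: str = "expression"):
    """Read a typed matrix from TSV/CSV.

    ``kind`` is one of ``expression`` (returns :class:`ExpressionMatrix`
    with an auto-detected scale tag: a maximum below 30 is taken as
    log2cpm), ``proportions`` (returns :class:`ProportionMatrix`, see
    :func:`read_proportions`) or ``dosage`` (plain DataFrame).
    """
    if kind == "proportions":
        return read_proportions(path)
    frame = _read_frame(path, kind)
    if kind == "expression":
        scale = "log2cpm" if frame.to_numpy().max() < _LOG_SUSPECT_MAX else "counts"
        return ExpressionMatrix(frame, scale=scale)
    if kind == "dosage":
        return frame
    raise ValueError(f"unknown matrix kind {kind!r}")


def write_matrix(obj, path: str | Path) -> Path:
    path = Path(path)
    frame = obj.data if hasattr(obj, "data") else obj
    frame.to_csv(path, sep=_sep_for(path))
    return path


def _comment_header(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for piece in line.lstrip("#").strip().split(","):
                if "=" in piece:
                    key, value = piece.split("=", 1)
                    meta[key.strip()] = value.strip()
    return meta


def read_proportions(path: str | Path, kind: str | None = None) -> ProportionMatrix:
    """Read a proportion table, validating the simplex for estimated ones.

    The table's ``# kind=...`` comment header is honoured unless ``kind``
    overrides it; absent both, the table is treated as measured (no exact
    sum-to-one requirement).
    """
    path = Path(path)
    meta = _comment_header(path)
    frame = _read_frame(path, "proportion matrix")
    resolved = kind or meta.get("kind", "measured")
    return ProportionMatrix(frame, kind=resolved)


def write_proportions(
    props: ProportionMatrix, path: str | Path, **meta: object
) -> Path:
    path = Path(path)
    fields = {"kind": props.kind, **meta}
    header = "# " + ", ".join(f"{k}={v}" for k, v in fields.items())
    with open(path, "w") as fh:
        fh.write(header + "\n")
        props.data.to_csv(fh, sep=_sep_for(path))
    return path


def read_markers(path: str | Path) -> MarkerSet:
    """Read a marker set from GMT or two-column (cell_type, gene) TSV."""
    path = Path(path)
    if path.suffix.lower() == ".gmt":
        sets: dict[str, list[str]] = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = [g for g in parts[2:] if g]
        return MarkerSet(sets)
    table = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if not {"cell_type", "gene"} <= set(table.columns):
        raise ValueError(f"marker TSV {path} lacks cell_type/gene columns")
    sets = {
        str(ct): sub.gene.astype(str).tolist()
        for ct, sub in table.groupby("cell_type", sort=False)
    }
    return MarkerSet(sets)


def write_markers_gmt(markers: MarkerSet, path: str | Path, description: str = "") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for ct, genes in markers.items():
            fh.write("\t".join([ct, description or ct] + list(genes)) + "\n")
    return path


def write_markers_tsv(markers: MarkerSet, path: str | Path) -> Path:
    path = Path(path)
    rows = [(ct, g) for ct, genes in markers.items() for g in genes]
    pd.DataFrame(rows, columns=["cell_type", "gene"]).to_csv(
        path, sep=_sep_for(path), index=False
    )
    return path


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column (sample, cell_type) label table."""
    path = Path(path)
    table = pd.read_csv(path, sep=_sep_for(path), comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"label table {path} needs two columns (sample, cell_type)")
    return pd.Series(
        table.iloc[:, 1].astype(str).to_numpy(), index=table.iloc[:, 0].astype(str)
    )


def reference_to_files(ref: ReferenceDataset, data_path: str | Path, labels_path: str | Path) -> None:
    write_matrix(ref, data_path)
    pd.DataFrame(
        {"sample": ref.labels.index, "cell_type": ref.labels.to_numpy()}
    ).to_csv(labels_path, sep=_sep_for(Path(labels_path)), index=False)


def manifest_hash(params: Mapping) -> str:
    canonical = yaml.safe_dump(dict(params), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def write_manifest(params: Mapping, path: str | Path) -> Path:
    path = Path(path)
    payload = dict(params)
    payload["manifest_hash"] = manifest_hash(params)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
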
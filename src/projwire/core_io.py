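"""Shared data model, validation and on-disk formats.

The pipeline works on a multi-modal single-cell dataset combining three
cell-indexed components — a viral-barcode UMI count matrix (the projectome
readout), a gene-expression matrix, and per-cell spatial/anatomical
metadata — plus a catalog of projection targets.

On-disk conventions
-------------------
``load_dataset`` takes four paths:

* ``barcode_path``: a directory containing either ``counts.csv`` (dense
  cells x barcodes, first column = cell_id) or ``matrix.mtx`` +
  ``cells.tsv`` + ``barcodes.tsv``, plus ``barcode_map.tsv`` with columns
  (barcode_id, target_id).
* ``expr_path``: a directory containing either ``expr.csv`` (dense cells x
  genes) or ``matrix.mtx`` + ``cells.tsv`` + ``genes.tsv``, plus a sidecar
  ``layer.yaml`` declaring ``layer: raw_counts`` or ``layer:
  log_normalized`` (missing sidecar defaults to log_normalized).
* ``meta_path``: a TSV with columns cell_id, ap_mm, dv_mm, ml_mm,
  slice_index, subtype, region.
* ``target_path``: a TSV with columns target_id, class_id (class_id may be
  empty).

Coordinates are millimetres; ap_mm is the distance anterior of Bregma
(larger = more anterior) and dv_mm increases ventrally, so a
"ventral-enriched" population has larger dv_mm.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "TargetCatalog",
    "BarcodeCountMatrix",
    "CellMetadata",
    "ExpressionMatrix",
    "MultiModalDataset",
    "FormatError",
    "AlignmentError",
    "load_dataset",
    "validate_dataset",
    "write_results",
    "read_table",
    "sha256_file",
]

META_COLUMNS = ["cell_id", "ap_mm", "dv_mm", "ml_mm", "slice_index", "subtype", "region"]

# 12 significant digits: round-trip safe for the table values we emit while
# keeping TSV diffs byte-stable across runs.
FLOAT_FORMAT = "%.12g"


class FormatError(ValueError):
    """A file violates the declared on-disk format."""


class AlignmentError(ValueError):
    """Cell-indexed components cannot be aligned."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

def _hemisphere_from_suffix(target_id: str) -> str | None:
    if target_id.endswith("-I"):
        return "ipsilateral"
    if target_id.endswith("-C"):
        return "contralateral"
    return None


@dataclass
class TargetCatalog:
    """Projection targets with hemisphere and optional projection class.

    Hemisphere is parsed from the conventional "-I"/"-C" target-id suffix
    (ipsilateral / contralateral to the traced cortex).
    """

    target_ids: list[str]
    class_ids: dict[str, str | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.target_ids)) != len(self.target_ids):
            raise FormatError("duplicate target_ids in catalog")
        self.hemisphere = {t: _hemisphere_from_suffix(t) for t in self.target_ids}

    @property
    def classes(self) -> list[str]:
        seen: list[str] = []
        for t in self.target_ids:
            c = self.class_ids.get(t)
            if c is not None and c not in seen:
                seen.append(c)
        return seen

    def class_of(self, target_id: str) -> str | None:
        return self.class_ids.get(target_id)


@dataclass
class BarcodeCountMatrix:
    """Raw cells x barcodes UMI counts plus the barcode -> target map."""

    cell_ids: list[str]
    barcode_ids: list[str]
    counts: np.ndarray  # (n_cells, n_barcodes) nonnegative integers
    barcode_to_target: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.barcode_ids)):
            raise FormatError("counts shape does not match cell/barcode ids")

    def violations(self) -> list[str]:
        out = []
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = pd.Index(self.cell_ids)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            out.append(f"duplicate cell_ids: {dupes}")
        if np.any(self.counts < 0):
            r, c = np.argwhere(self.counts < 0)[0]
            out.append(f"negative count at cell {self.cell_ids[r]!r}, barcode {self.barcode_ids[c]!r}")
        if not np.allclose(self.counts, np.round(self.counts)):
            out.append("non-integral barcode counts")
        for b in self.barcode_ids:
            if b not in self.barcode_to_target:
                out.append(f"barcode without target mapping: {b!r}")
        return out


@dataclass
class CellMetadata:
    """Per-cell spatial coordinates (mm), slice, subtype and region."""

    table: pd.DataFrame  # indexed by cell_id

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS[1:] if c not in self.table.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")

    @property
    def cell_ids(self) -> list[str]:
        return list(self.table.index)

    def violations(self) -> list[str]:
        out = []
        if self.table.index.duplicated().any():
            dupes = sorted(set(self.table.index[self.table.index.duplicated()]))
            out.append(f"duplicate cell_ids: {dupes}")
        coords = self.table[["ap_mm", "dv_mm", "ml_mm"]].to_numpy(float)
        if not np.all(np.isfinite(coords)):
            bad = self.table.index[~np.isfinite(coords).all(axis=1)][0]
            out.append(f"non-finite coordinate for cell {bad!r}")
        if (self.table["slice_index"].to_numpy() < 0).any():
            out.append("negative slice_index")
        return out


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix with a declared layer."""

    cell_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray
    layer: str = "log_normalized"  # or "raw_counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise FormatError("expression shape does not match cell/gene ids")
        if self.layer not in ("raw_counts", "log_normalized"):
            raise FormatError(f"unknown expression layer {self.layer!r}")

    def violations(self) -> list[str]:
        out = []
        if len(set(self.gene_ids)) != len(self.gene_ids):
            out.append("duplicate gene_ids")
        if not np.all(np.isfinite(self.values)):
            out.append("non-finite expression values")
        elif np.any(self.values < 0):
            out.append("negative expression values")
        if self.layer == "raw_counts" and not np.allclose(self.values, np.round(self.values)):
            out.append("raw_counts layer not integral")
        return out


@dataclass
class MultiModalDataset:
    """Aligned barcode + expression + metadata + target catalog."""

    barcode: BarcodeCountMatrix
    expr: ExpressionMatrix
    meta: CellMetadata
    targets: TargetCatalog
    n_dropped: int = 0

    @property
    def cell_ids(self) -> list[str]:
        return self.barcode.cell_ids


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _read_id_column(path: str) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def _read_matrix_dir(dirpath: str, dense_name: str, col_file: str):
    """Read a cells-x-features matrix from either a dense CSV or an MTX trio."""
    dense = os.path.join(dirpath, dense_name)
    mtx = os.path.join(dirpath, "matrix.mtx")
    if os.path.exists(dense):
        df = pd.read_csv(dense, index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise FormatError(f"{dense}: malformed numeric value ({exc})") from exc
        return [str(c) for c in df.index], [str(c) for c in df.columns], values
    if os.path.exists(mtx):
        mat = scipy.io.mmread(mtx)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        cells = _read_id_column(os.path.join(dirpath, "cells.tsv"))
        cols = _read_id_column(os.path.join(dirpath, col_file))
        mat = np.asarray(mat, dtype=float)
        if mat.shape != (len(cells), len(cols)):
            raise FormatError(
                f"{mtx}: shape {mat.shape} does not match cells.tsv/{col_file} lengths"
            )
        return cells, cols, mat
    raise FormatError(f"no {dense_name} or matrix.mtx found under {dirpath}")


def _read_barcode_component(dirpath: str) -> BarcodeCountMatrix:
    cells, barcodes, counts = _read_matrix_dir(dirpath, "counts.csv", "barcodes.tsv")
    if np.any(counts < 0):
        r, c = map(int, np.argwhere(counts < 0)[0])
        raise FormatError(
            f"{dirpath}: negative barcode count at row {r + 1} (cell {cells[r]!r}, "
            f"barcode {barcodes[c]!r})"
        )
    if not np.allclose(counts, np.round(counts)):
        raise FormatError(f"{dirpath}: non-integral barcode counts")
    map_path = os.path.join(dirpath, "barcode_map.tsv")
    bmap = pd.read_csv(map_path, sep="\t", dtype=str)
    if not {"barcode_id", "target_id"} <= set(bmap.columns):
        raise FormatError(f"{map_path}: expected columns barcode_id, target_id")
    if bmap["barcode_id"].duplicated().any():
        dupes = sorted(bmap.loc[bmap["barcode_id"].duplicated(), "barcode_id"])
        raise FormatError(f"{map_path}: barcode mapped to multiple targets: {dupes}")
    return BarcodeCountMatrix(
        cell_ids=cells,
        barcode_ids=barcodes,
        counts=counts.astype(np.int64),
        barcode_to_target=dict(zip(bmap["barcode_id"], bmap["target_id"])),
    )


def _read_expr_component(dirpath: str) -> ExpressionMatrix:
    cells, genes, values = _read_matrix_dir(dirpath, "expr.csv", "genes.tsv")
    layer = "log_normalized"
    sidecar = os.path.join(dirpath, "layer.yaml")
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            layer = yaml.safe_load(fh).get("layer", layer)
    return ExpressionMatrix(cell_ids=cells, gene_ids=genes, values=values, layer=layer)


def _read_meta(path: str) -> CellMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "subtype": str, "region": str})
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return CellMetadata(table=df.set_index("cell_id"))


def _read_targets(path: str) -> TargetCatalog:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "target_id" not in df.columns:
        raise FormatError(f"{path}: missing target_id column")
    class_ids = {}
    for _, row in df.iterrows():
        c = row.get("class_id")
        class_ids[row["target_id"]] = None if (c is None or pd.isna(c) or c == "") else c
    return TargetCatalog(target_ids=list(df["target_id"]), class_ids=class_ids)


def load_dataset(barcode_path: str, expr_path: str, meta_path: str, target_path: str) -> MultiModalDataset:
    """Load and align the four dataset components.

    Alignment restricts to the intersection of cell_ids across the
    cell-indexed components, preserving the barcode-matrix cell order, and
    records the number of dropped cells in ``n_dropped``.
    """
    barcode = _read_barcode_component(barcode_path)
    expr = _read_expr_component(expr_path)
    meta = _read_meta(meta_path)
    targets = _read_targets(target_path)

    shared = set(barcode.cell_ids) & set(expr.cell_ids) & set(meta.cell_ids)
    if not shared:
        raise AlignmentError("no cell_ids shared across barcode, expression and metadata")
    order = [c for c in barcode.cell_ids if c in shared]
    n_dropped = (
        len(set(barcode.cell_ids) | set(expr.cell_ids) | set(meta.cell_ids)) - len(shared)
    )

    b_idx = {c: i for i, c in enumerate(barcode.cell_ids)}
    e_idx = {c: i for i, c in enumerate(expr.cell_ids)}
    barcode = BarcodeCountMatrix(
        cell_ids=order,
        barcode_ids=barcode.barcode_ids,
        counts=barcode.counts[[b_idx[c] for c in order]],
        barcode_to_target=barcode.barcode_to_target,
    )
    expr = ExpressionMatrix(
        cell_ids=order,
        gene_ids=expr.gene_ids,
        values=expr.values[[e_idx[c] for c in order]],
        layer=expr.layer,
    )
    meta = CellMetadata(table=meta.table.loc[order])
    return MultiModalDataset(barcode=barcode, expr=expr, meta=meta, targets=targets, n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def validate_dataset(ds: MultiModalDataset) -> list[str]:
    """Return the list of invariant violations (empty list = valid).

    Violations are data, not exceptions; the dataset is never mutated.
    """
    out: list[str] = []
    out.extend(ds.barcode.violations())
    out.extend(ds.expr.violations())
    out.extend(ds.meta.violations())
    for b, t in ds.barcode.barcode_to_target.items():
        if t not in ds.targets.target_ids:
            out.append(f"barcode {b!r} maps to unknown target {t!r}")
    for t, h in ds.targets.hemisphere.items():
        suffix = {"ipsilateral": "-I", "contralateral": "-C"}.get(h)
        if suffix is not None and not t.endswith(suffix):
            out.append(f"target {t!r} hemisphere inconsistent with suffix")
    if ds.barcode.cell_ids != ds.expr.cell_ids or ds.barcode.cell_ids != ds.meta.cell_ids:
        out.append("cell-indexed components disagree on cell order")
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_results(result, path: str, format: str = "tsv") -> None:
    """Write a result table/record with a fixed column order.

    Tables (DataFrames) go to TSV with ``%.12g`` floats (round-trip safe to
    12 significant digits); mappings go to JSON. The index is written as the
    first column when it is named or non-trivial.
    """
    if format == "tsv":
        df = result if isinstance(result, pd.DataFrame) else pd.DataFrame(result)
        write_index = df.index.name is not None or not isinstance(df.index, pd.RangeIndex)
        df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=write_index)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(_jsonable(result), fh, indent=2, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return {"columns": list(obj.columns), "data": _jsonable(obj.to_numpy().tolist())}
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def read_table(path: str) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
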
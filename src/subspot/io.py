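"""Readers and writers for the plain-text and TIFF formats the pipeline touches.

On-disk conventions:

* gene-by-spot counts: MatrixMarket coordinate format with genes in rows
  (10x style), plus ``features.tsv`` (gene per line) and ``barcodes.tsv``
  (spot id per line, default dialect ``{i}x{j}`` with 1-based grid indices);
* cell tables and landmark pairs: CSV;
* masks and channel stacks: (multi-page) TIFF with a plain-text marker-name
  sidecar;
* transforms and configuration: YAML.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy import io as spio
from scipy import sparse

from .transforms import AffineTransform, SimilarityTransform

__all__ = [
    "parse_barcode",
    "read_gene_spot_matrix",
    "write_gene_spot_matrix",
    "read_cell_table",
    "write_cell_table",
    "read_mask_tiff",
    "write_mask_tiff",
    "read_channel_stack",
    "write_channel_stack",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_transform_yaml",
    "write_transform_yaml",
]

CELL_TABLE_REQUIRED = ("cell_id", "x", "y", "area")


def _barcode_regex(dialect: str) -> re.Pattern:
    pattern = re.escape(dialect).replace(r"\{i\}", r"(?P<i>\d+)").replace(r"\{j\}", r"(?P<j>\d+)")
    return re.compile(f"^{pattern}$")


def parse_barcode(barcode: str, dialect: str = "{i}x{j}") -> tuple[int, int]:
    """Parse a spot barcode into 0-based (i, j) grid indices.

    The default dialect is ``"{i}x{j}"`` with 1-based printed indices, e.g.
    ``"12x34"`` -> ``(11, 33)``.
    """
    m = _barcode_regex(dialect).match(barcode)
    if not m:
        raise ValueError(f"barcode {barcode!r} does not match dialect {dialect!r}")
    return int(m.group("i")) - 1, int(m.group("j")) - 1


def read_gene_spot_matrix(
    mtx_path,
    features_path,
    barcodes_path,
    dialect: str = "{i}x{j}",
) -> pd.DataFrame:
    """Read a gene-by-spot MatrixMarket triplet into a spots x genes DataFrame.

    On disk genes are rows and spots columns (10x style); in memory the
    matrix is always spots x genes, indexed by the barcode strings. Every
    barcode must parse under the dialect; the row index carries the parsed
    grid indices in ``df.attrs["grid_indices"]``. Spots present in the file
    are by definition tissue-covered.
    """
    try:
        mat = spio.mmread(str(mtx_path))
    except Exception as exc:
        raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    genes = Path(features_path).read_text().splitlines()
    genes = [g.split("\t")[0] for g in genes if g]
    barcodes = [b for b in Path(barcodes_path).read_text().splitlines() if b]
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if dense.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match {len(genes)} features x {len(barcodes)} barcodes"
        )
    indices = []
    for line_no, bc in enumerate(barcodes, start=1):
        try:
            indices.append(parse_barcode(bc, dialect))
        except ValueError as exc:
            raise ValueError(f"{barcodes_path}, line {line_no}: {exc}") from exc
    df = pd.DataFrame(dense.T, index=pd.Index(barcodes, name="spot"), columns=genes)
    df.attrs["grid_indices"] = indices
    df.attrs["dialect"] = dialect
    return df


def write_gene_spot_matrix(matrix: pd.DataFrame, mtx_path, features_path, barcodes_path) -> None:
    """Write a spots x genes DataFrame as a genes-in-rows MatrixMarket triplet."""
    vals = matrix.to_numpy()
    is_int = np.issubdtype(vals.dtype, np.integer) or np.allclose(vals, np.round(vals))
    coo = sparse.coo_matrix(vals.T.astype(np.int64 if is_int else float))
    spio.mmwrite(str(mtx_path), coo, field="integer" if is_int else "real")
    Path(features_path).write_text("\n".join(str(g) for g in matrix.columns) + "\n")
    Path(barcodes_path).write_text("\n".join(str(b) for b in matrix.index) + "\n")


def read_cell_table(path, require_label: bool = False) -> pd.DataFrame:
    """Read a cell table CSV; raises naming any missing required column."""
    df = pd.read_csv(path)
    required = CELL_TABLE_REQUIRED + (("label",) if require_label else ())
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing required column(s): {missing}")
    return df


def write_cell_table(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, index=False)


def write_mask_tiff(mask: np.ndarray, path) -> None:
    """Write a mask (bool -> uint8 0/1) or integer label image as TIFF."""
    arr = np.asarray(mask)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    tifffile.imwrite(str(path), arr)


def read_mask_tiff(path, as_bool: bool = False) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr.astype(bool) if as_bool else arr


def write_channel_stack(stack: np.ndarray, marker_names: list[str], tiff_path, names_path) -> None:
    """Write a (n_markers, H, W) stack as a multi-page TIFF plus a names sidecar."""
    stack = np.asarray(stack)
    if stack.shape[0] != len(marker_names):
        raise ValueError(f"{stack.shape[0]} pages but {len(marker_names)} marker names")
    tifffile.imwrite(str(tiff_path), stack)
    Path(names_path).write_text("\n".join(marker_names) + "\n")


def read_channel_stack(tiff_path, names_path) -> tuple[np.ndarray, list[str]]:
    stack = tifffile.imread(str(tiff_path))
    names = [n for n in Path(names_path).read_text().splitlines() if n]
    if stack.ndim == 2:
        stack = stack[None]
    if stack.shape[0] != len(names):
        raise ValueError(f"stack has {stack.shape[0]} pages but sidecar lists {len(names)} markers")
    return stack, names


def read_landmarks_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read matched landmark pairs from CSV with columns ax, ay, bx, by."""
    df = pd.read_csv(path)
    missing = [c for c in ("ax", "ay", "bx", "by") if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file {path} is missing column(s): {missing}")
    return df[["ax", "ay"]].to_numpy(dtype=float), df[["bx", "by"]].to_numpy(dtype=float)


def write_landmarks_csv(points_a: np.ndarray, points_b: np.ndarray, path) -> None:
    pd.DataFrame(
        {
            "ax": np.asarray(points_a)[:, 0],
            "ay": np.asarray(points_a)[:, 1],
            "bx": np.asarray(points_b)[:, 0],
            "by": np.asarray(points_b)[:, 1],
        }
    ).to_csv(path, index=False)


def write_transform_yaml(transform: SimilarityTransform | AffineTransform, path, extra: Optional[dict] = None) -> None:
    doc: dict = {"kind": "similarity" if isinstance(transform, SimilarityTransform) else "affine"}
    doc.update(transform.to_dict())
    if extra:
        doc.update(extra)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_transform_yaml(path) -> SimilarityTransform | AffineTransform:
    doc = yaml.safe_load(Path(path).read_text())
    if doc.get("kind") == "similarity":
        return SimilarityTransform.from_dict(doc)
    if doc.get("kind") == "affine":
        return AffineTransform.from_dict(doc)
    raise ValueError(f"unknown transform kind in {path}: {doc.get('kind')!r}")
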
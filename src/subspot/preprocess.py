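"""Per-cell protein quantification from a segmentation mask and channel stack.

The imaging side arrives as a label image (0 = background, positive integers =
cells, e.g. from Mesmer) plus one intensity image per antibody marker. Features
are extracted by *summing* each channel over each cell's pixels; cells are then
filtered on size (inside the [0.05, 0.95] area quantile range) and nuclear
signal (raw DAPI strictly above its 0.1 quantile); finally each marker is
scaled to [0, 1] by mapping its 0.05 quantile to 0 and its 0.95 quantile to 1,
clipping outside.

Quantiles use linear interpolation between order statistics throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

__all__ = ["extract_cell_features", "filter_cells", "scale_features", "ProteinMatrix", "marker_columns"]

RESERVED_COLUMNS = ("cell_id", "x", "y", "area", "label", "spot")


def marker_columns(cells: pd.DataFrame) -> list[str]:
    """Marker columns of a cell table = everything that is not a reserved field."""
    return [c for c in cells.columns if c not in RESERVED_COLUMNS]


def extract_cell_features(label_mask: np.ndarray, channels: np.ndarray, marker_names: list[str]) -> pd.DataFrame:
    """Sum each channel over each labelled cell.

    Parameters
    ----------
    label_mask:
        2D integer image; 0 is background, each positive value one cell.
    channels:
        3D stack ``(n_markers, H, W)`` of intensity images sharing the mask shape.
    marker_names:
        One name per channel, in stack order.

    Returns
    -------
    A cell table with one row per label: ``cell_id``, centroid ``x``/``y``
    (0-based pixel centers, x along columns), ``area`` in px^2, and one summed
    intensity column per marker.
    """
    label_mask = np.asarray(label_mask)
    channels = np.asarray(channels)
    if channels.ndim == 2:
        channels = channels[None]
    if channels.shape[0] != len(marker_names):
        raise ValueError(f"{channels.shape[0]} channels but {len(marker_names)} marker names")
    if channels.shape[1:] != label_mask.shape:
        raise ValueError(f"channel shape {channels.shape[1:]} != mask shape {label_mask.shape}")
    if label_mask.min() < 0:
        raise ValueError("label mask must be nonnegative")
    ids = np.unique(label_mask)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("label mask contains no cells (no positive labels)")
    area = ndi.sum_labels(np.ones_like(label_mask, dtype=np.int64), label_mask, ids)
    com = ndi.center_of_mass(np.ones(label_mask.shape), label_mask, ids)  # (row, col)
    com = np.asarray(com, dtype=float)
    df = pd.DataFrame({"cell_id": ids.astype(int), "x": com[:, 1], "y": com[:, 0], "area": area.astype(float)})
    for name, chan in zip(marker_names, channels):
        df[name] = ndi.sum_labels(chan.astype(np.float64), label_mask, ids)
    return df


def filter_cells(
    cells: pd.DataFrame,
    size_quantiles: tuple[float, float] = (0.05, 0.95),
    dapi_marker: str = "DAPI",
    dapi_quantile: float = 0.1,
) -> pd.DataFrame:
    """Keep cells inside the size-quantile band and above the DAPI quantile.

    Size bounds are inclusive; the DAPI bound is strict (``>``), both
    evaluated against quantiles of the *input* table. If DAPI is constant the
    strict rule would discard every cell, so that degenerate case keeps all
    cells and emits a warning instead.
    """
    if dapi_marker not in cells.columns:
        raise ValueError(f"DAPI marker column {dapi_marker!r} not present")
    if len(cells) < 2:
        raise ValueError("need at least 2 cells to compute quantiles")
    q_lo, q_hi = np.quantile(cells["area"], size_quantiles)  # linear interpolation
    keep = (cells["area"] >= q_lo) & (cells["area"] <= q_hi)
    dapi = cells[dapi_marker].to_numpy(dtype=float)
    thr = np.quantile(dapi, dapi_quantile)
    dapi_keep = dapi > thr
    if not dapi_keep.any():
        warnings.warn(
            f"DAPI filter at quantile {dapi_quantile} would remove every cell "
            "(constant or tied values); keeping all cells",
            stacklevel=2,
        )
        dapi_keep = np.ones(len(cells), dtype=bool)
    return cells.loc[keep & dapi_keep].reset_index(drop=True)


@dataclass
class ProteinMatrix:
    """Cells-by-markers values scaled to [0, 1], with per-marker scaling anchors.

    ``anchors`` has one row per marker with the raw values mapped to 0
    (``q05``) and 1 (``q95``); a marker whose two anchors coincide is
    degenerate and scaled to all zeros.
    """

    values: pd.DataFrame  # index cell_id, columns markers
    anchors: pd.DataFrame  # index marker, columns q05/q95

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("scaled protein values must lie in [0, 1]")


def scale_features(
    cells: pd.DataFrame,
    area_normalize: bool = True,
    q_low: float = 0.05,
    q_high: float = 0.95,
) -> ProteinMatrix:
    """Quantile-scale each marker to [0, 1].

    With ``area_normalize`` each cell's summed intensities are first divided
    by its area (signal density rather than total); then per marker the
    ``q_low`` quantile maps to 0 and ``q_high`` to 1, values outside clipped.
    A constant marker (coincident anchors) maps to all zeros with a warning.
    """
    if q_low >= q_high:
        raise ValueError(f"q_low must be < q_high, got {q_low} >= {q_high}")
    markers = marker_columns(cells)
    if not markers:
        raise ValueError("cell table has no marker columns")
    raw = cells[markers].to_numpy(dtype=float)
    if area_normalize:
        raw = raw / cells["area"].to_numpy(dtype=float)[:, None]
    lo = np.quantile(raw, q_low, axis=0)
    hi = np.quantile(raw, q_high, axis=0)
    scaled = np.zeros_like(raw)
    for m, name in enumerate(markers):
        if hi[m] <= lo[m]:
            warnings.warn(f"marker {name!r} has coincident scaling anchors; scaled to 0", stacklevel=2)
            continue
        scaled[:, m] = np.clip((raw[:, m] - lo[m]) / (hi[m] - lo[m]), 0.0, 1.0)
    values = pd.DataFrame(scaled, index=pd.Index(cells["cell_id"], name="cell_id"), columns=markers)
    anchors = pd.DataFrame({"q05": lo, "q95": hi}, index=pd.Index(markers, name="marker"))
    return ProteinMatrix(values=values, anchors=anchors)
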
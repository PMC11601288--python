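"""The deterministic-barcoding spot lattice.

Two orthogonal sets of microfluidic channels (A and B, 50 each on the standard
chip) deliver spatial barcodes; their intersections define a square array of
barcoded spots. Each spot is a square of side ``channel_width`` centred on the
lattice point ``origin + (i * pitch, j * pitch)``; the strip of tissue between
channels ("dead space") belongs to no spot. Cells registered into the spot
frame are assigned to spots by centroid, and per-spot cell-type proportions
(beta) are computed from the assigned, labelled cells.

All spot-frame coordinates are in micrometres; spot extents are half-open
``[lo, lo + width)`` so every point belongs to at most one spot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChannelLayout",
    "build_spot_grid",
    "spot_name",
    "assign_cells_to_spots",
    "SpotComposition",
    "compute_composition",
]


@dataclass(frozen=True)
class ChannelLayout:
    """Geometry of the two-axis microfluidic barcoding chip.

    Parameters
    ----------
    n_a, n_b:
        Number of A-axis (x) and B-axis (y) channels; the standard chip has 50
        each, giving 2,500 spots.
    channel_width:
        Channel (= spot) width in micrometres; chips are fabricated at 10, 20,
        25 or 50 um.
    pitch:
        Centre-to-centre channel spacing in micrometres. Defaults to
        ``2 * channel_width`` (equal channel and gap widths).
    origin_xy:
        Centre of spot (0, 0) in micrometres.
    """

    n_a: int = 50
    n_b: int = 50
    channel_width: float = 25.0
    pitch: Optional[float] = None
    origin_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.n_a < 1 or self.n_b < 1:
            raise ValueError("n_a and n_b must be >= 1")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")
        if self.pitch is None:
            object.__setattr__(self, "pitch", 2.0 * self.channel_width)
        if not (0 < self.channel_width <= self.pitch):
            raise ValueError(f"need 0 < channel_width <= pitch, got width={self.channel_width} pitch={self.pitch}")
        object.__setattr__(self, "origin_xy", tuple(float(v) for v in self.origin_xy))


def spot_name(i: int, j: int, dialect: str = "{i}x{j}") -> str:
    """Barcode-style spot id from 0-based grid indices (1-based in the name)."""
    return dialect.format(i=i + 1, j=j + 1)


def build_spot_grid(layout: ChannelLayout, dialect: str = "{i}x{j}") -> pd.DataFrame:
    """Enumerate the spot lattice.

    Returns a DataFrame with one row per spot: ``spot`` (barcode-style id),
    0-based indices ``i``/``j``, centre coordinates ``x``/``y`` in um, the
    square ``width`` and a ``tissue`` flag (initially True everywhere; callers
    restrict it to the spots present in a count matrix).
    """
    ii, jj = np.meshgrid(np.arange(layout.n_a), np.arange(layout.n_b), indexing="ij")
    ii, jj = ii.ravel(), jj.ravel()
    ox, oy = layout.origin_xy
    df = pd.DataFrame(
        {
            "spot": [spot_name(i, j, dialect) for i, j in zip(ii, jj)],
            "i": ii,
            "j": jj,
            "x": ox + ii * layout.pitch,
            "y": oy + jj * layout.pitch,
            "width": layout.channel_width,
            "tissue": True,
        }
    )
    df.attrs["layout"] = layout
    return df


def _layout_from_spots(spots: pd.DataFrame) -> ChannelLayout:
    layout = spots.attrs.get("layout")
    if isinstance(layout, ChannelLayout):
        return layout
    # Reconstruct from the table: centres are origin + index * pitch.
    width = float(spots["width"].iloc[0])
    ox = float(spots.loc[spots["i"] == 0, "x"].iloc[0])
    oy = float(spots.loc[spots["j"] == 0, "y"].iloc[0])
    n_a = int(spots["i"].max()) + 1
    n_b = int(spots["j"].max()) + 1
    if n_a > 1:
        pitch = (spots["x"].max() - ox) / (n_a - 1)
    elif n_b > 1:
        pitch = (spots["y"].max() - oy) / (n_b - 1)
    else:
        pitch = 2.0 * width
    return ChannelLayout(n_a, n_b, width, float(pitch), (ox, oy))


def assign_cells_to_spots(cells: pd.DataFrame, spots: pd.DataFrame) -> pd.Series:
    """Map each cell to the spot whose half-open square contains its centroid.

    ``cells`` must carry ``x``/``y`` columns in the spot frame (micrometres,
    i.e. already registered). Cells in the inter-channel dead space, or outside
    the grid, map to NA. Raises if *every* cell falls outside the grid
    bounding box, which indicates a coordinate-frame mismatch.
    """
    layout = _layout_from_spots(spots)
    ox, oy = layout.origin_xy
    w, pitch = layout.channel_width, layout.pitch
    x = cells["x"].to_numpy(dtype=float)
    y = cells["y"].to_numpy(dtype=float)

    # Spot i covers [origin + i*pitch - w/2, origin + i*pitch - w/2 + w).
    def channel_index(coord, origin, n):
        u = coord - (origin - w / 2.0)
        idx = np.floor(u / pitch).astype(int)
        offset = u - idx * pitch
        inside = (offset >= 0) & (offset < w) & (idx >= 0) & (idx < n)
        return idx, inside

    ix, in_x = channel_index(x, ox, layout.n_a)
    iy, in_y = channel_index(y, oy, layout.n_b)

    lo_x, hi_x = ox - w / 2.0, ox + (layout.n_a - 1) * pitch + w / 2.0
    lo_y, hi_y = oy - w / 2.0, oy + (layout.n_b - 1) * pitch + w / 2.0
    in_bbox = (x >= lo_x) & (x < hi_x) & (y >= lo_y) & (y < hi_y)
    if len(cells) > 0 and not in_bbox.any():
        raise ValueError(
            "all cells fall outside the spot-grid bounding box "
            f"[{lo_x}, {hi_x}) x [{lo_y}, {hi_y}); cells and spots are probably "
            "in different coordinate frames (register and convert px to um first)"
        )

    assigned = in_x & in_y
    spot_ids = pd.Series(pd.NA, index=cells["cell_id"], dtype="object", name="spot")
    dialect = spots.attrs.get("dialect", "{i}x{j}")
    known = set(spots["spot"])
    names = np.array([spot_name(i, j, dialect) for i, j in zip(ix[assigned], iy[assigned])], dtype=object)
    keep = np.array([n in known for n in names], dtype=bool)
    idx = np.flatnonzero(assigned)[keep]
    spot_ids.iloc[idx] = names[keep]
    return spot_ids


@dataclass
class SpotComposition:
    """Per-spot cell-type composition from imaging cells registered into spots.

    ``beta`` holds the proportions beta[i, k] (rows sum to 1); ``n_cells``
    holds the integer per-spot per-type counts. Only spots with at least one
    assigned cell appear as rows; spots without cells are *undefined*, listed
    in ``undefined_spots``, and must be skipped downstream rather than treated
    as zero.
    """

    beta: pd.DataFrame
    n_cells: pd.DataFrame
    undefined_spots: list

    def __post_init__(self):
        totals = self.beta.sum(axis=1)
        if len(totals) and not np.allclose(totals, 1.0, atol=1e-12, rtol=0):
            raise ValueError("beta rows must sum to 1")

    @property
    def types(self) -> list:
        return list(self.beta.columns)


def compute_composition(
    assignment: pd.Series,
    labels: pd.Series,
    types: Optional[Sequence[str]] = None,
    all_spots: Optional[Sequence[str]] = None,
) -> SpotComposition:
    """Compute beta[i, k] = n[i, k] / sum_k n[i, k] over assigned, labelled cells.

    Parameters
    ----------
    assignment:
        cell_id -> spot id (NA for dead-space cells), as from
        :func:`assign_cells_to_spots`.
    labels:
        cell_id -> cell-type label; every assigned cell must be labelled.
    types:
        Optional full type universe (columns of beta); defaults to the labels seen.
    all_spots:
        Optional full spot universe used to report undefined (cell-free) spots.
    """
    mapped = assignment.dropna()
    lab = labels.reindex(mapped.index)
    if lab.isna().any():
        bad = list(lab.index[lab.isna()][:5])
        raise ValueError(f"assigned cells without a type label, e.g. {bad}")
    counts = pd.crosstab(mapped, lab)
    counts.index.name = "spot"
    if types is not None:
        missing = set(counts.columns) - set(types)
        if missing:
            raise ValueError(f"labels outside the declared type set: {sorted(missing)}")
        counts = counts.reindex(columns=list(types), fill_value=0)
    counts = counts.sort_index()
    beta = counts.div(counts.sum(axis=1), axis=0)
    undefined = []
    if all_spots is not None:
        undefined = sorted(set(all_spots) - set(counts.index))
    return SpotComposition(beta=beta, n_cells=counts, undefined_spots=undefined)
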
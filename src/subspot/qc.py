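"""Cross-section imaging quality control by spatial binning and correlation.

Running the sequencing chemistry over a stained section can degrade the
subsequent imaging round; to quantify how much, two aligned cell tables
(e.g. adjacent sections, one imaged before and one after sequencing) are
compared. After landmark-based alignment, cell positions are discretised into
square bins (100 px by default), per-bin mean marker values are computed, and
the per-marker Pearson correlation over bins present in both datasets
measures agreement.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["bin_features", "correlate_bins"]


def bin_features(cells: pd.DataFrame, markers: list[str], bin_size_px: float = 100.0) -> pd.DataFrame:
    """Mean marker values per spatial bin.

    A cell at (x, y) falls in bin ``(floor(y / bin), floor(x / bin))``; bins
    are anchored at the common frame's origin, and negative coordinates floor
    consistently (toward minus infinity). Empty bins are absent. The returned
    frame is indexed by (row, col) and carries one mean column per marker plus
    the member count ``n``.
    """
    if bin_size_px <= 0:
        raise ValueError("bin_size_px must be positive")
    if len(cells) == 0:
        raise ValueError("no cells to bin")
    missing = [m for m in markers if m not in cells.columns]
    if missing:
        raise ValueError(f"markers not present in the cell table: {missing}")
    row = np.floor(cells["y"].to_numpy(dtype=float) / bin_size_px).astype(int)
    col = np.floor(cells["x"].to_numpy(dtype=float) / bin_size_px).astype(int)
    grouped = cells[markers].groupby([row, col], sort=True)
    out = grouped.mean()
    out["n"] = grouped.size()
    out.index.names = ["row", "col"]
    return out


def correlate_bins(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Per-marker Pearson correlation over bins present in both tables.

    Markers are the columns shared by both tables (``n`` excluded). A marker
    that is constant over the common bins in either table has no defined
    correlation; it gets ``r = NaN`` and ``constant = True`` rather than a
    silent value. Raises if fewer than three common bins exist.
    """
    markers = [c for c in a.columns if c in b.columns and c != "n"]
    if not markers:
        raise ValueError("no shared marker columns to correlate")
    common = a.index.intersection(b.index)
    if len(common) < 3:
        raise ValueError(f"need at least 3 common bins, got {len(common)}")
    rows = []
    for m in markers:
        va = a.loc[common, m].to_numpy(dtype=float)
        vb = b.loc[common, m].to_numpy(dtype=float)
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            rows.append({"marker": m, "r": np.nan, "n_common": len(common), "constant": True})
        else:
            r = stats.pearsonr(va, vb).statistic
            rows.append({"marker": m, "r": float(r), "n_common": len(common), "constant": False})
    return pd.DataFrame(rows).set_index("marker")
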
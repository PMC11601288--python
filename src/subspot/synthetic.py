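"""Synthetic paired imaging + spot-count datasets with known ground truth.

The generative model mirrors the data model the splitting formula assumes: a
tissue section carries cells of K types; each cell has type-specific protein
marker intensities (imaging side); each barcoded spot's gene counts are a
Poisson mixture over the cells truly inside it,

    x[i, j] ~ Poisson( d_i * sum_k n[i, k] * p[k, j] ),

where ``n[i, k]`` is the number of type-k cells in spot i, ``p`` is
``mu_true`` with rows normalised to sum to 1, and the per-spot depth factor
``d_i`` is set so that the expected spot total equals ``depth`` (so
``d_i = depth / n_i``). A spot with no cells yields all-zero counts.

Everything is deterministic under explicit integer seeds; there is no global
random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import draw as skdraw
from skimage import morphology

from .grid import ChannelLayout, assign_cells_to_spots, build_spot_grid
from .transforms import SimilarityTransform

__all__ = [
    "SyntheticTruth",
    "default_truth",
    "generate_tissue_mask",
    "generate_cells",
    "generate_spot_counts",
    "generate_transformed_copy",
    "render_images",
    "simulate_dataset",
]

MARKER_HIGH = 100.0  # mean summed intensity of a type's own marker
MARKER_LOW = 10.0  # off-target marker mean
DAPI_MEAN = 50.0  # nuclear stain, shared across types


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters of a simulated paired dataset.

    ``mu_true`` is the type-by-gene mean expression (types x genes DataFrame);
    ``protein_means`` the type-by-marker mean intensities. ``transform_true``
    maps imaging pixel coordinates into the spot frame (micrometres); its
    scale therefore carries the px -> um conversion. ``depth`` is the expected
    UMI total per occupied spot.
    """

    cell_types: tuple[str, ...]
    type_proportions: tuple[float, ...]
    mu_true: pd.DataFrame
    protein_means: pd.DataFrame
    transform_true: SimilarityTransform
    depth: float = 2000.0
    seed: int = 0
    protein_noise_sigma: float = 0.25  # lognormal sigma of per-cell marker noise
    area_meanlog: float = np.log(120.0)  # cell area ~ lognormal, px^2
    area_sdlog: float = 0.35

    def __post_init__(self):
        props = np.asarray(self.type_proportions, dtype=float)
        if props.min() < 0 or abs(props.sum() - 1.0) > 1e-12:
            raise ValueError("type_proportions must be nonnegative and sum to 1")
        if (self.mu_true.to_numpy() < 0).any():
            raise ValueError("mu_true must be nonnegative")
        if (self.protein_means.to_numpy() < 0).any():
            raise ValueError("protein_means must be nonnegative")
        for df, what in ((self.mu_true, "mu_true"), (self.protein_means, "protein_means")):
            if list(df.index) != list(self.cell_types):
                raise ValueError(f"{what} rows must match cell_types")

    @property
    def markers(self) -> list[str]:
        return list(self.protein_means.columns)


def default_truth(
    n_types: int = 4,
    n_genes: int = 200,
    depth: float = 2000.0,
    seed: int = 0,
    transform: Optional[SimilarityTransform] = None,
) -> SyntheticTruth:
    """The stated simulation world: 4 types, 200 genes, expected depth 2000.

    Type proportions are a fixed uneven mix; per-type gene means are gamma
    draws so every type has a distinct expression profile; protein means are
    a near-diagonal design (one bright marker per type plus DAPI), the
    idealised outcome of a well-chosen antibody panel.
    """
    rng = np.random.default_rng(seed)
    types = tuple(f"type{chr(ord('A') + k)}" for k in range(n_types))
    base = np.array([0.4, 0.3, 0.2, 0.1, 0.05, 0.05])
    props = base[:n_types] / base[:n_types].sum()
    genes = [f"gene{j:04d}" for j in range(n_genes)]
    mu = pd.DataFrame(rng.gamma(shape=2.0, scale=1.0, size=(n_types, n_genes)), index=list(types), columns=genes)
    markers = ["DAPI"] + [f"M_{t}" for t in types]
    pm = np.full((n_types, len(markers)), MARKER_LOW)
    pm[:, 0] = DAPI_MEAN
    for k in range(n_types):
        pm[k, 1 + k] = MARKER_HIGH
    protein_means = pd.DataFrame(pm, index=list(types), columns=markers)
    if transform is None:
        # px -> um: 4.5 um per px, a small section tilt, modest offset.
        transform = SimilarityTransform(rotation_deg=5.0, scale=4.5, translation_xy=(-30.0, 20.0))
    return SyntheticTruth(
        cell_types=types,
        type_proportions=tuple(props),
        mu_true=mu,
        protein_means=protein_means,
        transform_true=transform,
        depth=depth,
        seed=seed,
    )


def generate_tissue_mask(shape_px: tuple[int, int], n_blobs: int = 3, seed: int = 0) -> np.ndarray:
    """A connected, hole-free blob-shaped tissue mask covering 20-80% of the image.

    Blobs are overlapping discs: the first sits near the image centre and each
    subsequent disc is centred inside the union built so far, which guarantees
    a single connected component; hole filling guarantees no holes.
    """
    shape = tuple(int(v) for v in shape_px)
    if len(shape) != 2 or min(shape) < 64:
        raise ValueError(f"shape_px must be at least (64, 64), got {shape}")
    if n_blobs < 1:
        raise ValueError("n_blobs must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = shape
    mask = np.zeros(shape, dtype=bool)
    base_r = 0.32 * min(h, w) / np.sqrt(n_blobs) * np.sqrt(2.0)
    cy, cx = h / 2.0, w / 2.0
    for b in range(n_blobs):
        if b == 0:
            yc, xc = cy + rng.uniform(-0.05, 0.05) * h, cx + rng.uniform(-0.05, 0.05) * w
        else:
            ys, xs = np.nonzero(mask)
            pick = rng.integers(len(ys))
            yc, xc = float(ys[pick]), float(xs[pick])
        r = base_r * rng.uniform(0.7, 1.1)
        rr, cc = skdraw.disk((yc, xc), r, shape=shape)
        mask[rr, cc] = True
    mask = ndi.binary_fill_holes(mask)
    # Nudge the foreground fraction into [0.2, 0.8] if the draws were extreme.
    frac = mask.mean()
    while frac < 0.2:
        mask = morphology.binary_dilation(mask, morphology.disk(3))
        frac = mask.mean()
    while frac > 0.8:
        mask = morphology.binary_erosion(mask, morphology.disk(3))
        mask = ndi.binary_fill_holes(mask)
        frac = mask.mean()
    return mask


def generate_cells(mask: np.ndarray, n_cells: int, truth: SyntheticTruth, seed: Optional[int] = None) -> pd.DataFrame:
    """Sample cells inside the tissue mask with true type labels.

    Centroids are drawn uniformly over foreground pixels (so
    ``mask[y, x]`` is always True); types are i.i.d. from
    ``truth.type_proportions``; each marker intensity is a mean-preserving
    lognormal perturbation of ``protein_means[type, marker]``; areas are
    lognormal in px^2. Returns a cell table with columns
    ``cell_id, x, y, area, label`` plus one column per marker.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        raise ValueError("mask has no foreground")
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if n_cells > len(ys):
        raise ValueError(f"cannot place {n_cells} cells on {len(ys)} foreground pixels")
    pick = rng.choice(len(ys), size=n_cells, replace=False)  # distinct centroid pixels
    # sub-pixel jitter keeps centroids continuous (floor-indexing stays on the pixel)
    x = xs[pick] + rng.uniform(0.0, 0.5, n_cells)
    y = ys[pick] + rng.uniform(0.0, 0.5, n_cells)
    k = rng.choice(len(truth.cell_types), size=n_cells, p=np.asarray(truth.type_proportions))
    labels = np.asarray(truth.cell_types, dtype=object)[k]
    area = np.exp(rng.normal(truth.area_meanlog, truth.area_sdlog, size=n_cells))
    means = truth.protein_means.to_numpy()[k]  # n_cells x markers
    sig = truth.protein_noise_sigma
    if sig > 0:
        noise = np.exp(rng.normal(0.0, sig, size=means.shape) - sig**2 / 2.0)
        values = means * noise
    else:
        values = means.copy()
    df = pd.DataFrame({"cell_id": np.arange(1, n_cells + 1), "x": x, "y": y, "area": area, "label": labels})
    for m, col in zip(truth.markers, values.T):
        df[m] = col
    return df


def generate_spot_counts(
    spots: pd.DataFrame,
    assignment: pd.Series,
    labels: pd.Series,
    truth: SyntheticTruth,
    seed: Optional[int] = None,
    return_truth: bool = False,
):
    """Draw the gene-by-spot count matrix from the Poisson mixture model.

    Counts are drawn per (spot, type) component and summed, so the realised
    per-type contribution is known exactly; with ``return_truth`` the per-type
    gene totals (types x genes, summed over spots) are returned alongside.
    Spots with no assigned cells get all-zero rows.
    """
    rng = np.random.default_rng(truth.seed + 1 if seed is None else seed)
    mapped = assignment.dropna()
    lab = labels.reindex(mapped.index)
    if lab.isna().any():
        raise ValueError("every assigned cell needs a true type label")
    unknown = set(lab.unique()) - set(truth.cell_types)
    if unknown:
        raise ValueError(f"labels not covered by mu_true: {sorted(unknown)}")
    counts_kt = pd.crosstab(mapped, lab).reindex(columns=list(truth.cell_types), fill_value=0)
    spot_ids = list(spots["spot"])  # empty spots keep an all-zero row
    counts_kt = counts_kt.reindex(spot_ids, fill_value=0)

    mu = truth.mu_true.to_numpy(dtype=float)
    p = mu / mu.sum(axis=1, keepdims=True)  # rows sum to 1
    n_ik = counts_kt.to_numpy(dtype=float)  # spots x types
    n_i = n_ik.sum(axis=1)
    d_i = np.where(n_i > 0, truth.depth / np.maximum(n_i, 1.0), 0.0)
    # rate[i, k, j] = d_i * n_ik * p_kj; drawn per type so truth is observable
    genes = list(truth.mu_true.columns)
    x = np.zeros((len(spot_ids), len(genes)), dtype=np.int64)
    per_type_totals = np.zeros((len(truth.cell_types), len(genes)), dtype=np.int64)
    for k in range(len(truth.cell_types)):
        rate = (d_i * n_ik[:, k])[:, None] * p[k][None, :]
        draw = rng.poisson(rate)
        x += draw
        per_type_totals[k] = draw.sum(axis=0)
    matrix = pd.DataFrame(x, index=pd.Index(spot_ids, name="spot"), columns=genes)
    # spots in the grid but with zero cells: all-zero rows, flagged non-tissue downstream
    if return_truth:
        truth_totals = pd.DataFrame(per_type_totals, index=list(truth.cell_types), columns=genes)
        return matrix, truth_totals
    return matrix


def generate_transformed_copy(
    cells: pd.DataFrame,
    transform: SimilarityTransform,
    intensity_noise_sd: float = 0.0,
    seed: int = 0,
    markers: Optional[list[str]] = None,
) -> pd.DataFrame:
    """An adjacent-section stand-in: same cells, moved and re-measured.

    Positions are mapped through ``transform``; marker values get additive
    Gaussian noise truncated at zero. Used as the fixture for the binned
    cross-section correlation QC.
    """
    rng = np.random.default_rng(seed)
    out = cells.copy()
    xy = out[["x", "y"]].to_numpy(dtype=float)
    out[["x", "y"]] = transform.apply(xy)
    if markers is None:
        reserved = {"cell_id", "x", "y", "area", "label", "spot"}
        markers = [c for c in cells.columns if c not in reserved]
    if intensity_noise_sd > 0:
        vals = out[markers].to_numpy(dtype=float)
        vals = np.maximum(vals + rng.normal(0.0, intensity_noise_sd, size=vals.shape), 0.0)
        out[markers] = vals
    return out


def render_images(
    cells: pd.DataFrame,
    shape_px: tuple[int, int],
    markers: Optional[list[str]] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint cells into a label mask and per-marker channel stack.

    Pixels are partitioned among cells like a segmentation would: each pixel
    belongs to its nearest cell centroid, provided it lies within that cell's
    nominal radius (from its lognormal area). Every cell keeps at least its
    centroid pixel, so no cell is lost to crowding. Per-pixel channel values
    are ``marker_total / painted_area``, so summing a channel over a cell's
    pixels recovers its marker value exactly.
    """
    from scipy.spatial import cKDTree

    if markers is None:
        reserved = {"cell_id", "x", "y", "area", "label", "spot"}
        markers = [c for c in cells.columns if c not in reserved]
    h, w = shape_px
    centroids = cells[["x", "y"]].to_numpy(dtype=float)
    radii = np.maximum(1.0, np.sqrt(cells["area"].to_numpy(dtype=float) / np.pi))
    tree = cKDTree(centroids)
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    dist, nearest = tree.query(pix, k=1)
    ids = cells["cell_id"].to_numpy()
    owner = np.where(dist <= radii[nearest], ids[nearest], 0)
    label = owner.reshape(h, w).astype(np.int32)
    uniq, counts = np.unique(label[label > 0], return_counts=True)
    by_id = cells.set_index("cell_id")
    vals_all = by_id.loc[uniq, markers].to_numpy(dtype=float) / counts[:, None]  # per-pixel densities
    lut = np.zeros((int(uniq.max()) + 1, len(markers)), dtype=np.float64)
    lut[uniq] = vals_all
    stack = np.moveaxis(lut[label], -1, 0).astype(np.float32)
    return label, stack


@dataclass
class SimulatedDataset:
    """Everything one paired simulation produces, with full ground truth."""

    truth: SyntheticTruth
    layout: ChannelLayout
    tissue_mask: np.ndarray
    cells: pd.DataFrame  # imaging-frame (px) cell table with true labels
    cells_um: pd.DataFrame  # same cells in the spot frame (um)
    spots: pd.DataFrame
    assignment: pd.Series  # cell_id -> spot (truth, from true positions)
    counts: pd.DataFrame  # spots x genes
    per_type_gene_totals: pd.DataFrame  # types x genes, realised truth
    label_image: Optional[np.ndarray] = None
    channel_stack: Optional[np.ndarray] = None


def simulate_dataset(
    truth: Optional[SyntheticTruth] = None,
    layout: Optional[ChannelLayout] = None,
    shape_px: tuple[int, int] = (256, 256),
    n_cells: int = 2000,
    n_blobs: int = 3,
    seed: int = 0,
    render: bool = False,
) -> SimulatedDataset:
    """Run the full generative model once.

    Defaults state the simulation world used throughout the tests: a 256 px
    square image (~1.1 mm at 4.5 um/px), 2,000 cells, a 20x20 grid of 25 um
    spots at 50 um pitch, depth 2,000 UMI per spot.
    """
    if truth is None:
        truth = default_truth(seed=seed)
    if layout is None:
        layout = ChannelLayout(n_a=20, n_b=20, channel_width=25.0, pitch=50.0, origin_xy=(0.0, 0.0))
    mask = generate_tissue_mask(shape_px, n_blobs=n_blobs, seed=seed)
    cells = generate_cells(mask, n_cells, truth, seed=seed + 1)
    cells_um = cells.copy()
    cells_um[["x", "y"]] = truth.transform_true.apply(cells[["x", "y"]].to_numpy(dtype=float))
    spots = build_spot_grid(layout)
    assignment = assign_cells_to_spots(cells_um, spots)
    labels = cells.set_index("cell_id")["label"]
    counts, per_type = generate_spot_counts(spots, assignment, labels, truth, seed=seed + 2, return_truth=True)
    occupied = set(counts.index[counts.sum(axis=1) > 0]) | set(assignment.dropna().unique())
    spots["tissue"] = spots["spot"].isin(occupied)
    label_img = stack = None
    if render:
        label_img, stack = render_images(cells, shape_px)
    return SimulatedDataset(
        truth=truth,
        layout=layout,
        tissue_mask=mask,
        cells=cells,
        cells_um=cells_um,
        spots=spots,
        assignment=assignment,
        counts=counts,
        per_type_gene_totals=per_type,
        label_image=label_img,
        channel_stack=stack,
    )
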
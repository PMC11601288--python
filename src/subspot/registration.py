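"""Align the imaging frame to the spot grid, and fit landmark affines.

The imaging (high-resolution) side and the sequencing (spot-grid) side see the
same tissue section. Registration works on tissue silhouettes: each side is
reduced to a binary mask (Gaussian smoothing, Otsu threshold, hole filling on
the imaging side; rasterised tissue-covered spots on the grid side), and the
similarity transform (rotation + uniform scale + translation) minimising the
squared difference between the warped moving mask and the fixed mask is found.
The imaging side is always "moving", the spot image "fixed". The fitted
transform then registers cell centroids into the spot frame.

For cross-section quality control a small set of manually picked landmark
pairs is available instead; there the least-squares affine is fit directly to
the point pairs.

The squared-error loss is evaluated on Gaussian-blurred float renderings of
the masks; a strictly binary loss is flat almost everywhere and defeats local
refinement. Optimisation is closed-form moment initialisation, a coarse grid
over rotation and scale (translation set by matching centroids), then
derivative-free Nelder-Mead refinement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import optimize
from skimage import filters
from skimage import transform as sktransform

from .transforms import AffineTransform, SimilarityTransform, apply_transform  # noqa: F401

__all__ = [
    "detect_tissue_boundary",
    "rasterize_spot_mask",
    "SpotMaskRender",
    "fit_similarity",
    "SimilarityFitResult",
    "fit_landmark_affine",
    "AffineFitResult",
    "RegistrationError",
]


class RegistrationError(RuntimeError):
    """Raised when mask registration cannot produce a usable transform."""


def detect_tissue_boundary(image: np.ndarray, sigma_px: float = 5.0) -> np.ndarray:
    """Tissue silhouette: Gaussian smooth, Otsu threshold, fill holes.

    Foreground is the side of the Otsu threshold with the higher mean (tissue
    is assumed brighter after smoothing). Raises on a constant image, where
    the threshold is undefined.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2D image")
    if np.ptp(image) == 0:
        raise ValueError("constant image: Otsu threshold undefined")
    smoothed = filters.gaussian(image, sigma=sigma_px, preserve_range=True)
    thr = filters.threshold_otsu(smoothed, nbins=256)
    mask = smoothed > thr
    if not mask.any():
        raise RegistrationError("boundary detection produced an empty mask")
    return ndi.binary_fill_holes(mask)


@dataclass(frozen=True)
class SpotMaskRender:
    """A rasterised spot mask plus the px <-> um mapping of its frame."""

    mask: np.ndarray
    origin_um: tuple[float, float]  # um coordinates of pixel (0, 0)'s center... top-left corner
    um_per_px: float

    def px_to_um(self) -> SimilarityTransform:
        """Transform taking this render's pixel coordinates into micrometres."""
        return SimilarityTransform(0.0, self.um_per_px, self.origin_um)


def rasterize_spot_mask(spots: pd.DataFrame, px_per_pitch: int = 10, fill: str = "width") -> SpotMaskRender:
    """Render tissue-covered spots as filled squares on a low-resolution raster.

    One spot pitch spans ``px_per_pitch`` pixels. The raster covers the grid
    bounding box padded by half a pitch on every side, and the returned object
    records the um coordinates of its origin so fitted transforms can be
    carried back into the spot frame.

    ``fill="width"`` draws each spot at its true channel width (disjoint
    squares, the faithful spot geometry); ``fill="pitch"`` lets each
    tissue-covered spot fill its whole pitch cell, producing the solid tissue
    footprint that mask-to-mask registration needs (a silhouette cannot match
    a sparse checkerboard).
    """
    tissue = spots.loc[spots["tissue"]]
    if len(tissue) == 0:
        raise ValueError("no tissue-covered spots to rasterise")
    from .grid import _layout_from_spots

    layout = _layout_from_spots(spots)
    pitch = layout.pitch
    um_per_px = pitch / px_per_pitch
    ox, oy = layout.origin_xy
    origin_um = (ox - pitch, oy - pitch)  # one pitch of margin
    n_px_x = int(np.ceil((layout.n_a + 1) * px_per_pitch)) + px_per_pitch
    n_px_y = int(np.ceil((layout.n_b + 1) * px_per_pitch)) + px_per_pitch
    mask = np.zeros((n_px_y, n_px_x), dtype=bool)
    if fill not in ("width", "pitch"):
        raise ValueError(f"fill must be 'width' or 'pitch', got {fill!r}")
    side_um = layout.channel_width if fill == "width" else pitch
    side_px = max(1, int(round(side_um / um_per_px)))
    for row in tissue.itertuples(index=False):
        x0 = int(np.floor((row.x - side_um / 2.0 - origin_um[0]) / um_per_px + 0.5))
        y0 = int(np.floor((row.y - side_um / 2.0 - origin_um[1]) / um_per_px + 0.5))
        mask[y0 : y0 + side_px, x0 : x0 + side_px] = True
    return SpotMaskRender(mask=mask, origin_um=origin_um, um_per_px=um_per_px)


@dataclass(frozen=True)
class SimilarityFitResult:
    """Fitted mask-to-mask similarity transform with its final loss."""

    transform: SimilarityTransform
    loss: float
    reflected: bool = False
    n_evaluations: int = 0


def _mask_moments(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Centroid (x, y), covariance eigen-axis angle and RMS radius of a mask."""
    ys, xs = np.nonzero(mask)
    pts = np.column_stack([xs, ys]).astype(float)
    c = pts.mean(axis=0)
    cov = np.cov((pts - c).T)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    angle = np.rad2deg(np.arctan2(major[1], major[0])) % 180.0
    rms = float(np.sqrt(np.trace(cov)))
    return c, angle, rms


def _warp_loss_factory(moving_f: np.ndarray, fixed_f: np.ndarray):
    """Mean squared difference between the warped moving image and the fixed image."""

    def loss(params: np.ndarray) -> float:
        rot, log_s, tx, ty = params
        t = SimilarityTransform(rot, float(np.exp(log_s)), (tx, ty))
        inv = sktransform.ProjectiveTransform(matrix=t.inverse().matrix)
        warped = sktransform.warp(moving_f, inv, output_shape=fixed_f.shape, order=1, mode="constant", cval=0.0)
        return float(np.mean((warped - fixed_f) ** 2))

    return loss


def fit_similarity(
    moving: np.ndarray,
    fixed: np.ndarray,
    allow_reflection: bool = False,
    blur_sigma: float = 2.0,
    rotation_span_deg: float = 20.0,
    scale_span: float = 0.25,
    n_coarse: int = 9,
) -> SimilarityFitResult:
    """Fit the similarity transform mapping ``moving`` mask onto ``fixed`` mask.

    The search is seeded from mask moments (centroids give translation, RMS
    radii the scale, principal axes the rotation up to the 180-degree
    ambiguity, which is searched explicitly), refined on a coarse
    rotation x scale grid spanning ``rotation_span_deg`` and ``scale_span``
    around the seed, then polished with Nelder-Mead on the blurred masks.

    With ``allow_reflection`` the fit is repeated on the x-flipped moving mask
    and the better of the two kept; ``reflected=True`` then means the
    transform applies to coordinates flipped as ``x -> width - 1 - x``.
    """
    moving = np.asarray(moving, dtype=bool)
    fixed = np.asarray(fixed, dtype=bool)
    if not moving.any() or not fixed.any():
        raise ValueError("both masks need at least one foreground pixel")

    def fit_one(mov: np.ndarray) -> SimilarityFitResult:
        mov_f = filters.gaussian(mov.astype(float), blur_sigma, preserve_range=True)
        fix_f = filters.gaussian(fixed.astype(float), blur_sigma, preserve_range=True)
        loss = _warp_loss_factory(mov_f, fix_f)
        c_mov, ang_mov, rms_mov = _mask_moments(mov)
        c_fix, ang_fix, rms_fix = _mask_moments(fixed)
        s0 = rms_fix / rms_mov if rms_mov > 0 else 1.0
        rot_seeds = [(ang_fix - ang_mov + 90.0) % 180.0 - 90.0]
        rot_seeds.append(rot_seeds[0] + 180.0)
        n_eval = 0
        best = (np.inf, None)
        rot_offsets = np.linspace(-rotation_span_deg, rotation_span_deg, n_coarse)
        scale_factors = np.exp(np.linspace(np.log(1 - scale_span), np.log(1 + scale_span), n_coarse))
        for rot_seed in rot_seeds:
            for d_rot in rot_offsets:
                for fs in scale_factors:
                    rot = rot_seed + d_rot
                    s = s0 * fs
                    t = _translation_for(rot, s, c_mov, c_fix)
                    params = np.array([rot, np.log(s), t[0], t[1]])
                    val = loss(params)
                    n_eval += 1
                    if val < best[0]:
                        best = (val, params)
        res = optimize.minimize(
            loss,
            best[1],
            method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-12, "maxiter": 600},
        )
        n_eval += res.nfev
        rot, log_s, tx, ty = res.x
        t_final = SimilarityTransform(float(rot), float(np.exp(log_s)), (float(tx), float(ty)))
        # Sanity check: the warped mask must actually overlap the fixed mask.
        inv = sktransform.ProjectiveTransform(matrix=t_final.inverse().matrix)
        warped = sktransform.warp(mov.astype(float), inv, output_shape=fixed.shape, order=0)
        overlap = np.logical_and(warped > 0.5, fixed).sum()
        if overlap == 0:
            raise RegistrationError(
                f"registration optimum has no mask overlap (loss={res.fun:.4g}, "
                f"rotation={rot:.1f} deg, scale={np.exp(log_s):.3f}); check that the "
                "two masks show the same tissue and similar orientations"
            )
        return SimilarityFitResult(transform=t_final, loss=float(res.fun), n_evaluations=n_eval)

    result = fit_one(moving)
    if allow_reflection:
        flipped = moving[:, ::-1]
        try:
            alt = fit_one(flipped)
        except RegistrationError:
            alt = None
        if alt is not None and alt.loss < result.loss:
            result = SimilarityFitResult(alt.transform, alt.loss, reflected=True, n_evaluations=alt.n_evaluations)
    return result


def _translation_for(rot_deg: float, scale: float, c_mov: np.ndarray, c_fix: np.ndarray) -> np.ndarray:
    """Translation aligning the moving centroid onto the fixed one at (rot, scale)."""
    t = SimilarityTransform(rot_deg, scale, (0.0, 0.0))
    return np.asarray(c_fix) - t.apply(c_mov)


@dataclass(frozen=True)
class AffineFitResult:
    """Least-squares landmark affine with per-point residuals."""

    transform: AffineTransform
    residuals: np.ndarray  # per-point Euclidean residual after the fit
    rmse: float


def fit_landmark_affine(points_a, points_b) -> AffineFitResult:
    """Least-squares affine sending landmark set A onto matched set B.

    Needs at least three non-collinear pairs; minimises
    ``sum_i || A p_a_i - p_b_i ||^2`` via the normal equations (through a
    numerically stable lstsq solve) and reports the per-point residuals.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("points_a and points_b must be matched (N, 2) arrays")
    if a.shape[0] < 3:
        raise ValueError(f"need at least 3 landmark pairs, got {a.shape[0]}")
    design = np.column_stack([a, np.ones(len(a))])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("landmarks are collinear; the affine fit is degenerate")
    coef, *_ = np.linalg.lstsq(design, b, rcond=None)  # (3, 2)
    transform = AffineTransform(coef.T)
    resid = np.linalg.norm(transform.apply(a) - b, axis=1)
    return AffineFitResult(transform=transform, residuals=resid, rmse=float(np.sqrt(np.mean(resid**2))))
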
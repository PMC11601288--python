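"""Planar similarity and affine transforms used to move between coordinate frames.

Conventions used throughout the package:

* points are ``(x, y)`` pairs, with ``x`` along image columns and ``y`` along
  image rows, 0-based pixel centers;
* a similarity transform maps ``p' = s * R(theta) * p + t`` with ``theta`` in
  degrees, counter-clockwise, ``s > 0`` a uniform scale and ``t`` in the
  destination frame's units;
* an affine transform is a general 2x3 coefficient matrix with a nonsingular
  linear part.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SimilarityTransform", "AffineTransform", "apply_transform"]


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[-1] != 2:
        raise ValueError(f"points must be (N, 2), got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    return pts, single


@dataclass(frozen=True)
class SimilarityTransform:
    """Rotation + uniform scale + translation (no reflection).

    Parameters
    ----------
    rotation_deg:
        Counter-clockwise rotation angle in degrees.
    scale:
        Uniform scale factor, strictly positive.
    translation_xy:
        Translation ``(tx, ty)`` applied after rotation and scaling.
    """

    rotation_deg: float = 0.0
    scale: float = 1.0
    translation_xy: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        object.__setattr__(self, "translation_xy", tuple(float(v) for v in self.translation_xy))

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix mapping source (x, y, 1) to destination."""
        th = np.deg2rad(self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        tx, ty = self.translation_xy
        return np.array(
            [
                [self.scale * c, -self.scale * s, tx],
                [self.scale * s, self.scale * c, ty],
                [0.0, 0.0, 1.0],
            ]
        )

    def apply(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        out = pts @ self.matrix[:2, :2].T + np.asarray(self.translation_xy)
        return out[0] if single else out

    def inverse(self) -> "SimilarityTransform":
        inv_scale = 1.0 / self.scale
        th = np.deg2rad(-self.rotation_deg)
        c, s = np.cos(th), np.sin(th)
        tx, ty = self.translation_xy
        itx = -inv_scale * (c * tx - s * ty)
        ity = -inv_scale * (s * tx + c * ty)
        return SimilarityTransform(-self.rotation_deg, inv_scale, (itx, ity))

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        m = self.matrix @ other.matrix
        scale = float(np.hypot(m[0, 0], m[1, 0]))
        rot = float(np.rad2deg(np.arctan2(m[1, 0], m[0, 0])))
        return SimilarityTransform(rot, scale, (float(m[0, 2]), float(m[1, 2])))

    def to_dict(self) -> dict:
        return {
            "rotation_deg": float(self.rotation_deg),
            "scale": float(self.scale),
            "tx": float(self.translation_xy[0]),
            "ty": float(self.translation_xy[1]),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        return cls(float(d["rotation_deg"]), float(d["scale"]), (float(d["tx"]), float(d["ty"])))


@dataclass(frozen=True)
class AffineTransform:
    """General planar affine transform as a 2x3 coefficient matrix.

    The linear part must be nonsingular so the transform is invertible.
    """

    coefficients: np.ndarray = field(default_factory=lambda: np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def __post_init__(self):
        coef = np.asarray(self.coefficients, dtype=float)
        if coef.shape != (2, 3):
            raise ValueError(f"coefficients must be 2x3, got {coef.shape}")
        if abs(np.linalg.det(coef[:, :2])) < 1e-12:
            raise ValueError("linear part of affine transform is singular")
        coef.setflags(write=False)
        object.__setattr__(self, "coefficients", coef)

    @property
    def matrix(self) -> np.ndarray:
        return np.vstack([self.coefficients, [0.0, 0.0, 1.0]])

    def apply(self, points) -> np.ndarray:
        pts, single = _as_points(points)
        out = pts @ self.coefficients[:, :2].T + self.coefficients[:, 2]
        return out[0] if single else out

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv[:2, :])

    def to_dict(self) -> dict:
        return {"matrix": [[float(v) for v in row] for row in self.coefficients]}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform":
        return cls(np.asarray(d["matrix"], dtype=float))


def apply_transform(points, transform: SimilarityTransform | AffineTransform) -> np.ndarray:
    """Map points through a similarity or affine transform (exact matrix application)."""
    return transform.apply(points)
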
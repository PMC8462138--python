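"""Thin-plate-spline interpolation and backward-mapped image unwarping.

The TPS is the unique minimum-bending-energy interpolant through a set of
2-D anchor pairs.  We use the radial kernel ``U(r) = r^2 log r`` (with
``U(0) = 0``); the alternative ``r^2 log r^2`` convention differs only by a
constant factor absorbed into the kernel weights.

Image standardization maps *backward*: a TPS is fitted from the consensus
landmarks to the specimen landmarks, and each output (consensus-canvas)
pixel samples the source image at its mapped location by bilinear
interpolation.  Forward splatting would leave holes.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import GeometryError
from .types import ConsensusShape

__all__ = [
    "tps_kernel",
    "ThinPlateSpline",
    "fit_tps",
    "bending_energy_matrix",
    "bending_energy",
    "unwarp_image",
]


def tps_kernel(r: np.ndarray) -> np.ndarray:
    """Radial kernel U(r) = r^2 log r, with U(0) = 0."""
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


def _tps_system(points: np.ndarray) -> np.ndarray:
    """Assemble the (k+3, k+3) TPS system matrix [[K, P], [P^T, 0]]."""
    k = points.shape[0]
    d = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    K = tps_kernel(d)
    P = np.hstack([np.ones((k, 1)), points])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    return L


class ThinPlateSpline:
    """Exact TPS interpolant between two landmark configurations.

    Fitted attributes
    -----------------
    src_ : (k, 2) source anchors
    weights_ : (k, 2) kernel weights (columns orthogonal to [1, x, y])
    affine_ : (3, 2) affine coefficients (row 0 = translation)
    """

    def fit(self, src: np.ndarray, dst: np.ndarray) -> "ThinPlateSpline":
        src = np.asarray(src, dtype=float)
        dst = np.asarray(dst, dtype=float)
        if src.ndim != 2 or src.shape[1] != 2 or src.shape != dst.shape:
            raise GeometryError("src and dst must both be (k, 2) with matching k")
        k = src.shape[0]
        if k < 3:
            raise GeometryError("TPS needs at least 3 anchors")
        L = _tps_system(src)
        rhs = np.zeros((k + 3, 2))
        rhs[:k] = dst
        try:
            sol = np.linalg.solve(L, rhs)
        except np.linalg.LinAlgError as exc:
            raise GeometryError(
                "singular TPS system: anchors are collinear or duplicated"
            ) from exc
        if not np.all(np.isfinite(sol)):
            raise GeometryError("TPS solve produced non-finite coefficients")
        self.src_ = src
        self.weights_ = sol[:k]
        self.affine_ = sol[k:]
        return self

    def transform(self, pts: np.ndarray) -> np.ndarray:
        """Map (m, 2) points through the fitted spline."""
        pts = np.asarray(pts, dtype=float)
        d = np.linalg.norm(pts[:, None, :] - self.src_[None, :, :], axis=-1)
        U = tps_kernel(d)
        P = np.hstack([np.ones((pts.shape[0], 1)), pts])
        return U @ self.weights_ + P @ self.affine_

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return self.transform(pts)


def fit_tps(src: np.ndarray, dst: np.ndarray) -> ThinPlateSpline:
    """Fit a thin-plate spline mapping ``src`` anchors onto ``dst``."""
    return ThinPlateSpline().fit(src, dst)


def bending_energy_matrix(points: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of a reference configuration.

    The top-left k x k block of the inverse TPS system matrix.  For a target
    configuration Y (k x 2), ``trace(Y^T B Y)`` is (proportional to) the
    bending energy of the TPS mapping ``points`` onto Y.  B is symmetric
    positive semidefinite and annihilates affine functions of the reference
    coordinates.
    """
    points = np.asarray(points, dtype=float)
    k = points.shape[0]
    L = _tps_system(points)
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise GeometryError("singular TPS system for bending energy") from exc
    B = Linv[:k, :k]
    return (B + B.T) / 2.0  # symmetrize against round-off


def bending_energy(reference: np.ndarray, target: np.ndarray) -> float:
    """Bending energy of the TPS deforming ``reference`` into ``target``."""
    B = bending_energy_matrix(reference)
    Y = np.asarray(target, dtype=float)
    return float(np.trace(Y.T @ B @ Y))


def unwarp_image(
    image: np.ndarray,
    specimen_landmarks: np.ndarray,
    consensus: ConsensusShape,
    fill: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Standardize a specimen image to the consensus shape.

    Fits a TPS from the consensus landmarks to the specimen landmarks and,
    for every pixel of the consensus canvas, samples the source image at the
    mapped location with bilinear interpolation.  Locations outside the
    source raster receive ``fill``.

    Returns ``(raster, valid_mask)`` where ``raster`` has the consensus
    ``frame_dims`` and ``valid_mask`` flags output pixels whose mapped
    location fell inside the source raster.  Downstream sampling stays
    inside the outline polygon, so fill never reaches the color matrix.
    """
    image = np.asarray(image, dtype=float)
    H, W = consensus.frame_dims
    tps = fit_tps(consensus.points, specimen_landmarks)
    ys, xs = np.mgrid[0:H, 0:W]
    out_pts = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    mapped = tps.transform(out_pts)
    mx = mapped[:, 0].reshape(H, W)
    my = mapped[:, 1].reshape(H, W)
    src_h, src_w = image.shape[:2]
    eps = 1e-6  # guard against round-off at the raster border
    valid = (mx >= -eps) & (mx <= src_w - 1 + eps) & (my >= -eps) & (my <= src_h - 1 + eps)
    out = np.empty((H, W, 3), dtype=float)
    coords = np.stack([my, mx])  # map_coordinates wants (row, col)
    for c in range(3):
        out[:, :, c] = ndimage.map_coordinates(
            image[:, :, c], coords, order=1, mode="constant", cval=fill[c]
        )
    out[~valid] = np.asarray(fill, dtype=float)
    return np.clip(out, 0.0, 1.0), valid
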
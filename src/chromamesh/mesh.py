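"""Delaunay sampling templates, circular-mask color extraction, calibration.

The sampling template starts from the ordered perimeter ring of the
consensus shape.  Each round Delaunay-triangulates the current vertex set,
discards triangles whose centroid falls outside the outline polygon (a
no-op for convex outlines), and appends the retained centroids to the
vertex set.  Template points are the perimeter vertices plus every round's
centroids: for a convex b-gon in general position round k retains
``(b - 2) * 3**(k - 1)`` triangles, so K rounds give
``b + (b - 2) * (3**K - 1) / 2`` points — 2,462 for b = 62, K = 4.

Color is extracted as the per-channel mean over a circular pixel mask
centered on each template point; a diameter-1 circle is a single pixel (no
averaging).  Calibration applies an image-specific additive per-channel
correction computed from an in-image color standard of known values.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import Delaunay, cKDTree
from shapely.geometry import Polygon
from sklearn.base import BaseEstimator

from .errors import GeometryError, ParameterError, SamplingError, StructuralError
from .types import ColorMatrix, ConsensusShape, KnownStandard, SamplingCircle, SamplingTemplate

logger = logging.getLogger(__name__)

__all__ = [
    "build_template",
    "circle_mask",
    "sample_points",
    "sample_colors",
    "measure_standard",
    "calibrate",
    "DelaunayMeshSampler",
    "ColorCalibrator",
    "template_to_json",
    "template_from_json",
]


def build_template(
    consensus: ConsensusShape | np.ndarray,
    rounds: int,
    perimeter_map: np.ndarray | None = None,
) -> SamplingTemplate:
    """Build the accumulated Delaunay sampling template.

    Parameters
    ----------
    consensus : ConsensusShape or (b, 2) array
        Perimeter landmarks.  If they are not stored in ring order (e.g.
        traditional landmarks listed first), pass ``perimeter_map`` with the
        indices that order them into the outline polygon.
    rounds : int
        Number of triangulation rounds K >= 1.  Each round beyond the first
        uses the previous round's centroids as additional vertices, so the
        sampling density strictly increases with K.

    The construction is fully deterministic: no randomness is involved.
    """
    if rounds < 1:
        raise ParameterError("rounds must be >= 1")
    pts = consensus.points if isinstance(consensus, ConsensusShape) else np.asarray(consensus)
    pts = np.asarray(pts, dtype=float)
    if perimeter_map is not None:
        pts = pts[np.asarray(perimeter_map, dtype=int)]
    b = pts.shape[0]
    if b < 3:
        raise GeometryError("outline needs at least 3 vertices")
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise GeometryError("outline polygon is self-intersecting or degenerate")

    V = pts.copy()
    provenance = ["perimeter"] * b
    triangles: list[np.ndarray] = []
    for k in range(1, rounds + 1):
        tri = Delaunay(V)
        cent = V[tri.simplices].mean(axis=1)
        inside = shapely.intersects_xy(poly, cent[:, 0], cent[:, 1])
        kept = tri.simplices[inside]
        cent = cent[inside]
        # drop centroids that coincide with existing template points
        if cent.shape[0]:
            tree = cKDTree(V)
            dist, _ = tree.query(cent)
            dup_existing = dist <= 1e-9
            keep = ~dup_existing
            if cent[keep].shape[0] > 1:
                ctree = cKDTree(cent[keep])
                pairs = ctree.query_pairs(1e-9)
                drop = {max(a, b2) for a, b2 in pairs}
                sel = np.array([j for j in range(cent[keep].shape[0]) if j not in drop])
                new_pts = cent[keep][sel]
            else:
                new_pts = cent[keep]
            if new_pts.shape[0] < cent.shape[0]:
                logger.warning(
                    "round %d: deduplicated %d coincident centroids",
                    k,
                    cent.shape[0] - new_pts.shape[0],
                )
        else:
            new_pts = cent
        triangles.append(kept)
        V = np.vstack([V, new_pts])
        provenance.extend([f"centroid_round_{k}"] * new_pts.shape[0])

    return SamplingTemplate(
        outline=pts, rounds=rounds, points=V, provenance=provenance, triangles=triangles
    )


def circle_mask(diameter: int) -> SamplingCircle:
    """Integer offsets of a circular sampling mask of odd pixel ``diameter``.

    An offset (dx, dy) belongs to the mask iff sqrt(dx^2 + dy^2) <= d/2;
    diameter 1 is the single center pixel.
    """
    if not isinstance(diameter, (int, np.integer)) or diameter < 1 or diameter % 2 == 0:
        raise ParameterError(f"diameter must be an odd positive integer, got {diameter!r}")
    r = diameter // 2
    offs = []
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if 4 * (dx * dx + dy * dy) <= diameter * diameter:
                offs.append((dx, dy))
    return SamplingCircle(diameter=int(diameter), offsets=np.asarray(offs, dtype=int))


def sample_points(image: np.ndarray, points: np.ndarray, diameter: int = 1) -> np.ndarray:
    """Mean R,G,B over the sampling circle at each point.

    Points are rounded to the nearest pixel (ties away from zero toward the
    next pixel, i.e. half-up); mask offsets falling outside the raster are
    dropped from the mean.  A point whose center pixel lies outside the
    raster raises :class:`SamplingError`.
    """
    image = np.asarray(image, dtype=float)
    H, W = image.shape[:2]
    pts = np.asarray(points, dtype=float)
    circ = circle_mask(diameter)
    px = np.floor(pts[:, 0] + 0.5).astype(int)
    py = np.floor(pts[:, 1] + 0.5).astype(int)
    outside = (px < 0) | (px >= W) | (py < 0) | (py >= H)
    if outside.any():
        j = int(np.flatnonzero(outside)[0])
        raise SamplingError(
            f"template point {j} at ({pts[j, 0]:.1f}, {pts[j, 1]:.1f}) lies outside the raster"
        )
    total = np.zeros((pts.shape[0], 3))
    count = np.zeros(pts.shape[0])
    for dx, dy in circ.offsets:
        qx = px + dx
        qy = py + dy
        ok = (qx >= 0) & (qx < W) & (qy >= 0) & (qy < H)
        total[ok] += image[qy[ok], qx[ok], :]
        count += ok
    return total / count[:, None]


def sample_colors(
    image: np.ndarray, template: SamplingTemplate, diameter: int = 1
) -> np.ndarray:
    """Sample one image at every template point -> (n_points, 3)."""
    return sample_points(image, template.points, diameter)


def measure_standard(
    image: np.ndarray, standard_landmarks: np.ndarray, diameter: int = 1
) -> np.ndarray:
    """Sample the color-standard patches on an ORIGINAL (pre-warp) image.

    ``standard_landmarks`` are the 5 patch locations digitized on the
    original photograph; returns a (5, 3) matrix of measured patch means.
    """
    return sample_points(image, standard_landmarks, diameter)


def calibrate(
    sampled: ColorMatrix,
    standard_measured: np.ndarray,
    known: KnownStandard,
) -> ColorMatrix:
    """Apply the image-specific additive per-channel correction.

    For each specimen and channel c, the correction is the mean over the
    standard's patches of (known_c - measured_c); corrected values are
    ``sampled + correction``, clamped to [0, 1].
    """
    meas = np.asarray(standard_measured, dtype=float)
    if meas.ndim != 3 or meas.shape[0] != sampled.n_specimens or meas.shape[1:] != known.values.shape:
        raise StructuralError(
            f"standard_measured must be (n_specimens, {known.values.shape[0]}, 3), got {meas.shape}"
        )
    corrections = (known.values[None, :, :] - meas).mean(axis=1)  # (n, 3)
    big = np.abs(corrections) > 0.5
    if big.any():
        for i in np.flatnonzero(big.any(axis=1)):
            logger.warning(
                "specimen %s: |correction| > 0.5 (%s) — suspect standard localization",
                sampled.specimens[i],
                np.array2string(corrections[i], precision=3),
            )
    values = np.clip(sampled.values + corrections[:, None, :], 0.0, 1.0)
    return ColorMatrix(
        values=values, points=sampled.points, specimens=list(sampled.specimens), calibrated=True
    )


class DelaunayMeshSampler(BaseEstimator):
    """Template construction + color sampling as a transform-style estimator.

    ``fit`` builds the sampling template from the consensus outline;
    ``transform`` samples a stack/list of consensus-frame images into a
    :class:`ColorMatrix`.
    """

    def __init__(self, rounds: int = 4, diameter: int = 1):
        self.rounds = rounds
        self.diameter = diameter

    def fit(self, consensus: ConsensusShape | np.ndarray, perimeter_map=None) -> "DelaunayMeshSampler":
        self.template_ = build_template(consensus, self.rounds, perimeter_map=perimeter_map)
        return self

    def transform(self, images, specimens: list[str] | None = None) -> ColorMatrix:
        vals = np.stack([sample_colors(img, self.template_, self.diameter) for img in images])
        names = specimens or [f"specimen_{i}" for i in range(vals.shape[0])]
        return ColorMatrix(
            values=vals, points=self.template_.points, specimens=names, calibrated=False
        )


class ColorCalibrator(BaseEstimator):
    """Additive per-image calibration against a known color standard."""

    def __init__(self, known: KnownStandard | None = None):
        self.known = known

    def transform(self, sampled: ColorMatrix, standard_measured: np.ndarray) -> ColorMatrix:
        if self.known is None:
            raise StructuralError("ColorCalibrator needs a KnownStandard")
        return calibrate(sampled, standard_measured, self.known)


def template_to_json(template: SamplingTemplate, path) -> None:
    """Export a template (outline, points, provenance, triangles) as JSON."""
    payload = {
        "rounds": template.rounds,
        "outline": template.outline.tolist(),
        "points": template.points.tolist(),
        "provenance": list(template.provenance),
        "triangles": [t.tolist() for t in template.triangles],
    }
    Path(path).write_text(json.dumps(payload))


def template_from_json(path) -> SamplingTemplate:
    payload = json.loads(Path(path).read_text())
    return SamplingTemplate(
        outline=np.asarray(payload["outline"], dtype=float),
        rounds=int(payload["rounds"]),
        points=np.asarray(payload["points"], dtype=float),
        provenance=list(payload["provenance"]),
        triangles=[np.asarray(t, dtype=int) for t in payload["triangles"]],
    )
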
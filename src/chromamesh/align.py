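"""Generalized Procrustes Analysis with sliding semilandmarks.

GPA removes translation, scale and rotation from a set of landmark
configurations and iterates toward the mean (consensus) shape.  Reflection
is never allowed: the fitted rotation has determinant +1, so a mirrored
specimen is matched as well as possible by rotation alone and simply leaves
a larger residual.

Semilandmarks capture curves where point-to-point homology is undefined, so
during superimposition each is allowed to slide along the local tangent of
its curve (the chord between its two neighbors) to minimize the
thin-plate-spline bending energy between the specimen and the consensus —
the standard Gunz & Mitteroecker relaxation, solved here as an exact
least-squares step per pass.

The consensus is finally rescaled to the mean input centroid size and
translated to the center of the shared image canvas, so that unwarped
images all live on one pixel frame.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConvergenceError, GeometryError, StructuralError
from .types import ConsensusShape, ShapeSet
from .warp import bending_energy_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "centroid_size",
    "ProcrustesAligner",
    "gpa_align",
    "slide_semilandmarks",
    "hierarchical_consensus",
]


def centroid_size(points: np.ndarray) -> float:
    """Square root of the summed squared distances to the centroid."""
    pts = np.asarray(points, dtype=float)
    return float(np.sqrt(((pts - pts.mean(axis=0)) ** 2).sum()))


def _normalize(points: np.ndarray) -> np.ndarray:
    """Center and scale one configuration to unit centroid size."""
    pts = points - points.mean(axis=0)
    cs = np.sqrt((pts**2).sum())
    if cs == 0:
        raise GeometryError("configuration has zero centroid size")
    return pts / cs

def _rotation_onto(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (det = +1) minimizing ||A @ R - B||_F."""
    U, _, Vt = np.linalg.svd(A.T @ B)
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    return R


def _validate_config(pts: np.ndarray, label: str) -> None:
    if pts.shape[0] < 3:
        raise GeometryError(f"{label}: need at least 3 landmarks")
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() <= 0:
        raise GeometryError(f"{label}: duplicate landmarks")
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[1] < 1e-10 * max(sv[0], 1.0):
        raise GeometryError(f"{label}: landmarks are collinear")


class ProcrustesAligner(BaseEstimator):
    """GPA (optionally with sliding semilandmarks) as a fit-style estimator.

    Parameters
    ----------
    slide : bool
        Relax semilandmarks along tangents to minimize bending energy
        against the running consensus (requires a slider spec on the input).
    tol : float
        Convergence threshold on consensus displacement between iterations.
    max_iter : int
        Iteration budget; exceeding it raises :class:`ConvergenceError`.
    slide_iter : int
        Number of sliding cycles.  Sliding along the outline has a nearly
        energy-neutral direction (the curve's reparameterization), so the
        joint slide+GPA fixed point is approached only linearly; following
        standard practice the relaxation runs a small fixed number of
        cycles — each re-sliding from the measured configurations against
        the current consensus — after which the slid semilandmarks are held
        and plain GPA iterates to ``tol``.

    Fitted attributes
    -----------------
    consensus_ : ConsensusShape on the shared canvas
    aligned_ : ShapeSet of superimposed specimens on the same canvas
    mean_centroid_size_ : mean input centroid size (pixels)
    n_iter_ : plain-GPA iterations used after any sliding
    """

    def __init__(
        self, slide: bool = False, tol: float = 1e-8, max_iter: int = 100, slide_iter: int = 5
    ):
        self.slide = slide
        self.tol = tol
        self.max_iter = max_iter
        self.slide_iter = slide_iter

    def fit(self, shapes: ShapeSet, frame_dims: tuple[int, int] | None = None) -> "ProcrustesAligner":
        X = np.asarray(shapes.specimens, dtype=float)
        n, k, _ = X.shape
        if n < 2:
            raise StructuralError("GPA needs at least 2 configurations")
        names = shapes.names or [f"specimen_{i}" for i in range(n)]
        for i in range(n):
            _validate_config(X[i], names[i])
        if self.slide and shapes.slider_spec is None:
            raise StructuralError("slide=True requires a slider spec")

        sizes = np.array([centroid_size(X[i]) for i in range(n)])
        orig = np.stack([_normalize(X[i]) for i in range(n)])
        aligned = orig.copy()
        consensus = _normalize(aligned.mean(axis=0))

        if self.slide:
            # each cycle re-slides from the measured configurations, so slide
            # amounts never accumulate along the outline
            for _ in range(self.slide_iter):
                base = np.stack(
                    [orig[i] @ _rotation_onto(orig[i], consensus) for i in range(n)]
                )
                slid = _slide_all(base, consensus, shapes.slider_spec)
                aligned = np.stack([_normalize(s) for s in slid])
                new_consensus = _normalize(aligned.mean(axis=0))
                consensus = new_consensus @ _rotation_onto(new_consensus, consensus)

        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            for i in range(n):
                R = _rotation_onto(aligned[i], consensus)
                aligned[i] = aligned[i] @ R
            new_consensus = _normalize(aligned.mean(axis=0))
            # keep orientation stable across iterations
            new_consensus = new_consensus @ _rotation_onto(new_consensus, consensus)
            disp = np.linalg.norm(new_consensus - consensus)
            consensus = new_consensus
            if disp < self.tol:
                break
        else:
            raise ConvergenceError(
                f"GPA did not converge in {self.max_iter} iterations (residual {disp:.3g})"
            )

        mean_size = float(sizes.mean())
        if frame_dims is None:
            span = consensus * mean_size
            extent = span.max(axis=0) - span.min(axis=0)
            frame_dims = (int(np.ceil(extent[1] * 1.5)) + 2, int(np.ceil(extent[0] * 1.5)) + 2)
        H, W = frame_dims
        center = np.array([(W - 1) / 2.0, (H - 1) / 2.0])
        cons_px = consensus * mean_size + center
        aligned_px = aligned * mean_size + center

        self.consensus_ = ConsensusShape(
            points=cons_px,
            centroid_size=centroid_size(cons_px),
            frame_dims=(H, W),
            slider_spec=shapes.slider_spec,
        )
        self.aligned_ = ShapeSet(
            specimens=aligned_px,
            slider_spec=shapes.slider_spec,
            scales=shapes.scales,
            names=shapes.names,
        )
        self.mean_centroid_size_ = mean_size
        self.n_iter_ = n_iter
        return self


def _slide_all(aligned: np.ndarray, consensus: np.ndarray, slider_spec: np.ndarray) -> np.ndarray:
    """One sliding pass for every specimen against a fixed consensus."""
    B = bending_energy_matrix(consensus)
    out = aligned.copy()
    for i in range(aligned.shape[0]):
        out[i] = _slide_one(aligned[i], B, slider_spec)
    return out


def _slide_one(Y: np.ndarray, B: np.ndarray, slider_spec: np.ndarray) -> np.ndarray:
    """Slide the semilandmarks of one configuration.

    Each semilandmark s moves along the unit chord between its neighbors,
    ``Y' = Y + sum_s t_s e_s u_s^T``; minimizing ``trace(Y'^T B Y')`` over t
    is the linear system ``M t = -g`` with ``M[a,b] = B[s_a,s_b] u_a.u_b``
    and ``g[a] = (B Y)[s_a].u_a``.  B is PSD, so the minimizer never
    increases the energy.  Semilandmarks with coincident neighbors are left
    in place with a logged warning.
    """
    spec = np.asarray(slider_spec, dtype=int)
    idx = []
    tangents = []
    for before, slider, after in spec:
        chord = Y[after] - Y[before]
        norm = np.linalg.norm(chord)
        if norm == 0:
            logger.warning("semilandmark %d has coincident neighbors; not slid", slider)
            continue
        idx.append(slider)
        tangents.append(chord / norm)
    if not idx:
        return Y
    idx_arr = np.asarray(idx)
    U = np.asarray(tangents)  # (m, 2)
    BY = B @ Y
    g = np.einsum("ij,ij->i", BY[idx_arr], U)
    M = B[np.ix_(idx_arr, idx_arr)] * (U @ U.T)
    t, *_ = np.linalg.lstsq(M, -g, rcond=None)
    out = Y.copy()
    out[idx_arr] += t[:, None] * U
    return out


def gpa_align(
    shapes: ShapeSet,
    slide: bool = False,
    tol: float = 1e-8,
    max_iter: int = 100,
    frame_dims: tuple[int, int] | None = None,
) -> tuple[ShapeSet, ConsensusShape]:
    """Functional wrapper over :class:`ProcrustesAligner`.

    Returns ``(aligned ShapeSet, ConsensusShape)``.
    """
    est = ProcrustesAligner(slide=slide, tol=tol, max_iter=max_iter).fit(
        shapes, frame_dims=frame_dims
    )
    return est.aligned_, est.consensus_


def slide_semilandmarks(shapes: ShapeSet, consensus: ConsensusShape) -> ShapeSet:
    """One bending-energy sliding pass of every specimen against ``consensus``.

    Traditional landmarks stay fixed; each semilandmark moves along the
    chord between its two curve neighbors by the energy-minimizing amount.
    """
    if shapes.slider_spec is None:
        raise StructuralError("shapes carry no slider spec")
    slid = _slide_all(
        np.asarray(shapes.specimens, dtype=float),
        np.asarray(consensus.points, dtype=float),
        shapes.slider_spec,
    )
    return ShapeSet(
        specimens=slid,
        slider_spec=shapes.slider_spec,
        scales=shapes.scales,
        names=shapes.names,
    )


def hierarchical_consensus(
    consensus_list: list[ConsensusShape],
    frame_dims: tuple[int, int] | None = None,
    tol: float = 1e-8,
) -> ConsensusShape:
    """Overall consensus from population-specific consensuses.

    Runs a fresh GPA on the population consensuses themselves, so every
    population contributes equally regardless of its sample size — the
    overall shape is not dragged toward heavily sampled populations.
    """
    if not consensus_list:
        raise StructuralError("empty consensus list")
    ks = {c.points.shape[0] for c in consensus_list}
    if len(ks) > 1:
        raise StructuralError(f"consensuses disagree on landmark count: {sorted(ks)}")
    if len(consensus_list) == 1:
        return consensus_list[0]
    shapes = ShapeSet(
        specimens=np.stack([c.points for c in consensus_list]),
        slider_spec=consensus_list[0].slider_spec,
    )
    if frame_dims is None:
        frame_dims = consensus_list[0].frame_dims
    _, overall = gpa_align(shapes, slide=False, tol=tol, frame_dims=frame_dims)
    return overall
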
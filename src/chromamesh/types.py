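"""Core value types shared across the pipeline.

Coordinate convention
---------------------
All geometry inside the package uses raster coordinates: origin at the
top-left pixel center, ``x`` = column, ``y`` = row, 0-based, y increasing
downward.  Landmark files in the TPS dialect use a bottom-left origin with y
increasing upward; the conversion happens once, at the I/O boundary
(:mod:`chromamesh.io`), so every geometric module works in a single frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import StructuralError


@dataclass
class SpecimenRecord:
    """Identity and raster dimensions of one photographed specimen."""

    image_name: str
    population_id: str
    year: int
    image_width: int = 0
    image_height: int = 0


@dataclass
class LandmarkConfig:
    """One specimen's landmark configuration.

    Parameters
    ----------
    points : (k, 2) float array
        Landmark coordinates in internal pixel coordinates (x, y).
    scale : float or None
        Pixels per centimetre.  Absent (None) for standard-location files,
        which carry no size information.
    slider_spec : (m, 3) int array or None
        One row per semilandmark: indices of (previous neighbor, slider,
        next neighbor) along the curve.  Landmarks not listed are
        traditional (fixed) landmarks.
    """

    points: np.ndarray
    scale: float | None = None
    slider_spec: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise StructuralError("landmark points must be a (k, 2) array")
        if self.slider_spec is not None:
            self.slider_spec = np.asarray(self.slider_spec, dtype=int)

    @property
    def n_landmarks(self) -> int:
        return self.points.shape[0]

    @property
    def n_semilandmarks(self) -> int:
        return 0 if self.slider_spec is None else self.slider_spec.shape[0]

    @property
    def n_traditional(self) -> int:
        return self.n_landmarks - self.n_semilandmarks


@dataclass
class KnownStandard:
    """Known values of the in-image color standard, scaled to [0, 1]."""

    values: np.ndarray  # (5, 3)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (5, 3):
            raise StructuralError(
                f"known standard must be 5 patches x 3 channels, got {self.values.shape}"
            )

    @property
    def n_patches(self) -> int:
        return self.values.shape[0]


@dataclass
class ShapeSet:
    """Landmark configurations for a set of specimens in one frame.

    ``specimens`` is (n, k, 2); ``slider_spec`` and ``scales`` are shared /
    per-specimen annotations.
    """

    specimens: np.ndarray
    slider_spec: np.ndarray | None = None
    scales: np.ndarray | None = None
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.specimens = np.asarray(self.specimens, dtype=float)
        if self.specimens.ndim != 3 or self.specimens.shape[2] != 2:
            raise StructuralError("ShapeSet.specimens must be (n, k, 2)")

    @property
    def n_specimens(self) -> int:
        return self.specimens.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.specimens.shape[1]


@dataclass
class ConsensusShape:
    """GPA mean shape placed on the shared pixel canvas.

    The consensus is scaled back to the mean input centroid size and
    translated so that its centroid sits at the canvas center; all unwarped
    images share ``frame_dims`` = (height, width).
    """

    points: np.ndarray  # (k, 2)
    centroid_size: float
    frame_dims: tuple[int, int]
    slider_spec: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)


@dataclass
class SamplingTemplate:
    """Accumulated Delaunay sampling template.

    ``points`` holds the perimeter ring followed by every retained triangle
    centroid from each round; ``provenance[i]`` is ``"perimeter"`` or
    ``"centroid_round_k"``.  ``triangles`` stores, per round, the (T, 3)
    index array of retained triangles (indices into the vertex set used for
    that round).
    """

    outline: np.ndarray  # (b, 2) ordered perimeter polygon
    rounds: int
    points: np.ndarray  # (m, 2)
    provenance: list[str]
    triangles: list[np.ndarray] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass
class SamplingCircle:
    """Integer pixel offsets of a circular sampling mask."""

    diameter: int
    offsets: np.ndarray  # (m, 2) integer (dx, dy)


@dataclass
class ColorMatrix:
    """Sampled channel values: n_specimens x n_points x 3 in [0, 1]."""

    values: np.ndarray
    points: np.ndarray
    specimens: list[str]
    calibrated: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise StructuralError("ColorMatrix.values must be (n, m, 3)")
        if self.values.shape[1] != np.asarray(self.points).shape[0]:
            raise StructuralError(
                "ColorMatrix point count does not match template coordinates"
            )

    @property
    def n_specimens(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def flatten(self) -> np.ndarray:
        """Per-specimen color vectors of length 3 * n_points.

        Channel-major within each point: (R1, G1, B1, R2, G2, B2, ...).
        """
        return self.values.reshape(self.n_specimens, -1)


@dataclass
class PopulationSample:
    """Labeled set of flattened color vectors — the unit of all statistics."""

    label: str
    X: np.ndarray  # (n, p)
    year: int = 0

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise StructuralError("PopulationSample.X must be (n, p)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]
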
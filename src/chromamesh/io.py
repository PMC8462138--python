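"""Readers and writers for every external artifact the pipeline touches.

TPS landmark files, the specimen-metadata CSV, the known-standard CSV,
raster images, and the long-format color-matrix CSV with its JSON sidecar.

TPS files store coordinates with the origin at the *bottom-left* and y
increasing upward; internally we use raster coordinates (top-left origin, y
down).  The conversion ``y_int = (H - 1) - y_tps`` is applied on read and
inverted on write, so it is an involution and round trips are exact.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, StructuralError
from .types import ColorMatrix, KnownStandard, LandmarkConfig, SamplingTemplate

logger = logging.getLogger(__name__)

__all__ = [
    "read_tps",
    "write_tps",
    "read_slider_csv",
    "write_slider_csv",
    "read_perimeter_map",
    "write_perimeter_map",
    "read_metadata",
    "read_known_standard",
    "load_image",
    "save_image_png",
    "write_color_matrix",
    "read_color_matrix",
]


# ---------------------------------------------------------------------------
# TPS landmark files
# ---------------------------------------------------------------------------

def read_tps(path, image_height: int) -> list[tuple[str, LandmarkConfig]]:
    """Parse a TPS-dialect landmark file.

    Each record is ``LM=n`` followed by n ``x y`` coordinate lines and
    optional ``SCALE=``, ``IMAGE=``, ``ID=`` lines.  Coordinates are
    converted from the TPS bottom-left convention to internal raster
    coordinates using ``image_height``.

    Returns a list of ``(image_name, LandmarkConfig)`` in file order.  The
    stored SCALE is interpreted as pixels per centimetre.
    """
    if image_height <= 0:
        raise ParameterError("image_height must be positive")
    lines = Path(path).read_text().splitlines()
    records: list[tuple[str, LandmarkConfig]] = []

    i = 0
    n_lines = len(lines)
    while i < n_lines:
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise ParseError(f"{path}: expected LM= record at line {i + 1}, got {line!r}")
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise ParseError(f"{path}: bad LM count at line {i + 1}") from exc
        i += 1
        coords = []
        while i < n_lines and len(coords) < n_lm:
            ln = lines[i].strip()
            if not ln:
                i += 1
                continue
            if "=" in ln:  # next keyword before all coordinates were read
                break
            parts = ln.split()
            if len(parts) != 2:
                raise ParseError(f"{path}: bad coordinate line {i + 1}: {ln!r}")
            coords.append((float(parts[0]), float(parts[1])))
            i += 1
        scale = None
        image_name = None
        rec_id = None
        while i < n_lines:
            ln = lines[i].strip()
            if not ln:
                i += 1
                continue
            upper = ln.upper()
            if upper.startswith("LM="):
                break
            if upper.startswith("SCALE="):
                scale = float(ln.split("=", 1)[1])
            elif upper.startswith("IMAGE="):
                image_name = ln.split("=", 1)[1].strip()
            elif upper.startswith("ID="):
                rec_id = ln.split("=", 1)[1].strip()
            else:
                raise ParseError(f"{path}: unexpected line {i + 1}: {ln!r}")
            i += 1
        label = image_name or (f"id_{rec_id}" if rec_id is not None else f"record_{len(records)}")
        if len(coords) != n_lm:
            raise ParseError(
                f"{path}: record {label!r} declares LM={n_lm} but has {len(coords)} coordinate lines"
            )
        pts = np.asarray(coords, dtype=float)
        pts[:, 1] = (image_height - 1) - pts[:, 1]
        records.append((label, LandmarkConfig(points=pts, scale=scale)))

    counts = {cfg.n_landmarks for _, cfg in records}
    if len(counts) > 1:
        raise StructuralError(f"{path}: inconsistent landmark counts across records: {sorted(counts)}")
    return records


def write_tps(records: list[tuple[str, LandmarkConfig]], path, image_height: int) -> None:
    """Write ``(image_name, LandmarkConfig)`` pairs as a TPS file.

    Inverse of :func:`read_tps` (round trips are exact at 10 significant
    digits).  SCALE lines are emitted only when a scale is set.
    """
    if image_height <= 0:
        raise ParameterError("image_height must be positive")
    out = []
    for idx, (name, cfg) in enumerate(records):
        pts = np.asarray(cfg.points, dtype=float)
        out.append(f"LM={pts.shape[0]}")
        for x, y in pts:
            y_tps = (image_height - 1) - y
            out.append(f"{x:.10g} {y_tps:.10g}")
        if cfg.scale is not None:
            out.append(f"SCALE={cfg.scale:.10g}")
        out.append(f"IMAGE={name}")
        out.append(f"ID={idx}")
    Path(path).write_text("\n".join(out) + "\n")


def read_slider_csv(path) -> np.ndarray:
    """Read a semilandmark slider map: columns ``before,slider,after`` (0-based)."""
    df = pd.read_csv(path)
    required = {"before", "slider", "after"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: slider CSV needs columns {sorted(required)}")
    return df[["before", "slider", "after"]].to_numpy(dtype=int)


def write_slider_csv(slider_spec: np.ndarray, path) -> None:
    pd.DataFrame(np.asarray(slider_spec, dtype=int), columns=["before", "slider", "after"]).to_csv(
        path, index=False
    )


def read_perimeter_map(path) -> np.ndarray:
    """Read the ring-order index list (column ``index``) mapping file order
    to the perimeter polygon order."""
    df = pd.read_csv(path)
    if "index" not in df.columns:
        raise ParseError(f"{path}: perimeter map CSV needs an 'index' column")
    return df["index"].to_numpy(dtype=int)


def write_perimeter_map(order: np.ndarray, path) -> None:
    pd.DataFrame({"index": np.asarray(order, dtype=int)}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# CSV inputs
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Specimen metadata CSV with columns image_name, population, year."""
    df = pd.read_csv(path)
    required = {"image_name", "population", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: metadata CSV missing columns {sorted(missing)}")
    if df["image_name"].duplicated().any():
        dup = df.loc[df["image_name"].duplicated(), "image_name"].iloc[0]
        raise StructuralError(f"{path}: duplicate image_name {dup!r}")
    return df


def read_known_standard(path) -> KnownStandard:
    """Known color-standard CSV (columns R,G,B on a 0-255 scale) -> [0, 1].

    The file stores the manufacturer's 0-255 values; they are divided by 255
    so they share the scale of sampled raster values.
    """
    df = pd.read_csv(path)
    for col in ("R", "G", "B"):
        if col not in df.columns:
            raise ParseError(f"{path}: known standard CSV missing column {col}")
    vals = df[["R", "G", "B"]].to_numpy(dtype=float)
    if vals.shape[0] != 5:
        raise StructuralError(f"{path}: known standard must have 5 patches, got {vals.shape[0]}")
    if (vals < 0).any() or (vals > 255).any():
        raise ParameterError(f"{path}: known standard values must lie in [0, 255]")
    return KnownStandard(values=vals / 255.0)


# ---------------------------------------------------------------------------
# Raster images
# ---------------------------------------------------------------------------

def load_image(path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG raster as an (H, W, 3) float array in [0, 1].

    8- and 16-bit images are normalized by their maximum code value
    (255 / 65535).  No gamma decoding is applied: values are sampled in the
    encoded (sRGB) scale, as delivered by the camera pipeline.  Alpha
    channels are dropped with a logged warning; grayscale is replicated to
    three channels.
    """
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - wrap any backend failure
        raise OSError(f"could not read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3:
        raise StructuralError(f"{path}: unexpected image shape {arr.shape}")
    if arr.shape[2] == 4:
        logger.warning("%s: dropping alpha channel", path)
        arr = arr[:, :, :3]
    if arr.shape[2] != 3:
        raise StructuralError(f"{path}: unexpected channel count {arr.shape[2]}")
    if arr.dtype == np.uint8:
        out = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        out = arr.astype(float) / 65535.0
    else:
        out = arr.astype(float)
    return np.clip(out, 0.0, 1.0)


def save_image_png(raster: np.ndarray, path) -> None:
    """Write an (H, W, 3) [0, 1] raster as an 8-bit lossless PNG."""
    raster = np.asarray(raster, dtype=float)
    if raster.ndim != 3 or raster.shape[2] != 3:
        raise StructuralError("raster must be (H, W, 3)")
    data = np.clip(np.round(raster * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data, extension=".png")


# ---------------------------------------------------------------------------
# Color-matrix output
# ---------------------------------------------------------------------------

def write_color_matrix(matrix: ColorMatrix, template: SamplingTemplate, path) -> None:
    """Write sampled colors as a long-format CSV plus a JSON sidecar.

    CSV columns: specimen, point_index, x, y, R, G, B.  The sidecar
    (``<path>.meta.json``) records the template provenance, round count and
    calibration flag so the matrix is self-describing.
    """
    if matrix.n_points != template.n_points:
        raise StructuralError(
            f"matrix has {matrix.n_points} points but template has {template.n_points}"
        )
    n, m, _ = matrix.values.shape
    rows = {
        "specimen": np.repeat(matrix.specimens, m),
        "point_index": np.tile(np.arange(m), n),
        "x": np.tile(template.points[:, 0], n),
        "y": np.tile(template.points[:, 1], n),
        "R": matrix.values[:, :, 0].ravel(),
        "G": matrix.values[:, :, 1].ravel(),
        "B": matrix.values[:, :, 2].ravel(),
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "rounds": template.rounds,
        "calibrated": matrix.calibrated,
        "n_specimens": n,
        "n_points": m,
        "outline": template.outline.tolist(),
        "provenance": list(template.provenance),
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar, indent=1))


def read_color_matrix(path) -> ColorMatrix:
    """Read a color matrix written by :func:`write_color_matrix`."""
    df = pd.read_csv(path)
    required = {"specimen", "point_index", "x", "y", "R", "G", "B"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: color matrix CSV missing columns {sorted(missing)}")
    specimens = list(dict.fromkeys(df["specimen"].astype(str)))
    m = int(df["point_index"].max()) + 1
    n = len(specimens)
    if len(df) != n * m:
        raise StructuralError(f"{path}: expected {n * m} rows, found {len(df)}")
    order = pd.Categorical(df["specimen"].astype(str), categories=specimens).codes
    values = np.zeros((n, m, 3), dtype=float)
    idx = df["point_index"].to_numpy()
    values[order, idx, 0] = df["R"].to_numpy()
    values[order, idx, 1] = df["G"].to_numpy()
    values[order, idx, 2] = df["B"].to_numpy()
    first = df[order == 0].sort_values("point_index")
    points = first[["x", "y"]].to_numpy(dtype=float)
    calibrated = False
    sidecar = Path(str(path) + ".meta.json")
    if sidecar.exists():
        calibrated = bool(json.loads(sidecar.read_text()).get("calibrated", False))
    else:
        warnings.warn(f"{path}: no JSON sidecar found; calibration flag unknown", stacklevel=2)
    return ColorMatrix(values=values, points=points, specimens=specimens, calibrated=calibrated)
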
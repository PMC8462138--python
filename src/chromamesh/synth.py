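"""Synthetic fixture studies with known ground truth.

Generates complete, self-contained studies — specimen images, TPS landmark
files, standard-location file, metadata CSV, known-standard CSV, slider and
perimeter maps — that exercise every pipeline stage.  Each "fish" is an
elliptical body with population-specific spots; the color pattern is drawn
in the specimen's own (jittered) shape frame so that unwarping to the
consensus realigns homologous pattern elements, mirroring the biological
assumption of spatial homology.  A per-image additive color cast is applied
to the whole raster, including an embedded 5-patch standard of known
values, which makes the additive calibration exactly identifiable.

What the generator deliberately does not model: specular highlights and
iridescence, camera sensor noise, chromatic aberration, non-additive
illumination changes.  Passing tests therefore demonstrate correctness of
the pipeline's arithmetic, not robustness to real photographic artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from shapely.geometry import Polygon

from . import io as cio
from .errors import GeometryError, ParameterError
from .mesh import build_template, sample_colors
from .warp import fit_tps

__all__ = ["make_outline", "SynthConfig", "synth_study"]


def make_outline(
    n_points: int,
    elongation: float = 2.0,
    seed=None,
    center: tuple[float, float] = (0.0, 0.0),
    size: float = 1.0,
    angle_jitter: float = 0.15,
    notch_depth: float = 0.0,
) -> np.ndarray:
    """Simple fish-like polygon, vertices in ring order.

    Vertices lie on an ellipse with semi-axes ``size * elongation`` (x) and
    ``size`` (y), at equally spaced angles with optional seeded jitter
    (points remain on the ellipse, so the polygon stays convex and in
    general position).  ``notch_depth`` > 0 pulls a few trailing-edge
    vertices inward to cut a tail notch, producing a non-convex outline.
    """
    if n_points < 4:
        raise ParameterError("outline needs at least 4 points")
    if elongation <= 0 or size <= 0:
        raise ParameterError("elongation and size must be positive")
    base = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    if seed is not None and angle_jitter > 0:
        rng = np.random.default_rng(seed)
        gap = 2.0 * np.pi / n_points
        base = base + rng.uniform(-angle_jitter, angle_jitter, n_points) * gap
        base = np.sort(base % (2.0 * np.pi))
    a = size * elongation
    b = size
    radial = np.ones(n_points)
    if notch_depth > 0:
        # pull vertices near angle pi (the "tail") toward the center
        near_tail = np.abs(((base - np.pi + np.pi) % (2 * np.pi)) - np.pi) < (2 * np.pi / n_points)
        radial[near_tail] = 1.0 - notch_depth
    xs = center[0] + a * radial * np.cos(base)
    ys = center[1] - b * radial * np.sin(base)
    pts = np.column_stack([xs, ys])
    poly = Polygon(pts)
    if not poly.is_valid or not poly.is_simple:
        raise GeometryError("generated outline is self-intersecting")
    return pts


_DEFAULT_SPOTS = [
    # (relative x in [-1, 1] along the body axis, relative y in [-1, 1],
    #  radius as a fraction of the mean body half-extent, R, G, B)
    (-0.55, -0.15, 0.17, 0.86, 0.45, 0.12),  # orange, anterior flank
    (-0.15, 0.20, 0.15, 0.10, 0.10, 0.12),  # black, mid-body
    (0.25, -0.20, 0.15, 0.30, 0.50, 0.80),  # blue, posterior dorsal
    (0.55, 0.10, 0.13, 0.75, 0.70, 0.20),  # yellow, caudal peduncle
]

_DEFAULT_KNOWN = np.array(
    [
        [51.0, 51.0, 51.0],
        [102.0, 102.0, 102.0],
        [153.0, 153.0, 153.0],
        [204.0, 51.0, 51.0],
        [51.0, 102.0, 204.0],
    ]
)


@dataclass
class SynthConfig:
    """Study-design parameters for a synthetic fixture.

    Defaults emulate the guppy study structure: 62 perimeter landmarks of
    which 7 are traditional, populations of a few dozen males photographed
    in one of two years, the 4-round / diameter-1 sampling scheme, and
    modest within-population color noise with a per-image additive cast.
    """

    n_populations: int = 4
    n_per_population: int = 30
    n_perimeter_points: int = 62
    n_traditional: int = 7
    image_height: int = 240
    image_width: int = 360
    rounds: int = 4
    diameter: int = 1
    spots: list = field(default_factory=lambda: list(_DEFAULT_SPOTS))
    body_color: tuple[float, float, float] = (0.55, 0.52, 0.45)
    within_sd: float = 0.03
    between_shift: float = 0.08
    shape_jitter_sd: float = 1.5
    cast_sd: float = 0.05
    scale_px_per_cm: float = 100.0
    years: tuple = (2016, 2017)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.within_sd, self.between_shift, self.shape_jitter_sd, self.cast_sd) < 0:
            raise ParameterError("all SDs must be >= 0")
        if self.image_height < 120 or self.image_width < 160:
            raise ParameterError("image too small to hold outline plus standard patches")
        if not 0 < self.n_traditional < self.n_perimeter_points:
            raise ParameterError("n_traditional must be in (0, n_perimeter_points)")


_PATCH = 14  # standard patch edge length, px
_PATCH_GAP = 4


def _standard_boxes(n: int = 5):
    boxes = []
    x = _PATCH_GAP
    for _ in range(n):
        boxes.append((x, _PATCH_GAP, x + _PATCH, _PATCH_GAP + _PATCH))
        x += _PATCH + _PATCH_GAP
    return boxes


def _standard_centers(n: int = 5) -> np.ndarray:
    return np.array(
        [((x0 + x1 - 1) / 2.0, (y0 + y1 - 1) / 2.0) for x0, y0, x1, y1 in _standard_boxes(n)]
    )


def _landmark_scheme(cfg: SynthConfig):
    """Ring outline, file ordering (traditional first), sliders, perimeter map."""
    b = cfg.n_perimeter_points
    cy, cx = cfg.image_height / 2.0, cfg.image_width / 2.0
    size = min(cfg.image_height * 0.30, cfg.image_width * 0.20)
    elong = min(2.0, (cfg.image_width * 0.40) / size)
    ring = make_outline(b, elongation=elong, seed=cfg.seed, center=(cx, cy), size=size)
    trad_ring = np.round(np.linspace(0, b, cfg.n_traditional, endpoint=False)).astype(int)
    semi_ring = np.array([i for i in range(b) if i not in set(trad_ring)])
    file_order_of_ring = np.concatenate([trad_ring, semi_ring])  # ring index per file slot
    ring_to_file = np.empty(b, dtype=int)
    ring_to_file[file_order_of_ring] = np.arange(b)
    perimeter_map = ring_to_file  # perimeter_map[i] = file index of the i-th ring vertex
    sliders = []
    for ring_i in semi_ring:
        before = ring_to_file[(ring_i - 1) % b]
        after = ring_to_file[(ring_i + 1) % b]
        sliders.append((before, ring_to_file[ring_i], after))
    return ring, file_order_of_ring, perimeter_map, np.asarray(sliders, dtype=int)


def _render_specimen(
    cfg: SynthConfig,
    ring_landmarks: np.ndarray,
    base_ring: np.ndarray,
    body_color: np.ndarray,
    spot_colors: np.ndarray,
    cast: np.ndarray,
    with_standard: bool = True,
) -> np.ndarray:
    """Render one specimen raster in [0, 1]."""
    H, W = cfg.image_height, cfg.image_width
    img = np.full((H, W, 3), 0.5, dtype=float)

    mask_im = Image.new("L", (W, H), 0)
    ImageDraw.Draw(mask_im).polygon([tuple(p) for p in ring_landmarks], fill=1)
    body_mask = np.asarray(mask_im, dtype=bool)
    img[body_mask] = body_color

    # spot centers defined in the base frame ride the specimen's shape
    tps = fit_tps(base_ring, ring_landmarks)
    bb_min = base_ring.min(axis=0)
    bb_max = base_ring.max(axis=0)
    bb_c = (bb_min + bb_max) / 2.0
    bb_half = (bb_max - bb_min) / 2.0
    centers_base = np.array([[bb_c[0] + sx * bb_half[0], bb_c[1] + sy * bb_half[1]]
                             for sx, sy, *_ in cfg.spots])
    centers = tps.transform(centers_base)
    ys, xs = np.mgrid[0:H, 0:W]
    half_extent = float(bb_half.mean())
    for (spot, (cx0, cy0), col) in zip(cfg.spots, centers, spot_colors):
        radius = spot[2] * half_extent
        spot_mask = ((xs - cx0) ** 2 + (ys - cy0) ** 2 <= radius**2) & body_mask
        img[spot_mask] = col

    if with_standard:
        known = _DEFAULT_KNOWN / 255.0
        for patch, (x0, y0, x1, y1) in zip(known, _standard_boxes()):
            img[y0:y1, x0:x1] = patch

    img = img + cast[None, None, :]
    return np.clip(img, 0.0, 1.0)


def synth_study(config: SynthConfig, outdir) -> dict:
    """Write a complete synthetic study and its ground truth.

    Produces, under ``outdir``: ``images/<name>.png`` per specimen,
    ``landmarks.tps`` (traditional-first file order, SCALE records),
    ``standard.tps`` (patch centers, no scale), ``metadata.csv``,
    ``known_standard.csv``, ``sliders.csv``, ``perimeter_map.csv``, and
    ``ground_truth.json`` holding the true per-image casts, the true
    population mean color vectors at the template points, and the noise
    parameters.  Returns the manifest dictionary (also saved as
    ``manifest.json``).
    """
    cfg = config
    out = Path(outdir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    H, W = cfg.image_height, cfg.image_width

    ring, file_order_of_ring, perimeter_map, sliders = _landmark_scheme(cfg)
    b = cfg.n_perimeter_points

    # population-level color means
    pop_names = [f"pop{chr(ord('A') + i)}" for i in range(cfg.n_populations)]
    base_spot_cols = np.array([[r, g, bl] for *_, r, g, bl in cfg.spots])
    pop_spot_cols = {}
    pop_body_cols = {}
    for name in pop_names:
        shift = rng.normal(0.0, cfg.between_shift, size=base_spot_cols.shape)
        pop_spot_cols[name] = np.clip(base_spot_cols + shift, 0.05, 0.95)
        pop_body_cols[name] = np.clip(
            np.asarray(cfg.body_color) + rng.normal(0.0, cfg.between_shift / 2.0, 3), 0.05, 0.95
        )
    pop_years = {name: cfg.years[i % len(cfg.years)] for i, name in enumerate(pop_names)}

    tps_records = []
    meta_rows = []
    casts = {}
    for name in pop_names:
        for j in range(cfg.n_per_population):
            img_name = f"{name}_{j:03d}.png"
            # jittered specimen shape; retry until simple
            for _ in range(50):
                ring_lm = ring + rng.normal(0.0, cfg.shape_jitter_sd, size=ring.shape)
                if Polygon(ring_lm).is_simple:
                    break
            else:
                raise GeometryError("could not draw a simple jittered outline")
            cast = rng.normal(0.0, cfg.cast_sd, 3)
            spot_cols = np.clip(
                pop_spot_cols[name] + rng.normal(0.0, cfg.within_sd, base_spot_cols.shape),
                0.02,
                0.98,
            )
            body_col = np.clip(
                pop_body_cols[name] + rng.normal(0.0, cfg.within_sd, 3), 0.02, 0.98
            )
            raster = _render_specimen(cfg, ring_lm, ring, body_col, spot_cols, cast)
            cio.save_image_png(raster, out / "images" / img_name)
            casts[img_name] = cast.tolist()
            file_pts = ring_lm[file_order_of_ring]
            tps_records.append(
                (img_name, cio.LandmarkConfig(points=file_pts, scale=cfg.scale_px_per_cm))
            )
            meta_rows.append((img_name, name, pop_years[name]))

    cio.write_tps(tps_records, out / "landmarks.tps", image_height=H)
    std_centers = _standard_centers()
    std_records = [
        (img_name, cio.LandmarkConfig(points=std_centers, scale=None))
        for img_name, _, _ in meta_rows
    ]
    cio.write_tps(std_records, out / "standard.tps", image_height=H)
    cio.write_slider_csv(sliders, out / "sliders.csv")
    cio.write_perimeter_map(perimeter_map, out / "perimeter_map.csv")

    import pandas as pd

    pd.DataFrame(meta_rows, columns=["image_name", "population", "year"]).to_csv(
        out / "metadata.csv", index=False
    )
    pd.DataFrame(_DEFAULT_KNOWN, columns=["R", "G", "B"]).assign(
        patch=[f"patch{i + 1}" for i in range(5)]
    )[["patch", "R", "G", "B"]].to_csv(out / "known_standard.csv", index=False)

    # ground truth: clean (no jitter, no noise, no cast) population images
    # sampled on the template built from the base outline
    template = build_template(ring, cfg.rounds)
    true_means = {}
    for name in pop_names:
        clean = _render_specimen(
            cfg, ring, ring, pop_body_cols[name], pop_spot_cols[name], np.zeros(3)
        )
        true_means[name] = sample_colors(clean, template, cfg.diameter).ravel().tolist()

    ground_truth = {
        "reference_landmarks_file_order": ring[file_order_of_ring].tolist(),
        "reference_ring": ring.tolist(),
        "frame_dims": [H, W],
        "casts": casts,
        "population_spot_colors": {k: v.tolist() for k, v in pop_spot_cols.items()},
        "population_body_colors": {k: v.tolist() for k, v in pop_body_cols.items()},
        "population_years": pop_years,
        "true_mean_vectors": true_means,
        "template_n_points": template.n_points,
        "within_sd": cfg.within_sd,
        "between_shift": cfg.between_shift,
        "cast_sd": cfg.cast_sd,
        "scheme": {
            "n_perimeter_points": cfg.n_perimeter_points,
            "n_traditional": cfg.n_traditional,
            "n_semilandmarks": cfg.n_perimeter_points - cfg.n_traditional,
            "rounds": cfg.rounds,
            "diameter": cfg.diameter,
        },
    }
    (out / "ground_truth.json").write_text(json.dumps(ground_truth))

    manifest = {
        "images_dir": str(out / "images"),
        "landmarks": str(out / "landmarks.tps"),
        "standard_landmarks": str(out / "standard.tps"),
        "metadata": str(out / "metadata.csv"),
        "known_standard": str(out / "known_standard.csv"),
        "sliders": str(out / "sliders.csv"),
        "perimeter_map": str(out / "perimeter_map.csv"),
        "ground_truth": str(out / "ground_truth.json"),
        "image_height": H,
        "image_width": W,
        "n_specimens": len(meta_rows),
        "populations": pop_names,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
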
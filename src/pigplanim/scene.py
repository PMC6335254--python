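"""Synthetic top-view scenes with analytic ground truth.

Emulates the study's imaging geometry: a camera looking straight down from
245 cm above the floor of a high-contrast planimetry box, photographing a
single pig (or a rectangular reference board of known area) whose body plane
sits at a posture-dependent height — 69 cm for standing animals, 29 cm for
lying ones. Under an ideal pinhole model an object plane at height ``h``
is magnified by ``D / (D - h)`` relative to the floor plane, so its
projected area scales with the square of that factor.

Silhouettes are parametric polygons (body ellipse plus posture-dependent
head, curvature and limb extensions) scaled so their planform area follows
the allometric law ``a = k_g · W^0.66`` with per-posture coefficients fitted
from the study's summary tables, times a seeded multiplicative noise term.
The polygon itself is the analytic ground truth: its shoelace area and the
exact count of pixel centers it covers after projection are returned with
every render, so the measurement pipeline can be scored against a known
answer.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
import shapely.affinity as aff
from PIL import Image
from shapely.geometry import Point, Polygon, box
from shapely.ops import unary_union

from .postures import (
    POSTURE_CODES,
    InvalidPostureError,
    StudyGroupSummary,
    posture_class,
    reference_height_for,
)

__all__ = [
    "ALLOMETRIC_EXPONENT",
    "CameraModel",
    "SilhouetteSpec",
    "BoardSpec",
    "ArtifactSpec",
    "SceneSpec",
    "GroundTruth",
    "GeometryError",
    "OutOfFrameError",
    "project_scale",
    "fit_shape_coefficient",
    "make_silhouette",
    "render_scene",
    "tune_shape_noise",
    "cohort_specs",
    "write_scene",
]

#: Exponent of the allometric area-weight law a = k · W^0.66.
ALLOMETRIC_EXPONENT = 0.66

#: Lens-to-floor distance of the study's planimetry box (cm).
DEFAULT_LENS_HEIGHT_CM = 245.0

#: Known area of the rectangular calibration board (m²).
REFERENCE_BOARD_AREA_M2 = 0.420


class GeometryError(ValueError):
    """Degenerate camera/object geometry (object at or above the lens)."""


class OutOfFrameError(ValueError):
    """An object's projection falls outside the rendered image."""


@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole camera pointing straight down.

    ``floor_scale`` is the sampling density at the floor plane in pixels per
    meter; the principal axis passes through the image center.
    """

    lens_height_cm: float = DEFAULT_LENS_HEIGHT_CM
    image_width: int = 1600
    image_height: int = 1100
    floor_scale: float = 500.0

    def __post_init__(self) -> None:
        if self.lens_height_cm <= 0:
            raise GeometryError("lens height must be positive")
        if self.floor_scale <= 0:
            raise ValueError("floor_scale must be positive")


@dataclass(frozen=True)
class SilhouetteSpec:
    """One synthetic animal: posture, weight, plane height, noise, seed."""

    posture: str
    live_weight_kg: float
    object_height_cm: float | None = None  # default: posture reference height
    position_m: tuple[float, float] = (0.0, 0.0)
    shape_seed: int = 0
    shape_noise: float = 0.0

    def height_cm(self) -> float:
        if self.object_height_cm is not None:
            return self.object_height_cm
        return reference_height_for(self.posture)


@dataclass(frozen=True)
class BoardSpec:
    """Rectangular reference surface of known area at a known height."""

    known_area_m2: float = REFERENCE_BOARD_AREA_M2
    height_cm: float = 0.0
    aspect: float = 2.8  # length:width, pig-like planform
    position_m: tuple[float, float] = (0.0, 0.0)

    def polygon(self) -> Polygon:
        width = math.sqrt(self.known_area_m2 / self.aspect)
        length = self.aspect * width
        return box(-length / 2, -width / 2, length / 2, width / 2)


@dataclass(frozen=True)
class ArtifactSpec:
    """Elliptical intensity blob emulating a shadow or contamination speck."""

    center_m: tuple[float, float]
    semi_axes_m: tuple[float, float]
    angle_deg: float
    level: int  # drawn intensity


@dataclass
class SceneSpec:
    """Everything needed to render one image deterministically."""

    camera: CameraModel = field(default_factory=CameraModel)
    objects: list[SilhouetteSpec | BoardSpec] = field(default_factory=list)
    background_level: int = 25
    foreground_level: int = 230
    artifacts: list[ArtifactSpec] = field(default_factory=list)


@dataclass(frozen=True)
class GroundTruth:
    """Analytic truth for one rendered object."""

    object_id: int
    posture: str  # "board" for the reference surface
    live_weight_kg: float
    object_height_cm: float
    planform_area_m2: float
    projected_pixel_area: int
    polygon: Polygon
    position_m: tuple[float, float]


def project_scale(camera: CameraModel, object_height_cm: float) -> float:
    """Linear magnification of a plane at ``object_height_cm`` above the floor.

    Returns ``D / (D - h)`` for lens height ``D``; projected areas scale with
    the square. Raises :class:`GeometryError` for h ≥ D or h < 0.
    """
    D = camera.lens_height_cm
    if not 0 <= object_height_cm < D:
        raise GeometryError(
            f"object height {object_height_cm} cm outside [0, {D}) cm"
        )
    return D / (D - object_height_cm)


def fit_shape_coefficient(
    study_tables: Sequence[StudyGroupSummary],
) -> dict[str, float]:
    """Per-posture allometric coefficient k_g = mean area / mean weight^0.66.

    Silhouettes generated with these coefficients reproduce each posture
    group's mean covered area at its mean live weight by construction.
    """
    coeffs: dict[str, float] = {}
    for rec in study_tables:
        if rec.weight_mean <= 0:
            raise ValueError(f"non-positive mean weight for {rec.posture}")
        coeffs[rec.posture] = rec.area_mean / rec.weight_mean**ALLOMETRIC_EXPONENT
    return coeffs


def _ellipse(a: float, b: float, cx: float = 0.0, cy: float = 0.0,
             angle: float = 0.0, n: int = 72) -> Polygon:
    t = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    poly = Polygon(pts)
    if angle:
        poly = aff.rotate(poly, angle, origin=(0, 0))
    return aff.translate(poly, cx, cy)


# Relative geometry per posture: (body semi-axes, head length factor,
# lateral head offset for "curved sideways" codes, limb extensions).
# Units are arbitrary — the final polygon is rescaled to the target area —
# so only the outline style differs between postures.
_HEAD_LENGTH = {"A": 0.70, "B": 0.80, "C": 1.00, "D": 1.10, "E": 0.90}


def _base_outline(posture: str, rng: np.random.Generator) -> Polygon:
    cls = posture_class(posture)
    jitter = 1.0 + 0.04 * rng.standard_normal(4)  # mild shape diversity
    if cls == "standing":
        root = posture[0]  # A..E
        curved = posture.endswith("S")
        body = _ellipse(0.50 * jitter[0], 0.155 * jitter[1])
        hl = 0.24 * _HEAD_LENGTH[root] * jitter[2]
        if curved:
            # head swung sideways: offset laterally and rotated
            head = _ellipse(hl, 0.095 * jitter[3], 0.42, 0.20, angle=35.0)
            shoulder = _ellipse(0.18, 0.13, 0.30, 0.06)
            parts = [body, shoulder, head]
        else:
            head = _ellipse(hl, 0.095 * jitter[3], 0.50 + 0.6 * hl, 0.0)
            parts = [body, head]
    elif posture == "LBC":
        body = _ellipse(0.52 * jitter[0], 0.21 * jitter[1])
        head = _ellipse(0.20 * jitter[2], 0.11 * jitter[3], 0.58, 0.0)
        parts = [body, head]
    elif posture == "LSL":
        body = _ellipse(0.53 * jitter[0], 0.24 * jitter[1])
        head = _ellipse(0.20 * jitter[2], 0.11 * jitter[3], 0.58, 0.0)
        leg = aff.rotate(box(0.05, -0.36, 0.33, -0.22), -8, origin=(0.1, -0.25))
        parts = [body, head, leg]
    elif posture == "LL":
        body = _ellipse(0.54 * jitter[0], 0.24 * jitter[1])
        head = _ellipse(0.20 * jitter[2], 0.11 * jitter[3], 0.60, 0.0)
        legs = [
            aff.rotate(box(0.05, 0.20, 0.38, 0.31), 12, origin=(0.1, 0.25)),
            aff.rotate(box(-0.30, 0.18, 0.02, 0.29), 5, origin=(-0.1, 0.23)),
        ]
        parts = [body, head, *legs]
    else:  # pragma: no cover - guarded by posture_class
        raise InvalidPostureError(posture)
    merged = unary_union(parts)
    if merged.geom_type != "Polygon":  # keep the dominant lobe, just in case
        merged = max(merged.geoms, key=lambda g: g.area)
    return Polygon(merged.exterior)  # fill any interior rings


def make_silhouette(
    spec: SilhouetteSpec, k_g: float
) -> tuple[Polygon, float]:
    """Build a posture-shaped simple polygon with allometric planform area.

    The polygon (object-plane coordinates, meters, centered on the spec
    position) is uniformly scaled so its shoelace area equals
    ``k_g · W^0.66 · (1 + ε)`` with ε drawn from a zero-mean normal of SD
    ``shape_noise`` truncated at ±3 SD. Deterministic given ``shape_seed``.
    Returns the polygon and its exact area.
    """
    if spec.shape_noise < 0:
        raise ValueError("shape_noise must be non-negative")
    if spec.live_weight_kg <= 0:
        raise ValueError("live weight must be positive")
    posture_class(spec.posture)  # validates the code
    rng = np.random.default_rng(spec.shape_seed)
    outline = _base_outline(spec.posture, rng)
    eps = 0.0
    if spec.shape_noise > 0:
        eps = float(np.clip(rng.normal(0.0, spec.shape_noise),
                            -3 * spec.shape_noise, 3 * spec.shape_noise))
    target = k_g * spec.live_weight_kg**ALLOMETRIC_EXPONENT * (1.0 + eps)
    s = math.sqrt(target / outline.area)
    poly = aff.scale(outline, s, s, origin=(0, 0))
    poly = aff.translate(poly, *spec.position_m)
    return poly, poly.area


def _pixel_centers_inside(poly: Polygon, camera: CameraModel) -> np.ndarray:
    """Boolean raster (full image frame) of pixel centers inside ``poly``.

    ``poly`` is in projected floor-plane meters; a pixel belongs to the
    object iff its center lies inside the polygon.
    """
    s = camera.floor_scale
    cx, cy = camera.image_width / 2.0, camera.image_height / 2.0
    minx, miny, maxx, maxy = poly.bounds
    c0 = max(0, int(math.floor(minx * s + cx)))
    c1 = min(camera.image_width, int(math.ceil(maxx * s + cx)) + 1)
    r0 = max(0, int(math.floor(miny * s + cy)))
    r1 = min(camera.image_height, int(math.ceil(maxy * s + cy)) + 1)
    mask = np.zeros((camera.image_height, camera.image_width), dtype=bool)
    if c1 <= c0 or r1 <= r0:
        return mask
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xs = (cols + 0.5 - cx) / s
    ys = (rows + 0.5 - cy) / s
    X, Y = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(X.shape)
    mask[r0:r1, c0:c1] = inside
    return mask


def _project(poly: Polygon, magnification: float) -> Polygon:
    return aff.scale(poly, magnification, magnification, origin=(0, 0))


def render_scene(
    scene: SceneSpec,
    coefficients: dict[str, float] | None = None,
) -> tuple[np.ndarray, list[GroundTruth]]:
    """Render a scene to an 8-bit grayscale image with per-object truth.

    Objects are drawn at ``foreground_level`` after projecting their
    object-plane polygon through the pinhole model; artifacts are drawn at
    their own levels underneath the objects; everything else is background.
    Raises :class:`OutOfFrameError` if an object's projection leaves the
    frame.
    """
    cam = scene.camera
    img = np.full((cam.image_height, cam.image_width),
                  scene.background_level, dtype=np.uint8)
    half_w = cam.image_width / (2 * cam.floor_scale)
    half_h = cam.image_height / (2 * cam.floor_scale)

    for art in scene.artifacts:
        blob = _ellipse(*art.semi_axes_m, *art.center_m, angle=art.angle_deg)
        img[_pixel_centers_inside(blob, cam)] = art.level

    truths: list[GroundTruth] = []
    for idx, obj in enumerate(scene.objects):
        if isinstance(obj, BoardSpec):
            poly = aff.translate(obj.polygon(), *obj.position_m)
            height, posture, weight = obj.height_cm, "board", float("nan")
        else:
            if coefficients is None:
                raise ValueError("silhouette objects need fitted coefficients")
            poly, _ = make_silhouette(obj, coefficients[obj.posture])
            height, posture, weight = obj.height_cm(), obj.posture, obj.live_weight_kg
        mag = project_scale(cam, height)
        proj = _project(poly, mag)
        minx, miny, maxx, maxy = proj.bounds
        if minx < -half_w or maxx > half_w or miny < -half_h or maxy > half_h:
            raise OutOfFrameError(
                f"object {idx} ({posture}) projects outside the frame"
            )
        mask = _pixel_centers_inside(proj, cam)
        img[mask] = scene.foreground_level
        truths.append(
            GroundTruth(
                object_id=idx,
                posture=posture,
                live_weight_kg=weight,
                object_height_cm=height,
                planform_area_m2=poly.area,
                projected_pixel_area=int(mask.sum()),
                polygon=poly,
                position_m=(
                    obj.position_m if isinstance(obj, BoardSpec) else obj.position_m
                ),
            )
        )
    return img, truths


def tune_shape_noise(
    study_tables: Sequence[StudyGroupSummary],
    weight_cv: float,
) -> dict[str, float]:
    """Per-posture shape-noise SD matched to the study's area dispersion.

    Generated areas are ``k · W^0.66 · (1 + ε)``, so their coefficient of
    variation combines the weight-driven part (≈ 0.66 · CV(W)) with the shape
    term in quadrature. This inverts that relation: for each posture the
    returned SD is the residual dispersion needed so a cohort with weight
    CV ``weight_cv`` reproduces the posture's observed area SD/mean; floored
    at zero when weight spread alone already accounts for it.
    """
    out: dict[str, float] = {}
    for rec in study_tables:
        cv_area = rec.area_sd / rec.area_mean
        cv_from_weight = ALLOMETRIC_EXPONENT * weight_cv
        out[rec.posture] = math.sqrt(max(cv_area**2 - cv_from_weight**2, 0.0))
    return out


def cohort_specs(
    n_per_posture: int,
    master_seed: int,
    weight_range: tuple[float, float] = (75.0, 133.0),
    shape_noise: float | dict[str, float] = 0.0,
    postures: Sequence[str] = POSTURE_CODES,
) -> list[SilhouetteSpec]:
    """Deterministic cohort of silhouette specs.

    Weights are uniform on ``weight_range`` (the study's span). Per-animal
    seeds derive from the master seed through a counter so the cohort is
    reproducible animal-by-animal.
    """
    for p in postures:
        posture_class(p)
    rng = np.random.default_rng(master_seed)
    specs: list[SilhouetteSpec] = []
    counter = 0
    for posture in postures:
        noise = shape_noise[posture] if isinstance(shape_noise, dict) else shape_noise
        for _ in range(n_per_posture):
            w = float(rng.uniform(*weight_range))
            specs.append(
                SilhouetteSpec(
                    posture=posture,
                    live_weight_kg=w,
                    shape_seed=master_seed * 100_003 + counter,
                    shape_noise=noise,
                )
            )
            counter += 1
    return specs


def write_scene(
    image: np.ndarray,
    truths: Sequence[GroundTruth],
    png_path: str | Path,
    csv_path: str | Path | None = None,
) -> None:
    """Save a rendered scene as 8-bit PNG plus a ground-truth sidecar CSV."""
    Image.fromarray(image, mode="L").save(png_path)
    if csv_path is not None:
        with open(csv_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["object_id", "posture", "live_weight_kg", "object_height_cm",
                 "planform_area_m2", "projected_pixel_area", "x_m", "y_m"]
            )
            for t in truths:
                writer.writerow(
                    [t.object_id, t.posture,
                     "" if math.isnan(t.live_weight_kg) else f"{t.live_weight_kg:.2f}",
                     f"{t.object_height_cm:.2f}", f"{t.planform_area_m2:.6f}",
                     t.projected_pixel_area,
                     f"{t.position_m[0]:.4f}", f"{t.position_m[1]:.4f}"]
                )
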
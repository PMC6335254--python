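"""Contrast-based planimetric area measurement.

The measurement chain mirrors manual planimetry software practice: reduce to
one channel, stretch the contrast, threshold (automatic inter-class-variance
threshold by default), zero out manually excluded regions, keep the dominant
connected component(s), fill enclosed holes, and convert the foreground
pixel count to m² with a calibration obtained from a reference surface of
known area photographed under identical geometry.

Because the reference board is mounted at the typical body-plane height of
the animals (69 cm standing / 29 cm lying), the perspective magnification of
camera-facing planes cancels between reference and subject, and the pixel
density ``pixels_per_m2`` converts counts directly to planform area. A
subject whose body plane differs from the calibration height is biased by
``((D - h_ref) / (D - h_obj))²`` — enforced as an error in strict mode.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.filters import threshold_otsu

from .postures import posture_class, reference_height_for

__all__ = [
    "SegmentationConfig",
    "Calibration",
    "AreaMeasurement",
    "NoContrastError",
    "NoObjectError",
    "HeightMismatchError",
    "to_grayscale",
    "enhance_contrast",
    "segment",
    "calibrate",
    "measure_area",
    "measure_batch",
    "read_image",
    "write_measurements",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


class NoContrastError(ValueError):
    """Image is constant; contrast stretching is undefined."""


class NoObjectError(ValueError):
    """No foreground pixels survive thresholding/exclusion."""


class HeightMismatchError(ValueError):
    """Calibration height does not match the posture's reference height."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding and component-selection parameters.

    ``threshold_mode`` is ``"automatic"`` (inter-class-variance maximising,
    i.e. Otsu) or ``"fixed"`` (use ``fixed_threshold``). Components smaller
    than ``min_component_fraction`` of the largest are discarded; enclosed
    holes are filled when ``fill_holes`` (a pig seen from above is simply
    connected).
    """

    threshold_mode: str = "automatic"
    fixed_threshold: float = 128.0
    min_component_fraction: float = 0.5
    fill_holes: bool = True
    strict_heights: bool = False

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("automatic", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if not 0.0 <= self.min_component_fraction <= 1.0:
            raise ValueError("min_component_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-area conversion anchored to a reference surface."""

    pixels_per_m2: float
    reference_area_m2: float
    reference_height_cm: float
    reference_pixel_count: int

    def __post_init__(self) -> None:
        if self.pixels_per_m2 <= 0:
            raise ValueError("pixels_per_m2 must be positive")


@dataclass(frozen=True)
class AreaMeasurement:
    """One measured covered-floor area."""

    subject_id: str
    posture: str
    pixel_count: int
    area_m2: float
    live_weight_kg: float | None = None
    calibration_height_cm: float | None = None


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Reduce an image to a single float channel (luminance for RGB)."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2:
        raise ValueError(f"expected 2-D or RGB image, got shape {arr.shape}")
    return arr


def enhance_contrast(image: np.ndarray) -> np.ndarray:
    """Linear contrast stretch mapping the 1st/99th percentiles to [0, 255].

    Monotone and order-preserving; output clipped to the intensity range.
    Raises :class:`NoContrastError` on a constant image.
    """
    gray = to_grayscale(image)
    lo, hi = np.percentile(gray, [1.0, 99.0])
    if hi <= lo:
        lo, hi = gray.min(), gray.max()
        if hi <= lo:
            raise NoContrastError("image has no intensity variation")
    return np.clip((gray - lo) * (255.0 / (hi - lo)), 0.0, 255.0)


def segment(
    image: np.ndarray,
    config: SegmentationConfig = SegmentationConfig(),
    exclusion_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Binary silhouette mask from a preprocessed single-channel image.

    Thresholds bright-on-dark foreground, removes excluded pixels, keeps the
    largest 8-connected component plus any component at least
    ``min_component_fraction`` of its size, and optionally fills holes.
    """
    gray = to_grayscale(image)
    if config.threshold_mode == "automatic":
        if np.ptp(gray) == 0:
            raise NoObjectError("uniform image: nothing to segment")
        thr = threshold_otsu(gray)
    else:
        thr = config.fixed_threshold
    fg = gray > thr
    if exclusion_mask is not None:
        excl = np.asarray(exclusion_mask).astype(bool)
        if excl.shape != fg.shape:
            raise ValueError("exclusion mask shape mismatch")
        fg &= ~excl
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        raise NoObjectError("no foreground pixels after thresholding")
    sizes = ndimage.sum_labels(fg, labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= config.min_component_fraction * sizes.max()) + 1
    mask = np.isin(labels, keep)
    if config.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask


def calibrate(
    reference_image: np.ndarray,
    known_area_m2: float,
    reference_height_cm: float,
    config: SegmentationConfig = SegmentationConfig(),
    exclusion_mask: np.ndarray | None = None,
) -> Calibration:
    """Derive pixels-per-m² from an image of the reference surface."""
    if known_area_m2 <= 0:
        raise ValueError("known_area_m2 must be positive")
    mask = segment(enhance_contrast(reference_image), config, exclusion_mask)
    count = int(mask.sum())
    return Calibration(
        pixels_per_m2=count / known_area_m2,
        reference_area_m2=known_area_m2,
        reference_height_cm=reference_height_cm,
        reference_pixel_count=count,
    )


def measure_area(
    mask_or_image: np.ndarray,
    calibration: Calibration,
    posture: str,
    subject_id: str = "",
    live_weight_kg: float | None = None,
    config: SegmentationConfig = SegmentationConfig(),
    exclusion_mask: np.ndarray | None = None,
) -> AreaMeasurement:
    """Covered floor area of one subject: pixel count / pixels_per_m².

    Accepts either a boolean mask or a raw image (segmented internally). A
    calibration whose height differs from the posture's reference height is
    an error in strict mode and a warning otherwise.
    """
    posture_class(posture)
    expected = reference_height_for(posture)
    if calibration.reference_height_cm != expected:
        msg = (
            f"calibration at {calibration.reference_height_cm} cm used for "
            f"posture {posture} (reference height {expected} cm)"
        )
        if config.strict_heights:
            raise HeightMismatchError(msg)
        warnings.warn(msg, stacklevel=2)
    arr = np.asarray(mask_or_image)
    if arr.dtype == bool:
        mask = arr
    else:
        mask = segment(enhance_contrast(arr), config, exclusion_mask)
    count = int(mask.sum())
    if count == 0:
        raise NoObjectError("empty silhouette mask")
    return AreaMeasurement(
        subject_id=subject_id,
        posture=posture,
        pixel_count=count,
        area_m2=count / calibration.pixels_per_m2,
        live_weight_kg=live_weight_kg,
        calibration_height_cm=calibration.reference_height_cm,
    )


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF image as a numpy array."""
    with Image.open(path) as im:
        return np.asarray(im)


@dataclass
class BatchResult:
    """Measurements plus itemized failures from a manifest run."""

    measurements: list[AreaMeasurement] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)  # (file, reason)


def measure_batch(
    image_dir: str | Path,
    manifest: str | Path,
    calibrations: dict[float, Calibration],
    config: SegmentationConfig = SegmentationConfig(),
) -> BatchResult:
    """Measure every image listed in a manifest CSV.

    The manifest maps ``filename`` to ``subject_id``, ``posture`` and an
    optional ``weight_kg``; the calibration is selected per posture via its
    reference height. Failures (missing file, unknown posture, empty
    segmentation, missing calibration) are collected and reported, never
    silently dropped.
    """
    image_dir = Path(image_dir)
    result = BatchResult()
    with open(manifest, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    if not rows:
        warnings.warn("empty manifest: no images to measure", stacklevel=2)
        return result
    for row in rows:
        fname = row["filename"].strip()
        try:
            posture = row["posture"].strip()
            height = reference_height_for(posture)
            cal = calibrations.get(height)
            if cal is None:
                raise KeyError(f"no calibration at {height} cm")
            path = image_dir / fname
            if not path.exists():
                raise FileNotFoundError(f"missing image {path}")
            weight = row.get("weight_kg")
            result.measurements.append(
                measure_area(
                    read_image(path), cal, posture,
                    subject_id=row.get("subject_id", fname),
                    live_weight_kg=float(weight) if weight else None,
                    config=config,
                )
            )
        except Exception as exc:  # noqa: BLE001 - itemized error report
            result.failures.append((fname, f"{type(exc).__name__}: {exc}"))
    return result


def write_measurements(
    measurements: Sequence[AreaMeasurement], path: str | Path
) -> None:
    """Write measurements to CSV; areas rounded to 3 dp only here."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["subject_id", "posture", "weight_kg", "pixel_count", "area_m2",
             "calibration_height_cm"]
        )
        for m in measurements:
            writer.writerow(
                [m.subject_id, m.posture,
                 "" if m.live_weight_kg is None else f"{m.live_weight_kg:.2f}",
                 m.pixel_count, f"{m.area_m2:.3f}",
                 "" if m.calibration_height_cm is None
                 else f"{m.calibration_height_cm:.2f}"]
            )
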
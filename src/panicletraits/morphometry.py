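"""Grain length / width / aspect-ratio measurement.

Only grains that are unoccluded (or nearly so) give honest dimensions,
so detections are first screened with non-maximum suppression at an IoU
threshold of 0.8 and a confidence threshold of 0.7 — the combination
that maximised agreement with hand measurements — then each survivor is
cropped, segmented to its main body, and measured by the minimum-area
rotated bounding rectangle: the long side is grain length, the short
side grain width.  Pixel dimensions convert to millimetres through the
calibrator-derived pel density, and per-panicle traits are the means
over measured grains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from skimage.filters import threshold_otsu
from skimage.measure import label

from .calibration import PelDensity
from .detection import BBox, DetectionSet, filter_confidence, iou, nms

log = logging.getLogger(__name__)


class NoGrainBodyError(ValueError):
    """Segmentation of a crop produced no foreground."""


class NoMeasurableGrainsError(ValueError):
    """No grain in the image survived screening + segmentation."""


@dataclass(frozen=True)
class ScreeningConfig:
    """Unoccluded-grain screening parameters.

    ``nms_iou`` is the IoU threshold applied as non-maximum suppression
    over the detector output and ``conf`` the confidence floor; defaults
    (0.7 / 0.8, no padding) are the best-performing combination.
    ``max_pairwise_iou`` < 1 additionally drops any surviving box that
    still overlaps another survivor beyond that ratio (off by default).
    """

    conf: float = 0.7
    nms_iou: float = 0.8
    pad_pixels: int = 0
    max_pairwise_iou: float = 1.0

    def __post_init__(self) -> None:
        for name in ("conf", "nms_iou", "max_pairwise_iou"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.pad_pixels not in (0, 2):
            raise ValueError("pad_pixels must be 0 or 2")


@dataclass(frozen=True)
class GrainMeasurement:
    length_mm: float
    width_mm: float
    aspect_ratio: float
    length_px: float
    width_px: float
    angle: float  # degrees of the length axis, in [0, 180)


@dataclass(frozen=True)
class PanicleGrainStats:
    n_measured: int
    mean_length_mm: float
    mean_width_mm: float
    mean_aspect: float


def screen_grains(d: DetectionSet, cfg: ScreeningConfig | None = None) -> DetectionSet:
    """NMS at ``cfg.nms_iou``, then confidence filter at ``cfg.conf``,
    then (optionally) drop boxes still overlapping beyond
    ``cfg.max_pairwise_iou``."""
    cfg = cfg or ScreeningConfig()
    out = filter_confidence(nms(d, cfg.nms_iou), cfg.conf)
    if cfg.max_pairwise_iou < 1.0:
        keep = []
        for i, a in enumerate(out.boxes):
            if all(
                iou(a, b) <= cfg.max_pairwise_iou
                for j, b in enumerate(out.boxes)
                if j != i
            ):
                keep.append(a)
        out = DetectionSet(out.image_id, out.image_size, keep)
    return out


def crop_grain(
    image: np.ndarray, box: BBox, pad_pixels: int = 0
) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop ``box`` dilated by ``pad_pixels`` per side, clipped to bounds.

    Returns the crop and the (row, col) offset of its origin in the
    full image.  A box entirely outside the image is an error.
    """
    h, w = image.shape[:2]
    r0 = int(np.floor(box.y_min)) - pad_pixels
    c0 = int(np.floor(box.x_min)) - pad_pixels
    r1 = int(np.ceil(box.y_max)) + pad_pixels
    c1 = int(np.ceil(box.x_max)) + pad_pixels
    r0c, c0c = max(r0, 0), max(c0, 0)
    r1c, c1c = min(r1, h), min(c1, w)
    if r0c >= r1c or c0c >= c1c:
        raise ValueError("box lies fully outside the image")
    return image[r0c:r1c, c0c:c1c], (r0c, c0c)


def segment_grain(crop: np.ndarray, method: str = "otsu",
                  rgb_low=(120, 100, 0), rgb_high=(255, 230, 140)) -> np.ndarray:
    """Threshold a grain crop and keep the largest component (main body)."""
    if crop.size == 0:
        raise ValueError("empty crop")
    if method == "otsu":
        gray = crop.mean(axis=-1) if crop.ndim == 3 else crop.astype(float)
        if gray.max() == gray.min():
            raise NoGrainBodyError("uniform crop, nothing to segment")
        fg = gray > threshold_otsu(gray)
        # the grain sits centrally in its crop; whichever Otsu class
        # dominates the crop border is the background
        border = np.concatenate(
            [fg[0, :], fg[-1, :], fg[1:-1, 0], fg[1:-1, -1]])
        if border.mean() > 0.5:
            fg = ~fg
    elif method == "rgb_range":
        img = crop if crop.dtype == np.uint8 else (crop * 255).astype(np.uint8)
        fg = np.all((img >= np.asarray(rgb_low)) & (img <= np.asarray(rgb_high)),
                    axis=-1)
    else:
        raise ValueError(f"unknown segmentation method {method!r}")
    labels = label(fg, connectivity=2)
    if labels.max() == 0:
        raise NoGrainBodyError("no grain body after thresholding")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def min_bounding_rect(mask: np.ndarray) -> tuple[float, float, float]:
    """Minimum-area rotated rectangle of a binary mask.

    Foreground pixels are treated as unit squares (their four corners
    enter the hull), so an axis-aligned w x h block measures exactly
    (w, h).  Rotating calipers: the minimum-area rectangle has a side
    collinear with a convex-hull edge, so each hull edge is tried and
    the smallest-area candidate kept.

    Returns (length_px, width_px, angle_deg) with length >= width and
    the angle of the length axis (from the +x/column axis) in [0, 180).
    """
    pts = np.argwhere(mask)
    if len(pts) == 0:
        raise ValueError("empty mask")
    r, c = pts[:, 0], pts[:, 1]
    # unit-square corners in (x, y) = (col, row) coordinates
    corners = np.concatenate([
        np.stack([c, r], axis=1),
        np.stack([c + 1, r], axis=1),
        np.stack([c, r + 1], axis=1),
        np.stack([c + 1, r + 1], axis=1),
    ]).astype(float)
    hull_pts = corners[ConvexHull(corners).vertices]
    n = len(hull_pts)
    best = None
    for i in range(n):
        ex, ey = hull_pts[(i + 1) % n] - hull_pts[i]
        norm = np.hypot(ex, ey)
        if norm == 0:
            continue
        ux, uy = ex / norm, ey / norm
        # project hull points onto the edge direction and its normal
        along = hull_pts @ (ux, uy)
        across = hull_pts @ (-uy, ux)
        da = along.max() - along.min()
        dc = across.max() - across.min()
        area = da * dc
        if best is None or area < best[0] * (1 - 1e-12):
            theta = np.degrees(np.arctan2(uy, ux))
            best = (area, da, dc, theta)
    _, da, dc, theta = best
    if da >= dc:
        length, width, ang = da, dc, theta
    else:
        length, width, ang = dc, da, theta + 90.0
    ang %= 180.0
    # snap float noise from exact-tie edges (e.g. axis-aligned blocks)
    if abs(ang - round(ang)) < 1e-9:
        ang = round(ang) % 180.0
    return float(length), float(width), float(ang)


def measure_grains(
    image: np.ndarray,
    detections: DetectionSet,
    cfg: ScreeningConfig | None = None,
    pel: PelDensity | None = None,
    segmentation: str = "otsu",
) -> list[GrainMeasurement]:
    """Screen detections, then crop / segment / min-rect each survivor.

    Grains whose crop fails segmentation are skipped (and logged); if
    nothing survives, :class:`NoMeasurableGrainsError` is raised.
    ``pel`` converts pixels to millimetres and is required.
    """
    cfg = cfg or ScreeningConfig()
    if pel is None:
        raise ValueError("a calibrated PelDensity is required")
    screened = screen_grains(detections, cfg)
    out: list[GrainMeasurement] = []
    skipped = 0
    for box in screened.boxes:
        try:
            crop, _ = crop_grain(image, box, cfg.pad_pixels)
            body = segment_grain(crop, method=segmentation)
            length_px, width_px, angle = min_bounding_rect(body)
        except (NoGrainBodyError, ValueError) as exc:
            skipped += 1
            log.info("%s: grain at (%.0f,%.0f) skipped: %s",
                     detections.image_id, box.x_min, box.y_min, exc)
            continue
        length_mm = length_px * pel.mm_per_pixel
        width_mm = width_px * pel.mm_per_pixel
        out.append(GrainMeasurement(
            length_mm=length_mm,
            width_mm=width_mm,
            aspect_ratio=length_mm / width_mm,
            length_px=length_px,
            width_px=width_px,
            angle=angle,
        ))
    if skipped:
        log.warning("%s: %d grain(s) skipped during measurement",
                    detections.image_id, skipped)
    if not out:
        raise NoMeasurableGrainsError("no measurable grains")
    return out


def panicle_grain_stats(measurements: list[GrainMeasurement]) -> PanicleGrainStats:
    """Panicle-level means; aspect is the mean of per-grain aspect ratios
    (not the ratio of mean length to mean width)."""
    if not measurements:
        raise ValueError("no measurements to aggregate")
    return PanicleGrainStats(
        n_measured=len(measurements),
        mean_length_mm=float(np.mean([m.length_mm for m in measurements])),
        mean_width_mm=float(np.mean([m.width_mm for m in measurements])),
        mean_aspect=float(np.mean([m.aspect_ratio for m in measurements])),
    )
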
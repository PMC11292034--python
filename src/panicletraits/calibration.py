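"""Distance calibration from the red calibrator disk.

Every acquisition includes a red circular calibrator of known physical
radius (25 mm by protocol).  Locating it in the image and measuring its
radius in pixels yields the "pel density" — the physical size one pixel
represents — which converts every downstream pixel measurement (grain
dimensions, panicle length) into millimetres and makes the pipeline
independent of camera distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from ._color import classify_hsv


class CalibratorNotFoundError(ValueError):
    """No red connected component above the minimum area."""


class AmbiguousCalibratorError(ValueError):
    """More than one red component of comparable size."""


@dataclass(frozen=True)
class CalibratorDetection:
    """A located calibrator: centroid, equal-area-circle radius, and mask."""

    center: tuple[float, float]  # (row, col)
    pixel_radius: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if self.pixel_radius <= 0:
            raise ValueError("pixel_radius must be > 0")


@dataclass(frozen=True)
class PelDensity:
    """Physical scale of the image: millimetres represented by one pixel."""

    mm_per_pixel: float
    real_radius_mm: float
    pixel_radius: float


def _red_mask(
    image: np.ndarray,
    hue_max_deg: float = 10.0,
    hue_min_deg: float = 350.0,
    s_min: float = 0.4,
    v_min: float = 0.2,
) -> np.ndarray:
    """Classify red pixels in HSV: hue in [0, hue_max] U [hue_min, 360]."""
    return classify_hsv(
        image, [(0.0, hue_max_deg), (hue_min_deg, 360.0)], s_min, v_min)


def detect_calibrator(
    image: np.ndarray,
    *,
    min_area: float = 200.0,
    hue_max_deg: float = 10.0,
    hue_min_deg: float = 350.0,
    s_min: float = 0.4,
    v_min: float = 0.2,
    ambiguity_ratio: float = 0.8,
) -> CalibratorDetection:
    """Locate the red calibrator disk and measure its pixel radius.

    The largest red-classified connected component is taken as the
    calibrator; its radius is that of the equal-area circle,
    ``sqrt(area / pi)``, which is robust to ragged segmentation edges.

    Parameters
    ----------
    image : (H, W, 3) RGB array, uint8 or float in [0, 1].
    min_area : smallest component area (px^2) considered a candidate.
    ambiguity_ratio : a second candidate whose area exceeds this fraction
        of the largest's raises :class:`AmbiguousCalibratorError`.

    Raises
    ------
    CalibratorNotFoundError
        If no red component reaches ``min_area``.
    AmbiguousCalibratorError
        If two candidates are within 20 % of each other in area
        (default ``ambiguity_ratio`` 0.8).
    """
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an RGB image of shape (H, W, 3)")
    red = _red_mask(image, hue_max_deg, hue_min_deg, s_min, v_min)
    labels = label(red, connectivity=2)
    props = [p for p in regionprops(labels) if p.area >= min_area]
    if not props:
        raise CalibratorNotFoundError(
            f"calibrator not found: no red component with area >= {min_area}"
        )
    props.sort(key=lambda p: p.area, reverse=True)
    if len(props) > 1 and props[1].area >= ambiguity_ratio * props[0].area:
        raise AmbiguousCalibratorError(
            "ambiguous calibrator: two red components of comparable area "
            f"({props[0].area} and {props[1].area} px^2)"
        )
    best = props[0]
    return CalibratorDetection(
        center=tuple(best.centroid),
        pixel_radius=float(np.sqrt(best.area / np.pi)),
        mask=labels == best.label,
    )


def compute_pel_density(
    pixel_radius: float, real_radius_mm: float = 25.0
) -> PelDensity:
    """Pel density: real calibrator radius divided by its pixel radius."""
    if pixel_radius <= 0:
        raise ValueError("pixel_radius must be > 0")
    if real_radius_mm <= 0:
        raise ValueError("real_radius_mm must be > 0")
    return PelDensity(
        mm_per_pixel=real_radius_mm / pixel_radius,
        real_radius_mm=real_radius_mm,
        pixel_radius=pixel_radius,
    )


def calibration_row(image_id: str, det: CalibratorDetection, pel: PelDensity) -> dict:
    """One CSV-ready record of a calibration result."""
    return {
        "image_id": image_id,
        "pixel_radius": det.pixel_radius,
        "mm_per_pixel": pel.mm_per_pixel,
    }
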
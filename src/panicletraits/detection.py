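"""Grain detections: data model, IoU / confidence / NMS, file I/O, and a
classical colour-segmentation baseline detector.

Detections are axis-aligned boxes with a confidence in [0, 1] — the
currency between the detector, the counter, and morphometry.  A trained
network can supply them through the detection-file formats (flat CSV or
COCO-style JSON); the baseline detector lets the pipeline run end to end
without trained weights.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.segmentation import watershed

from ._color import classify_hsv, value_channel

log = logging.getLogger(__name__)


class DetectionParseError(ValueError):
    """A detection file could not be parsed; names the offending line/field."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, half-open ([x_min, x_max) x [y_min, y_max)), 0-based."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(
                f"degenerate box: ({self.x_min}, {self.y_min}, "
                f"{self.x_max}, {self.y_max})"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)


@dataclass
class DetectionSet:
    """All detections for one image."""

    image_id: str
    image_size: tuple[int, int]  # (H, W)
    boxes: list[BBox] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.boxes)

    def clipped(self) -> "DetectionSet":
        """Clip boxes to image bounds; drop (with a warning) any emptied box."""
        h, w = self.image_size
        kept = []
        for b in self.boxes:
            x0, y0 = max(b.x_min, 0.0), max(b.y_min, 0.0)
            x1, y1 = min(b.x_max, float(w)), min(b.y_max, float(h))
            if x0 < x1 and y0 < y1:
                kept.append(BBox(x0, y0, x1, y1, b.confidence))
            else:
                log.warning(
                    "%s: box (%s,%s,%s,%s) clipped to empty, dropped",
                    self.image_id, b.x_min, b.y_min, b.x_max, b.y_max,
                )
        return DetectionSet(self.image_id, self.image_size, kept)


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; 0 = disjoint, 1 = identical."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def filter_confidence(d: DetectionSet, conf: float) -> DetectionSet:
    """Keep boxes with confidence >= conf, preserving order."""
    if not 0.0 <= conf <= 1.0:
        raise ValueError("conf must be in [0, 1]")
    return replace(d, boxes=[b for b in d.boxes if b.confidence >= conf])


def _nms_order(boxes: list[BBox]) -> list[int]:
    return sorted(
        range(len(boxes)),
        key=lambda i: (-boxes[i].confidence, boxes[i].x_min, boxes[i].y_min),
    )


def nms(d: DetectionSet, iou_threshold: float) -> DetectionSet:
    """Greedy non-maximum suppression.

    Boxes are visited in order of descending confidence (ties broken by
    x_min then y_min ascending); each kept box suppresses remaining boxes
    whose IoU with it exceeds ``iou_threshold``.  Survivors keep the
    confidence-sorted order, so the result is deterministic.
    """
    if not 0.0 <= iou_threshold <= 1.0:
        raise ValueError("iou_threshold must be in [0, 1]")
    order = _nms_order(d.boxes)
    kept: list[int] = []
    suppressed = [False] * len(d.boxes)
    for i in order:
        if suppressed[i]:
            continue
        kept.append(i)
        for j in order:
            if not suppressed[j] and j != i:
                if iou(d.boxes[i], d.boxes[j]) > iou_threshold:
                    suppressed[j] = True
    return replace(d, boxes=[d.boxes[i] for i in kept])


@dataclass(frozen=True)
class BaselineDetectorConfig:
    """Classical grain detector: colour threshold -> components -> watershed split.

    ``method`` selects the foreground rule:

    * ``"hsv_range"`` (default): pixels inside a hue/saturation/value band
      tuned to grain colour — the only rule that isolates grains in a
      scene that also contains a green stem and a red calibrator;
    * ``"otsu_value"``: Otsu threshold on the HSV value channel (bright
      objects on a darker board);
    * ``"rgb_range"``: fixed per-channel RGB bounds.

    Components larger than ``split_factor`` x the median component area
    are split by distance-transform watershed (touching grains).
    Confidence of each box is the component's solidity, clamped to [0, 1]:
    clean single grains are convex (solidity near 1) while merged or
    partial blobs score lower.
    """

    method: str = "hsv_range"
    hue_range_deg: tuple[float, float] = (20.0, 75.0)
    s_min: float = 0.25
    v_min: float = 0.35
    rgb_low: tuple[int, int, int] = (120, 100, 0)
    rgb_high: tuple[int, int, int] = (255, 230, 140)
    min_area: float = 30.0
    split_factor: float = 1.6
    watershed_min_distance: int = 5


def _foreground(image: np.ndarray, cfg: BaselineDetectorConfig) -> np.ndarray:
    if cfg.method == "hsv_range":
        return classify_hsv(image, [cfg.hue_range_deg], cfg.s_min, cfg.v_min)
    if cfg.method == "otsu_value":
        v = value_channel(image)
        return v > threshold_otsu(v)
    if cfg.method == "rgb_range":
        img = image if image.dtype == np.uint8 else (image * 255).astype(np.uint8)
        lo = np.asarray(cfg.rgb_low)
        hi = np.asarray(cfg.rgb_high)
        return np.all((img >= lo) & (img <= hi), axis=-1)
    raise ValueError(f"unknown segmentation method {cfg.method!r}")


def _split_component(mask: np.ndarray, min_distance: int) -> np.ndarray:
    """Distance-transform watershed labels of one oversized component."""
    dist = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        dist, min_distance=min_distance, labels=mask, exclude_border=False
    )
    if len(peaks) < 2:
        return mask.astype(np.int32)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    return watershed(-dist, markers, mask=mask)


def baseline_detect(
    image: np.ndarray, cfg: BaselineDetectorConfig | None = None
) -> DetectionSet:
    """Detect grain-like blobs without trained weights.

    Pipeline: foreground threshold -> connected components -> components
    whose area exceeds ``split_factor`` x the median are re-split by a
    distance-transform watershed -> one box per final component with
    confidence = solidity.  An empty foreground yields an empty set.
    """
    cfg = cfg or BaselineDetectorConfig()
    h, w = image.shape[:2]
    fg = _foreground(image, cfg)
    labels = label(fg, connectivity=2)
    props = [p for p in regionprops(labels) if p.area >= cfg.min_area]
    if not props:
        return DetectionSet("", (h, w), [])
    median_area = float(np.median([p.area for p in props]))
    boxes: list[BBox] = []
    for p in props:
        sub_masks: list[tuple[np.ndarray, tuple[int, int]]] = []
        if p.area > cfg.split_factor * median_area:
            sub = _split_component(p.image, cfg.watershed_min_distance)
            for lab in np.unique(sub):
                if lab == 0:
                    continue
                sub_masks.append((sub == lab, p.bbox[:2]))
        else:
            sub_masks.append((p.image, p.bbox[:2]))
        for m, (r0, c0) in sub_masks:
            if m.sum() < cfg.min_area:
                continue
            rows, cols = np.nonzero(m)
            rp = regionprops(m.astype(np.uint8))[0]
            conf = float(np.clip(rp.solidity, 0.0, 1.0))
            boxes.append(
                BBox(
                    x_min=float(c0 + cols.min()),
                    y_min=float(r0 + rows.min()),
                    x_max=float(c0 + cols.max() + 1),
                    y_max=float(r0 + rows.max() + 1),
                    confidence=conf,
                )
            )
    boxes.sort(key=lambda b: (b.y_min, b.x_min))
    return DetectionSet("", (h, w), boxes)


# ---------------------------------------------------------------------------
# file formats

_CSV_FIELDS = ["image_id", "image_h", "image_w",
               "x_min", "y_min", "x_max", "y_max", "confidence"]


def write_detections(d: DetectionSet, path) -> None:
    """Write a DetectionSet as a flat CSV (one row per box)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        h, w = d.image_size
        if not d.boxes:
            # sizes still recorded for an empty set
            writer.writerow([d.image_id, h, w, "", "", "", "", ""])
        for b in d.boxes:
            writer.writerow(
                [d.image_id, h, w, repr(b.x_min), repr(b.y_min),
                 repr(b.x_max), repr(b.y_max), repr(b.confidence)]
            )


def _parse_row(row: dict, lineno: int) -> BBox | None:
    if row["x_min"] == "" and row["x_max"] == "":
        return None
    vals = {}
    for fld in ("x_min", "y_min", "x_max", "y_max", "confidence"):
        try:
            vals[fld] = float(row[fld])
        except (TypeError, ValueError, KeyError):
            raise DetectionParseError(
                f"line {lineno}: field {fld!r} is not a number: {row.get(fld)!r}"
            )
    try:
        return BBox(**vals)
    except ValueError as exc:
        raise DetectionParseError(f"line {lineno}: {exc}") from exc


def read_detections(path) -> DetectionSet:
    """Read a flat-CSV detection file written by :func:`write_detections`."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(_CSV_FIELDS) - set(reader.fieldnames):
            raise DetectionParseError(
                f"header must contain fields {_CSV_FIELDS}, got {reader.fieldnames}"
            )
        image_id, size = None, None
        boxes: list[BBox] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                size = (int(row["image_h"]), int(row["image_w"]))
            except (TypeError, ValueError):
                raise DetectionParseError(
                    f"line {lineno}: bad image size "
                    f"({row.get('image_h')!r}, {row.get('image_w')!r})"
                )
            image_id = row["image_id"]
            box = _parse_row(row, lineno)
            if box is not None:
                boxes.append(box)
    if image_id is None:
        raise DetectionParseError("empty detection file")
    return DetectionSet(image_id, size, boxes)


def read_detections_coco(path) -> list[DetectionSet]:
    """Read COCO-style JSON: bbox given as [x, y, w, h], optional 'score'."""
    with open(path) as fh:
        doc = json.load(fh)
    try:
        images = {im["id"]: im for im in doc["images"]}
    except (KeyError, TypeError) as exc:
        raise DetectionParseError(f"missing/invalid 'images' section: {exc}")
    sets: dict = {
        im_id: DetectionSet(
            str(im.get("file_name", im_id)), (im["height"], im["width"]), []
        )
        for im_id, im in images.items()
    }
    for i, ann in enumerate(doc.get("annotations", [])):
        try:
            x, y, w, h = ann["bbox"]
            box = BBox(x, y, x + w, y + h, float(ann.get("score", 1.0)))
            sets[ann["image_id"]].boxes.append(box)
        except (KeyError, ValueError, TypeError) as exc:
            raise DetectionParseError(f"annotation {i}: {exc}") from exc
    return list(sets.values())
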
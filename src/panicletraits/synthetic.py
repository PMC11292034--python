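"""Ground-truthed synthetic panicle scenes.

Scenes emulate the acquisition protocol the pipeline targets: a single
panicle laid on a uniform board, photographed face-on, with a red
circular calibrator of known physical radius in frame.  A scene holds

* a board-coloured background with mild sensor noise,
* a red calibrator disk of known pixel radius (anchoring mm/px),
* a curved main stem (quadratic Bezier) with short upward branches,
* ``n_grains`` elliptical grains of configurable physical size placed
  in a band around the stem, never touching it, at a controllable
  mutual-overlap level,

plus complete ground truth: per-grain ellipse and box, stem polyline
and rasterised stem-skeleton pixel count, calibrator geometry, and the
implied mm/px.  A detection error model simulates a detector whose
miss probability grows with per-grain occlusion, providing the forecast
side of the PMI at controlled occlusion without trained weights.

All randomness flows from the scene seed through independent
substreams (stem shape / grain sizes / placement / pixel noise), so a
scene is bit-reproducible and its stem geometry is unchanged by
resolution rescaling (:meth:`SceneSpec.scaled`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.morphology import skeletonize as _sk_skeletonize

from .detection import BBox, DetectionSet
from .counting import CountPair, pmi_from_counts


class PlacementError(RuntimeError):
    """Grains could not be placed at the requested overlap level."""


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic panicle scene.

    Physical quantities are in mm; pixel quantities scale with
    resolution via :meth:`scaled`.  Positions given as fractions of the
    image size are resolution-free.
    """

    image_id: str = "scene"
    image_size: tuple[int, int] = (2000, 1500)  # (H, W)
    calibrator_center_frac: tuple[float, float] = (0.14, 0.82)
    calibrator_pixel_radius: float = 250.0  # 25 mm -> 0.1 mm/px
    real_radius_mm: float = 25.0
    stem_bottom_frac: tuple[float, float] = (0.94, 0.42)
    stem_top_frac: tuple[float, float] = (0.15, 0.50)
    stem_thickness_px: float = 7.0
    n_branches: int = 5
    branch_length_frac: tuple[float, float] = (0.035, 0.065)  # of H
    n_grains: int = 50
    grain_length_mm: float = 9.0
    grain_width_mm: float = 3.0
    grain_length_sd_mm: float = 0.25
    grain_width_sd_mm: float = 0.12
    grain_band_frac: float = 0.24  # lateral band half-width, of W
    overlap_level: float = 0.0
    board_rgb: tuple[int, int, int] = (205, 205, 208)
    stem_rgb: tuple[int, int, int] = (60, 150, 70)
    grain_rgb: tuple[int, int, int] = (215, 185, 90)
    calibrator_rgb: tuple[int, int, int] = (200, 35, 35)
    noise_sd: float = 2.0
    max_place_attempts: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_level <= 1.0:
            raise ValueError("overlap_level must be in [0, 1]")
        for v in (self.calibrator_pixel_radius, self.real_radius_mm,
                  self.stem_thickness_px, self.grain_length_mm,
                  self.grain_width_mm):
            if v <= 0:
                raise ValueError("all dimensions must be positive")

    @property
    def mm_per_pixel(self) -> float:
        return self.real_radius_mm / self.calibrator_pixel_radius

    def scaled(self, k: float) -> "SceneSpec":
        """Same scene at k-times the resolution (same physical content)."""
        h, w = self.image_size
        return replace(
            self,
            image_size=(int(round(h * k)), int(round(w * k))),
            calibrator_pixel_radius=self.calibrator_pixel_radius * k,
            stem_thickness_px=self.stem_thickness_px * k,
        )


@dataclass(frozen=True)
class GrainTruth:
    """One grain: oriented ellipse (semi-axes, px) and axis-aligned box."""

    center: tuple[float, float]  # (row, col)
    semi_axes: tuple[float, float]  # (a, b), a >= b, px
    angle_deg: float  # of the major axis from the +col axis
    box: BBox
    length_mm: float
    width_mm: float


@dataclass
class SceneTruth:
    image_id: str
    image_size: tuple[int, int]
    mm_per_pixel: float
    calibrator_center: tuple[float, float]
    calibrator_radius_px: float
    real_radius_mm: float
    grains: list[GrainTruth]
    stem_polyline: np.ndarray  # (N, 2) float (row, col)
    stem_skeleton_pixel_count: int

    @property
    def count(self) -> int:
        return len(self.grains)

    def detection_set(self) -> DetectionSet:
        """Ground-truth boxes as a perfect-confidence DetectionSet."""
        return DetectionSet(
            self.image_id, self.image_size,
            [g.box for g in self.grains],
        )

    def to_json(self) -> str:
        doc = {
            "image_id": self.image_id,
            "image_size": list(self.image_size),
            "mm_per_pixel": self.mm_per_pixel,
            "calibrator_center": list(self.calibrator_center),
            "calibrator_radius_px": self.calibrator_radius_px,
            "real_radius_mm": self.real_radius_mm,
            "stem_skeleton_pixel_count": self.stem_skeleton_pixel_count,
            "grains": [
                {
                    "center": list(g.center),
                    "semi_axes": list(g.semi_axes),
                    "angle_deg": g.angle_deg,
                    "box": [g.box.x_min, g.box.y_min, g.box.x_max, g.box.y_max],
                    "length_mm": g.length_mm,
                    "width_mm": g.width_mm,
                }
                for g in self.grains
            ],
        }
        return json.dumps(doc, indent=1)


def _bezier(p0, p1, p2, n=1600):
    t = np.linspace(0.0, 1.0, n)[:, None]
    return ((1 - t) ** 2) * p0 + 2 * (1 - t) * t * p1 + t * t * p2


def _paint_curve(canvas: np.ndarray, pts: np.ndarray, radius: float) -> None:
    """Paint disks of ``radius`` along a polyline onto a boolean canvas."""
    h, w = canvas.shape
    r = max(1, int(round(radius)))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    disk = (yy ** 2 + xx ** 2) <= radius ** 2
    dy, dx = np.nonzero(disk)
    dy, dx = dy - r, dx - r
    ij = np.unique(np.round(pts).astype(int), axis=0)
    rows = (ij[:, 0][:, None] + dy[None, :]).ravel()
    cols = (ij[:, 1][:, None] + dx[None, :]).ravel()
    ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
    canvas[rows[ok], cols[ok]] = True


def _stem_geometry(spec: SceneSpec, rng: np.random.Generator):
    """Stem polyline, branch polylines, and the combined raster mask."""
    h, w = spec.image_size
    p0 = np.array([spec.stem_bottom_frac[0] * h, spec.stem_bottom_frac[1] * w])
    p2 = np.array([spec.stem_top_frac[0] * h, spec.stem_top_frac[1] * w])
    # lateral bow of the stem, as a resolution-free fraction of width
    bow = rng.uniform(-0.12, 0.12)
    mid = (p0 + p2) / 2 + np.array([0.0, bow * w])
    stem = _bezier(p0, mid, p2)

    branches = []
    for _ in range(spec.n_branches):
        t = rng.uniform(0.30, 0.72)
        idx = int(t * (len(stem) - 1))
        attach = stem[idx]
        ang = rng.uniform(np.radians(25), np.radians(65)) * rng.choice([-1, 1])
        length = rng.uniform(*spec.branch_length_frac) * h
        # branches point upward (decreasing row)
        direction = np.array([-np.cos(ang), np.sin(ang)])
        end = attach + direction * length
        branches.append(_bezier(attach, (attach + end) / 2, end, n=200))

    stem_mask = np.zeros((h, w), dtype=bool)
    _paint_curve(stem_mask, stem, spec.stem_thickness_px / 2)
    full_mask = stem_mask.copy()
    br_radius = max(1.0, spec.stem_thickness_px / 2 - 1.5)
    for br in branches:
        _paint_curve(full_mask, br, br_radius)
    return stem, branches, stem_mask, full_mask


def _ellipse_box(center, a, b, angle_deg) -> BBox:
    th = np.radians(angle_deg)
    ex = np.sqrt((a * np.cos(th)) ** 2 + (b * np.sin(th)) ** 2)
    ey = np.sqrt((a * np.sin(th)) ** 2 + (b * np.cos(th)) ** 2)
    cy, cx = center
    return BBox(cx - ex, cy - ey, cx + ex, cy + ey, 1.0)


def ellipse_mask(grain: GrainTruth, shape: tuple[int, int]) -> np.ndarray:
    """Rasterise a ground-truth grain ellipse (pixel-centre inclusion)."""
    h, w = shape
    cy, cx = grain.center
    a, b = grain.semi_axes
    th = np.radians(grain.angle_deg)
    r0, r1 = max(0, int(cy - a - 2)), min(h, int(cy + a + 3))
    c0, c1 = max(0, int(cx - a - 2)), min(w, int(cx + a + 3))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dx = (xx + 0.5) - cx
    dy = (yy + 0.5) - cy
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    out = np.zeros(shape, dtype=bool)
    out[r0:r1, c0:c1] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return out


def _boxes_disjoint(a: BBox, b: BBox, margin: float = 1.0) -> bool:
    return (
        a.x_max + margin <= b.x_min or b.x_max + margin <= a.x_min
        or a.y_max + margin <= b.y_min or b.y_max + margin <= a.y_min
    )


def _place_grains(spec: SceneSpec, stem: np.ndarray, full_mask: np.ndarray,
                  r_sizes: np.random.Generator, r_place: np.random.Generator
                  ) -> list[GrainTruth]:
    h, w = spec.image_size
    mmpp = spec.mm_per_pixel
    cal_box = BBox(
        spec.calibrator_center_frac[1] * w - spec.calibrator_pixel_radius - 10,
        spec.calibrator_center_frac[0] * h - spec.calibrator_pixel_radius - 10,
        spec.calibrator_center_frac[1] * w + spec.calibrator_pixel_radius + 10,
        spec.calibrator_center_frac[0] * h + spec.calibrator_pixel_radius + 10,
    )
    band = spec.grain_band_frac * w
    # grain sizes and orientations are drawn up-front from their own
    # substream, so placement retries never perturb them
    lengths = np.maximum(
        r_sizes.normal(spec.grain_length_mm, spec.grain_length_sd_mm,
                       spec.n_grains), 0.2 * spec.grain_length_mm)
    widths = np.maximum(
        r_sizes.normal(spec.grain_width_mm, spec.grain_width_sd_mm,
                       spec.n_grains), 0.2 * spec.grain_width_mm)
    angles = r_sizes.uniform(0.0, 180.0, spec.n_grains)

    grains: list[GrainTruth] = []
    for i in range(spec.n_grains):
        a = lengths[i] / 2 / mmpp
        b = widths[i] / 2 / mmpp
        placed = False
        for _ in range(spec.max_place_attempts):
            overlap_mode = grains and r_place.random() < spec.overlap_level
            if overlap_mode:
                anchor = grains[r_place.integers(len(grains))]
                phi = r_place.uniform(0, 2 * np.pi)
                dist = (anchor.semi_axes[1] + b) * r_place.uniform(0.5, 1.0)
                cy = anchor.center[0] + dist * np.sin(phi)
                cx = anchor.center[1] + dist * np.cos(phi)
            else:
                t = r_place.uniform(0.05, 0.95)
                idx = int(t * (len(stem) - 1))
                phi = r_place.uniform(0, 2 * np.pi)
                rad = band * np.sqrt(r_place.random())
                cy = stem[idx, 0] + rad * np.sin(phi)
                cx = stem[idx, 1] + rad * np.cos(phi)
            box = _ellipse_box((cy, cx), a, b, angles[i])
            if box.x_min < 2 or box.y_min < 2 or box.x_max > w - 2 \
                    or box.y_max > h - 2:
                continue
            if not _boxes_disjoint(box, cal_box, margin=0):
                continue
            # conservative no-touch test: the grain's circumscribed
            # square around the stem raster must be stem-free
            ir, ic = int(round(cy)), int(round(cx))
            rad = int(np.ceil(a + 2))
            win = full_mask[max(0, ir - rad):ir + rad + 1,
                            max(0, ic - rad):ic + rad + 1]
            if win.any():
                continue
            if overlap_mode:
                anchor_iou_ok = not _boxes_disjoint(box, anchor.box, margin=-1)
                others_ok = True  # overlapping others too is acceptable
                if not anchor_iou_ok or not others_ok:
                    continue
            else:
                if any(not _boxes_disjoint(box, g.box) for g in grains):
                    continue
            grains.append(GrainTruth(
                center=(cy, cx), semi_axes=(a, b), angle_deg=float(angles[i]),
                box=box, length_mm=float(lengths[i]), width_mm=float(widths[i]),
            ))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place grain {i} at overlap_level "
                f"{spec.overlap_level} within {spec.max_place_attempts} attempts"
            )
    return grains


def _paint_ellipse(img: np.ndarray, grain: GrainTruth, color, rng) -> None:
    """Anti-aliased ellipse fill (2x2 supersampling per pixel)."""
    h, w = img.shape[:2]
    cy, cx = grain.center
    a, b = grain.semi_axes
    th = np.radians(grain.angle_deg)
    r0, r1 = max(0, int(cy - a - 2)), min(h, int(cy + a + 3))
    c0, c1 = max(0, int(cx - a - 2)), min(w, int(cx + a + 3))
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    cov = np.zeros(yy.shape, dtype=float)
    for oy in (0.25, 0.75):
        for ox in (0.25, 0.75):
            dx = (xx + ox) - cx
            dy = (yy + oy) - cy
            u = dx * np.cos(th) + dy * np.sin(th)
            v = -dx * np.sin(th) + dy * np.cos(th)
            cov += ((u / a) ** 2 + (v / b) ** 2 <= 1.0)
    cov /= 4.0
    shade = np.asarray(color, dtype=float) + rng.normal(0, 4, size=3)
    patch = img[r0:r1, c0:c1].astype(float)
    img[r0:r1, c0:c1] = (
        patch * (1 - cov[..., None]) + shade[None, None, :] * cov[..., None]
    ).clip(0, 255).astype(np.uint8)


def _paint_disk_aa(img: np.ndarray, center, radius: float, color) -> None:
    h, w = img.shape[:2]
    cy, cx = center
    r0, r1 = max(0, int(cy - radius - 2)), min(h, int(cy + radius + 3))
    c0, c1 = max(0, int(cx - radius - 2)), min(w, int(cx + radius + 3))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    cov = np.zeros(yy.shape, dtype=float)
    for oy in (0.25, 0.75):
        for ox in (0.25, 0.75):
            cov += ((yy + oy - cy) ** 2 + (xx + ox - cx) ** 2) <= radius ** 2
    cov /= 4.0
    patch = img[r0:r1, c0:c1].astype(float)
    col = np.asarray(color, dtype=float)
    img[r0:r1, c0:c1] = (
        patch * (1 - cov[..., None]) + col[None, None, :] * cov[..., None]
    ).clip(0, 255).astype(np.uint8)


def generate_scene(
    spec: SceneSpec, render: bool = True
) -> tuple[np.ndarray | None, SceneTruth]:
    """Generate one scene; deterministic given ``spec.seed``.

    With ``render=False`` only the ground truth is built (placement,
    stem geometry, skeleton count) — much faster for counting
    simulations that never look at pixels.
    """
    h, w = spec.image_size
    ss = np.random.SeedSequence(spec.seed)
    r_stem, r_sizes, r_place, r_noise = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    stem, branches, stem_mask, full_mask = _stem_geometry(spec, r_stem)
    grains = _place_grains(spec, stem, full_mask, r_sizes, r_place)
    skeleton_count = int(_sk_skeletonize(stem_mask).sum())
    cal_center = (spec.calibrator_center_frac[0] * h,
                  spec.calibrator_center_frac[1] * w)
    truth = SceneTruth(
        image_id=spec.image_id,
        image_size=spec.image_size,
        mm_per_pixel=spec.mm_per_pixel,
        calibrator_center=cal_center,
        calibrator_radius_px=spec.calibrator_pixel_radius,
        real_radius_mm=spec.real_radius_mm,
        grains=grains,
        stem_polyline=stem,
        stem_skeleton_pixel_count=skeleton_count,
    )
    if not render:
        return None, truth

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[...] = np.asarray(spec.board_rgb, dtype=np.uint8)
    stem_col = np.asarray(spec.stem_rgb, dtype=np.uint8)
    img[full_mask] = stem_col
    _paint_disk_aa(img, cal_center, spec.calibrator_pixel_radius,
                   spec.calibrator_rgb)
    for g in grains:
        _paint_ellipse(img, g, spec.grain_rgb, r_noise)
    if spec.noise_sd > 0:
        noise = r_noise.standard_normal(img.shape, dtype=np.float32)
        noise *= spec.noise_sd
        noise += img
        img = noise.clip(0, 255).astype(np.uint8)
    return img, truth


@dataclass(frozen=True)
class DetectionErrorModel:
    """Simulated detector: miss probability grows with occlusion.

    A grain whose box has maximum IoU ``o`` with any other grain box is
    detected with probability ``1 - alpha * o`` (``miss_curve
    "linear"``) or ``1 - 1/(1 + exp(-steepness*(o - midpoint)))``
    (``"logistic"``).  Detected boxes get i.i.d. Gaussian corner jitter
    and a confidence drawn around ``conf_mean - conf_slope * o``.
    """

    alpha: float = 0.9
    miss_curve: str = "linear"
    logistic_midpoint: float = 0.35
    logistic_steepness: float = 10.0
    jitter_sd: float = 1.0
    conf_mean: float = 0.92
    conf_slope: float = 0.35
    conf_sd: float = 0.04

    def detect_probability(self, o: np.ndarray) -> np.ndarray:
        o = np.asarray(o, dtype=float)
        if self.miss_curve == "linear":
            return np.clip(1.0 - self.alpha * o, 0.0, 1.0)
        if self.miss_curve == "logistic":
            return 1.0 - 1.0 / (
                1.0 + np.exp(-self.logistic_steepness * (o - self.logistic_midpoint))
            )
        raise ValueError(f"unknown miss_curve {self.miss_curve!r}")


def grain_occlusions(truth: SceneTruth) -> np.ndarray:
    """Per-grain occlusion: max IoU of its box with any other grain box."""
    from .detection import iou as box_iou

    boxes = [g.box for g in truth.grains]
    n = len(boxes)
    occ = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            v = box_iou(boxes[i], boxes[j])
            if v > occ[i]:
                occ[i] = v
            if v > occ[j]:
                occ[j] = v
    return occ


def simulate_detections(
    truth: SceneTruth,
    error_model: DetectionErrorModel | None = None,
    seed: int = 0,
) -> DetectionSet:
    """Simulated detector output for a scene; deterministic given seed."""
    em = error_model or DetectionErrorModel()
    rng = np.random.default_rng(seed)
    occ = grain_occlusions(truth)
    p = em.detect_probability(occ)
    h, w = truth.image_size
    boxes: list[BBox] = []
    for g, pi, oi in zip(truth.grains, p, occ):
        if rng.random() >= pi:
            continue
        jit = rng.normal(0.0, em.jitter_sd, size=4) if em.jitter_sd > 0 \
            else np.zeros(4)
        x0 = g.box.x_min + jit[0]
        y0 = g.box.y_min + jit[1]
        x1 = max(g.box.x_max + jit[2], x0 + 1.0)
        y1 = max(g.box.y_max + jit[3], y0 + 1.0)
        x0, x1 = max(x0, 0.0), min(x1, float(w))
        y0, y1 = max(y0, 0.0), min(y1, float(h))
        conf = float(np.clip(
            rng.normal(em.conf_mean - em.conf_slope * oi, em.conf_sd),
            0.01, 1.0))
        boxes.append(BBox(x0, y0, x1, y1, conf))
    return DetectionSet(truth.image_id, truth.image_size, boxes)


def pmi_dataset(
    specs: list[SceneSpec],
    error_model: DetectionErrorModel | None = None,
    seed: int = 0,
):
    """Simulate a (image_id, n_actual, n_forecast, pmi) table.

    For each spec the scene truth is generated (no rendering), a
    detector pass is simulated, and the ground-truth PMI computed from
    the count pair.  Per-scene randomness is spawned from ``seed`` so
    row i does not depend on batch size.
    """
    import pandas as pd

    children = np.random.SeedSequence(seed).spawn(len(specs))
    rows = []
    for spec, child in zip(specs, children):
        _, truth = generate_scene(spec, render=False)
        det = simulate_detections(truth, error_model,
                                  seed=int(child.generate_state(1)[0] % (2**31)))
        n_actual, n_forecast = truth.count, len(det.boxes)
        pmi = pmi_from_counts(CountPair(n_actual, n_forecast)).value \
            if n_actual >= 1 else float("nan")
        rows.append({
            "image_id": spec.image_id,
            "n_actual": n_actual,
            "n_forecast": n_forecast,
            "pmi": pmi,
        })
    return pd.DataFrame(rows)
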
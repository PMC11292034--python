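"""Batch pipeline: image -> calibrate -> detect -> count -> measure.

Each image is processed in isolation: a stage failure nulls that
image's affected trait fields and records the reason, but never aborts
the batch or alters another image's row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import calibration, counting, detection, morphometry, panicle_length
from .detection import BaselineDetectorConfig, DetectionSet
from .morphometry import ScreeningConfig

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything the batch pipeline needs, overridable from YAML/flags."""

    real_radius_mm: float = 25.0
    calibrator_min_area: float = 200.0
    detector: str = "baseline"  # "baseline" | path to a detections CSV dir
    baseline: BaselineDetectorConfig = field(default_factory=BaselineDetectorConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    pmi_source: str = "heuristic"  # "heuristic" | path to a PMI CSV
    pmi_floor: float = 0.05
    s_threshold: str | float = "otsu"
    length_min_area: float | None = None
    length_mode: str = "pixel_count"
    grain_segmentation: str = "otsu"
    seed: int = 0


@dataclass
class PanicleTraits:
    """Per-image trait record; missing stages are None with a reason."""

    image_id: str
    mm_per_pixel: float | None = None
    n_predict: int | None = None
    pmi: float | None = None
    n_grain: int | None = None
    n_measured: int | None = None
    mean_length_mm: float | None = None
    mean_width_mm: float | None = None
    mean_aspect: float | None = None
    panicle_length_px: float | None = None
    panicle_length_mm: float | None = None
    reasons: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "image_id": self.image_id,
            "mm_per_pixel": self.mm_per_pixel,
            "n_predict": self.n_predict,
            "pmi": self.pmi,
            "n_grain": self.n_grain,
            "n_measured": self.n_measured,
            "mean_length_mm": self.mean_length_mm,
            "mean_width_mm": self.mean_width_mm,
            "mean_aspect": self.mean_aspect,
            "panicle_length_px": self.panicle_length_px,
            "panicle_length_mm": self.panicle_length_mm,
        }
        row["reasons"] = ";".join(f"{k}:{v}" for k, v in self.reasons.items())
        return row


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def _get_detections(image, image_id, cfg: PipelineConfig) -> DetectionSet:
    if cfg.detector == "baseline":
        d = detection.baseline_detect(image, cfg.baseline)
        d.image_id = image_id
        return d
    path = Path(cfg.detector)
    f = path / f"{image_id}.csv" if path.is_dir() else path
    return detection.read_detections(f).clipped()


def analyze_image(
    image: np.ndarray,
    image_id: str,
    cfg: PipelineConfig | None = None,
    pmi_lookup=None,
) -> PanicleTraits:
    """Run the full trait pipeline on one RGB image.

    ``pmi_lookup`` is an optional ``image_id -> PMIValue`` provider
    (e.g. from :func:`panicletraits.counting.pmi_provider`); without it
    the geometric box-overlap heuristic is used.
    """
    cfg = cfg or PipelineConfig()
    traits = PanicleTraits(image_id=image_id)

    pel = None
    try:
        cal = calibration.detect_calibrator(
            image, min_area=cfg.calibrator_min_area)
        pel = calibration.compute_pel_density(
            cal.pixel_radius, cfg.real_radius_mm)
        traits.mm_per_pixel = pel.mm_per_pixel
    except Exception as exc:  # degraded mode: pixel traits only
        traits.reasons["calibration"] = str(exc)
        log.warning("%s calibration failed: %s", image_id, exc)

    dets = None
    try:
        dets = _get_detections(image, image_id, cfg)
        traits.n_predict = len(dets.boxes)
    except Exception as exc:
        traits.reasons["detection"] = str(exc)
        log.warning("%s detection failed: %s", image_id, exc)

    if dets is not None:
        try:
            if pmi_lookup is not None:
                pmi = pmi_lookup(image_id)
            else:
                pmi = counting.pmi_heuristic(dets)
            traits.pmi = pmi.value
            traits.n_grain = counting.calibrate_count(
                len(dets.boxes), pmi, cfg.pmi_floor).n_grain
        except Exception as exc:
            traits.reasons["counting"] = str(exc)
            log.warning("%s counting failed: %s", image_id, exc)

    if dets is not None and pel is not None:
        try:
            meas = morphometry.measure_grains(
                image, dets, cfg.screening, pel,
                segmentation=cfg.grain_segmentation)
            stats = morphometry.panicle_grain_stats(meas)
            traits.n_measured = stats.n_measured
            traits.mean_length_mm = stats.mean_length_mm
            traits.mean_width_mm = stats.mean_width_mm
            traits.mean_aspect = stats.mean_aspect
        except Exception as exc:
            traits.reasons["morphometry"] = str(exc)
            log.warning("%s morphometry failed: %s", image_id, exc)

    try:
        mask = panicle_length.segment_panicle(image, cfg.s_threshold)
        mask = panicle_length.clean_mask(mask, cfg.length_min_area)
        sk = panicle_length.skeletonize(mask)
        path = panicle_length.main_path(sk)
        traits.panicle_length_px = float(path.pixel_count)
        if pel is not None:
            res = panicle_length.panicle_length_mm(path, pel, cfg.length_mode)
            traits.panicle_length_mm = res.length_mm
    except Exception as exc:
        traits.reasons["panicle_length"] = str(exc)
        log.warning("%s panicle length failed: %s", image_id, exc)

    log.info("%s done: %s", image_id,
             traits.reasons if traits.reasons else "all stages ok")
    return traits


def run_batch(
    image_paths: list, cfg: PipelineConfig | None = None, pmi_lookup=None
) -> pd.DataFrame:
    """Analyze a list of image files; one row per image, failures nulled."""
    cfg = cfg or PipelineConfig()
    rows = []
    for p in image_paths:
        image_id = Path(p).stem
        try:
            img = load_image(p)
        except Exception as exc:
            t = PanicleTraits(image_id=image_id)
            t.reasons["load"] = str(exc)
            rows.append(t.to_row())
            continue
        rows.append(analyze_image(img, image_id, cfg, pmi_lookup).to_row())
    return pd.DataFrame(rows)
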
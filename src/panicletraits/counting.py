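"""Occlusion-calibrated grain counting via the panicle morphology index.

A detector looking at an intact panicle systematically undercounts
because grains occlude one another.  The panicle morphology index (PMI)
quantifies that occlusion:

    PMI = 1 - |N_actual - N_forecast| / N_actual,      clamped to [0, 1]

so PMI = 1 means the detector saw every grain and PMI -> 0 means severe
occlusion.  Given a PMI for an image (from ground truth, an external
regression model, or the geometric heuristic below), the raw detector
count is calibrated by

    N_grain = round(N_predict / PMI)

which exactly recovers the true count whenever the detector only missed
grains (N_forecast <= N_actual), since then PMI = N_forecast / N_actual.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from typing import Callable

from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from .detection import DetectionSet

log = logging.getLogger(__name__)

PMI_SOURCES = ("ground_truth", "external", "heuristic")


@dataclass(frozen=True)
class CountPair:
    """Actual vs forecast grain count for one panicle."""

    n_actual: int
    n_forecast: int

    def __post_init__(self) -> None:
        if self.n_actual < 1:
            raise ValueError("n_actual must be >= 1")
        if self.n_forecast < 0:
            raise ValueError("n_forecast must be >= 0")


@dataclass(frozen=True)
class PMIValue:
    """Panicle morphology index in [0, 1]; 1 = no occlusion."""

    value: float
    source: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"PMI {self.value} outside [0, 1]")
        if self.source not in PMI_SOURCES:
            raise ValueError(f"source must be one of {PMI_SOURCES}")


@dataclass(frozen=True)
class CalibratedCount:
    """Raw detector count, the PMI used, and the calibrated grain count."""

    n_predict: int
    pmi: PMIValue
    n_grain: int


def pmi_from_counts(pair: CountPair) -> PMIValue:
    """Ground-truth PMI from an (actual, forecast) count pair.

    The unclamped expression can go negative when the forecast exceeds
    twice the actual count; the index is defined on [0, 1], so the value
    is clamped.
    """
    raw = 1.0 - abs(pair.n_actual - pair.n_forecast) / pair.n_actual
    return PMIValue(value=min(1.0, max(0.0, raw)), source="ground_truth")


def calibrate_count(
    n_predict: int, pmi: PMIValue, pmi_floor: float = 0.002
) -> CalibratedCount:
    """Calibrated grain count: raw count divided by PMI, rounded half-up.

    ``pmi_floor`` bounds the divisor away from zero (the calibration is
    undefined at PMI = 0); grain counts are integers, so the quotient is
    rounded to the nearest integer, halves up.  The default floor of
    0.002 sits below the smallest ground-truth PMI a panicle of up to
    500 grains can produce (1/500), so flooring never interferes with
    the exact undercount-recovery identity while still catching the
    degenerate PMI = 0 case.
    """
    if n_predict < 0:
        raise ValueError("n_predict must be >= 0")
    if pmi_floor <= 0:
        raise ValueError("pmi_floor must be > 0")
    divisor = max(pmi.value, pmi_floor)
    n_grain = math.floor(n_predict / divisor + 0.5)
    return CalibratedCount(n_predict=n_predict, pmi=pmi, n_grain=n_grain)


def pmi_heuristic(
    detections: DetectionSet, panicle_mask=None
) -> PMIValue:
    """Geometric PMI proxy from detection-box overlap.

    overlap_fraction = (sum of box areas - area of box union) / sum of
    box areas; PMI = 1 - overlap_fraction.  Pairwise-disjoint boxes give
    1.0; heavily stacked boxes drive the value toward 0.  A desk-scale
    stand-in for an image-based PMI regressor; ``panicle_mask`` is
    accepted for signature compatibility and currently unused.
    """
    if not detections.boxes:
        log.warning("%s: no detections; heuristic PMI defaults to 1.0",
                    detections.image_id)
        return PMIValue(1.0, source="heuristic")
    polys = [shapely_box(b.x_min, b.y_min, b.x_max, b.y_max)
             for b in detections.boxes]
    total = sum(p.area for p in polys)
    union = unary_union(polys).area
    overlap_fraction = (total - union) / total
    return PMIValue(min(1.0, max(0.0, 1.0 - overlap_fraction)),
                    source="heuristic")


class PMILookupError(KeyError):
    """A queried image_id is absent from the PMI source."""


def pmi_provider(
    kind: str, source=None
) -> Callable[[str], PMIValue]:
    """Build an ``image_id -> PMIValue`` provider.

    kind = "ground_truth": ``source`` maps image_id to :class:`CountPair`
    (or an ``(n_actual, n_forecast)`` tuple); the provider applies
    :func:`pmi_from_counts`.

    kind = "external": ``source`` is a CSV path with header
    ``image_id,pmi``, e.g. values produced by a trained regression model.
    """
    if kind == "ground_truth":
        pairs = {
            k: v if isinstance(v, CountPair) else CountPair(*v)
            for k, v in dict(source).items()
        }

        def from_pairs(image_id: str) -> PMIValue:
            if image_id not in pairs:
                raise PMILookupError(f"no count pair for image_id {image_id!r}")
            return pmi_from_counts(pairs[image_id])

        return from_pairs

    if kind == "external":
        table: dict[str, float] = {}
        with open(source, newline="") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), start=2):
                try:
                    table[row["image_id"]] = float(row["pmi"])
                except (KeyError, TypeError, ValueError) as exc:
                    raise ValueError(f"line {lineno}: bad PMI row: {exc}")

        def from_file(image_id: str) -> PMIValue:
            if image_id not in table:
                raise PMILookupError(f"image_id {image_id!r} not in PMI file")
            return PMIValue(table[image_id], source="external")

        return from_file

    raise ValueError(f"unknown PMI provider kind {kind!r}")
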
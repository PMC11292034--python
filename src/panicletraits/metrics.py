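"""Evaluation metrics for paired actual/forecast trait series, plus
single-class mAP50 for detector quality.

For a series of n panicles with actual values a_i and forecasts f_i:

    MAPE     = 100/n * sum |a_i - f_i| / a_i          (percent)
    RMSE     = sqrt( sum (a_i - f_i)^2 / n )
    MAE      = 1/n * sum |a_i - f_i|
    R^2      = 1 - sum (a_i - f_i)^2 / sum (a_i - <a>)^2
    Accuracy = 100 * (1 - MAE / <a>)                  (percent)

where <a> is the mean of the actual values — used both to centre R^2
and as the Accuracy denominator (a per-series MAE needs a per-series
scale).  The per-item alternative, mean of 100*(1 - |err|/a_i) =
100 - MAPE, is exposed as :func:`accuracy_mape_complement`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .detection import BBox, DetectionSet, iou


def _as_series(actual, forecast) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(actual, dtype=float)
    f = np.asarray(forecast, dtype=float)
    if a.ndim != 1 or a.shape != f.shape or a.size == 0:
        raise ValueError("actual and forecast must be equal-length 1-D, n >= 1")
    return a, f


@dataclass(frozen=True)
class PairedSeries:
    """Validated actual/forecast value pair lists."""

    actual: tuple[float, ...]
    forecast: tuple[float, ...]

    def __post_init__(self) -> None:
        _as_series(self.actual, self.forecast)

    @property
    def n(self) -> int:
        return len(self.actual)


def _unpack(s, forecast):
    if forecast is None:
        return _as_series(s.actual, s.forecast)
    return _as_series(s, forecast)


def mape(actual, forecast=None) -> float:
    """Mean absolute percentage error, in percent."""
    a, f = _unpack(actual, forecast)
    if np.any(a == 0):
        raise ValueError("MAPE undefined: actual contains zero")
    return float(np.mean(np.abs(a - f) / np.abs(a)) * 100.0)


def rmse(actual, forecast=None) -> float:
    a, f = _unpack(actual, forecast)
    return float(np.sqrt(np.mean((a - f) ** 2)))


def mae(actual, forecast=None) -> float:
    a, f = _unpack(actual, forecast)
    return float(np.mean(np.abs(a - f)))


def r2(actual, forecast=None) -> float:
    """Coefficient of determination, centred on the mean of the actual values."""
    a, f = _unpack(actual, forecast)
    ss_tot = float(np.sum((a - a.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: actual series has zero variance")
    return 1.0 - float(np.sum((a - f) ** 2)) / ss_tot


def accuracy(actual, forecast=None) -> float:
    """100 * (1 - MAE / mean(actual)), in percent."""
    a, f = _unpack(actual, forecast)
    if np.any(a == 0):
        raise ValueError("accuracy undefined: actual contains zero")
    return float((1.0 - mae(a, f) / a.mean()) * 100.0)


def accuracy_mape_complement(actual, forecast=None) -> float:
    """Per-item accuracy reading: mean of 100*(1 - |err|/actual) = 100 - MAPE."""
    return 100.0 - mape(actual, forecast)


@dataclass(frozen=True)
class MetricReport:
    """All five paired-series metrics plus the sample size."""

    n: int
    mae: float
    rmse: float
    mape_percent: float
    r2: float
    accuracy_percent: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mae": self.mae,
            "rmse": self.rmse,
            "mape_percent": self.mape_percent,
            "r2": self.r2,
            "accuracy_percent": self.accuracy_percent,
        }


def evaluate(actual, forecast=None) -> MetricReport:
    a, f = _unpack(actual, forecast)
    return MetricReport(
        n=a.size,
        mae=mae(a, f),
        rmse=rmse(a, f),
        mape_percent=mape(a, f),
        r2=r2(a, f),
        accuracy_percent=accuracy(a, f),
    )


def _single_image_matches(
    pred: DetectionSet, truth: DetectionSet, iou_threshold: float
) -> list[tuple[float, bool]]:
    """(confidence, is_true_positive) per prediction: greedy matching in
    confidence-descending order against unmatched truth boxes."""
    order = sorted(
        range(len(pred.boxes)),
        key=lambda i: (-pred.boxes[i].confidence,
                       pred.boxes[i].x_min, pred.boxes[i].y_min),
    )
    used = [False] * len(truth.boxes)
    out = []
    for i in order:
        p = pred.boxes[i]
        best_j, best_iou = -1, iou_threshold
        for j, t in enumerate(truth.boxes):
            if used[j]:
                continue
            v = iou(p, t)
            if v >= best_iou and v > 0:
                if v > best_iou or best_j < 0:
                    best_j, best_iou = j, v
        if best_j >= 0:
            used[best_j] = True
            out.append((p.confidence, True))
        else:
            out.append((p.confidence, False))
    return out


def map50(
    pred: DetectionSet | list[DetectionSet],
    truth: DetectionSet | list[DetectionSet],
    iou_threshold: float = 0.5,
) -> float:
    """Single-class average precision at IoU >= ``iou_threshold``.

    Predictions are matched greedily to unmatched ground-truth boxes in
    confidence order; AP is the area under the interpolated
    precision-recall curve (continuous, all-points interpolation).
    """
    preds = [pred] if isinstance(pred, DetectionSet) else list(pred)
    truths = [truth] if isinstance(truth, DetectionSet) else list(truth)
    n_truth = sum(len(t.boxes) for t in truths)
    if n_truth == 0:
        raise ValueError("mAP undefined: no ground-truth boxes")
    scored: list[tuple[float, bool]] = []
    for p, t in zip(preds, truths, strict=True):
        scored.extend(_single_image_matches(p, t, iou_threshold))
    if not scored:
        return 0.0
    scored.sort(key=lambda st: -st[0])
    tp = np.cumsum([s[1] for s in scored])
    fp = np.cumsum([not s[1] for s in scored])
    recall = tp / n_truth
    precision = tp / (tp + fp)
    # all-points interpolation: precision envelope, integrate over recall
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, prec_env):
        ap += (r - r_prev) * p
        r_prev = r
    return float(ap)
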
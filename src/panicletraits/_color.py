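"""Fast HSV-based colour classification for large RGB frames.

Scene-sized images are classified several times per pipeline run, so
these helpers avoid full-frame hue computation: saturation and value
come from cheap channel min/max passes, and hue — the expensive part —
is only evaluated on the (usually small) subset of pixels that already
pass the saturation/value gates.  Hue is in degrees [0, 360),
saturation and value in [0, 1], matching the usual HSV convention.
"""

from __future__ import annotations

import numpy as np


def _channels_f32(image: np.ndarray):
    # contiguous per-channel copies: arithmetic on the stride-3 views a
    # channel slice gives is several times slower on large frames
    scale = np.float32(1 / 255) if image.dtype == np.uint8 else np.float32(1)
    r = np.ascontiguousarray(image[..., 0]).astype(np.float32) * scale
    g = np.ascontiguousarray(image[..., 1]).astype(np.float32) * scale
    b = np.ascontiguousarray(image[..., 2]).astype(np.float32) * scale
    return r, g, b


def _hue_deg(r, g, b, v, delta):
    safe = np.where(delta > 0, delta, np.float32(1))
    h = np.where(
        v == r, (g - b) / safe,
        np.where(v == g, np.float32(2) + (b - r) / safe,
                 np.float32(4) + (r - g) / safe),
    )
    h = (h * np.float32(60)) % np.float32(360)
    h[delta == 0] = 0
    return h


def saturation_channel(image: np.ndarray) -> np.ndarray:
    """HSV saturation of every pixel, float32 in [0, 1]."""
    r, g, b = _channels_f32(image)
    v = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    return (v - mn) / np.where(v > 0, v, np.float32(1))


def value_channel(image: np.ndarray) -> np.ndarray:
    """HSV value (channel maximum) of every pixel, float32 in [0, 1]."""
    r, g, b = _channels_f32(image)
    return np.maximum(np.maximum(r, g), b)


def classify_hsv(
    image: np.ndarray,
    hue_ranges_deg: list[tuple[float, float]],
    s_min: float,
    v_min: float,
) -> np.ndarray:
    """Boolean mask of pixels inside any hue range with s >= s_min and
    v >= v_min.  Hue is computed only for pixels passing the s/v gates.
    """
    r, g, b = _channels_f32(image)
    v = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = v - mn
    # s >= s_min  <=>  delta >= s_min * v  (v > 0), avoiding a division
    cand = (v >= np.float32(v_min)) & (delta >= np.float32(s_min) * v)
    out = np.zeros(cand.shape, dtype=bool)
    if not cand.any():
        return out
    rr, gg, bb, vv, dd = (x[cand] for x in (r, g, b, v, delta))
    h = _hue_deg(rr, gg, bb, vv, dd)
    ok = np.zeros(h.shape, dtype=bool)
    for lo, hi in hue_ranges_deg:
        ok |= (h >= lo) & (h <= hi)
    out[cand] = ok
    return out


def hsv_channels(image: np.ndarray):
    """Full (hue_deg, saturation, value) float32 triplet."""
    r, g, b = _channels_f32(image)
    v = np.maximum(np.maximum(r, g), b)
    mn = np.minimum(np.minimum(r, g), b)
    delta = v - mn
    s = delta / np.where(v > 0, v, np.float32(1))
    return _hue_deg(r, g, b, v, delta), s, v
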
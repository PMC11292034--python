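"""Panicle length from the skeleton main path.

The panicle is segmented by thresholding the HSV saturation channel
(the board is unsaturated, plant tissue is not), cleaned (small objects
removed — which also eliminates the calibrator — holes filled, largest
component kept) and thinned to a 1-pixel-wide skeleton.  Endpoints are
skeleton pixels with exactly one 8-neighbour.  The main path starts at
the bottom-most endpoint; shortest paths (A*, unit cost per move so the
optimised quantity is the pixel count) are computed to the 20 top-most
endpoints and the longest of those shortest paths is the main path.
Its pixel count times the pel density gives panicle length in mm.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import skeletonize as _sk_skeletonize

from ._color import saturation_channel
from .calibration import PelDensity, _red_mask


class NoPanicleError(ValueError):
    """Segmentation or cleaning produced no panicle foreground."""


class DegenerateSkeletonError(ValueError):
    """Skeleton has fewer than two endpoints."""


class DisconnectedSkeletonError(ValueError):
    """No top candidate endpoint is reachable from the bottom endpoint."""


@dataclass(frozen=True)
class SkeletonImage:
    """1-pixel-wide, 8-connected binary skeleton."""

    mask: np.ndarray


@dataclass(frozen=True)
class SkeletonPath:
    """Ordered 8-connected chain of skeleton pixels."""

    pixels: tuple[tuple[int, int], ...]

    @property
    def pixel_count(self) -> int:
        return len(self.pixels)


@dataclass(frozen=True)
class PanicleLengthResult:
    path: SkeletonPath
    length_px: float
    length_mm: float
    start: tuple[int, int]
    end: tuple[int, int]
    mode: str


# reference resolution for the small-object area floor
_REF_AREA = 3000 * 4000
_REF_MIN_AREA = 100.0


def segment_panicle(
    image: np.ndarray, s_threshold="otsu", exclude_red: bool = True
) -> np.ndarray:
    """Foreground = pixels whose HSV saturation exceeds the threshold.

    ``s_threshold`` is ``"otsu"`` (threshold chosen by Otsu's method on
    the saturation channel) or a fixed float in [0, 1].  The red
    calibrator is as saturated as plant tissue, so calibrator-coloured
    pixels are excluded up front by default (``exclude_red``); cleaning
    then removes any red residue below the area floor.
    """
    s = saturation_channel(image)
    thr = threshold_otsu(s) if s_threshold == "otsu" else float(s_threshold)
    mask = s > thr
    if exclude_red:
        mask &= ~_red_mask(image)
    if not mask.any():
        raise NoPanicleError("no panicle found: empty saturation foreground")
    return mask


def clean_mask(
    mask: np.ndarray, min_area: float | None = None, fill_holes: bool = True
) -> np.ndarray:
    """Remove small components (noise, the calibrator), fill holes, and
    keep the largest remaining component.

    ``min_area`` defaults to 100 px^2 at 3000x4000 resolution, scaled by
    the actual image area for other resolutions.
    """
    if min_area is None:
        min_area = max(1.0, _REF_MIN_AREA * mask.size / _REF_AREA)
    labels = label(mask, connectivity=2)
    if labels.max() == 0:
        raise NoPanicleError("no panicle found: empty mask")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = np.flatnonzero(counts >= min_area)
    if keep.size == 0:
        raise NoPanicleError(
            f"no panicle found: every component below min_area {min_area:.0f}"
        )
    largest = keep[np.argmax(counts[keep])]
    out = labels == largest
    if fill_holes:
        out = ndi.binary_fill_holes(out)
    return out


def skeletonize(mask: np.ndarray) -> SkeletonImage:
    """Thin a cleaned mask to a 1-px-wide, topology-preserving skeleton."""
    return SkeletonImage(_sk_skeletonize(mask.astype(bool)))


_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def find_endpoints(sk: SkeletonImage) -> list[tuple[int, int]]:
    """Skeleton pixels with exactly one foreground 8-neighbour,
    sorted bottom-to-top (row descending, then column ascending)."""
    m = sk.mask.astype(np.uint8)
    nb = ndi.convolve(m, _NEIGHBOR_KERNEL, mode="constant", cval=0)
    ends = np.argwhere((m == 1) & (nb == 1))
    return sorted(map(tuple, ends), key=lambda rc: (-rc[0], rc[1]))


# neighbour scan order: N, NE, E, SE, S, SW, W, NW
_NEIGHBOR_ORDER = ((-1, 0), (-1, 1), (0, 1), (1, 1),
                   (1, 0), (1, -1), (0, -1), (-1, -1))


def astar_path(
    sk: SkeletonImage, start: tuple[int, int], goal: tuple[int, int]
) -> SkeletonPath | None:
    """Minimum-pixel-count 8-connected path on the skeleton, or ``None``
    if the goal is unreachable.

    Unit cost per move (diagonals included) so the minimised quantity is
    the number of pixels; the Chebyshev-distance heuristic is admissible
    under that cost.  Ties are broken by insertion order with a fixed
    neighbour scan (N, NE, E, SE, S, SW, W, NW), so results are
    deterministic.
    """
    mask = sk.mask
    start, goal = tuple(start), tuple(goal)
    for p in (start, goal):
        if not mask[p]:
            raise ValueError(f"{p} is not a skeleton pixel")
    h, w = mask.shape

    def heur(rc):
        return max(abs(rc[0] - goal[0]), abs(rc[1] - goal[1]))

    g = {start: 0}
    parent: dict[tuple[int, int], tuple[int, int]] = {}
    counter = 0
    open_heap = [(heur(start), counter, start)]
    closed: set[tuple[int, int]] = set()
    while open_heap:
        _, _, cur = heapq.heappop(open_heap)
        if cur in closed:
            continue
        if cur == goal:
            chain = [cur]
            while cur in parent:
                cur = parent[cur]
                chain.append(cur)
            return SkeletonPath(tuple(reversed(chain)))
        closed.add(cur)
        r, c = cur
        for dr, dc in _NEIGHBOR_ORDER:
            nr, nc = r + dr, c + dc
            if not (0 <= nr < h and 0 <= nc < w) or not mask[nr, nc]:
                continue
            nxt = (nr, nc)
            tentative = g[cur] + 1
            if tentative < g.get(nxt, np.inf):
                g[nxt] = tentative
                parent[nxt] = cur
                counter += 1
                heapq.heappush(open_heap, (tentative + heur(nxt), counter, nxt))
    return None


def main_path(sk: SkeletonImage, n_candidates: int = 20) -> SkeletonPath:
    """Main stem path of the panicle skeleton.

    Start = bottom-most endpoint (tie: smallest column); candidates =
    up to ``n_candidates`` top-most endpoints; among the shortest paths
    from start to each reachable candidate, the one with the greatest
    pixel count is the main path (tie: first candidate in top-to-bottom,
    left-to-right order).
    """
    endpoints = find_endpoints(sk)
    if len(endpoints) < 2:
        raise DegenerateSkeletonError(
            f"degenerate skeleton: {len(endpoints)} endpoint(s)"
        )
    start = endpoints[0]  # sorted (row desc, col asc)
    candidates = sorted(
        (e for e in endpoints if e != start), key=lambda rc: (rc[0], rc[1])
    )[:n_candidates]
    best: SkeletonPath | None = None
    for cand in candidates:
        path = astar_path(sk, start, cand)
        if path is None:
            continue
        if best is None or path.pixel_count > best.pixel_count:
            best = path
    if best is None:
        raise DisconnectedSkeletonError(
            "disconnected skeleton: no top candidate reachable from bottom"
        )
    return best


def panicle_length_mm(
    path: SkeletonPath, pel: PelDensity, mode: str = "pixel_count"
) -> PanicleLengthResult:
    """Convert a skeleton path to a physical panicle length.

    ``pixel_count`` (default): length = number of path pixels x
    mm/pixel.  ``euclidean_steps``: sum of per-step lengths (1 for
    axis moves, sqrt(2) for diagonals) x mm/pixel, which does not
    underestimate diagonal runs.
    """
    if mode == "pixel_count":
        length_px = float(path.pixel_count)
    elif mode == "euclidean_steps":
        px = np.asarray(path.pixels, dtype=float)
        if len(px) == 1:
            length_px = 1.0
        else:
            steps = np.abs(np.diff(px, axis=0))
            length_px = 1.0 + float(
                np.where(steps.max(axis=1) > 0,
                         np.hypot(steps[:, 0], steps[:, 1]), 0).sum()
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return PanicleLengthResult(
        path=path,
        length_px=length_px,
        length_mm=length_px * pel.mm_per_pixel,
        start=path.pixels[0],
        end=path.pixels[-1],
        mode=mode,
    )
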
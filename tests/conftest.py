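"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities by brute force
(pixel counting, exhaustive search, breadth-first search) so the
library code is checked against something it does not share a code
path with.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from panicletraits.detection import BBox, DetectionSet
from panicletraits.synthetic import SceneSpec, generate_scene


# ---------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def default_scene():
    """One rendered default scene with its ground truth."""
    return generate_scene(SceneSpec(image_id="fixture", seed=7))


@pytest.fixture(scope="session")
def small_scene():
    """A quarter-resolution scene for fast CLI / pipeline tests."""
    spec = SceneSpec(
        image_id="small", image_size=(1000, 750),
        calibrator_pixel_radius=125.0, stem_thickness_px=4.0,
        n_grains=12, seed=11,
    )
    return spec, generate_scene(spec)


# ---------------------------------------------------------------------------
# oracles

def iou_pixel_oracle(a: BBox, b: BBox) -> float:
    """IoU by rasterising integer-coordinate boxes onto a unit grid."""
    w = int(max(a.x_max, b.x_max)) + 1
    h = int(max(a.y_max, b.y_max)) + 1
    ga = np.zeros((h, w), dtype=bool)
    gb = np.zeros((h, w), dtype=bool)
    ga[int(a.y_min):int(a.y_max), int(a.x_min):int(a.x_max)] = True
    gb[int(b.y_min):int(b.y_max), int(b.x_min):int(b.x_max)] = True
    union = (ga | gb).sum()
    return (ga & gb).sum() / union if union else 0.0


def nms_reference(d: DetectionSet, thr: float) -> list[BBox]:
    """O(n^2) greedy NMS written independently of the library version."""
    from panicletraits.detection import iou

    remaining = sorted(
        d.boxes, key=lambda b: (-b.confidence, b.x_min, b.y_min))
    kept: list[BBox] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [b for b in remaining if iou(best, b) <= thr]
    return kept


def union_area_raster(boxes: list[BBox]) -> float:
    """Exact union area of integer-coordinate boxes by pixel counting."""
    w = int(max(b.x_max for b in boxes)) + 1
    h = int(max(b.y_max for b in boxes)) + 1
    grid = np.zeros((h, w), dtype=bool)
    for b in boxes:
        grid[int(b.y_min):int(b.y_max), int(b.x_min):int(b.x_max)] = True
    return float(grid.sum())


def bfs_path_length(mask: np.ndarray, start, goal) -> int | None:
    """Shortest 8-connected path pixel count by plain BFS; None if cut off."""
    start, goal = tuple(start), tuple(goal)
    if start == goal:
        return 1
    h, w = mask.shape
    dist = {start: 1}
    q = deque([start])
    while q:
        r, c = q.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                nr, nc = r + dr, c + dc
                if 0 <= nr < h and 0 <= nc < w and mask[nr, nc] \
                        and (nr, nc) not in dist:
                    dist[(nr, nc)] = dist[(r, c)] + 1
                    if (nr, nc) == goal:
                        return dist[(nr, nc)]
                    q.append((nr, nc))
    return None


def min_rect_angle_sweep(mask: np.ndarray, step_deg: float = 0.1) -> float:
    """Best (smallest) enclosing-rectangle area over a dense angle sweep,
    treating foreground pixels as unit squares."""
    pts = np.argwhere(mask).astype(float)
    corners = np.concatenate([
        pts, pts + (1, 0), pts + (0, 1), pts + (1, 1)])
    best = np.inf
    for ang in np.arange(0.0, 180.0, step_deg):
        th = np.radians(ang)
        rot = corners @ np.array(
            [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        extent = rot.max(axis=0) - rot.min(axis=0)
        best = min(best, extent[0] * extent[1])
    return float(best)


def random_skeleton(rng: np.random.Generator, size: int = 60):
    """A random branching 8-connected curve on a size x size grid.

    Returns (mask, list of walk endpoints).  Not thinned — a stand-in
    for arbitrary skeleton-like graphs when testing path search.
    """
    mask = np.zeros((size, size), dtype=bool)
    moves = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]
    start = (int(rng.integers(5, size - 5)), int(rng.integers(5, size - 5)))
    mask[start] = True
    tips = [start]
    visited = [start]
    n_walks = int(rng.integers(2, 5))
    for _ in range(n_walks):
        r, c = visited[int(rng.integers(len(visited)))]
        direction = int(rng.integers(8))
        for _ in range(int(rng.integers(10, 3 * size))):
            if rng.random() < 0.25:
                direction = (direction + int(rng.integers(-1, 2))) % 8
            dr, dc = moves[direction]
            nr, nc = r + dr, c + dc
            if not (1 <= nr < size - 1 and 1 <= nc < size - 1):
                break
            r, c = nr, nc
            mask[r, c] = True
            visited.append((r, c))
        tips.append((r, c))
    return mask, tips
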
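"""Slow brute-force reference implementations used as independent oracles.

These deliberately avoid the optimized code paths (scikit-image labelling,
cropped distance transforms) so that agreement between the pipeline and this
module is meaningful validation. They are quadratic-or-worse and intended for
grids up to roughly 64x64.
"""

from __future__ import annotations

import numpy as np


def flood_fill_components(grid: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Label connected components by explicit stack-based flood fill.

    ``connectivity=2`` includes diagonal neighbours (8-connectivity),
    ``connectivity=1`` only edge neighbours (4-connectivity). Labels are
    assigned in raster-scan order of each component's first pixel.
    """
    grid = np.asarray(grid, dtype=bool)
    h, w = grid.shape
    if connectivity == 1:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                if (dr, dc) != (0, 0)]
    labels = np.zeros((h, w), dtype=np.int32)
    current = 0
    for r in range(h):
        for c in range(w):
            if grid[r, c] and labels[r, c] == 0:
                current += 1
                stack = [(r, c)]
                labels[r, c] = current
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in nbrs:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < h and 0 <= nc < w
                                and grid[nr, nc] and labels[nr, nc] == 0):
                            labels[nr, nc] = current
                            stack.append((nr, nc))
    return labels


def remove_small_components_bruteforce(
    grid: np.ndarray, min_size: int, connectivity: int = 2
) -> np.ndarray:
    """Small-object exclusion via the flood-fill labelling above."""
    labels = flood_fill_components(grid, connectivity)
    out = np.zeros_like(np.asarray(grid, dtype=bool))
    for k in range(1, labels.max() + 1):
        comp = labels == k
        if comp.sum() >= min_size:
            out |= comp
    return out


def pixel_order_counts_bruteforce(grids: list[np.ndarray]) -> dict[int, int]:
    """Per-pixel enumeration of labelling order across masks."""
    h, w = grids[0].shape
    counts: dict[int, int] = {k: 0 for k in range(1, len(grids) + 1)}
    for r in range(h):
        for c in range(w):
            k = sum(bool(g[r, c]) for g in grids)
            if k > 0:
                counts[k] += 1
    return counts


def nearest_nucleus_rings_bruteforce(
    labels: np.ndarray, expansion_distance: float
) -> np.ndarray:
    """Exhaustive per-pixel nearest-nucleus doughnut assignment.

    For every background pixel, the distance to each nucleus is the minimum
    Euclidean distance (pixel centres) to any pixel of that nucleus. The pixel
    joins the ring of the nearest nucleus if that distance is within
    ``expansion_distance``; ties go to the lower label. Nucleus-interior
    pixels are never ring pixels.
    """
    labels = np.asarray(labels)
    h, w = labels.shape
    nuclei = {}
    for k in range(1, labels.max() + 1):
        pts = np.argwhere(labels == k)
        if len(pts):
            nuclei[k] = pts
    rings = np.zeros((h, w), dtype=np.int32)
    for r in range(h):
        for c in range(w):
            if labels[r, c] != 0:
                continue
            best_d = np.inf
            best_k = 0
            for k, pts in nuclei.items():
                d = np.sqrt(((pts - (r, c)) ** 2).sum(axis=1)).min()
                if d < best_d - 1e-12:
                    best_d, best_k = d, k
            if best_k and best_d <= expansion_distance + 1e-12:
                rings[r, c] = best_k
    return rings
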
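"""Binary-mask operations: channel thresholding, small-component exclusion,
and single/double/triple-positive pixel logic.

Each antibody channel is thresholded to a binary image; pixel groups smaller
than a configured size (default 9 pixels, i.e. groups of fewer than 9 pixels
are excluded) are removed before any per-cell or per-pixel quantification.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from stromaquant.types import BinaryMask, MultiplexImage, ThresholdConfig


def threshold_channel(
    image: MultiplexImage,
    marker: str,
    threshold: float,
    inclusive: bool = True,
) -> BinaryMask:
    """Threshold one channel to a binary mask.

    A pixel is positive when its intensity is ``>= threshold`` (or strictly
    ``>`` with ``inclusive=False``).
    """
    channel = image.channel(marker)
    grid = channel >= threshold if inclusive else channel > threshold
    return BinaryMask(grid=grid, marker=marker, pixel_size=image.pixel_size)


def remove_small_components(
    mask: BinaryMask, min_size: int = 9, connectivity: int = 2
) -> BinaryMask:
    """Drop connected components with fewer than ``min_size`` pixels.

    ``connectivity=2`` treats diagonal neighbours as connected
    (8-connectivity, default); ``connectivity=1`` is 4-connectivity.
    Idempotent; never adds pixels.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    labels, n = measure.label(
        mask.grid, connectivity=connectivity, return_num=True
    )
    if n == 0:
        return BinaryMask(mask.grid.copy(), mask.marker, mask.pixel_size)
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    keep = sizes >= min_size
    keep[0] = False
    return BinaryMask(keep[labels], mask.marker, mask.pixel_size)


def build_marker_mask(
    image: MultiplexImage, marker: str, config: ThresholdConfig
) -> BinaryMask:
    """Full per-channel pipeline: threshold then small-component exclusion."""
    if marker not in config.thresholds:
        raise KeyError(f"no threshold configured for marker {marker!r}")
    mask = threshold_channel(
        image, marker, config.thresholds[marker], inclusive=config.inclusive
    )
    return remove_small_components(
        mask, config.min_component_size, config.connectivity
    )


def _check_dims(masks: list[BinaryMask]) -> tuple[int, int]:
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"masks differ in shape: {sorted(shapes)}")
    return masks[0].shape


def positive_pixel_counts(masks: list[BinaryMask]) -> dict[int, int]:
    """Count pixels by labelling order.

    Returns ``{k: number of pixels positive in exactly k masks}`` for
    k = 1..len(masks). Single-positive pixels (order 1) are those coloured by
    only one antibody after excluding double and higher-order labelled pixels.
    """
    if not masks:
        raise ValueError("need at least one mask")
    _check_dims(masks)
    order = np.zeros(masks[0].shape, dtype=np.int64)
    for m in masks:
        order += m.grid
    counts = np.bincount(order.ravel(), minlength=len(masks) + 1)
    return {k: int(counts[k]) for k in range(1, len(masks) + 1)}


def intersect_masks(masks: list[BinaryMask]) -> BinaryMask:
    """Logical intersection of two or more masks (double/triple-positive
    pixel construction)."""
    if len(masks) < 2:
        raise ValueError("intersection needs at least 2 masks")
    _check_dims(masks)
    grid = np.logical_and.reduce([m.grid for m in masks])
    marker = "+".join(m.marker for m in masks if m.marker)
    return BinaryMask(grid, marker, masks[0].pixel_size)


# --- mask round-trip as run-length-encoded CSV rows and 0/255 TIFF -------

def mask_to_rle(mask: BinaryMask) -> list[tuple[int, int, int]]:
    """Encode as (row, start_col, run_length) triples, row-major."""
    runs = []
    for r, row in enumerate(mask.grid):
        padded = np.diff(np.concatenate(([0], row.view(np.uint8), [0])))
        starts = np.flatnonzero(padded == 1)
        ends = np.flatnonzero(padded == -1)
        runs.extend((r, int(s), int(e - s)) for s, e in zip(starts, ends))
    return runs


def mask_from_rle(
    runs: list[tuple[int, int, int]],
    shape: tuple[int, int],
    marker: str = "",
    pixel_size: float = 0.5,
) -> BinaryMask:
    grid = np.zeros(shape, dtype=bool)
    for r, start, length in runs:
        grid[r, start : start + length] = True
    return BinaryMask(grid, marker, pixel_size)
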
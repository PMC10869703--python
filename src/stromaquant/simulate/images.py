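"""Synthetic multiplex-immunofluorescence core images with planted ground
truth.

Each simulated core carries one DAPI channel plus one channel per antibody
marker. Nuclei are non-overlapping discs; surface/cytoplasmic markers (CD3,
CD4, CD8, alpha-SMA, keratin 8/18) stain an annular ring just outside the
nucleus, while the nuclear transcription factor FOXP3 stains the nucleus
itself. Gaussian camera noise and sub-9-pixel speckle components can be
injected to exercise the downstream thresholding and small-object filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from stromaquant.phenotyping import assign_phenotype
from stromaquant.types import (
    GATED_MARKERS,
    NUCLEAR_MARKERS,
    GatingConfig,
    MultiplexImage,
    ThresholdConfig,
)

#: Marker flags implied by each planted phenotype.
PHENOTYPE_FLAGS: dict[str, tuple[str, ...]] = {
    "Treg": ("CD3", "CD4", "FOXP3"),
    "CD4T": ("CD3", "CD4"),
    "CD8T": ("CD3", "CD8"),
    "fibroblast": ("aSMA",),
    "cancer": ("CK818",),
    "other": (),
}

_DEFAULT_FREQUENCIES = {
    "Treg": 0.10,
    "CD4T": 0.20,
    "CD8T": 0.15,
    "fibroblast": 0.25,
    "cancer": 0.20,
    "other": 0.10,
}


@dataclass
class GroundTruthCell:
    """One planted cell: centre, radius, phenotype and the marker flags it
    implies (flags may deviate from the phenotype table only when a flag-flip
    error rate is simulated, in which case the phenotype is re-derived from
    the flipped flags so the two stay consistent)."""

    cell_id: int
    centroid: tuple[float, float]
    radius: float
    true_phenotype: str
    true_marker_flags: dict[str, bool]


@dataclass
class ImageSimParams:
    """Parameters of one synthetic core image.

    Intensities are on a 16-bit scale. ``n_speckles`` small (3-8 px)
    foreground components are scattered over random marker channels away
    from genuine staining; they are exactly the pixel groups the
    fewer-than-9-pixels exclusion rule is meant to remove.
    ``flag_flip_rate`` independently flips each planted marker flag to
    emulate co-expression noise (default off).
    """

    height: int = 512
    width: int = 512
    pixel_size: float = 0.5
    n_cells: int = 50
    phenotype_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FREQUENCIES)
    )
    nucleus_radius_mean: float = 7.0
    nucleus_radius_sd: float = 1.0
    ring_thickness: float = 3.0
    foreground_intensity: float = 3000.0
    background_intensity: float = 500.0
    noise_sd: float = 0.0
    n_speckles: int = 0
    flag_flip_rate: float = 0.0
    seed: int = 0
    max_attempts_per_cell: int = 500

    def __post_init__(self) -> None:
        total = sum(self.phenotype_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"phenotype_frequencies must sum to 1 (got {total})"
            )
        if self.nucleus_radius_mean <= 0:
            raise ValueError("nucleus_radius_mean must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.foreground_intensity <= self.background_intensity:
            raise ValueError("foreground must exceed background intensity")
        unknown = set(self.phenotype_frequencies) - set(PHENOTYPE_FLAGS)
        if unknown:
            raise ValueError(f"unknown phenotypes: {sorted(unknown)}")


class PlacementError(RuntimeError):
    """Raised when non-overlapping nucleus placement fails; the requested
    cell density exceeds what the image area can hold."""


def _disk_coords(center: tuple[float, float], radius: float,
                 shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    r0, c0 = center
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return np.nonzero((rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2)


def _annulus_coords(center, r_in, r_out, shape):
    r0, c0 = center
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    return np.nonzero((d2 > r_in**2) & (d2 <= r_out**2))


def generate_core_image(
    params: ImageSimParams,
) -> tuple[MultiplexImage, list[GroundTruthCell]]:
    """Simulate one multi-channel core image and its planted ground truth.

    Nuclei are placed by rejection sampling with a separation large enough
    that no cell's stained ring reaches a neighbouring cell's doughnut;
    after ``max_attempts_per_cell`` failed draws a :class:`PlacementError`
    names the density limit. Identical parameters (including the seed) give
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.height, params.width)
    markers = list(GATED_MARKERS)
    channels = {
        name: np.full(shape, params.background_intensity, dtype=float)
        for name in ["DAPI", *markers]
    }

    # --- place non-overlapping nuclei -----------------------------------
    # canonical order: results do not depend on dict insertion order
    labels = sorted(params.phenotype_frequencies)
    probs = np.array([params.phenotype_frequencies[k] for k in labels])
    margin = params.ring_thickness + 1.0
    placed: list[tuple[float, float, float]] = []
    cells: list[GroundTruthCell] = []
    for i in range(params.n_cells):
        radius = max(
            2.0,
            rng.normal(params.nucleus_radius_mean, params.nucleus_radius_sd),
        )
        for _ in range(params.max_attempts_per_cell):
            r = rng.uniform(radius + margin, params.height - radius - margin)
            c = rng.uniform(radius + margin, params.width - radius - margin)
            sep_ok = all(
                (r - pr) ** 2 + (c - pc) ** 2
                >= (radius + prad + 2 * params.ring_thickness + 2) ** 2
                for pr, pc, prad in placed
            )
            if sep_ok:
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{params.n_cells}: the "
                f"{params.height}x{params.width} image is too dense for "
                f"non-overlapping nuclei of radius ~{params.nucleus_radius_mean}"
            )
        placed.append((r, c, radius))
        phenotype = labels[rng.choice(len(labels), p=probs)]
        flags = {m: m in PHENOTYPE_FLAGS[phenotype] for m in markers}
        if params.flag_flip_rate > 0:
            for m in markers:
                if rng.random() < params.flag_flip_rate:
                    flags[m] = not flags[m]
            phenotype = assign_phenotype(flags)
        cells.append(
            GroundTruthCell(
                cell_id=i + 1,
                centroid=(r, c),
                radius=radius,
                true_phenotype=phenotype,
                true_marker_flags=flags,
            )
        )

    # --- paint staining compartments ------------------------------------
    fg = params.foreground_intensity
    for cell in cells:
        disk = _disk_coords(cell.centroid, cell.radius, shape)
        channels["DAPI"][disk] = fg
        for m, positive in cell.true_marker_flags.items():
            if not positive:
                continue
            if m in NUCLEAR_MARKERS:
                channels[m][disk] = fg
            else:
                ring = _annulus_coords(
                    cell.centroid,
                    cell.radius,
                    cell.radius + params.ring_thickness,
                    shape,
                )
                channels[m][ring] = fg

    # --- speckles: isolated sub-9-pixel foreground components -----------
    painted = {m: channels[m] > params.background_intensity for m in markers}
    for _ in range(params.n_speckles):
        m = markers[rng.integers(len(markers))]
        _place_speckle(channels[m], painted[m], fg, rng, params)

    # --- camera noise ----------------------------------------------------
    if params.noise_sd > 0:
        for name in channels:
            noise = rng.normal(0.0, params.noise_sd, size=shape)
            channels[name] = np.clip(channels[name] + noise, 0, 65535)

    image = MultiplexImage(
        channels=channels,
        pixel_size=params.pixel_size,
        core_id=f"sim-{params.seed}",
    )
    return image, cells


def _place_speckle(channel, painted, fg, rng, params, max_attempts=2000):
    """Grow a random connected blob of 3-8 pixels in a clear background spot.

    The blob plus a one-pixel guard band must be stain-free so that it forms
    its own connected component (under either connectivity convention) of
    size below 9 pixels.
    """
    size = int(rng.integers(3, 9))
    h, w = channel.shape
    for _ in range(max_attempts):
        r0 = int(rng.integers(2, h - 10))
        c0 = int(rng.integers(2, w - 10))
        pixels = {(r0, c0)}
        while len(pixels) < size:
            rr, cc = list(pixels)[rng.integers(len(pixels))]
            dr, dc = [(-1, 0), (1, 0), (0, -1), (0, 1)][rng.integers(4)]
            nr, nc = rr + dr, cc + dc
            if 1 <= nr < h - 1 and 1 <= nc < w - 1:
                pixels.add((nr, nc))
        guard_clear = all(
            not painted[rr + dr, cc + dc]
            for rr, cc in pixels
            for dr in (-1, 0, 1)
            for dc in (-1, 0, 1)
        )
        if guard_clear:
            for rr, cc in pixels:
                channel[rr, cc] = fg
                painted[rr, cc] = True
            return
    raise PlacementError("could not place an isolated speckle component")


def default_threshold_config(params: ImageSimParams) -> ThresholdConfig:
    """Channel thresholds at the midpoint between background and foreground,
    with the standard 9-pixel exclusion."""
    mid = 0.5 * (params.background_intensity + params.foreground_intensity)
    return ThresholdConfig(
        thresholds={m: mid for m in GATED_MARKERS}, min_component_size=9
    )


def default_gating_config(
    params: ImageSimParams, threshold_count: float = 30.0
) -> GatingConfig:
    """Count-mode density gates sized to the simulated doughnut geometry.

    A positive cell's doughnut (or nucleus, for FOXP3) is painted nearly
    fully foreground, giving counts of the order of the region area
    (~60-200 px for the default geometry), while planted negatives collect
    no stain, so a gate well below the smallest region area separates them.
    """
    return GatingConfig(
        density_thresholds={m: threshold_count for m in GATED_MARKERS},
        mode="count",
        foxp3_region="nucleus",
    )


def match_to_ground_truth(
    records, cells: list[GroundTruthCell], max_distance: float = 3.0
) -> list[tuple]:
    """Greedily match segmented cells to planted cells by centroid distance.

    Returns (record, ground-truth cell) pairs; each side is used at most
    once and pairs farther apart than ``max_distance`` pixels are not made.
    """
    if not records or not cells:
        return []
    rec_xy = np.array([r.centroid for r in records])
    true_xy = np.array([c.centroid for c in cells])
    d = np.sqrt(((rec_xy[:, None, :] - true_xy[None, :, :]) ** 2).sum(-1))
    pairs = []
    used_r: set[int] = set()
    used_t: set[int] = set()
    order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
    for i, j in order:
        if d[i, j] > max_distance:
            break
        if i in used_r or j in used_t:
            continue
        used_r.add(int(i))
        used_t.add(int(j))
        pairs.append((records[i], cells[j]))
    return pairs
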
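"""Shared domain types for the multiplex-immunofluorescence pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Markers gated per cell by positive-pixel density in the doughnut / nucleus.
GATED_MARKERS = ("CD3", "CD4", "CD8", "FOXP3", "aSMA", "CK818")

#: Markers whose stain localizes to the perinuclear ring (membrane/cytoplasm).
RING_MARKERS = ("CD3", "CD4", "CD8", "aSMA", "CK818")

#: Markers whose stain localizes to the nucleus.
NUCLEAR_MARKERS = ("FOXP3",)

#: T-cell compound phenotypes plus the stromal/epithelial classes used by the
#: synthetic ground truth.
PHENOTYPES = ("Treg", "CD4T", "CD8T", "fibroblast", "cancer", "other")


@dataclass
class MultiplexImage:
    """A named multi-channel 2D intensity image.

    Parameters
    ----------
    channels
        Mapping from marker name (e.g. ``"DAPI"``, ``"CD3"``) to a 2D
        array of intensities on a 16-bit scale.
    pixel_size
        Physical pixel size in micrometres per pixel.
    core_id
        Identifier of the tissue-microarray core the image came from.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 0.5
    core_id: str = "core"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        shapes = {name: ch.shape for name, ch in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels differ in shape: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.channels.values()))
        return first.shape

    def channel(self, marker: str) -> np.ndarray:
        if marker not in self.channels:
            raise KeyError(
                f"marker {marker!r} not in image; available: "
                f"{sorted(self.channels)}"
            )
        return self.channels[marker]


@dataclass
class BinaryMask:
    """Boolean mask for one marker after thresholding / filtering."""

    grid: np.ndarray
    marker: str = ""
    pixel_size: float = 0.5

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def count(self) -> int:
        return int(self.grid.sum())


@dataclass
class ThresholdConfig:
    """Per-channel intensity thresholds and the small-component cutoff.

    ``min_component_size`` is the minimum surviving connected-component size
    in pixels: groups of fewer than this many positive pixels are excluded.
    ``connectivity`` is 2 for 8-connectivity (diagonals connect, default) or
    1 for 4-connectivity. ``inclusive`` controls whether the channel
    threshold comparison is ``>=`` (default) or strict ``>``.
    """

    thresholds: dict[str, float] = field(default_factory=dict)
    min_component_size: int = 9
    connectivity: int = 2
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
        for marker, thr in self.thresholds.items():
            if thr < 0:
                raise ValueError(f"threshold for {marker!r} is negative")


#: Density thresholds as printed in the source study (units unstated there;
#: interpreted as raw positive-pixel counts per doughnut, the magnitudes'
#: most natural reading, and exposed as configuration).
DEFAULT_DENSITY_THRESHOLDS = {
    "CD3": 240.0,
    "CD4": 640.0,
    "CD8": 520.0,
    "FOXP3": 1200.0,
}


@dataclass
class GatingConfig:
    """Per-marker positive-pixel density gates applied per cell.

    ``mode`` selects the density unit: ``"count"`` gates on the raw number of
    positive pixels in the gating region, ``"per_mm2"`` on positive pixels per
    square millimetre of region area. ``foxp3_region`` selects whether FOXP3
    (a nuclear transcription factor) is gated in the nucleus (default) or the
    ring like the surface markers. A cell is positive when its density
    strictly exceeds the threshold.
    """

    density_thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITY_THRESHOLDS)
    )
    mode: str = "count"
    foxp3_region: str = "nucleus"
    compartment_overlap_fraction: float = 0.5
    compartment_mode: str = "overlap"

    def __post_init__(self) -> None:
        if self.mode not in ("count", "per_mm2"):
            raise ValueError("mode must be 'count' or 'per_mm2'")
        if self.foxp3_region not in ("ring", "nucleus"):
            raise ValueError("foxp3_region must be 'ring' or 'nucleus'")
        if self.compartment_mode not in ("overlap", "centroid"):
            raise ValueError("compartment_mode must be 'overlap' or 'centroid'")
        for marker, thr in self.density_thresholds.items():
            if thr <= 0:
                raise ValueError(f"density threshold for {marker!r} must be > 0")

    def region_for(self, marker: str) -> str:
        if marker == "FOXP3":
            return self.foxp3_region
        return "ring"


@dataclass
class NucleusLabelMap:
    """Labelled nuclei: 0 = background, k > 0 = nucleus k (contiguous)."""

    labels: np.ndarray
    areas: np.ndarray  # pixels, indexed by label-1
    centroids: np.ndarray  # (n, 2) float (row, col)

    @property
    def n_nuclei(self) -> int:
        return len(self.areas)

    @property
    def equivalent_radii(self) -> np.ndarray:
        """Equivalent-circle radius sqrt(area / pi) per nucleus, pixels."""
        return np.sqrt(self.areas / np.pi)


@dataclass
class DoughnutMap:
    """Per-cell perinuclear rings sharing labels with a NucleusLabelMap."""

    rings: np.ndarray  # integer grid, 0 = no ring
    expansion_distance: float  # pixels
    ring_areas: np.ndarray  # pixels per cell, indexed by label-1


@dataclass
class CellRecord:
    """One segmented cell with its per-marker gating results."""

    cell_id: int
    centroid: tuple[float, float]
    counts: dict[str, int]
    areas: dict[str, float]
    densities: dict[str, float]
    flags: dict[str, bool]
    phenotype: str = "other"
    compartment: str = "other"


@dataclass
class CompartmentMasks:
    """Tissue compartments from stain masks: fibroblast (alpha-SMA) and
    cancer (cytokeratin 8/18), both built through the thresholding and
    small-component pipeline."""

    fibroblast_mask: BinaryMask
    cancer_mask: BinaryMask
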
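"""Per-cell marker gating, compound phenotype calls, and compartment
assignment.

A cell is positive for a marker when the positive-pixel density of that
marker's mask inside the cell's gating region (the perinuclear doughnut for
membrane/cytoplasmic markers, the nucleus for FOXP3 by default) strictly
exceeds the configured threshold. Compound phenotypes follow the standard
T-cell definitions: Treg = CD3(+) CD4(+) FOXP3(+), CD4T = CD3(+) CD4(+)
FOXP3(-), CD8T = CD3(+) CD8(+). Cells are assigned to the fibroblast or
cancer compartment by the overlap of their doughnut with the alpha-SMA or
keratin 8/18 tissue mask.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from stromaquant import masks as mask_ops
from stromaquant import nuclei as nuclei_mod
from stromaquant.types import (
    GATED_MARKERS,
    BinaryMask,
    CellRecord,
    CompartmentMasks,
    DoughnutMap,
    GatingConfig,
    MultiplexImage,
    NucleusLabelMap,
    ThresholdConfig,
)

#: Phenotype rule table, evaluated top-down; the first matching row wins.
#: Flags not listed in a row are "don't care". The T-cell rows take
#: precedence over the stromal/epithelial rows so that, e.g., a CD3(+)
#: CD4(+) FOXP3(+) cell inside an alpha-SMA-positive region is still a Treg.
PHENOTYPE_RULES: list[tuple[str, dict[str, bool]]] = [
    ("Treg", {"CD3": True, "CD4": True, "FOXP3": True}),
    ("CD4T", {"CD3": True, "CD4": True, "FOXP3": False}),
    ("CD8T", {"CD3": True, "CD8": True}),
    ("fibroblast", {"aSMA": True}),
    ("cancer", {"CK818": True}),
]

_T_FLAGS = ("CD3", "CD4", "CD8", "FOXP3")


def assign_phenotype(flags: dict[str, bool]) -> str:
    """Map per-marker positivity flags to a phenotype label.

    Requires CD3, CD4, CD8 and FOXP3 flags; aSMA and CK818 are optional and
    only consulted when no T-cell rule matches. Returns ``"other"`` when no
    rule matches.
    """
    missing = [m for m in _T_FLAGS if m not in flags]
    if missing:
        raise KeyError(f"missing marker flags: {missing}")
    for label, rule in PHENOTYPE_RULES:
        if all(flags.get(m, False) == want for m, want in rule.items()):
            return label
    return "other"


def gate_marker(
    region: np.ndarray,
    marker_mask: BinaryMask,
    threshold: float,
    mode: str = "count",
) -> tuple[int, float, bool]:
    """Gate one cell for one marker.

    ``region`` is the boolean gating region of the cell (its doughnut or
    nucleus). Returns (positive-pixel count, density, positivity flag);
    the flag is ``density > threshold`` (strict). Density equals the raw
    count in ``"count"`` mode and positive pixels per mm^2 in ``"per_mm2"``
    mode.
    """
    region = np.asarray(region, dtype=bool)
    if region.shape != marker_mask.shape:
        raise ValueError("region and marker mask dimensions differ")
    area = int(region.sum())
    if area == 0:
        raise ValueError("empty gating region")
    count = int((region & marker_mask.grid).sum())
    density = _density(count, area, marker_mask.pixel_size, mode)
    return count, density, density > threshold


def _density(count, area_px, pixel_size_um, mode):
    if mode == "count":
        return float(count)
    area_mm2 = area_px * (pixel_size_um * 1e-3) ** 2
    return count / area_mm2


def compartment_fractions(
    region: np.ndarray, masks: CompartmentMasks
) -> tuple[float, float]:
    """Fraction of a cell's gating-region pixels inside the fibroblast and
    cancer masks."""
    region = np.asarray(region, dtype=bool)
    area = region.sum()
    if area == 0:
        return 0.0, 0.0
    fib = (region & masks.fibroblast_mask.grid).sum() / area
    can = (region & masks.cancer_mask.grid).sum() / area
    return float(fib), float(can)


def assign_compartment(
    fibroblast_fraction: float,
    cancer_fraction: float,
    overlap_fraction: float = 0.5,
) -> str:
    """Compartment call from overlap fractions; fibroblast takes precedence
    over cancer when both exceed the cutoff."""
    if fibroblast_fraction > overlap_fraction:
        return "fibroblast"
    if cancer_fraction > overlap_fraction:
        return "cancer"
    return "other"


def build_compartment_masks(
    image: MultiplexImage, threshold_config: ThresholdConfig
) -> CompartmentMasks:
    """Fibroblast and cancer tissue masks from alpha-SMA and keratin 8/18
    channels through the full threshold + small-component pipeline."""
    return CompartmentMasks(
        fibroblast_mask=mask_ops.build_marker_mask(image, "aSMA", threshold_config),
        cancer_mask=mask_ops.build_marker_mask(image, "CK818", threshold_config),
    )


def classify_all(
    image: MultiplexImage,
    threshold_config: ThresholdConfig,
    gating_config: GatingConfig | None = None,
    segmentation_config: nuclei_mod.SegmentationConfig | None = None,
    expansion_fraction: float = 1 / 3,
    markers: tuple[str, ...] | None = None,
) -> tuple[list[CellRecord], NucleusLabelMap, DoughnutMap]:
    """Run the whole per-image pipeline: per-marker binary masks, nuclear
    segmentation, doughnut construction, density gating, phenotype and
    compartment assignment.

    Deterministic for fixed input and configuration. Returns the per-cell
    records together with the segmentation and doughnut maps for inspection.
    """
    gating_config = gating_config or GatingConfig()
    markers = markers or tuple(
        m for m in GATED_MARKERS if m in image.channels
    )
    if "DAPI" not in image.channels:
        raise KeyError("image lacks a DAPI channel (required for segmentation)")
    needed = [m for m in markers if m not in image.channels]
    if needed:
        raise KeyError(f"image lacks required channels: {needed}")
    for m in markers:
        if m not in gating_config.density_thresholds:
            raise KeyError(f"no density threshold configured for {m!r}")

    seg = nuclei_mod.segment_nuclei(image.channel("DAPI"), segmentation_config)
    if seg.n_nuclei == 0:
        return [], seg, DoughnutMap(
            rings=np.zeros(image.shape, dtype=np.int32),
            expansion_distance=0.0,
            ring_areas=np.zeros(0, dtype=np.int64),
        )
    dough = nuclei_mod.build_doughnuts(seg, expansion_fraction=expansion_fraction)

    n = seg.n_nuclei
    empty_rings = np.flatnonzero(dough.ring_areas == 0)
    if len(empty_rings):
        raise ValueError(
            f"cell(s) {[int(k) + 1 for k in empty_rings]} have an empty doughnut"
        )

    marker_masks = {
        m: mask_ops.build_marker_mask(image, m, threshold_config) for m in markers
    }
    compartments = CompartmentMasks(
        fibroblast_mask=marker_masks.get(
            "aSMA", BinaryMask(np.zeros(image.shape, bool), "aSMA", image.pixel_size)
        ),
        cancer_mask=marker_masks.get(
            "CK818", BinaryMask(np.zeros(image.shape, bool), "CK818", image.pixel_size)
        ),
    )

    counts: dict[str, np.ndarray] = {}
    areas: dict[str, np.ndarray] = {}
    for m in markers:
        region_kind = gating_config.region_for(m)
        region_labels = dough.rings if region_kind == "ring" else seg.labels
        region_areas = (
            dough.ring_areas if region_kind == "ring" else seg.areas
        )
        counts[m] = np.bincount(
            region_labels[marker_masks[m].grid], minlength=n + 1
        )[1:]
        areas[m] = region_areas

    # compartment overlap of each doughnut, vectorized over cells
    ring_labels = dough.rings
    fib_counts = np.bincount(
        ring_labels[compartments.fibroblast_mask.grid], minlength=n + 1
    )[1:]
    can_counts = np.bincount(
        ring_labels[compartments.cancer_mask.grid], minlength=n + 1
    )[1:]
    fib_frac = fib_counts / dough.ring_areas
    can_frac = can_counts / dough.ring_areas

    records: list[CellRecord] = []
    for k in range(n):
        cell_counts, cell_areas, cell_dens, cell_flags = {}, {}, {}, {}
        for m in markers:
            c = int(counts[m][k])
            a = float(areas[m][k])
            d = _density(c, a, image.pixel_size, gating_config.mode)
            cell_counts[m] = c
            cell_areas[m] = a
            cell_dens[m] = d
            cell_flags[m] = d > gating_config.density_thresholds[m]
        if gating_config.compartment_mode == "centroid":
            r, c = (int(round(x)) for x in seg.centroids[k])
            in_fib = bool(compartments.fibroblast_mask.grid[r, c])
            in_can = bool(compartments.cancer_mask.grid[r, c])
            comp = "fibroblast" if in_fib else ("cancer" if in_can else "other")
        else:
            comp = assign_compartment(
                float(fib_frac[k]),
                float(can_frac[k]),
                gating_config.compartment_overlap_fraction,
            )
        records.append(
            CellRecord(
                cell_id=k + 1,
                centroid=(float(seg.centroids[k, 0]), float(seg.centroids[k, 1])),
                counts=cell_counts,
                areas=cell_areas,
                densities=cell_dens,
                flags=cell_flags,
                phenotype=assign_phenotype(cell_flags),
                compartment=comp,
            )
        )
    return records, seg, dough


def phenotype_counts(phenotypes: list[str]) -> dict[str, int]:
    """Tally phenotype labels into the per-core count-table schema:
    fibroblasts, cancer_cells, immunocytes (all T-cell classes), others,
    plus the Treg/CD4T numerator and denominator counts."""
    tally = {p: phenotypes.count(p) for p in set(phenotypes)}
    treg = tally.get("Treg", 0)
    cd4t = tally.get("CD4T", 0)
    return {
        "fibroblasts": tally.get("fibroblast", 0),
        "cancer_cells": tally.get("cancer", 0),
        "immunocytes": treg + cd4t + tally.get("CD8T", 0),
        "others": tally.get("other", 0),
        "cd3cd4": treg + cd4t,
        "cd3cd4foxp3": treg,
    }


def cells_to_dataframe(records: list[CellRecord]) -> pd.DataFrame:
    """Flatten cell records to a table (one row per cell)."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "cell_id": rec.cell_id,
            "centroid_row": rec.centroid[0],
            "centroid_col": rec.centroid[1],
            "phenotype": rec.phenotype,
            "compartment": rec.compartment,
        }
        for m in rec.counts:
            row[f"{m}_count"] = rec.counts[m]
            row[f"{m}_area"] = rec.areas[m]
            row[f"{m}_density"] = rec.densities[m]
            row[f"{m}_flag"] = rec.flags[m]
        rows.append(row)
    return pd.DataFrame(rows)
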
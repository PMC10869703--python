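"""Reading and writing the pipeline's file formats.

Images travel as multi-page TIFF (one page per channel) with a JSON
description tag carrying the channel names, pixel size and core id; binary
masks as 0/255 single-page TIFF; tables as CSV with documented headers; and
run/simulation parameters as YAML.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from stromaquant.simulate.images import GroundTruthCell
from stromaquant.types import GATED_MARKERS, BinaryMask, MultiplexImage


# --- multi-channel images --------------------------------------------------

def write_image(path: str | Path, image: MultiplexImage) -> None:
    """Write a multiplex image as a multi-page 16-bit TIFF.

    Channel order, pixel size (um/px) and core id go into the TIFF
    description tag as JSON. Intensities are clipped to [0, 65535] and
    rounded."""
    names = list(image.channels)
    stack = np.stack(
        [np.clip(np.rint(image.channels[n]), 0, 65535).astype(np.uint16)
         for n in names]
    )
    meta = {
        "channels": names,
        "pixel_size_um": image.pixel_size,
        "core_id": image.core_id,
    }
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def read_image(path: str | Path) -> MultiplexImage:
    """Read a multi-page TIFF written by :func:`write_image`."""
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
        names = meta["channels"]
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ValueError(
            f"{path}: missing or malformed channel metadata in TIFF "
            "description tag"
        ) from exc
    if stack.ndim == 2:
        stack = stack[None]
    if len(names) != stack.shape[0]:
        raise ValueError(
            f"{path}: {len(names)} channel names for {stack.shape[0]} pages"
        )
    return MultiplexImage(
        channels={n: stack[i].astype(float) for i, n in enumerate(names)},
        pixel_size=float(meta.get("pixel_size_um", 0.5)),
        core_id=str(meta.get("core_id", Path(path).stem)),
    )


# --- binary masks ----------------------------------------------------------

def write_mask(path: str | Path, mask: BinaryMask) -> None:
    """Write a binary mask as 0/255 uint8 TIFF."""
    tifffile.imwrite(
        path,
        mask.grid.astype(np.uint8) * 255,
        description=json.dumps(
            {"marker": mask.marker, "pixel_size_um": mask.pixel_size}
        ),
    )


def read_mask(path: str | Path) -> BinaryMask:
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        meta = {}
    return BinaryMask(
        grid=arr > 0,
        marker=str(meta.get("marker", "")),
        pixel_size=float(meta.get("pixel_size_um", 0.5)),
    )


# --- ground truth ----------------------------------------------------------

def ground_truth_to_dataframe(cells: list[GroundTruthCell]) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = {
            "cell_id": c.cell_id,
            "centroid_row": c.centroid[0],
            "centroid_col": c.centroid[1],
            "radius": c.radius,
            "true_phenotype": c.true_phenotype,
        }
        for m in GATED_MARKERS:
            row[f"{m}_true"] = bool(c.true_marker_flags.get(m, False))
        rows.append(row)
    return pd.DataFrame(rows)


def ground_truth_from_dataframe(df: pd.DataFrame) -> list[GroundTruthCell]:
    cells = []
    for _, row in df.iterrows():
        cells.append(
            GroundTruthCell(
                cell_id=int(row["cell_id"]),
                centroid=(float(row["centroid_row"]), float(row["centroid_col"])),
                radius=float(row["radius"]),
                true_phenotype=str(row["true_phenotype"]),
                true_marker_flags={
                    m: bool(row[f"{m}_true"])
                    for m in GATED_MARKERS
                    if f"{m}_true" in row
                },
            )
        )
    return cells


# --- tables and configs ----------------------------------------------------

def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """CSV writer with a fixed float format so identical inputs give
    byte-identical files."""
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return data or {}


def dump_yaml(path: str | Path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def params_from_mapping(cls, mapping: dict):
    """Build a params dataclass from a (possibly partial) mapping, rejecting
    unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}; "
            f"valid keys: {sorted(names)}"
        )
    return cls(**mapping)
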
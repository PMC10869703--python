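"""End-to-end orchestration: simulate -> quantify -> cohort, with a
reproducible run manifest.

One global seed is fanned out to per-stage sub-seeds through
``numpy.random.SeedSequence(seed).spawn``; the manifest records the config
(and its hash), the seed, package and library versions, per-stage record
counts and a checksum for every file written, so a run can be reproduced
and verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import stromaquant
from stromaquant import cohort as cohort_stats
from stromaquant import io as sqio
from stromaquant import phenotyping
from stromaquant.nuclei import SegmentationConfig
from stromaquant.simulate import (
    CohortSimParams,
    ImageSimParams,
    default_gating_config,
    default_threshold_config,
    generate_cell_count_tables,
    generate_core_image,
    generate_expression_matrix,
    generate_survival_cohort,
)
from stromaquant.types import GatingConfig, ThresholdConfig

DEFAULT_METAGENES = {
    "Treg": [f"TREG_{i}" for i in range(1, 11)],
    "activated_CD4T": [f"ACD4_{i}" for i in range(1, 11)],
    "activated_CD8T": [f"ACD8_{i}" for i in range(1, 11)],
}


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    out_dir: str = "run"
    n_images: int = 3
    image: ImageSimParams = field(default_factory=ImageSimParams)
    cohort: CohortSimParams = field(default_factory=CohortSimParams)
    thresholds: ThresholdConfig | None = None
    gating: GatingConfig | None = None
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    expansion_fraction: float = 1 / 3
    min_cancer_cells: int = 500
    n_expression_samples: int = 130
    inhba_treg_correlation: float = 0.6
    metagene_sets: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_METAGENES.items()}
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = sqio.load_yaml(path)
        kwargs = dict(data)
        if "image" in kwargs:
            kwargs["image"] = sqio.params_from_mapping(
                ImageSimParams, kwargs["image"]
            )
        if "cohort" in kwargs:
            kwargs["cohort"] = sqio.params_from_mapping(
                CohortSimParams, kwargs["cohort"]
            )
        if "segmentation" in kwargs:
            kwargs["segmentation"] = sqio.params_from_mapping(
                SegmentationConfig, kwargs["segmentation"]
            )
        if "thresholds" in kwargs:
            kwargs["thresholds"] = ThresholdConfig(**kwargs["thresholds"])
        if "gating" in kwargs:
            kwargs["gating"] = GatingConfig(**kwargs["gating"])
        return sqio.params_from_mapping(cls, kwargs)

    def to_mapping(self) -> dict:
        def conv(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        return conv(dataclasses.asdict(self))


class PipelineError(RuntimeError):
    """A stage failed; the manifest records which one."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    canon = json.dumps(config.to_mapping(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> quantify -> cohort and write a manifest.

    Returns the manifest dict. On a stage failure the completed stages'
    outputs and a manifest with an error record naming the failed stage are
    left in place, and a :class:`PipelineError` is raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sub = np.random.SeedSequence(config.seed).spawn(4)
    stage_seeds = {
        "simulate_images": int(sub[0].generate_state(1)[0] % (2**31)),
        "simulate_cohort": int(sub[1].generate_state(1)[0] % (2**31)),
        "simulate_expression": int(sub[2].generate_state(1)[0] % (2**31)),
    }
    manifest: dict = {
        "config": config.to_mapping(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stage_seeds": stage_seeds,
        "versions": {
            "stromaquant": stromaquant.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "stages": {},
        "files": {},
    }

    def record(stage: str, counts: dict, files: list[Path]) -> None:
        manifest["stages"][stage] = {"status": "completed", **counts}
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)

    def fail(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        _write_manifest(out, manifest)
        raise PipelineError(stage, str(exc)) from exc

    # --- stage 1: simulate ------------------------------------------------
    image_paths: list[Path] = []
    try:
        files: list[Path] = []
        for i in range(config.n_images):
            params = dataclasses.replace(
                config.image, seed=stage_seeds["simulate_images"] + i
            )
            image, truth = generate_core_image(params)
            img_path = out / f"image_{i + 1:03d}.tif"
            truth_path = out / f"truth_{i + 1:03d}.csv"
            sqio.write_image(img_path, image)
            sqio.write_table(truth_path, sqio.ground_truth_to_dataframe(truth))
            image_paths.append(img_path)
            files += [img_path, truth_path]
        cohort_params = dataclasses.replace(
            config.cohort, seed=stage_seeds["simulate_cohort"]
        )
        counts_df = generate_cell_count_tables(cohort_params)
        surv_df = generate_survival_cohort(cohort_params)
        expr = generate_expression_matrix(
            config.n_expression_samples,
            config.metagene_sets,
            config.inhba_treg_correlation,
            seed=stage_seeds["simulate_expression"],
        )
        for name, df in [
            ("core_counts.csv", counts_df),
            ("survival_cohort.csv", surv_df),
        ]:
            sqio.write_table(out / name, df)
            files.append(out / name)
        expr.to_csv(out / "expression.csv", float_format="%.10g")
        files.append(out / "expression.csv")
        record(
            "simulate",
            {
                "images": config.n_images,
                "cores": len(counts_df),
                "survival_samples": len(surv_df),
                "genes": len(expr),
            },
            files,
        )
    except Exception as exc:  # noqa: BLE001 - error record by stage
        fail("simulate", exc)

    # --- stage 2: quantify ------------------------------------------------
    try:
        thr = config.thresholds or default_threshold_config(config.image)
        gat = config.gating or default_gating_config(config.image)
        files = []
        n_cells_total = 0
        flag_totals: dict[str, int] = {}
        for img_path in image_paths:
            image = sqio.read_image(img_path)
            records, _, _ = phenotyping.classify_all(
                image,
                thr,
                gat,
                config.segmentation,
                expansion_fraction=config.expansion_fraction,
            )
            cells_df = phenotyping.cells_to_dataframe(records)
            cells_path = out / f"cells_{img_path.stem}.csv"
            sqio.write_table(cells_path, cells_df)
            files.append(cells_path)
            n_cells_total += len(records)
            for rec in records:
                for m, v in rec.flags.items():
                    flag_totals[m] = flag_totals.get(m, 0) + int(v)
        record(
            "quantify",
            {"cells": n_cells_total, "positive_by_marker": flag_totals},
            files,
        )
    except Exception as exc:  # noqa: BLE001
        fail("quantify", exc)

    # --- stage 3: cohort ----------------------------------------------------
    try:
        files = []
        with_ratios = cohort_stats.compute_core_ratios(counts_df)
        included = cohort_stats.apply_core_exclusion(
            with_ratios, config.min_cancer_cells
        )
        per_sample = cohort_stats.average_per_sample(
            included, all_samples=list(with_ratios["sample_id"].unique())
        )
        stratum, threshold = cohort_stats.split_low_high(
            per_sample, "inhba_ratio"
        )
        per_sample["stratum"] = stratum
        surv = surv_df
        comparison = cohort_stats.survival_compare(surv)
        metagenes = cohort_stats.metagene_correlate(expr, config.metagene_sets)
        for name, df in [
            ("core_ratios.csv", with_ratios),
            ("sample_ratios.csv", per_sample),
            ("metagene_correlations.csv", metagenes),
            ("survival_curves.csv", comparison.survival_table()),
        ]:
            sqio.write_table(out / name, df)
            files.append(out / name)
        stats_summary = {
            "split_threshold": threshold,
            "logrank_statistic": comparison.statistic,
            "logrank_p": comparison.p_value,
            "km_medians": comparison.medians,
            "cores_excluded": int(len(with_ratios) - len(included)),
        }
        with open(out / "cohort_stats.json", "w") as fh:
            json.dump(stats_summary, fh, indent=2, sort_keys=True)
        files.append(out / "cohort_stats.json")
        record(
            "cohort",
            {
                "cores": len(with_ratios),
                "cores_included": len(included),
                "samples": len(per_sample),
            },
            files,
        )
    except Exception as exc:  # noqa: BLE001
        fail("cohort", exc)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
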
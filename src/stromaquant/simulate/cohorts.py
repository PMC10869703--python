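"""Synthetic tissue-microarray cohorts: per-core cell-count tables with
group-dependent INHBA(+) fibroblast ratios, and survival cohorts whose
hazard depends on the low/high INHBA stratum.

The count tables emulate the output of a morphology-based cell classifier
applied to bright-field cores (fibroblast / epithelial cancer cell /
immunocyte / other counts, plus alpha-SMA(+) and INHBA(+) cells and the
CD3(+)CD4(+)(FOXP3+/-) counts inside the fibroblast compartment). Samples
are patient-matched across disease groups so paired comparisons apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUPS = ("primary", "metastatic", "recurrent")


@dataclass
class CohortSimParams:
    """Cohort-level simulation parameters.

    ``inhba_ratio_means`` sets the group-wise mean INHBA(+) fibroblast
    ratio; patient-matched samples share a patient random effect of sd
    ``patient_effect_sd`` so that metastatic/recurrent ratios are elevated
    within patients, as in a matched design. The Treg ratio of a sample is
    ``treg_intercept + treg_slope * inhba_ratio`` plus noise. Survival is
    exponential with rate ``baseline_hazard`` for the low stratum and
    ``baseline_hazard * hazard_ratio_high_vs_low`` for the high stratum;
    censoring is independent with probability ``censor_rate``.
    """

    n_samples_per_group: dict[str, int] = field(
        default_factory=lambda: {g: 42 for g in GROUPS}
    )
    inhba_ratio_means: dict[str, float] = field(
        default_factory=lambda: {
            "primary": 0.15,
            "metastatic": 0.30,
            "recurrent": 0.30,
        }
    )
    inhba_ratio_sd: float = 0.06
    patient_effect_sd: float = 0.05
    treg_slope: float = 0.5
    treg_intercept: float = 0.05
    treg_noise_sd: float = 0.03
    baseline_hazard: float = 0.02  # events per month (median ~35 months)
    hazard_ratio_high_vs_low: float = 3.0
    censor_rate: float = 0.2
    low_cancer_core_fraction: float = 0.0
    mean_fibroblasts: float = 800.0
    mean_cancer_cells: float = 2000.0
    mean_immunocytes: float = 400.0
    mean_others: float = 300.0
    mean_cd3cd4: float = 150.0
    asma_positive_rate: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for g, m in self.inhba_ratio_means.items():
            if not 0 < m < 1:
                raise ValueError(f"inhba_ratio_means[{g!r}] must be in (0,1)")
        if self.hazard_ratio_high_vs_low <= 0:
            raise ValueError("hazard_ratio_high_vs_low must be > 0")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must be in [0,1)")
        if any(n < 0 for n in self.n_samples_per_group.values()):
            raise ValueError("n_samples_per_group values must be >= 0")
        if not 0 <= self.low_cancer_core_fraction <= 1:
            raise ValueError("low_cancer_core_fraction must be in [0,1]")


_CLIP = 1e-3


def _sample_ratio(rng, mean, sd, offset=0.0):
    return float(np.clip(rng.normal(mean + offset, sd), _CLIP, 1 - _CLIP))


def generate_cell_count_tables(params: CohortSimParams) -> pd.DataFrame:
    """Per-core cell-count table for a patient-matched cohort.

    Each sample contributes 1-3 cores. A ``low_cancer_core_fraction`` of
    cores is drawn with fewer than 500 cancer cells to exercise the core
    exclusion rule. Columns: core_id, sample_id, patient_id, group, and the
    integer counts fibroblasts, cancer_cells, immunocytes, others, asma_pos,
    inhba_pos, cd3cd4, cd3cd4foxp3.
    """
    rng = np.random.default_rng(params.seed)
    n_patients = max(params.n_samples_per_group.values(), default=0)
    patient_effects = rng.normal(0.0, params.patient_effect_sd, size=n_patients)
    rows = []
    for group in GROUPS:
        n = params.n_samples_per_group.get(group, 0)
        for p in range(n):
            sample_id = f"{group}-{p + 1:03d}"
            p_sample = _sample_ratio(
                rng,
                params.inhba_ratio_means[group],
                params.inhba_ratio_sd,
                offset=patient_effects[p],
            )
            t_sample = float(
                np.clip(
                    params.treg_intercept
                    + params.treg_slope * p_sample
                    + rng.normal(0.0, params.treg_noise_sd),
                    _CLIP,
                    1 - _CLIP,
                )
            )
            n_cores = int(rng.integers(1, 4))
            for k in range(n_cores):
                fib = int(rng.poisson(params.mean_fibroblasts))
                if rng.random() < params.low_cancer_core_fraction:
                    cancer = int(rng.integers(0, 500))
                else:
                    cancer = int(rng.poisson(params.mean_cancer_cells))
                cd3cd4 = int(rng.poisson(params.mean_cd3cd4))
                rows.append(
                    {
                        "core_id": f"{sample_id}-c{k + 1}",
                        "sample_id": sample_id,
                        "patient_id": f"pt-{p + 1:03d}",
                        "group": group,
                        "fibroblasts": fib,
                        "cancer_cells": cancer,
                        "immunocytes": int(rng.poisson(params.mean_immunocytes)),
                        "others": int(rng.poisson(params.mean_others)),
                        "asma_pos": int(
                            rng.binomial(fib, params.asma_positive_rate)
                        ),
                        "inhba_pos": int(rng.binomial(fib, p_sample)),
                        "cd3cd4": cd3cd4,
                        "cd3cd4foxp3": int(rng.binomial(cd3cd4, t_sample)),
                    }
                )
    columns = [
        "core_id", "sample_id", "patient_id", "group",
        "fibroblasts", "cancer_cells", "immunocytes", "others",
        "asma_pos", "inhba_pos", "cd3cd4", "cd3cd4foxp3",
    ]
    return pd.DataFrame(rows, columns=columns)


def generate_survival_cohort(
    params: CohortSimParams, n_samples: int | None = None, group: str = "metastatic"
) -> pd.DataFrame:
    """Survival cohort with ratio-dependent hazard.

    Samples draw an INHBA(+) fibroblast ratio around the group mean, are
    stratified low/high at the cohort mean ratio, and draw exponential
    survival times with hazard ``baseline_hazard`` (low) or
    ``baseline_hazard * hazard_ratio_high_vs_low`` (high). Censored records
    (probability ``censor_rate``) report a uniform fraction of the latent
    event time. Columns: sample_id, group, inhba_ratio, stratum, os_months,
    os_event.
    """
    rng = np.random.default_rng(params.seed)
    if n_samples is None:
        n_samples = params.n_samples_per_group.get(group, 0)
    ratios = np.clip(
        rng.normal(
            params.inhba_ratio_means[group], params.inhba_ratio_sd, n_samples
        ),
        _CLIP,
        1 - _CLIP,
    )
    strata = np.where(ratios > ratios.mean(), "high", "low")
    hazards = np.where(
        strata == "high",
        params.baseline_hazard * params.hazard_ratio_high_vs_low,
        params.baseline_hazard,
    )
    times = rng.exponential(1.0 / hazards)
    events = rng.random(n_samples) >= params.censor_rate
    observed = np.where(events, times, times * rng.random(n_samples))
    return pd.DataFrame(
        {
            "sample_id": [f"{group}-{i + 1:03d}" for i in range(n_samples)],
            "group": group,
            "inhba_ratio": ratios,
            "stratum": strata,
            "os_months": observed,
            "os_event": events,
        }
    )
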
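"""Cohort-level aggregation and statistics.

Per-core cell counts become the four stromal ratios; cores with fewer than
500 cancer cells are excluded; the 1-3 remaining cores per sample are
averaged; samples are stratified low/high at the cohort mean ratio; and the
strata are compared by Kaplan-Meier / log-rank survival analysis and the
standard group tests (one-way ANOVA, paired t, Mann-Whitney U, Pearson
correlation). Metagene scores are the mean of per-gene standardized
expression, correlated against a target gene across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

COUNT_COLUMNS = (
    "fibroblasts",
    "cancer_cells",
    "immunocytes",
    "others",
    "asma_pos",
    "inhba_pos",
    "cd3cd4",
    "cd3cd4foxp3",
)

RATIO_COLUMNS = ("fibroblast_ratio", "asma_ratio", "inhba_ratio", "treg_ratio")


def compute_core_ratios(cores: pd.DataFrame) -> pd.DataFrame:
    """Add the four stromal ratios to a per-core count table.

    - fibroblast_ratio = fibroblasts / (fibroblasts + cancer_cells + immunocytes)
    - asma_ratio       = alpha-SMA(+) cells / fibroblasts
    - inhba_ratio      = INHBA(+) cells / fibroblasts
    - treg_ratio       = CD3(+)CD4(+)FOXP3(+) / CD3(+)CD4(+)  (both counted
      in the fibroblast compartment)

    A zero denominator yields a missing value (NaN), never an exception.
    Negative counts are rejected.
    """
    present = [c for c in COUNT_COLUMNS if c in cores.columns]
    if (cores[present] < 0).any().any():
        raise ValueError("counts must be non-negative")
    out = cores.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (
            out["fibroblasts"] + out["cancer_cells"] + out["immunocytes"]
        ).astype(float)
        out["fibroblast_ratio"] = np.where(
            denom > 0, out["fibroblasts"] / denom, np.nan
        )
        fib = out["fibroblasts"].astype(float)
        out["asma_ratio"] = np.where(fib > 0, out["asma_pos"] / fib, np.nan)
        out["inhba_ratio"] = np.where(fib > 0, out["inhba_pos"] / fib, np.nan)
        cd3cd4 = out["cd3cd4"].astype(float)
        out["treg_ratio"] = np.where(
            cd3cd4 > 0, out["cd3cd4foxp3"] / cd3cd4, np.nan
        )
    return out


def apply_core_exclusion(
    cores: pd.DataFrame, min_cancer_cells: int = 500
) -> pd.DataFrame:
    """Drop cores with fewer than ``min_cancer_cells`` cancer cells.

    A core with exactly ``min_cancer_cells`` is kept (the rule excludes
    strictly fewer)."""
    return cores[cores["cancer_cells"] >= min_cancer_cells].copy()


def average_per_sample(
    cores: pd.DataFrame,
    all_samples: list[str] | None = None,
    ratio_columns: tuple[str, ...] = RATIO_COLUMNS,
) -> pd.DataFrame:
    """Unweighted mean of each ratio over a sample's included cores.

    ``all_samples`` optionally lists every sample of the cohort; samples
    that lost all cores to exclusion then appear with missing ratios and
    ``n_cores = 0``."""
    keep_meta = [c for c in ("patient_id", "group") if c in cores.columns]
    present = [c for c in ratio_columns if c in cores.columns]
    grouped = cores.groupby("sample_id", sort=True)
    out = grouped[list(present)].mean()
    out["n_cores"] = grouped.size()
    for c in keep_meta:
        out[c] = grouped[c].first()
    if all_samples is not None:
        out = out.reindex(sorted(all_samples))
        out["n_cores"] = out["n_cores"].fillna(0).astype(int)
    return out.reset_index()


def split_low_high(
    samples: pd.DataFrame, ratio_field: str
) -> tuple[pd.Series, float]:
    """Stratify samples at the cohort mean of ``ratio_field``.

    Values strictly above the mean are "high", values at or below it are
    "low"; missing values get a missing stratum. Returns the stratum series
    (aligned to ``samples``) and the threshold used. Warns when a stratum
    is empty (e.g. all values identical)."""
    values = samples[ratio_field]
    non_missing = values.dropna()
    if len(non_missing) < 2:
        raise ValueError("need at least 2 non-missing samples to stratify")
    threshold = float(non_missing.mean())
    stratum = pd.Series(
        np.where(values > threshold, "high", "low"), index=samples.index
    )
    stratum[values.isna()] = np.nan
    counts = stratum.value_counts()
    if counts.get("high", 0) == 0 or counts.get("low", 0) == 0:
        warnings.warn(
            f"stratification on {ratio_field!r} left a stratum empty "
            f"(threshold {threshold:.4g})",
            stacklevel=2,
        )
    return stratum, threshold


@dataclass
class SurvivalComparison:
    """Two-group survival comparison: per-stratum Kaplan-Meier fits plus the
    log-rank chi-square statistic and two-sided p-value."""

    fitters: dict[str, KaplanMeierFitter]
    statistic: float
    p_value: float
    medians: dict[str, float]

    def survival_table(self) -> pd.DataFrame:
        frames = []
        for name, kmf in self.fitters.items():
            tbl = kmf.survival_function_.reset_index()
            tbl.columns = ["time", "survival"]
            tbl["stratum"] = name
            frames.append(tbl)
        return pd.concat(frames, ignore_index=True)


def survival_compare(
    samples: pd.DataFrame,
    stratum_col: str = "stratum",
    time_col: str = "os_months",
    event_col: str = "os_event",
) -> SurvivalComparison:
    """Kaplan-Meier estimates per stratum and the two-group log-rank test."""
    strata = samples[stratum_col].dropna().unique()
    if len(strata) != 2:
        raise ValueError(f"expected exactly 2 strata, got {sorted(strata)}")
    groups = {}
    for name in sorted(strata):
        sub = samples[samples[stratum_col] == name]
        if len(sub) == 0:
            raise ValueError(f"stratum {name!r} has no subjects")
        if not sub[event_col].any():
            raise ValueError(f"stratum {name!r} has no events")
        groups[name] = sub
    fitters, medians = {}, {}
    for name, sub in groups.items():
        kmf = KaplanMeierFitter(label=name)
        kmf.fit(sub[time_col], sub[event_col])
        fitters[name] = kmf
        medians[name] = float(kmf.median_survival_time_)
    a, b = sorted(groups)
    res = logrank_test(
        groups[a][time_col],
        groups[b][time_col],
        event_observed_A=groups[a][event_col],
        event_observed_B=groups[b][event_col],
    )
    return SurvivalComparison(
        fitters=fitters,
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        medians=medians,
    )


def anova_across_groups(
    samples: pd.DataFrame, value_col: str, group_col: str = "group"
) -> tuple[float, float]:
    """One-way ANOVA of a ratio across disease groups (unpaired)."""
    groups = [
        g[value_col].dropna().to_numpy()
        for _, g in samples.groupby(group_col)
    ]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def paired_t_by_patient(
    samples: pd.DataFrame,
    value_col: str,
    group_a: str,
    group_b: str,
    patient_col: str = "patient_id",
    group_col: str = "group",
    drop_incomplete: bool = False,
) -> tuple[float, float]:
    """Paired t-test between two groups matched on patient.

    Raises a ``ValueError`` naming the unmatched patients when the pairing
    is incomplete, unless ``drop_incomplete`` restricts the test to
    patients with both measurements (e.g. after core exclusion)."""
    wide = samples.pivot_table(
        index=patient_col, columns=group_col, values=value_col, aggfunc="mean"
    )
    for g in (group_a, group_b):
        if g not in wide.columns:
            raise ValueError(f"group {g!r} absent from the table")
    pair = wide[[group_a, group_b]]
    unmatched = pair.index[pair.isna().any(axis=1)].tolist()
    if unmatched:
        if not drop_incomplete:
            raise ValueError(
                f"patients without a complete {group_a}/{group_b} pair: "
                f"{unmatched}"
            )
        pair = pair.dropna()
    if len(pair) < 2:
        raise ValueError("fewer than 2 complete pairs")
    diff = pair[group_a].to_numpy() - pair[group_b].to_numpy()
    if np.all(diff == 0):
        return 0.0, 1.0  # no within-pair differences at all
    t, p = stats.ttest_rel(pair[group_a], pair[group_b])
    return float(t), float(p)


def mann_whitney_low_high(
    samples: pd.DataFrame, value_col: str, stratum_col: str = "stratum"
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing a ratio between low and high
    strata."""
    low = samples.loc[samples[stratum_col] == "low", value_col].dropna()
    high = samples.loc[samples[stratum_col] == "high", value_col].dropna()
    if len(low) == 0 or len(high) == 0:
        raise ValueError("both strata need at least one non-missing value")
    u, p = stats.mannwhitneyu(low, high, alternative="two-sided")
    return float(u), float(p)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value (e.g. alpha-SMA(+) cells
    vs morphology-classified fibroblasts across cores)."""
    r, p = stats.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def group_compare(
    samples: pd.DataFrame, value_col: str = "inhba_ratio"
) -> dict[str, tuple[float, float]]:
    """Convenience wrapper running the standard group tests on a per-sample
    ratio table: one-way ANOVA across the three groups and paired t-tests of
    primary vs metastatic and primary vs recurrent, restricted to patients
    with both measurements."""
    results = {"anova": anova_across_groups(samples, value_col)}
    for other in ("metastatic", "recurrent"):
        results[f"paired_t_primary_vs_{other}"] = paired_t_by_patient(
            samples, value_col, "primary", other, drop_incomplete=True
        )
    return results


def metagene_score(
    expression: pd.DataFrame, genes: list[str], method: str = "mean"
) -> pd.Series:
    """Per-sample metagene score from a genes x samples matrix.

    ``method='mean'`` (default) averages per-gene standardized expression;
    ``'median'`` takes the median of the standardized members; ``'pc1'``
    projects on the first principal component (oriented to correlate
    positively with the mean score)."""
    present = [g for g in genes if g in expression.index]
    if not present:
        raise ValueError(f"no member genes present; wanted {genes}")
    sub = expression.loc[present].astype(float)
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1, ddof=0), axis=0)
    if method == "mean":
        return z.mean(axis=0)
    if method == "median":
        return z.median(axis=0)
    if method == "pc1":
        centered = z.to_numpy()
        _, _, vt = np.linalg.svd(centered - centered.mean(1, keepdims=True))
        pc1 = pd.Series(vt[0], index=z.columns)
        if pc1.corr(z.mean(axis=0)) < 0:
            pc1 = -pc1
        return pc1
    raise ValueError(f"unknown method {method!r}")


def metagene_correlate(
    expression: pd.DataFrame,
    metagene_sets: dict[str, list[str]],
    target_gene: str = "INHBA",
    method: str = "mean",
) -> pd.DataFrame:
    """Pearson correlation of each metagene score with a target gene's
    expression across samples."""
    if target_gene not in expression.index:
        raise KeyError(f"target gene {target_gene!r} absent from the matrix")
    target = expression.loc[target_gene].astype(float)
    rows = []
    for name, genes in metagene_sets.items():
        score = metagene_score(expression, genes, method=method)
        r, p = pearson_correlation(target.to_numpy(), score.to_numpy())
        rows.append({"metagene": name, "pearson_r": r, "p_value": p,
                     "n_genes": len([g for g in genes if g in expression.index])})
    return pd.DataFrame(rows)
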
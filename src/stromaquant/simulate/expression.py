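"""Synthetic genes-by-samples expression matrices with planted metagene
structure.

Member genes of each metagene share a latent per-sample factor; the INHBA
row is constructed so that its Pearson correlation with the realized Treg
metagene score equals the requested value exactly in-sample (the noise
component is residualized against the score before mixing, analogous to
``MASS::mvrnorm(..., empirical = TRUE)``). Monte-Carlo recovery over seeds
then measures the analysis path rather than raw bivariate sampling noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        raise ValueError("zero-variance vector cannot be standardized")
    return (x - x.mean()) / s


def generate_expression_matrix(
    n_samples: int,
    metagene_sets: dict[str, list[str]],
    inhba_treg_correlation: float,
    seed: int = 0,
    treg_set: str = "Treg",
    loading: float = 0.7,
    n_noise_genes: int = 50,
    target_gene: str = "INHBA",
) -> pd.DataFrame:
    """Simulate a genes x samples expression matrix.

    Parameters
    ----------
    metagene_sets
        Mapping metagene name -> member gene names. Genes within a set share
        a latent factor with variance fraction ``loading``; sets are
        mutually independent.
    inhba_treg_correlation
        In-sample Pearson correlation planted between ``target_gene`` and
        the ``treg_set`` metagene score (mean of per-gene standardized
        expression). Must lie in [-1, 1].

    Returns a DataFrame indexed by gene name with sample columns
    ``s001 ...``; values are on a standardized (z-score-like) scale.
    """
    r = float(inhba_treg_correlation)
    if not -1.0 <= r <= 1.0:
        raise ValueError("inhba_treg_correlation must be in [-1, 1]")
    if treg_set not in metagene_sets:
        raise KeyError(f"metagene set {treg_set!r} not provided")
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)

    rows: dict[str, np.ndarray] = {}
    for name, genes in metagene_sets.items():
        if not genes:
            raise ValueError(f"metagene {name!r} has no member genes")
        z = rng.normal(size=n_samples)
        for g in genes:
            eps = rng.normal(size=n_samples)
            rows[g] = np.sqrt(loading) * z + np.sqrt(1 - loading) * eps

    # realized Treg metagene score, as the analysis computes it
    members = metagene_sets[treg_set]
    score = np.mean([_standardize(rows[g]) for g in members], axis=0)
    u = _standardize(score)

    eps = rng.normal(size=n_samples)
    resid = eps - (eps @ u) / (u @ u) * u  # orthogonal to the score
    if np.allclose(resid, 0):
        resid = np.zeros_like(u)
    else:
        resid = _standardize(resid)
    rows[target_gene] = r * u + np.sqrt(1 - r**2) * resid

    for i in range(n_noise_genes):
        rows[f"noise{i + 1:04d}"] = rng.normal(size=n_samples)

    columns = [f"s{i + 1:03d}" for i in range(n_samples)]
    return pd.DataFrame(
        np.vstack(list(rows.values())), index=list(rows), columns=columns
    )
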
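"""Repeated k-means cluster-stability score for gene selection.

Genes (optionally alongside synthetic noise variables) are clustered on
their z-scored per-sample profiles. In each repeat, the "top-scoring"
cluster is the one whose per-sample median profile has the largest
Spearman correlation with dose; a gene's score is how many repeats placed
it there. Strong dose reporters land in the top cluster nearly every
repeat, noise variables only rarely, so the frequency separates the two.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .dataset import ExpressionDataset
from .screen import NoiseAugmentation


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    # missing entries are imputed at the row mean (0 after standardization)
    X = np.array(values, dtype=float)
    mean = np.nanmean(X, axis=1, keepdims=True)
    sd = np.nanstd(X, axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    X = (X - mean) / sd
    return np.nan_to_num(X, nan=0.0)


def kmeans_top_cluster_frequency(
    values: pd.DataFrame,
    dose: np.ndarray,
    repeats: int = 50,
    avg_cluster_size: int = 30,
    seed: int = 0,
    max_iter: int = 100,
) -> pd.Series:
    """Per-row count (0..repeats) of appearances in the top-scoring cluster.

    ``values`` is rows (genes and/or noise variables) x samples; ``dose``
    aligns with its columns. k = round(n_rows / avg_cluster_size); each
    repeat uses a different initialization seed derived from ``seed``.
    """
    n_rows = values.shape[0]
    if n_rows < 2 * avg_cluster_size:
        raise ValueError("need at least 2 * avg_cluster_size rows")
    k = int(round(n_rows / avg_cluster_size))
    if k < 2:
        raise ValueError("average cluster size too large: fewer than 2 clusters")

    X = _zscore_rows(values.to_numpy())
    dose = np.asarray(dose, dtype=float)
    dr = stats.rankdata(dose)
    dr = (dr - dr.mean()) / dr.std()
    n_samp = dose.size

    counts = np.zeros(n_rows, dtype=int)
    seeds = np.random.SeedSequence(seed).generate_state(repeats) % (2**31 - 1)
    for rep_seed in seeds:
        km = KMeans(n_clusters=k, n_init=1, max_iter=max_iter, random_state=int(rep_seed))
        labels = km.fit_predict(X)
        best_rho, best_cluster = -np.inf, -1
        for c in range(k):
            members = labels == c
            profile = np.median(X[members], axis=0)
            pr = stats.rankdata(profile)
            sd = pr.std()
            if sd == 0:
                continue
            rho = ((pr - pr.mean()) / sd) @ dr / n_samp
            if rho > best_rho:
                best_rho, best_cluster = rho, c
        counts[labels == best_cluster] += 1
    return pd.Series(counts, index=values.index.copy(), name="kmeans_top_frequency")


def kmeans_frequencies_with_noise(
    ds: ExpressionDataset,
    noise: NoiseAugmentation | None = None,
    repeats: int = 50,
    avg_cluster_size: int = 30,
    seed: int = 0,
    dose: np.ndarray | None = None,
) -> pd.Series:
    """Cluster real genes together with noise variables (when given) and
    return top-cluster frequencies for every row."""
    mats = [ds.values]
    if noise is not None:
        mats.append(noise.values)
    combined = pd.concat(mats, axis=0)
    if dose is None:
        dose = ds.dose_gy.to_numpy()
    return kmeans_top_cluster_frequency(
        combined, dose, repeats=repeats, avg_cluster_size=avg_cluster_size, seed=seed
    )
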
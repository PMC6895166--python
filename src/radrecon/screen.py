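"""Dose-correlation screen and synthetic-noise benchmark.

Candidate signature genes must (a) pass a Bonferroni-corrected Spearman
test of rank correlation with dose and (b) beat every injected synthetic
noise variable's correlation. The noise matrix — normal and uniform
pseudo-genes matched to the pooled mean and SD of the real data — acts
as an empirical ceiling on what chance alone achieves at this sample
size, independent of the parametric p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset

log = logging.getLogger(__name__)


def _spearman_t_pvalue(rho: np.ndarray, n: int | np.ndarray) -> np.ndarray:
    """Two-sided p for H0: rho=0 via the t approximation with n-2 df.

    Midrank-tied data are handled upstream (ranks already computed with
    ties as midranks); |rho| == 1 maps to p = 0.
    """
    rho = np.asarray(rho, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2.0) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2.0)
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, p)
    return p


def spearman_matrix(values: np.ndarray, dose: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman correlation of ``values`` (rows x samples) with
    ``dose``, with pairwise deletion of missing entries per row.

    Returns (rho, p_raw); rows constant after rank transformation (or with
    < 3 paired observations) get NaN.
    """
    values = np.asarray(values, dtype=float)
    dose = np.asarray(dose, dtype=float)
    n_rows, n_samp = values.shape
    if np.unique(dose).size < 2:
        raise ValueError("all doses are equal; correlation with dose undefined")

    rho = np.full(n_rows, np.nan)
    eff_n = np.full(n_rows, n_samp, dtype=float)
    complete = ~np.isnan(values).any(axis=1)

    if complete.any():
        sub = values[complete]
        ranks = stats.rankdata(sub, axis=1)
        dr = stats.rankdata(dose)
        ranks -= ranks.mean(axis=1, keepdims=True)
        dr = dr - dr.mean()
        sd = ranks.std(axis=1)
        dsd = dr.std()
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ranks @ dr) / n_samp / (sd * dsd)
        r[sd == 0] = np.nan
        rho[complete] = r

    for i in np.flatnonzero(~complete):
        mask = ~np.isnan(values[i])
        eff_n[i] = mask.sum()
        if mask.sum() < 3 or np.unique(dose[mask]).size < 2:
            continue
        x = stats.rankdata(values[i, mask])
        if np.all(x == x[0]):
            continue
        y = stats.rankdata(dose[mask])
        rho[i] = np.corrcoef(x, y)[0, 1]

    p = _spearman_t_pvalue(rho, eff_n)
    return rho, p


def spearman_with_dose(ds: ExpressionDataset) -> pd.DataFrame:
    """Per-gene Spearman correlation with dose.

    Returns a DataFrame indexed by gene with columns ``rho`` and ``p_raw``;
    constant genes carry NaN and are excluded downstream. Requires >= 3
    samples spanning >= 2 distinct doses.
    """
    dose = ds.dose_gy.to_numpy()
    if ds.n_samples < 3:
        raise ValueError("need at least 3 samples")
    rho, p = spearman_matrix(ds.values.to_numpy(), dose)
    return pd.DataFrame({"rho": rho, "p_raw": p}, index=ds.values.index.copy())


def bonferroni_adjust(p_raw, n_tests: int) -> np.ndarray:
    """Family-wise adjustment p_adj = min(1, p_raw * n_tests)."""
    p = np.asarray(p_raw, dtype=float)
    finite = p[~np.isnan(p)]
    if finite.size and (finite.min() < 0 or finite.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if n_tests < p.size:
        raise ValueError("n_tests must be >= number of p-values")
    return np.minimum(1.0, p * n_tests)


@dataclass
class NoiseAugmentation:
    """Synthetic noise pseudo-genes injected alongside the real matrix."""

    values: pd.DataFrame          # noise variables x samples
    labels: pd.Series             # "normal" | "uniform" per noise row
    mean: float
    sd: float
    seed: int

    @property
    def n_noise(self) -> int:
        return self.values.shape[0]


def default_noise_counts(n_genes: int) -> tuple[int, int]:
    """Noise counts keeping the ~3:1 noise-to-real ratio (2x normal,
    1x uniform), i.e. 40,000 + 20,000 at 20,000 real genes."""
    return 2 * n_genes, n_genes


def inject_noise_variables(
    ds: ExpressionDataset,
    n_normal: int | None = None,
    n_uniform: int | None = None,
    seed: int = 0,
) -> NoiseAugmentation:
    """Draw noise pseudo-genes matched to the pooled moments of the data.

    Normal rows are N(m, s); uniform rows span [m - s*sqrt(3), m + s*sqrt(3)]
    so both families share the real data's pooled mean m and SD s.
    """
    if ds.n_genes == 0:
        raise ValueError("empty dataset")
    if n_normal is None or n_uniform is None:
        dn, du = default_noise_counts(ds.n_genes)
        n_normal = dn if n_normal is None else n_normal
        n_uniform = du if n_uniform is None else n_uniform
    flat = ds.values.to_numpy().ravel()
    flat = flat[~np.isnan(flat)]
    m = float(flat.mean())
    s = float(flat.std(ddof=1))
    if s == 0:
        raise ValueError("pooled SD of real genes is zero")
    rng = np.random.default_rng(seed)
    half = s * np.sqrt(3.0)
    normal = rng.normal(m, s, (n_normal, ds.n_samples))
    uniform = rng.uniform(m - half, m + half, (n_uniform, ds.n_samples))
    idx = pd.Index(
        [f"noise_normal_{i}" for i in range(n_normal)]
        + [f"noise_uniform_{i}" for i in range(n_uniform)],
        name="noise_id",
    )
    values = pd.DataFrame(np.vstack([normal, uniform]), index=idx, columns=ds.sample_ids)
    labels = pd.Series(["normal"] * n_normal + ["uniform"] * n_uniform, index=idx)
    return NoiseAugmentation(values=values, labels=labels, mean=m, sd=s, seed=seed)


def noise_benchmark_filter(
    screen: pd.DataFrame,
    noise_rhos: np.ndarray,
    alpha: float = 0.05,
    direction: int = 1,
) -> list[str]:
    """Keep genes with Bonferroni p <= alpha whose correlation beats every
    noise variable (rho above the noise maximum for up-regulated screens,
    below the noise minimum for down-regulated ones).

    ``screen`` must carry columns ``rho`` and ``p_bonferroni``.
    """
    noise_rhos = np.asarray(noise_rhos, dtype=float)
    noise_rhos = noise_rhos[~np.isnan(noise_rhos)]
    if noise_rhos.size == 0:
        raise ValueError("empty noise benchmark")
    sig = screen["p_bonferroni"] <= alpha
    if direction >= 0:
        beats = screen["rho"] > noise_rhos.max()
    else:
        beats = screen["rho"] < noise_rhos.min()
    return list(screen.index[sig & beats])
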
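"""Negative and positive controls for the selection machinery.

The permutation control destroys any real gene-dose association by
shuffling dose labels and checks that nothing survives the screen or
scores highly in clustering (false-positive rate). The planted-dependence
control does the opposite: it makes dose a deterministic-plus-noise
function of one chosen noise variable and checks that the analysis finds
that variable (sensitivity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster import kmeans_frequencies_with_noise
from .dataset import ExpressionDataset
from .screen import NoiseAugmentation, inject_noise_variables
from .signature import screen_genes


def _with_dose(ds: ExpressionDataset, dose: np.ndarray) -> ExpressionDataset:
    out = ds.copy()
    out.sample_meta["dose_gy"] = np.asarray(dose, dtype=float)
    return out


@dataclass
class PermutationReport:
    n_pass_benchmark: int
    max_cluster_frequency: int | None
    repeats: int | None
    seed: int
    permutation: np.ndarray


def permute_dose_control(
    ds: ExpressionDataset,
    seed: int = 0,
    noise: NoiseAugmentation | None = None,
    alpha: float = 0.05,
    include_clustering: bool = True,
    repeats: int = 50,
    avg_cluster_size: int = 30,
    permutation: np.ndarray | None = None,
) -> PermutationReport:
    """Re-run screen + noise benchmark (and optionally clustering) with
    permuted dose labels; reports how many genes still pass and the highest
    clustering frequency seen. ``permutation=None`` draws a random one from
    ``seed``; pass an explicit index array (e.g. the identity) to control it.
    """
    rng = np.random.default_rng(seed)
    dose = ds.dose_gy.to_numpy()
    if permutation is None:
        permutation = rng.permutation(ds.n_samples)
    permuted = _with_dose(ds, dose[permutation])
    if noise is None:
        noise = inject_noise_variables(ds, seed=seed)
    _, kept = screen_genes(permuted, noise=noise, alpha=alpha)
    max_freq = None
    if include_clustering:
        freqs = kmeans_frequencies_with_noise(
            permuted, noise=noise, repeats=repeats,
            avg_cluster_size=avg_cluster_size, seed=seed,
        )
        max_freq = int(freqs.max())
    return PermutationReport(
        n_pass_benchmark=len(kept),
        max_cluster_frequency=max_freq,
        repeats=repeats if include_clustering else None,
        seed=seed,
        permutation=np.asarray(permutation),
    )


@dataclass
class PlantedDependenceReport:
    noise_index: str
    detected_in: int
    repeats: int
    seed: int


def planted_dependence_control(
    ds: ExpressionDataset,
    noise: NoiseAugmentation,
    noise_index: str,
    a: float = 0.0,
    b: float = 1.0,
    seed: int = 0,
    repeats: int = 50,
    avg_cluster_size: int = 30,
) -> PlantedDependenceReport:
    """Replace dose with ``a + b * noise_value`` for a chosen noise variable
    and count in how many k-means repeats that variable lands in the
    top-scoring cluster."""
    if b == 0:
        raise ValueError("b must be nonzero: no dependence to detect")
    if noise_index not in noise.values.index:
        raise KeyError(f"unknown noise variable {noise_index!r}")
    fake_dose = a + b * noise.values.loc[noise_index].to_numpy(dtype=float)
    freqs = kmeans_frequencies_with_noise(
        ds, noise=noise, repeats=repeats, avg_cluster_size=avg_cluster_size,
        seed=seed, dose=fake_dose,
    )
    return PlantedDependenceReport(
        noise_index=noise_index,
        detected_in=int(freqs.loc[noise_index]),
        repeats=repeats,
        seed=seed,
    )
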
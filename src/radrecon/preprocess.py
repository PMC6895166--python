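"""Pre-analysis normalization and filtering.

Mirrors standard single-channel microarray practice on the log2 scale:
collapse replicate probes/symbols by averaging, drop genes with too many
missing values, and median-center each array to the grand
median-of-medians (an additive shift, so within-sample rank order — and
hence every downstream rank statistic — is untouched).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset


def median_array_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Shift each sample so its median (over non-missing genes) equals the
    median of all per-sample medians."""
    if ds.n_samples < 1:
        raise ValueError("dataset has no samples")
    medians = ds.values.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = list(medians.index[medians.isna()])
        raise ValueError(f"samples with all values missing: {bad}")
    target = float(medians.median())
    values = ds.values.add(target - medians, axis=1)
    return ExpressionDataset(values, ds.sample_meta.copy())


def filter_missing_genes(ds: ExpressionDataset, max_frac: float = 0.20) -> ExpressionDataset:
    """Remove genes whose missing fraction is strictly greater than
    ``max_frac`` (a gene missing in exactly 20% of samples is kept at the
    default). Gene order is preserved."""
    if not 0.0 <= max_frac <= 1.0:
        raise ValueError("max_frac must be in [0, 1]")
    frac = ds.values.isna().mean(axis=1)
    keep = frac <= max_frac
    return ExpressionDataset(ds.values.loc[keep].copy(), ds.sample_meta.copy())


def collapse_gene_symbols(ds: ExpressionDataset) -> ExpressionDataset:
    """Average replicate rows that share a gene symbol.

    The collapsed value is the unweighted mean over non-missing replicate
    entries; a cell stays missing only when every replicate is missing.
    First-occurrence gene order is preserved.
    """
    if not ds.values.index.duplicated().any():
        return ds.copy()
    order = ds.values.index.drop_duplicates()
    collapsed = ds.values.groupby(level=0, sort=False).mean()
    collapsed = collapsed.loc[order]
    return ExpressionDataset(collapsed, ds.sample_meta.copy())


def preprocess(
    ds: ExpressionDataset,
    max_missing_frac: float = 0.20,
    collapse: bool = True,
    normalize: bool = True,
) -> ExpressionDataset:
    """Default pipeline: collapse symbols, filter missing genes, median-center."""
    out = collapse_gene_symbols(ds) if collapse else ds
    out = filter_missing_genes(out, max_missing_frac)
    if normalize:
        out = median_array_normalize(out)
    return out
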
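"""Expression dataset container and TSV round-trip I/O.

The pipeline's universal carrier is a log2 gene-by-sample matrix plus
per-sample metadata (dose in Gy, blood donor, originating dataset,
measurement platform). Missing measurements are NaN in the matrix and
the literal ``NA`` (or an empty cell) on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

META_COLUMNS = ["dose_gy", "donor_id", "dataset_id", "platform"]


@dataclass
class ExpressionDataset:
    """Log2 expression matrix (genes x samples) with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene symbol, columns are sample identifiers,
        float entries on the log2 scale; NaN marks a missing measurement.
    sample_meta
        DataFrame indexed by sample identifier with columns ``dose_gy``
        (non-negative, Gy), ``donor_id``, ``dataset_id`` and ``platform``.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        missing_cols = [c for c in META_COLUMNS if c not in self.sample_meta.columns]
        if missing_cols:
            raise ValueError(f"sample_meta lacks required columns: {missing_cols}")
        if list(self.values.columns) != list(self.sample_meta.index):
            # allow metadata in any order but it must cover every sample
            extra = set(self.values.columns) - set(self.sample_meta.index)
            if extra:
                raise ValueError(
                    f"samples absent from metadata: {sorted(extra)}"
                )
            self.sample_meta = self.sample_meta.loc[list(self.values.columns)]
        doses = self.sample_meta["dose_gy"].to_numpy(dtype=float)
        if np.any(np.isnan(doses)) or np.any(doses < 0):
            raise ValueError("dose_gy must be non-negative for every sample")
        if self.sample_meta["donor_id"].isna().any() or self.sample_meta["dataset_id"].isna().any():
            raise ValueError("every sample needs a donor_id and a dataset_id")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample identifiers")

    # -- convenience accessors -------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def dose_gy(self) -> pd.Series:
        return self.sample_meta["dose_gy"].astype(float)

    @property
    def donor_id(self) -> pd.Series:
        return self.sample_meta["donor_id"]

    @property
    def dataset_id(self) -> pd.Series:
        return self.sample_meta["dataset_id"]

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(self.values.copy(), self.sample_meta.copy())

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionDataset":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionDataset(self.values.loc[genes].copy(), self.sample_meta.copy())

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionDataset":
        samples = list(samples)
        return ExpressionDataset(
            self.values[samples].copy(), self.sample_meta.loc[samples].copy()
        )

    def control_samples(self) -> list[str]:
        """Samples with dose exactly 0 Gy (unirradiated controls)."""
        return list(self.sample_meta.index[self.sample_meta["dose_gy"] == 0.0])


def read_expression_table(matrix_path, meta_path) -> ExpressionDataset:
    """Read a TSV expression matrix plus its sample metadata table.

    The matrix file has a header row (``gene_id`` then sample IDs) and one
    row per gene. Empty cells and the literal ``NA`` are treated as missing;
    any other non-numeric cell is a hard error reporting its coordinates.
    """
    raw = pd.read_csv(matrix_path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2:
        raise ValueError(f"{matrix_path}: expected gene_id column plus >=1 sample")
    gene_col = raw.columns[0]
    raw = raw.set_index(gene_col)
    raw.index.name = "gene_id"

    cleaned = raw.replace({"": np.nan, "NA": np.nan})
    values = cleaned.apply(pd.to_numeric, errors="coerce")
    bad = values.isna() & cleaned.notna()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{matrix_path}: non-numeric cell at gene {raw.index[g]!r}, "
            f"sample {raw.columns[s]!r}: {raw.iloc[g, s]!r}"
        )

    meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str, "donor_id": str,
                                                   "dataset_id": str, "platform": str})
    if "sample_id" not in meta.columns:
        raise ValueError(f"{meta_path}: missing sample_id column")
    meta = meta.set_index("sample_id")
    unknown = [s for s in values.columns if s not in meta.index]
    if unknown:
        raise ValueError(
            f"matrix samples missing from metadata {meta_path}: {unknown}"
        )
    return ExpressionDataset(values, meta.loc[list(values.columns), META_COLUMNS].copy())


def write_expression_table(ds: ExpressionDataset, matrix_path, meta_path) -> None:
    """Write the matrix and metadata as TSV; inverse of read_expression_table."""
    out = ds.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", na_rep="NA")  # full repr precision
    meta = ds.sample_meta[META_COLUMNS].copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


def merge_datasets(datasets: Sequence[ExpressionDataset]) -> ExpressionDataset:
    """Concatenate samples across datasets on the shared gene set.

    Genes are restricted to the exact intersection (order taken from the
    first input); samples keep their per-sample ``dataset_id``. Duplicate
    sample identifiers across inputs are an error.
    """
    if len(datasets) < 2:
        raise ValueError("merge_datasets needs at least two datasets")
    shared = set(datasets[0].gene_ids)
    for ds in datasets[1:]:
        shared &= set(ds.gene_ids)
    if not shared:
        raise ValueError("empty gene intersection across datasets")
    genes = [g for g in datasets[0].gene_ids if g in shared]

    all_samples: list[str] = []
    for ds in datasets:
        all_samples.extend(ds.sample_ids)
    if len(all_samples) != len(set(all_samples)):
        dupes = sorted({s for s in all_samples if all_samples.count(s) > 1})
        raise ValueError(f"duplicate sample_ids across inputs: {dupes}")

    values = pd.concat([ds.values.loc[genes] for ds in datasets], axis=1)
    meta = pd.concat([ds.sample_meta for ds in datasets], axis=0)
    return ExpressionDataset(values, meta)
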
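"""Normalizer-gene selection and the normalized reconstructor signal S.

Baseline expression in unirradiated samples drifts 2-4 fold between
independent studies, which wrecks any absolute-signal reconstructor. A
normalizer gene (i) tracks the signature group's median closely in the
0-Gy control samples of pooled training datasets (small sum of squared
differences) and (ii) has no dose response of its own (|Spearman with
dose| near zero). Subtracting the normalizer median from the signature
median yields S, a per-sample signal invariant to array-wide shifts and
largely free of cross-dataset baseline drift.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .screen import spearman_matrix
from .signature import SignatureSet, median_signature_signal

log = logging.getLogger(__name__)


def score_normalizer_candidates(
    pooled: ExpressionDataset,
    signature: SignatureSet | list[str],
) -> pd.DataFrame:
    """Score every non-signature gene as a normalizer candidate.

    ``ssd_control``: sum over pooled 0-Gy control samples of the squared
    difference between the gene's signal and that sample's signature
    median (genes missing in some controls are rescaled to the full
    control count so missingness does not fake a low score).
    ``abs_rho_dose``: |Spearman with dose| over all pooled samples.
    """
    sig_genes = signature.gene_ids if isinstance(signature, SignatureSet) else list(signature)
    ds_ids = pooled.dataset_id.unique()
    if len(ds_ids) < 2:
        raise ValueError("pooled input must contain >= 2 dataset_ids")
    for d in ds_ids:
        in_d = pooled.dataset_id == d
        if not ((pooled.dose_gy == 0) & in_d).any():
            raise ValueError(f"dataset {d!r} has no 0-Gy control samples")

    sig_median = median_signature_signal(pooled, sig_genes)
    controls = pooled.control_samples()
    candidates = [g for g in pooled.gene_ids if g not in set(sig_genes)]
    if not candidates:
        raise ValueError("no candidate genes outside the signature")

    vals = pooled.values.loc[candidates, controls].to_numpy()
    diff2 = (vals - sig_median[controls].to_numpy()[None, :]) ** 2
    n_ctrl = len(controls)
    n_obs = (~np.isnan(diff2)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ssd = np.nanmean(diff2, axis=1) * n_ctrl
    ssd[n_obs == 0] = np.inf

    # Dose correlation is assessed within each training dataset and then
    # combined (sample-size-weighted mean rho; Stouffer-combined p on the
    # Fisher z scale). A pooled-across-datasets Spearman would be
    # confounded by exactly the cross-dataset baseline shifts that
    # normalizer genes are supposed to track: a perfectly dose-inert,
    # shift-tracking gene acquires a spurious pooled correlation whenever
    # the datasets' dose distributions differ.
    rho_sum = np.zeros(len(candidates))
    w_sum = np.zeros(len(candidates))
    z_sum = np.zeros(len(candidates))
    z_w2 = np.zeros(len(candidates))
    for d in ds_ids:
        cols = list(pooled.sample_meta.index[pooled.dataset_id == d])
        n_d = len(cols)
        if n_d < 4:
            continue
        rho_d, _ = spearman_matrix(
            pooled.values.loc[candidates, cols].to_numpy(),
            pooled.dose_gy[cols].to_numpy(),
        )
        ok = ~np.isnan(rho_d)
        rho_sum[ok] += n_d * rho_d[ok]
        w_sum[ok] += n_d
        with np.errstate(divide="ignore"):
            z = np.arctanh(np.clip(rho_d, -0.999999, 0.999999)) * np.sqrt(n_d - 3)
        z_sum[ok] += z[ok]
        z_w2[ok] += 1.0
    from scipy import stats as _stats

    with np.errstate(invalid="ignore", divide="ignore"):
        rho = rho_sum / w_sum
        z_comb = z_sum / np.sqrt(z_w2)
    rho_p = 2.0 * _stats.norm.sf(np.abs(z_comb))
    rho_p[w_sum == 0] = np.nan
    rho[w_sum == 0] = np.nan
    return pd.DataFrame(
        {"ssd_control": ssd, "abs_rho_dose": np.abs(rho), "rho_p": rho_p},
        index=pd.Index(candidates, name="gene_id"),
    )


@dataclass
class NormalizerSet:
    gene_ids: list[str]
    scores: pd.DataFrame
    target_size: int
    relaxed: bool = False

    def __len__(self) -> int:
        return len(self.gene_ids)


def select_normalizers(
    scores: pd.DataFrame,
    target_size: int,
    rho_cutoff: float | None = None,
    alpha: float = 0.05,
) -> NormalizerSet:
    """Pick the ``target_size`` candidates with smallest control SSD among
    those with no detectable dose response; if too few are eligible, fill
    the remainder by combined (SSD rank + |rho| rank), logging the
    relaxation.

    Eligibility ("as close to zero correlation as possible") defaults to a
    significance test — the gene's dose correlation must not reject rho = 0
    at ``alpha`` — because at realistic sample sizes a truly unresponsive
    gene's sample rho scatters with SD ~ 1/sqrt(n); a fixed cutoff tighter
    than that rejects half of the genuinely eligible genes. Passing an
    explicit ``rho_cutoff`` switches to the fixed-threshold rule
    |rho| <= rho_cutoff instead.
    """
    if scores.empty:
        raise ValueError("no normalizer candidates scored")
    usable = scores[np.isfinite(scores["ssd_control"]) & scores["abs_rho_dose"].notna()]
    if rho_cutoff is None:
        if "rho_p" not in usable.columns:
            raise ValueError("scores lack rho_p; pass an explicit rho_cutoff")
        mask = usable["rho_p"] > alpha
    else:
        mask = usable["abs_rho_dose"] <= rho_cutoff
    eligible = usable[mask].sort_values("ssd_control")
    chosen = list(eligible.index[:target_size])
    relaxed = False
    if len(chosen) < target_size:
        relaxed = True
        log.warning(
            "only %d candidates pass the dose-response eligibility; "
            "filling to %d by rank sum",
            len(chosen), target_size,
        )
        rest = usable.drop(index=chosen)
        rank_sum = rest["ssd_control"].rank() + rest["abs_rho_dose"].rank()
        chosen += list(rank_sum.sort_values().index[: target_size - len(chosen)])
    return NormalizerSet(
        gene_ids=chosen,
        scores=scores.loc[chosen].copy(),
        target_size=target_size,
        relaxed=relaxed,
    )


@dataclass
class NormalizedSignal:
    """Per-sample S = median(signature) - median(normalizers), in log2 units."""

    s: pd.Series
    signature_coverage: float
    normalizer_coverage: float

    def frame(self, ds: ExpressionDataset) -> pd.DataFrame:
        out = ds.sample_meta[["dose_gy", "dataset_id"]].copy()
        out["S"] = self.s
        return out


def compute_normalized_signal(
    ds: ExpressionDataset,
    signature: SignatureSet | list[str],
    normalizers: NormalizerSet | list[str],
    min_present_frac: float = 0.5,
) -> NormalizedSignal:
    """Compute S per sample, tolerating cross-platform gene loss down to
    ``min_present_frac`` coverage of each gene list."""
    sig_genes = signature.gene_ids if isinstance(signature, SignatureSet) else list(signature)
    norm_genes = normalizers.gene_ids if isinstance(normalizers, NormalizerSet) else list(normalizers)
    present = set(ds.gene_ids)
    sig_present = [g for g in sig_genes if g in present]
    norm_present = [g for g in norm_genes if g in present]
    cov_sig = len(sig_present) / len(sig_genes) if sig_genes else 0.0
    cov_norm = len(norm_present) / len(norm_genes) if norm_genes else 0.0
    if cov_sig < min_present_frac or cov_norm < min_present_frac:
        raise ValueError(
            f"gene coverage too low: signature {cov_sig:.2f}, "
            f"normalizers {cov_norm:.2f} (min {min_present_frac})"
        )
    s = (
        ds.values.loc[sig_present].median(axis=0, skipna=True)
        - ds.values.loc[norm_present].median(axis=0, skipna=True)
    )
    s.name = "S"
    return NormalizedSignal(s=s, signature_coverage=cov_sig, normalizer_coverage=cov_norm)
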
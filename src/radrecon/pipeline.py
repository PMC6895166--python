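"""End-to-end study analysis: train the reconstructor, test it, report.

This is the orchestration used by the command-line ``run-all``, the
examples, and the acceptance script: preprocess each dataset, select
signature genes on the first training set, select normalizer genes on the
pooled training sets, fit the standard curve on pooled training S values,
and reconstruct doses on both test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .curve import (
    DoseReconstruction,
    StandardCurveModel,
    fit_standard_curve,
    reconstruct_doses,
    select_model_structure,
)
from .dataset import ExpressionDataset, merge_datasets
from .normalizers import (
    NormalizerSet,
    compute_normalized_signal,
    score_normalizer_candidates,
    select_normalizers,
)
from .preprocess import preprocess
from .screen import inject_noise_variables
from .signature import SignatureSet, build_signature

log = logging.getLogger(__name__)


@dataclass
class StudyResult:
    signature: SignatureSet
    normalizers: NormalizerSet
    train_s: pd.Series
    train_dose: pd.Series
    train_spearman_s_dose: float
    model_ols: StandardCurveModel
    model_robust: StandardCurveModel
    aicc_table: pd.DataFrame
    reconstructions: dict[str, dict[str, DoseReconstruction]] = field(default_factory=dict)


def run_study_analysis(
    datasets: dict[str, ExpressionDataset],
    cfg: PipelineConfig | None = None,
    train_ids: tuple[str, str] = ("train1", "train2"),
    test_ids: tuple[str, ...] = ("test1", "test2"),
    select_structure: bool = True,
) -> StudyResult:
    cfg = cfg or PipelineConfig()
    cfg.validate()
    cfg.log_resolved()
    from scipy import stats

    prep = {k: preprocess(ds, cfg.max_missing_frac) for k, ds in datasets.items()}

    train1 = prep[train_ids[0]]
    noise = inject_noise_variables(
        train1, n_normal=cfg.n_noise_normal, n_uniform=cfg.n_noise_uniform, seed=cfg.seed
    )
    signature, _ = build_signature(train1, direction=1, alpha=cfg.alpha,
                                   seed=cfg.seed, noise=noise)
    log.info("signature: %d genes", len(signature))

    pooled = merge_datasets([prep[t] for t in train_ids])
    scores = score_normalizer_candidates(pooled, signature)
    normalizers = select_normalizers(scores, target_size=len(signature),
                                     rho_cutoff=cfg.rho_cutoff)

    train_sig = compute_normalized_signal(pooled, signature, normalizers,
                                          cfg.min_present_frac)
    train_dose = pooled.dose_gy
    rho_s = float(stats.spearmanr(train_sig.s.to_numpy(), train_dose.to_numpy()).statistic)

    S = train_sig.s.to_numpy()
    d = train_dose.to_numpy()
    if select_structure:
        best, table = select_model_structure(S, d, cfg.candidate_power_sets)
        powers = best.powers
    else:
        powers = (1, 4)
        best = fit_standard_curve(S, d, powers=powers, variant="ols")
        table = pd.DataFrame([{"powers": powers, "aicc": best.aicc, "rss": best.rss}])
    model_ols = best if best.variant == "ols" else fit_standard_curve(S, d, powers, "ols")
    model_robust = fit_standard_curve(S, d, powers=powers, variant="robust")

    result = StudyResult(
        signature=signature,
        normalizers=normalizers,
        train_s=train_sig.s,
        train_dose=train_dose,
        train_spearman_s_dose=rho_s,
        model_ols=model_ols,
        model_robust=model_robust,
        aicc_table=table,
    )
    for t in test_ids:
        test_ds = prep[t]
        sig_t = compute_normalized_signal(test_ds, signature, normalizers,
                                          cfg.min_present_frac)
        result.reconstructions[t] = {
            "ols": reconstruct_doses(model_ols, sig_t.s, test_ds.dose_gy),
            "robust": reconstruct_doses(model_robust, sig_t.s, test_ds.dose_gy),
        }
        log.info(
            "%s: RMSE ols %.3f Gy, robust %.3f Gy",
            t,
            result.reconstructions[t]["ols"].rmse,
            result.reconstructions[t]["robust"].rmse,
        )
    return result
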
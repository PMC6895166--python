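"""Standard-curve fitting, structure selection, and dose reconstruction.

The calibration relates the normalized signal S to absorbed dose through
a sparse polynomial,

    Dose = k0 + k1 * S + k2 * S**4

(the default {1, 4} power structure), fitted on training data either by
ordinary least squares or by Huber M-estimation (tuning constant 1.345,
which down-weights gross outliers at 95% Gaussian efficiency). The power
structure itself is chosen among a handful of alternatives by the
small-sample-corrected Akaike criterion. Test-set doses are reconstructed
by evaluating the fitted curve at each sample's S; negative estimates are
reported as-is (the curve can legitimately dip below zero near S = 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import ExpressionDataset

log = logging.getLogger(__name__)

DEFAULT_POWER_SETS: tuple[tuple[int, ...], ...] = ((1,), (1, 2), (1, 3), (1, 4), (1, 2, 4))


def aicc(rss: float, n: int, p_params: int) -> float:
    """Akaike criterion with small-sample correction for a Gaussian fit.

    ``p_params`` counts the regression coefficients; the residual-variance
    parameter is added internally, so with p = p_params + 1:

        AICc = n * ln(rss / n) + 2 p + 2 p (p + 1) / (n - p - 1)
    """
    if rss <= 0:
        raise ValueError("rss must be positive")
    p = p_params + 1
    if n - p - 1 <= 0:
        raise ValueError("n too small for the AICc correction term")
    return float(n * np.log(rss / n) + 2 * p + 2 * p * (p + 1) / (n - p - 1))


def _design(S: np.ndarray, powers: tuple[int, ...]) -> np.ndarray:
    return np.column_stack([np.ones_like(S)] + [S**p for p in powers])


@dataclass
class StandardCurveModel:
    """Fitted calibration curve Dose = k0 + sum_p k_p * S**p."""

    variant: str                      # "ols" | "robust"
    powers: tuple[int, ...]
    params: np.ndarray                # [k0, k_p1, k_p2, ...]
    ses: np.ndarray
    n_train: int
    aicc: float
    rss: float

    def predict(self, S) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return _design(S, self.powers) @ self.params

    def to_record(self) -> dict:
        return {
            "variant": self.variant,
            "powers": list(self.powers),
            "params": [float(v) for v in self.params],
            "ses": [float(v) for v in self.ses],
            "n_train": self.n_train,
            "aicc": self.aicc,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "StandardCurveModel":
        return cls(
            variant=rec["variant"],
            powers=tuple(rec["powers"]),
            params=np.asarray(rec["params"], dtype=float),
            ses=np.asarray(rec["ses"], dtype=float),
            n_train=int(rec["n_train"]),
            aicc=float(rec["aicc"]),
            rss=float(rec.get("rss", np.nan)),
        )


def fit_standard_curve(
    S, dose, powers: tuple[int, ...] = (1, 4), variant: str = "ols"
) -> StandardCurveModel:
    """Fit the calibration polynomial.

    The robust variant runs iteratively reweighted least squares with
    Huber weights (c = 1.345), converging on coefficients to 1e-8 within
    100 iterations. The AICc stored on either variant comes from the
    ordinary fit of the same structure (information criteria are not well
    defined for M-estimators).
    """
    S = np.asarray(S, dtype=float)
    dose = np.asarray(dose, dtype=float)
    powers = tuple(powers)
    if S.size != dose.size:
        raise ValueError("S and dose must have equal length")
    n_par = len(powers) + 1
    if S.size < n_par + 2:
        raise ValueError("too few observations for this structure")
    X = _design(S, powers)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient basis (is S constant?)")

    ols = sm.OLS(dose, X).fit()
    rss = float(np.sum(ols.resid**2))
    crit = aicc(rss, S.size, n_par)
    if variant == "ols":
        return StandardCurveModel(
            "ols", powers, np.asarray(ols.params), np.asarray(ols.bse),
            S.size, crit, rss,
        )
    if variant != "robust":
        raise ValueError(f"unknown variant {variant!r}")
    rlm = sm.RLM(dose, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
        maxiter=100, tol=1e-8, conv="coefs"
    )
    return StandardCurveModel(
        "robust", powers, np.asarray(rlm.params), np.asarray(rlm.bse),
        S.size, crit, float(np.sum(rlm.resid**2)),
    )


def select_model_structure(
    S,
    dose,
    candidate_power_sets: tuple[tuple[int, ...], ...] = DEFAULT_POWER_SETS,
) -> tuple[StandardCurveModel, pd.DataFrame]:
    """Fit each candidate power set by OLS and return the minimum-AICc
    model together with the full AICc table."""
    if len(candidate_power_sets) < 1:
        raise ValueError("need at least one candidate structure")
    rows, fits = [], []
    for powers in candidate_power_sets:
        try:
            model = fit_standard_curve(S, dose, powers=tuple(powers), variant="ols")
        except ValueError as exc:
            log.info("structure %s skipped: %s", powers, exc)
            continue
        fits.append(model)
        rows.append({"powers": tuple(powers), "aicc": model.aicc, "rss": model.rss})
    if not fits:
        raise ValueError("every candidate structure was rank-deficient")
    table = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    best = min(fits, key=lambda m: m.aicc)
    log.info("AICc table:\n%s", table)
    return best, table


def predict_dose(model: StandardCurveModel, S) -> np.ndarray:
    """Evaluate the fitted curve; no clipping (negative estimates pass through)."""
    return model.predict(S)


def evaluate_reconstruction(true_dose, estimated_dose) -> tuple[float, float]:
    """(R^2, RMSE) of estimated vs true dose.

    R^2 = 1 - SSE/SST measures agreement with the 1:1 line, not squared
    correlation; it is NaN (flagged via warning) when true doses are constant.
    """
    t = np.asarray(true_dose, dtype=float)
    e = np.asarray(estimated_dose, dtype=float)
    if t.size != e.size or t.size < 2:
        raise ValueError("need equal-length vectors with >= 2 samples")
    sse = float(np.sum((e - t) ** 2))
    rmse = float(np.sqrt(sse / t.size))
    sst = float(np.sum((t - t.mean()) ** 2))
    if sst == 0:
        log.warning("true doses constant; R^2 undefined")
        return float("nan"), rmse
    return 1.0 - sse / sst, rmse


@dataclass
class DoseReconstruction:
    """Per-sample reconstructed doses with per-true-dose summary and metrics."""

    per_sample: pd.DataFrame          # sample_id, true_dose_gy, estimated_dose_gy
    r2: float
    rmse: float

    @property
    def summary(self) -> pd.DataFrame:
        return summarize_by_dose(self)


def reconstruct_doses(
    model: StandardCurveModel, S: pd.Series, true_dose: pd.Series
) -> DoseReconstruction:
    est = predict_dose(model, S.to_numpy())
    r2, rmse = evaluate_reconstruction(true_dose.to_numpy(), est)
    frame = pd.DataFrame(
        {
            "true_dose_gy": true_dose.to_numpy(dtype=float),
            "estimated_dose_gy": est,
        },
        index=S.index.rename("sample_id"),
    )
    return DoseReconstruction(per_sample=frame, r2=r2, rmse=rmse)


def summarize_by_dose(recon: DoseReconstruction) -> pd.DataFrame:
    """Mean and sample SD of reconstructed dose per distinct true dose
    (SD is NaN for single-member groups)."""
    g = recon.per_sample.groupby("true_dose_gy")["estimated_dose_gy"]
    out = g.agg(n="count", mean="mean", sd=lambda x: x.std(ddof=1))
    return out.reset_index()
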
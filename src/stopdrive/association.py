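"""Standardized-coefficient linear models for parameter-covariate relations.

Each model z-scores the outcome and every predictor (binaries included)
before an ordinary least-squares fit with intercept, so the reported
coefficients are standardized betas.  The model set mirrors the task's
analysis grid: outcomes {mean log K_p, mean log K_d, mean final car
position, log error-trial count}, each regressed on {PANAS-X fear, age,
male gender, bachelor's-or-higher education}, plus demographics-only
variants for the two log gains.  No multiple-testing correction is
applied; the suite reports how many models were fitted.  Missing
covariates are handled by listwise deletion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SubjectCovariates",
    "ModelResult",
    "standardized_linear_model",
    "run_association_suite",
]

DEMOGRAPHICS = ("age", "gender_male", "education_bachelor_plus")
FULL_PREDICTORS = ("fear",) + DEMOGRAPHICS
OUTCOMES = (
    "mean_log_k_p",
    "mean_log_k_d",
    "final_position_mean",
    "log_error_trial_count",
)


@dataclass(frozen=True)
class SubjectCovariates:
    """One subject's self-report and demographic covariates.

    ``fear`` is the PANAS-X Fear subscale score (6 items scored 1-5, so
    the instrument's range is 6-30 unless configured otherwise); binaries
    are 0/1 flags.  ``device_mobile`` and ``same_day_sessions`` are the
    sensitivity-analysis exclusion flags, not regression predictors.
    """

    subject_id: str
    fear: float
    age: float
    gender_male: int
    education_bachelor_plus: int
    device_mobile: int = 1
    same_day_sessions: int = 0
    fear_range: tuple[float, float] = (6.0, 30.0)

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        lo, hi = self.fear_range
        if not (lo <= self.fear <= hi):
            raise ValueError(f"fear {self.fear} outside configured range [{lo}, {hi}]")
        for name in ("gender_male", "education_bachelor_plus", "device_mobile", "same_day_sessions"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1")


@dataclass
class ModelResult:
    """One fitted standardized-beta model.

    ``betas`` and ``p_values`` are keyed by predictor name and come from
    the fit in which every variable (outcome and predictors) was z-scored.
    """

    outcome: str
    predictors: tuple[str, ...]
    betas: dict[str, float]
    p_values: dict[str, float]
    n: int

    def to_rows(self) -> list[dict]:
        return [
            {
                "outcome": self.outcome,
                "predictor": name,
                "beta": self.betas[name],
                "p": self.p_values[name],
                "n": self.n,
                "model": "+".join(self.predictors),
            }
            for name in self.predictors
        ]


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def standardized_linear_model(
    data: pd.DataFrame, outcome: str, predictors: list[str] | tuple[str, ...]
) -> ModelResult:
    """OLS on z-scored variables; coefficients are standardized betas.

    Listwise-deletes rows with any missing value among the outcome and
    predictors, z-scores every column (ddof=1), and fits OLS with an
    intercept.  Requires at least ``len(predictors) + 2`` complete cases
    and nonzero variance in every column.
    """
    predictors = tuple(predictors)
    cols = [outcome, *predictors]
    frame = data[cols].dropna()
    n = len(frame)
    if n < len(predictors) + 2:
        raise ValueError(
            f"need >= {len(predictors) + 2} complete cases for {len(predictors)} "
            f"predictors, got {n}"
        )
    for col in cols:
        if frame[col].std(ddof=1) == 0:
            raise ValueError(f"zero variance in {col!r}")

    y = _zscore(frame[outcome].to_numpy(dtype=float))
    x = np.column_stack([_zscore(frame[p].to_numpy(dtype=float)) for p in predictors])
    design = sm.add_constant(x)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    fit = sm.OLS(y, design).fit()

    return ModelResult(
        outcome=outcome,
        predictors=predictors,
        betas={name: float(b) for name, b in zip(predictors, fit.params[1:])},
        p_values={name: float(p) for name, p in zip(predictors, fit.pvalues[1:])},
        n=n,
    )


def run_association_suite(
    cohort: pd.DataFrame,
    *,
    exclude_same_day: bool = False,
    exclude_non_mobile: bool = False,
) -> list[ModelResult]:
    """Fit the full model grid on a per-session cohort table.

    ``cohort`` holds one row per subject with session summaries
    (``mean_log_k_p``, ``mean_log_k_d``, ``final_position_mean``,
    ``log_error_trial_count``) joined to covariates.  Fits the
    fear + demographics model for all four outcomes, plus
    demographics-only models for the two log gains (6 models total).
    Exclusion flags drop subjects before fitting.
    """
    data = cohort.copy()
    if exclude_same_day:
        data = data[data["same_day_sessions"] == 0]
    if exclude_non_mobile:
        data = data[data["device_mobile"] == 1]
    if data.empty:
        raise ValueError("cohort empty after exclusions")

    results = []
    for outcome in ("mean_log_k_p", "mean_log_k_d"):
        results.append(standardized_linear_model(data, outcome, DEMOGRAPHICS))
    for outcome in OUTCOMES:
        results.append(standardized_linear_model(data, outcome, FULL_PREDICTORS))
    return results


def results_to_frame(results: list[ModelResult]) -> pd.DataFrame:
    """Tidy table: one row per (outcome, predictor) with beta, p, n."""
    rows = [row for res in results for row in res.to_rows()]
    frame = pd.DataFrame(rows)
    frame.attrs["n_models"] = len(results)
    return frame
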
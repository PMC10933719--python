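"""Adjusted associations between discounting scores and momentary outcomes.

Per-person outcome variables are the percentage of completed follow-up
surveys endorsing past-hour use or craving of alcohol, cannabis or tobacco.
Each outcome is regressed (OLS) on the phase-2 baseline log discounting
score, adjusted for age, sex and number of completed surveys, with
continuous predictors mean-centered.  The coefficient on the log score is
reported as an adjusted mean difference in percentage points per unit
log-rate, with a 95% CI and p-value.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from .simulate import OUTCOME_COLUMNS

__all__ = ["endorsement_percentages", "fit_adjusted_models", "DEFAULT_OUTCOMES"]

DEFAULT_OUTCOMES = tuple(f"pct_{c}" for c in OUTCOME_COLUMNS)


def endorsement_percentages(
    followup_surveys: pd.DataFrame,
    *,
    outcome_columns: Sequence[str] = OUTCOME_COLUMNS,
) -> pd.DataFrame:
    """Per-person endorsement percentages over completed surveys.

    ``followup_surveys`` holds one row per *completed* survey with binary
    endorsement columns.  Returns one row per participant with
    ``surveys_completed`` and ``pct_<outcome> = 100 * endorsing / completed``.
    Participants with zero completed surveys simply do not appear.
    """
    g = followup_surveys.groupby("participant_id", sort=True)
    out = g.size().rename("surveys_completed").to_frame()
    for col in outcome_columns:
        out[f"pct_{col}"] = 100.0 * g[col].mean()
    return out.reset_index()


def _design(df: pd.DataFrame, score_col: str) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["log_k_centered"] = df[score_col] - df[score_col].mean()
    X["age_centered"] = df["age"] - df["age"].mean()
    # sex indicator: male = 1, reference level female
    X["sex_male"] = (df["sex"] == "male").astype(float)
    X["surveys_centered"] = df["surveys_completed"] - df["surveys_completed"].mean()
    return X


def fit_adjusted_models(
    outcomes: pd.DataFrame,
    scores: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    *,
    scales: Sequence[str] = ("mcq", "time", "monetary"),
    phase: str = "phase2_baseline",
    outcome_names: Sequence[str] = DEFAULT_OUTCOMES,
    participants: Iterable[str] | None = None,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """One adjusted OLS fit per (predictor scale x outcome).

    Parameters
    ----------
    outcomes:
        Per-participant table with the outcome columns plus
        ``surveys_completed`` (and ``sex``/``age`` unless supplied via
        ``covariates``).
    scores:
        Scale-score table; the ``phase`` baseline ``log_k`` per scale is the
        predictor.
    bh_correction:
        If True, adds a Benjamini-Hochberg adjusted p column (off by
        default; the primary analysis reports unadjusted p-values).

    Returns the regression table: ``predictor_scale, outcome,
    adjusted_mean_difference, ci_low, ci_high, p_value, n``.
    """
    df = outcomes.copy()
    if covariates is not None:
        df = df.merge(covariates, on="participant_id", how="inner")
    for col in ("sex", "age", "surveys_completed"):
        if col not in df:
            raise ValueError(f"missing covariate column: {col}")
    if participants is not None:
        df = df[df["participant_id"].isin(set(participants))]

    rows = []
    for scale in scales:
        sc = scores[
            (scores["scale"] == scale)
            & (scores["phase"] == phase)
            & (scores["occasion"] == 0)
        ][["participant_id", "log_k"]]
        merged = df.merge(sc, on="participant_id", how="inner").dropna(
            subset=["log_k", "sex", "age", "surveys_completed"]
        )
        X = _design(merged, "log_k")
        rank = np.linalg.matrix_rank(X.to_numpy())
        if rank < X.shape[1]:
            corr = X.drop(columns="const").corr().abs()
            np.fill_diagonal(corr.values, 0)
            worst = corr.stack().idxmax()
            raise ValueError(
                f"rank-deficient design for scale {scale!r}; "
                f"most collinear columns: {worst}"
            )
        for outcome in outcome_names:
            y = merged[outcome].to_numpy(dtype=float)
            res = sm.OLS(y, X).fit()
            lo, hi = res.conf_int().loc["log_k_centered"]
            rows.append(
                {
                    "predictor_scale": scale,
                    "outcome": outcome,
                    "adjusted_mean_difference": res.params["log_k_centered"],
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": res.pvalues["log_k_centered"],
                    "n": int(res.nobs),
                }
            )
    table = pd.DataFrame(rows)
    if bh_correction and len(table):
        table["p_bh"] = multipletests(table["p_value"], method="fdr_bh")[1]
    return table
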
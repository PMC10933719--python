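"""Synthetic two-phase EMA study generator.

Emulates a cohort of respondents with latent hyperbolic discounting rates
answering the continuous time- and monetary-selection banks and the binary
MCQ across phase 1, a phase-2 baseline roughly six months later, and 18
momentary follow-up surveys (3/day x 6 days), with per-survey substance
use/craving endorsements linked to the latent rate.

Generative model
----------------
* Per person, latent natural-log rates for the two phases are bivariate
  normal: mean ``mu_log_k``, SD ``sigma_log_k``, correlation ``rho_phases``.
* At each survey, each item sees an independent occasion-level draw
  ``ln k = latent + N(0, tau_scale)``.
* The ideal response follows the hyperbolic model (``D* = (A/V - 1)/k`` for
  time items, ``V* = A/(1 + kD)`` for monetary items); it is clamped to the
  slider bounds and, optionally, rounded to the slider resolution (1 day /
  $1).  MCQ choices are logistic in ``ln k - ln k_indiff``.
* Behavioral contaminants: straightliners answer every slider at its
  minimum or maximum; "outlier" respondents have their latent log-rate
  shifted upward by ``outlier_shift`` log units in both phases.
* Substance endorsement: per completed follow-up survey, each of the six
  binary outcomes is Bernoulli with a logistic link on the standardized
  latent phase-2 log-rate plus a per-person random intercept (captures the
  near-bimodal use percentages seen in general-population EMA samples).

Defaults place the cohort so that the central time items' ideal delays fall
inside the 1–364-day slider while the $99-today item's ideal delay falls
below one day for most respondents (that item's indifference delay is under
a day whenever k > 1/99 per day), mechanically producing the floor-clamping
that makes it uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import expit

from .hyperbolic import hyperbolic_value
from .items import (
    DiscountingItem,
    ItemBank,
    ItemKind,
    mcq_bank,
    monetary_selection_bank,
    time_selection_bank,
)
from .mcq import CHOICE_DELAYED, CHOICE_IMMEDIATE, indifference_k

__all__ = [
    "Behavior",
    "RespondentProfile",
    "StudyConfig",
    "SimulatedStudy",
    "clean_config",
    "contaminated_config",
    "null_config",
    "calibration_config",
    "ideal_response",
    "simulate_response",
    "simulate_study",
    "simulate_linear_outcomes",
]

PHASE1 = "phase1"
PHASE2_BASELINE = "phase2_baseline"
PHASE2_FOLLOWUP = "phase2_followup"

SUBSTANCES = ("alcohol", "cannabis", "tobacco")
OUTCOME_COLUMNS = tuple(
    f"{kind}_{s}" for kind in ("use", "crave") for s in SUBSTANCES
)


class Behavior(str, Enum):
    NORMAL = "normal"
    STRAIGHTLINE_MIN = "straightline_min"
    STRAIGHTLINE_MAX = "straightline_max"
    SD_OUTLIER = "sd_outlier"


@dataclass(frozen=True)
class RespondentProfile:
    """One simulated agent's latent parameters."""

    participant_id: str
    latent_log_k_phase1: float
    latent_log_k_phase2: float
    behavior: Behavior = Behavior.NORMAL
    tau_time: float = 0.3
    tau_money: float = 0.55
    mcq_choice_scale: float = 0.6
    compliance: float = 1.0


@dataclass(frozen=True)
class StudyConfig:
    """Full description of a synthetic study; the seed fixes everything."""

    n_participants: int = 97
    n_followups: int = 18  # 3 surveys/day x 6 days; +1 baseline = 19 total
    seed: int = 0

    # latent trait distribution (natural-log rate per day)
    mu_log_k: float = -3.0
    sigma_log_k: float = 1.0
    rho_phases: float = 0.75

    # occasion-level instrument noise SDs on the log-rate scale
    tau_time: float = 0.3
    tau_money: float = 0.55
    mcq_choice_scale: float = 0.6

    # slider mechanics
    round_responses: bool = True
    min_delay_days: float = 1.0

    # contamination
    n_straightline_min: int = 0
    n_straightline_max: int = 0
    n_sd_outliers: int = 0
    outlier_shift: float = 2.2  # log units added to contaminants' latent rate

    # follow-up compliance: P(completing each follow-up survey); the default
    # yields ~16 of 19 surveys completed on average
    compliance: float = 15.0 / 18.0

    # substance endorsement: logit(p) = intercept + slope * z + u_person,
    # z the standardized latent phase-2 log-rate, u ~ N(0, person_sd^2)
    endorse_intercepts: dict = field(
        default_factory=lambda: {
            "use_alcohol": -4.4, "use_cannabis": -4.6, "use_tobacco": -4.8,
            "crave_alcohol": -3.9, "crave_cannabis": -4.0, "crave_tobacco": -4.2,
        }
    )
    endorse_slopes: dict = field(
        default_factory=lambda: {
            "use_alcohol": 0.3, "use_cannabis": 0.3, "use_tobacco": 1.2,
            "crave_alcohol": 0.3, "crave_cannabis": 0.3, "crave_tobacco": 1.2,
        }
    )
    endorse_person_sd: float = 2.0

    # item banks (None -> package defaults)
    time_bank: ItemBank | None = None
    monetary_bank: ItemBank | None = None
    mcq_bank: ItemBank | None = None
    include_mcq: bool = True
    include_followups: bool = True

    def banks(self) -> dict[str, ItemBank]:
        banks = {
            "time": self.time_bank or time_selection_bank(),
            "monetary": self.monetary_bank or monetary_selection_bank(),
        }
        if self.include_mcq:
            banks["mcq"] = self.mcq_bank or mcq_bank()
        return banks


def clean_config(**overrides) -> StudyConfig:
    """Default cohort: no planted contamination."""
    return replace(StudyConfig(), **overrides)


def contaminated_config(**overrides) -> StudyConfig:
    """Cohort with planted invalid responders and score outliers.

    A deliberately narrow trait distribution keeps the clean scores tight so
    the planted contaminants sit far (>5 clean SDs) outside it: 2 minimum-
    and 1 maximum-straightliners plus 5 latent-shifted outlier respondents.
    """
    base = StudyConfig(
        sigma_log_k=0.2,
        tau_time=0.15,
        tau_money=0.15,
        rho_phases=0.9,
        n_straightline_min=2,
        n_straightline_max=1,
        n_sd_outliers=5,
        outlier_shift=2.2,
    )
    return replace(base, **overrides)


def null_config(**overrides) -> StudyConfig:
    """Cohort with no discounting-substance association (all slopes zero)."""
    base = StudyConfig(
        endorse_slopes={k: 0.0 for k in OUTCOME_COLUMNS},
    )
    return replace(base, **overrides)


def calibration_config(**overrides) -> StudyConfig:
    """Narrow, clamp-free cohort for parameter-recovery checks.

    Uses the six informative time items (the $99 item's ideal delay is below
    one day for any rate that keeps the $10 item on-slider, so no rate keeps
    all seven unclamped) and a trait range whose ideal responses stay
    strictly inside both sliders; slider rounding is disabled so noiseless
    scoring is exact.
    """
    six_item_time = time_selection_bank().subset(
        [i for i in time_selection_bank().item_ids if i != "time_99"]
    )
    base = StudyConfig(
        n_participants=500,
        n_followups=0,
        include_followups=False,
        mu_log_k=-2.5,
        sigma_log_k=0.25,
        tau_time=0.3,
        tau_money=0.3,
        rho_phases=0.75,
        round_responses=False,
        time_bank=six_item_time,
    )
    return replace(base, **overrides)


# ---------------------------------------------------------------------------
# Response generation
# ---------------------------------------------------------------------------

def ideal_response(item: DiscountingItem, k: float) -> float:
    """Noise-free, unclamped response implied by rate ``k`` (per day)."""
    if item.kind is ItemKind.TIME_SELECTION:
        return item.reward_ratio / k
    if item.kind is ItemKind.MONETARY_SELECTION:
        return hyperbolic_value(item.A, k, item.D)
    raise ValueError("MCQ items have no continuous ideal response")


def _finalize(item: DiscountingItem, raw: float, *, rnd: bool, lo: float) -> float:
    value = min(max(raw, lo), item.response_max)
    return round(value) if rnd else value


def simulate_response(
    profile: RespondentProfile,
    item: DiscountingItem,
    occasion: int,
    rng: np.random.Generator,
    *,
    phase: str = PHASE1,
    round_responses: bool = True,
    min_delay_days: float = 1.0,
) -> float:
    """Draw one response value for one (agent, item, occasion).

    Continuous responses are the ideal hyperbolic response at an
    occasion-level noisy log-rate, clamped to the slider and rounded to its
    resolution; straightliner agents pin every slider to one end.  MCQ
    choices are logistic in ``ln k - ln k_indiff``.
    """
    del occasion  # occasions are exchangeable; noise is drawn fresh each call
    latent = (
        profile.latent_log_k_phase1 if phase == PHASE1 else profile.latent_log_k_phase2
    )
    if item.kind is ItemKind.MCQ_BINARY:
        log_k = latent
        p_imm = expit((log_k - np.log(indifference_k(item))) / profile.mcq_choice_scale)
        return CHOICE_IMMEDIATE if rng.random() < p_imm else CHOICE_DELAYED

    lo = (
        max(item.response_min, min_delay_days)
        if item.kind is ItemKind.TIME_SELECTION
        else item.response_min
    )
    if profile.behavior is Behavior.STRAIGHTLINE_MIN:
        return _finalize(item, lo, rnd=round_responses, lo=lo)
    if profile.behavior is Behavior.STRAIGHTLINE_MAX:
        return _finalize(item, item.response_max, rnd=round_responses, lo=lo)

    tau = (
        profile.tau_time
        if item.kind is ItemKind.TIME_SELECTION
        else profile.tau_money
    )
    log_k = latent + rng.normal(0.0, tau)
    return _finalize(item, ideal_response(item, np.exp(log_k)),
                     rnd=round_responses, lo=lo)


def _continuous_block(
    cfg: StudyConfig,
    bank: ItemBank,
    latent: np.ndarray,
    behavior: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized (n_participants x n_items) response matrix for one occasion."""
    n = latent.shape[0]
    m = len(bank)
    tau = cfg.tau_time if bank.kind is ItemKind.TIME_SELECTION else cfg.tau_money
    log_k = latent[:, None] + rng.normal(0.0, tau, size=(n, m))
    k = np.exp(log_k)
    out = np.empty((n, m))
    for j, item in enumerate(bank):
        if bank.kind is ItemKind.TIME_SELECTION:
            raw = item.reward_ratio / k[:, j]
            lo = max(item.response_min, cfg.min_delay_days)
        else:
            raw = item.A / (1.0 + k[:, j] * item.D)
            lo = item.response_min
        col = np.clip(raw, lo, item.response_max)
        col[behavior == Behavior.STRAIGHTLINE_MIN.value] = lo
        col[behavior == Behavior.STRAIGHTLINE_MAX.value] = item.response_max
        out[:, j] = np.round(col) if cfg.round_responses else col
    return out


def _mcq_block(
    cfg: StudyConfig,
    bank: ItemBank,
    latent: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    n = latent.shape[0]
    ln_ki = np.array([np.log(indifference_k(it)) for it in bank])
    p_imm = expit((latent[:, None] - ln_ki[None, :]) / cfg.mcq_choice_scale)
    u = rng.random(size=(n, len(bank)))
    return np.where(u < p_imm, CHOICE_IMMEDIATE, CHOICE_DELAYED)


@dataclass
class SimulatedStudy:
    """Container for one simulated study's tables."""

    responses: pd.DataFrame  # long format: participant, phase, occasion, item, value
    covariates: pd.DataFrame  # participant_id, sex, age
    followup_surveys: pd.DataFrame  # completed surveys with binary endorsements
    truth: pd.DataFrame  # latent log-rates and behavior per participant
    config: StudyConfig


def simulate_study(config: StudyConfig, seed: int | None = None) -> SimulatedStudy:
    """Generate a full reproducible study from a config (and optional seed)."""
    cfg = config if seed is None else replace(config, seed=seed)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants
    n_contam = cfg.n_straightline_min + cfg.n_straightline_max + cfg.n_sd_outliers
    if n_contam > n:
        raise ValueError("more planted contaminants than participants")

    width = max(3, len(str(n)))
    pids = np.array([f"p{i + 1:0{width}d}" for i in range(n)])

    behavior = np.array([Behavior.NORMAL.value] * n, dtype=object)
    contam_idx = rng.choice(n, size=n_contam, replace=False)
    i0 = 0
    for count, lab in (
        (cfg.n_straightline_min, Behavior.STRAIGHTLINE_MIN.value),
        (cfg.n_straightline_max, Behavior.STRAIGHTLINE_MAX.value),
        (cfg.n_sd_outliers, Behavior.SD_OUTLIER.value),
    ):
        behavior[contam_idx[i0:i0 + count]] = lab
        i0 += count

    cov = np.array(
        [[cfg.sigma_log_k**2, cfg.rho_phases * cfg.sigma_log_k**2],
         [cfg.rho_phases * cfg.sigma_log_k**2, cfg.sigma_log_k**2]]
    )
    latent = rng.multivariate_normal([cfg.mu_log_k, cfg.mu_log_k], cov, size=n)
    # contaminants are planted at a fixed latent rate (not drawn), so their
    # separation from the clean cohort is exactly outlier_shift in both phases
    latent[behavior == Behavior.SD_OUTLIER.value] = cfg.mu_log_k + cfg.outlier_shift

    # demographics loosely matching a social-media convenience sample
    sex = np.where(rng.random(n) < 0.74, "female", "male")
    bins = [(18, 25), (26, 35), (36, 50), (51, 70), (71, 75)]
    bin_idx = rng.choice(len(bins), size=n, p=[0.29, 0.26, 0.27, 0.16, 0.02])
    age = np.array([rng.integers(lo, hi + 1) for lo, hi in (bins[i] for i in bin_idx)])

    banks = cfg.banks()
    frames = []

    def emit(bank: ItemBank, values: np.ndarray, phase: str, occasion: int,
             mask: np.ndarray | None = None) -> None:
        sel = np.ones(n, dtype=bool) if mask is None else mask
        if not sel.any():
            return
        idx = np.where(sel)[0]
        frames.append(
            pd.DataFrame(
                {
                    "participant_id": np.repeat(pids[idx], len(bank)),
                    "phase": phase,
                    "occasion": occasion,
                    "item_id": np.tile(np.array(bank.item_ids, dtype=object), len(idx)),
                    "value": values[idx].ravel(),
                }
            )
        )

    # phase 1 and phase 2 baseline: both continuous banks (+ MCQ)
    for phase, col in ((PHASE1, 0), (PHASE2_BASELINE, 1)):
        for name in ("time", "monetary"):
            vals = _continuous_block(cfg, banks[name], latent[:, col], behavior, rng)
            emit(banks[name], vals, phase, 0)
        if cfg.include_mcq:
            vals = _mcq_block(cfg, banks["mcq"], latent[:, col], rng)
            emit(banks["mcq"], vals, phase, 0)

    # phase 2 follow-ups: continuous banks only, with Bernoulli compliance
    outcome_rows = []
    if cfg.include_followups and cfg.n_followups > 0:
        z = (latent[:, 1] - cfg.mu_log_k) / cfg.sigma_log_k
        person_logit = {
            out: cfg.endorse_intercepts[out]
            + cfg.endorse_slopes[out] * z
            + rng.normal(0.0, cfg.endorse_person_sd, size=n)
            for out in OUTCOME_COLUMNS
        }
        for occ in range(1, cfg.n_followups + 1):
            completed = rng.random(n) < cfg.compliance
            for name in ("time", "monetary"):
                vals = _continuous_block(cfg, banks[name], latent[:, 1], behavior, rng)
                emit(banks[name], vals, PHASE2_FOLLOWUP, occ, mask=completed)
            row = {"participant_id": pids[completed], "occasion": occ}
            for out in OUTCOME_COLUMNS:
                p = expit(person_logit[out][completed])
                row[out] = (rng.random(completed.sum()) < p).astype(int)
            outcome_rows.append(pd.DataFrame(row))

    responses = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["participant_id", "phase", "occasion",
                                   "item_id", "value"])
    )
    followups = (
        pd.concat(outcome_rows, ignore_index=True)
        if outcome_rows
        else pd.DataFrame(columns=["participant_id", "occasion", *OUTCOME_COLUMNS])
    )
    covariates = pd.DataFrame({"participant_id": pids, "sex": sex, "age": age})
    truth = pd.DataFrame(
        {
            "participant_id": pids,
            "behavior": behavior,
            "latent_log_k_phase1": latent[:, 0],
            "latent_log_k_phase2": latent[:, 1],
        }
    )
    return SimulatedStudy(responses, covariates, followups, truth, cfg)


def simulate_linear_outcomes(
    scores: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    scale: str = "time",
    phase: str = PHASE2_BASELINE,
    beta_log_k: float = 4.0,
    beta_age: float = 0.05,
    beta_sex_male: float = 1.0,
    beta_surveys: float = 0.1,
    intercept: float = 50.0,
    noise_sd: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Outcome table generated from an exactly linear model.

    Used for regression-recovery checks: the continuous percentage outcome
    is ``intercept + beta_log_k * centered log_k + covariate effects +
    N(0, noise_sd)`` with no clipping, so the adjusted-model coefficient has
    a known truth.  Returns one outcome column ``pct_outcome``.
    """
    rng = np.random.default_rng(seed)
    sub = scores[(scores["scale"] == scale) & (scores["phase"] == phase)]
    df = sub.merge(covariates, on="participant_id")
    if "surveys_completed" not in df:
        # 1 baseline + Binomial follow-ups, matching the EMA compliance model
        df["surveys_completed"] = 1 + rng.binomial(18, 15.0 / 18.0, size=len(df))
    y = (
        intercept
        + beta_log_k * (df["log_k"] - df["log_k"].mean())
        + beta_age * (df["age"] - df["age"].mean())
        + beta_sex_male * (df["sex"] == "male").astype(float)
        + beta_surveys * (df["surveys_completed"] - df["surveys_completed"].mean())
        + rng.normal(0.0, noise_sd, size=len(df))
    )
    out = df[["participant_id", "sex", "age", "surveys_completed"]].copy()
    out["pct_outcome"] = y
    return out
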
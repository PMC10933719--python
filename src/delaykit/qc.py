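"""Participant-level quality control.

Two exclusion rules, applied in order per phase and scale:

1. **Straightlining** — a respondent whose every continuous response in a
   phase sits at the slider minimum (or every one at the maximum) carries no
   rate information and is flagged invalid.
2. **3-SD outliers** — after straightliners are removed, log scale scores
   are standardized within each phase x scale group and respondents beyond
   ``threshold`` SDs of the mean are flagged, in a single pass (no
   iterative re-standardization).

The analytic sample is the set of participants retained in *every* screened
phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .items import ItemBank, ItemKind

__all__ = [
    "QcFlag",
    "QcResult",
    "flag_straightliners",
    "flag_sd_outliers",
    "build_analytic_sample",
    "run_qc",
]

BASELINE_PHASES = ("phase1", "phase2_baseline")


class QcFlag(str, Enum):
    STRAIGHTLINE_MIN = "straightline_min"
    STRAIGHTLINE_MAX = "straightline_max"
    SD_OUTLIER = "sd_outlier"
    CLAMPED_RESPONSE = "clamped_response"
    RETAINED = "retained"


DECISION_COLUMNS = ["participant_id", "phase", "scale", "flag", "z_score"]


def _empty_decisions() -> pd.DataFrame:
    return pd.DataFrame(columns=DECISION_COLUMNS)


def flag_straightliners(
    responses: pd.DataFrame,
    bank: ItemBank,
    *,
    min_delay_days: float = 1.0,
    phases: tuple[str, ...] = BASELINE_PHASES,
) -> pd.DataFrame:
    """Flag respondents answering every item of a phase at one slider end.

    The effective minimum for time-selection items is the deployed slider
    floor (``min_delay_days``), since responses below it are
    indistinguishable after clamping.
    """
    if bank.kind is ItemKind.MCQ_BINARY:
        raise ValueError("straightlining is defined for continuous banks only")
    lows = {
        it.item_id: (
            max(it.response_min, min_delay_days)
            if bank.kind is ItemKind.TIME_SELECTION
            else it.response_min
        )
        for it in bank
    }
    highs = {it.item_id: it.response_max for it in bank}
    sub = responses[
        responses["item_id"].isin(bank.item_ids) & responses["phase"].isin(phases)
    ]
    rows = []
    for (pid, phase), grp in sub.groupby(["participant_id", "phase"], sort=True):
        if grp.empty:  # pragma: no cover - groupby never yields empty groups
            continue
        lo = grp["item_id"].map(lows).to_numpy()
        hi = grp["item_id"].map(highs).to_numpy()
        vals = grp["value"].to_numpy(dtype=float)
        flag = None
        if np.all(vals <= lo):
            flag = QcFlag.STRAIGHTLINE_MIN
        elif np.all(vals >= hi):
            flag = QcFlag.STRAIGHTLINE_MAX
        if flag is not None:
            rows.append(
                {"participant_id": pid, "phase": phase, "scale": bank.scale,
                 "flag": flag.value, "z_score": np.nan}
            )
    return pd.DataFrame(rows, columns=DECISION_COLUMNS) if rows else _empty_decisions()


def flag_sd_outliers(
    scores: pd.DataFrame,
    *,
    threshold: float = 3.0,
    on: str = "log_k",
) -> pd.DataFrame:
    """Flag scores beyond ``threshold`` SDs of their phase x scale mean.

    ``scores`` is one phase x scale group of scale scores (occasion 0);
    standardization uses the group's own mean and SD in one pass.  ``on``
    selects the standardized column: ``"log_k"`` (default; rates are
    log-normal, so the rule operates on the log scale) or ``"k_geomean"``.
    """
    if on not in ("log_k", "k_geomean"):
        raise ValueError(f"unknown standardization column: {on!r}")
    rows = []
    for (phase, scale), grp in scores.groupby(["phase", "scale"], sort=True):
        if len(grp) < 3:
            raise ValueError(
                f"need at least 3 estimates to screen outliers in {phase}/{scale}"
            )
        x = grp[on].to_numpy(dtype=float)
        sd = x.std(ddof=1)
        if sd == 0:
            warnings.warn(
                f"zero variance in {phase}/{scale}; no outliers flagged",
                stacklevel=2,
            )
            continue
        z = (x - x.mean()) / sd
        for pid, zi in zip(grp["participant_id"], z):
            if abs(zi) > threshold:
                rows.append(
                    {"participant_id": pid, "phase": phase, "scale": scale,
                     "flag": QcFlag.SD_OUTLIER.value, "z_score": zi}
                )
    return pd.DataFrame(rows, columns=DECISION_COLUMNS) if rows else _empty_decisions()


def build_analytic_sample(
    retained_by_phase: dict[str, set[str]],
) -> set[str]:
    """Participants retained in every screened phase (set intersection)."""
    sets = list(retained_by_phase.values())
    if not sets:
        return set()
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return out


@dataclass
class QcResult:
    """Outcome of the full exclusion pipeline."""

    decisions: pd.DataFrame  # non-retained flags (one row per flag raised)
    retained_by_phase: dict[str, set[str]]
    analytic_sample: list[str]  # sorted retained participant ids
    all_participants: list[str]

    @property
    def excluded(self) -> list[str]:
        return sorted(set(self.all_participants) - set(self.analytic_sample))

    def summary(self) -> str:
        """Flowchart-style text summary of exclusion counts per phase."""
        lines = [f"Participants screened: {len(self.all_participants)}"]
        for phase in sorted(self.retained_by_phase):
            sub = self.decisions[self.decisions["phase"] == phase]
            n_excl = len(set(self.all_participants) - self.retained_by_phase[phase])
            lines.append(f"{phase}: {n_excl} participant(s) excluded")
            for (scale, flag), grp in sub.groupby(["scale", "flag"], sort=True):
                lines.append(
                    f"  {scale} / {flag}: {grp['participant_id'].nunique()}"
                )
        lines.append(
            f"Analytic sample (valid in all phases): {len(self.analytic_sample)}"
        )
        return "\n".join(lines)


def run_qc(
    responses: pd.DataFrame,
    banks: dict[str, ItemBank],
    scores: pd.DataFrame,
    *,
    threshold: float = 3.0,
    on: str = "log_k",
    min_delay_days: float = 1.0,
    phases: tuple[str, ...] = BASELINE_PHASES,
    scales: tuple[str, ...] = ("time", "monetary"),
) -> QcResult:
    """Run the two-stage exclusion pipeline on baseline data.

    Straightliner flags are raised first; the SD-outlier pass then
    standardizes each phase x scale score distribution with straightliners
    already removed, mirroring the narrative order of the screening.
    """
    all_pids = sorted(responses["participant_id"].unique())
    straight_frames = [
        flag_straightliners(
            responses, banks[s], min_delay_days=min_delay_days, phases=phases
        )
        for s in scales
        if banks[s].kind is not ItemKind.MCQ_BINARY
    ]
    straight = (
        pd.concat(straight_frames, ignore_index=True)
        if straight_frames
        else _empty_decisions()
    )

    base = scores[
        scores["phase"].isin(phases)
        & scores["scale"].isin(scales)
        & (scores["occasion"] == 0)
    ]
    frames = [straight]
    for phase in phases:
        bad = set(straight.loc[straight["phase"] == phase, "participant_id"])
        grp = base[(base["phase"] == phase) & ~base["participant_id"].isin(bad)]
        if len(grp):
            frames.append(flag_sd_outliers(grp, threshold=threshold, on=on))
    frames = [f for f in frames if len(f)]
    decisions = (
        pd.concat(frames, ignore_index=True) if frames else _empty_decisions()
    )

    retained_by_phase = {}
    for phase in phases:
        flagged = set(decisions.loc[decisions["phase"] == phase, "participant_id"])
        retained_by_phase[phase] = set(all_pids) - flagged
    analytic = sorted(build_analytic_sample(retained_by_phase))
    return QcResult(decisions, retained_by_phase, analytic, all_pids)
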
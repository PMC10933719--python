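"""Monetary Choice Questionnaire (MCQ) scoring.

Each binary item offers $V today versus $A after D days.  Under the
hyperbolic model the two options are equally valued at the item's
indifference rate ``k_indiff = (A - V) / (V * D)``: a respondent with
personal rate above it should take the immediate option, below it the
delayed one.

The per-person score is the Kirby-style consistency-maximizing rate: the
items partition the positive axis into intervals at their sorted
indifference rates; one candidate rate is placed in each interval (the
geometric mean of its endpoints, with half / double the extreme rates used
as outer endpoints) and the candidate predicting the largest number of the
observed choices is returned.  Ties are broken by the geometric mean of all
maximizing candidates.

Response coding: 0 = chose the immediate option, 1 = chose the delayed one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .hyperbolic import DomainError
from .items import DiscountingItem, ItemBank, ItemKind

__all__ = [
    "CHOICE_IMMEDIATE",
    "CHOICE_DELAYED",
    "indifference_k",
    "candidate_rates",
    "consistency_count",
    "score_mcq",
    "score_mcq_table",
]

CHOICE_IMMEDIATE = 0.0
CHOICE_DELAYED = 1.0


def indifference_k(item: DiscountingItem) -> float:
    """Rate at which $V now and $A in D days are equally valued."""
    if item.kind is not ItemKind.MCQ_BINARY:
        raise DomainError(f"{item.item_id}: not an MCQ item")
    return item.k_indiff


def _sorted_k_indiff(bank: ItemBank) -> np.ndarray:
    ks = np.array([indifference_k(it) for it in bank])
    ks_sorted = np.sort(ks)
    if np.any(np.diff(ks_sorted) == 0):
        raise ValueError("MCQ bank has tied indifference rates")
    return ks_sorted


def candidate_rates(bank: ItemBank) -> np.ndarray:
    """One candidate rate per interval between sorted indifference rates.

    With m items there are m + 1 candidates: geometric means of adjacent
    indifference rates, plus ``geomean(k_min/2, k_min)`` below the smallest
    and ``geomean(k_max, 2 k_max)`` above the largest.
    """
    ks = _sorted_k_indiff(bank)
    edges = np.concatenate(([ks[0] / 2.0], ks, [ks[-1] * 2.0]))
    return np.sqrt(edges[:-1] * edges[1:])


def consistency_count(bank: ItemBank, choices: dict[str, float], k: float) -> int:
    """Number of observed choices a candidate rate ``k`` predicts correctly."""
    n = 0
    for it in bank:
        predicted = CHOICE_IMMEDIATE if k > indifference_k(it) else CHOICE_DELAYED
        if predicted == float(choices[it.item_id]):
            n += 1
    return n


def score_mcq(choices: dict[str, float], bank: ItemBank) -> dict:
    """Score one person's full MCQ response pattern.

    Parameters
    ----------
    choices:
        Mapping item_id -> choice (0 immediate, 1 delayed), covering every
        item of the bank exactly.

    Returns
    -------
    dict with keys ``k_geomean`` (the consistency-maximizing rate),
    ``log_k``, ``consistency`` (count of correctly predicted choices) and
    ``n_items_used``.
    """
    missing = [it.item_id for it in bank if it.item_id not in choices]
    if missing:
        raise ValueError(f"missing MCQ responses for items: {missing}")
    bad = {
        i: v for i, v in choices.items()
        if i in bank and float(v) not in (CHOICE_IMMEDIATE, CHOICE_DELAYED)
    }
    if bad:
        raise ValueError(f"non-binary MCQ responses: {bad}")

    cands = candidate_rates(bank)
    counts = np.array([consistency_count(bank, choices, c) for c in cands])
    best = counts.max()
    winners = cands[counts == best]
    k = float(np.exp(np.mean(np.log(winners))))
    return {
        "k_geomean": k,
        "log_k": float(np.log(k)),
        "consistency": int(best),
        "n_items_used": len(bank),
    }


def score_mcq_table(responses: pd.DataFrame, bank: ItemBank) -> pd.DataFrame:
    """Score MCQ responses in long format into per-occasion estimates.

    ``responses`` needs columns ``participant_id, phase, occasion, item_id,
    value`` and is filtered to the bank's items.  Returns one row per
    (participant, phase, occasion) with scale ``"mcq"``.
    """
    sub = responses[responses["item_id"].isin(bank.item_ids)]
    rows = []
    for (pid, phase, occ), grp in sub.groupby(
        ["participant_id", "phase", "occasion"], sort=True
    ):
        dup = grp["item_id"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate MCQ responses for {pid}/{phase}/{occ}: "
                f"{sorted(grp.loc[dup, 'item_id'])}"
            )
        est = score_mcq(dict(zip(grp["item_id"], grp["value"])), bank)
        rows.append(
            {
                "participant_id": pid,
                "phase": phase,
                "occasion": occ,
                "scale": bank.scale,
                "k_geomean": est["k_geomean"],
                "log_k": est["log_k"],
                "n_items": est["n_items_used"],
                "n_clamped": 0,
                "consistency": est["consistency"],
            }
        )
    return pd.DataFrame(rows)
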
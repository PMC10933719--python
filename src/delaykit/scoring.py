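"""Score long-format response tables into per-item rates and scale scores."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import mcq as _mcq
from .hyperbolic import invert_k_from_money, invert_k_from_time
from .items import ItemBank, ItemKind

__all__ = ["item_k_table", "scale_scores", "score_study", "DEFAULT_MIN_DELAY_DAYS"]

#: deployed floor of the delay slider: a willingness-to-wait of less than one
#: day is clamped up to one day before inversion (and flagged)
DEFAULT_MIN_DELAY_DAYS = 1.0

RESPONSE_COLUMNS = ["participant_id", "phase", "occasion", "item_id", "value"]


def item_k_table(
    responses: pd.DataFrame,
    bank: ItemBank,
    *,
    min_delay_days: float = DEFAULT_MIN_DELAY_DAYS,
) -> pd.DataFrame:
    """Per-item discounting rates for one continuous bank.

    Returns a tidy frame with columns ``participant_id, phase, occasion,
    scale, item_id, k, log_k, clamped``; ``clamped`` marks time-selection
    responses lifted to the ``min_delay_days`` floor before inversion.
    """
    if bank.kind is ItemKind.MCQ_BINARY:
        raise ValueError("item_k_table handles continuous banks only")
    sub = responses[responses["item_id"].isin(bank.item_ids)].copy()
    ks = np.empty(len(sub))
    clamped = np.zeros(len(sub), dtype=bool)
    for item in bank:
        m = (sub["item_id"] == item.item_id).to_numpy()
        if not m.any():
            continue
        vals = sub.loc[m, "value"].to_numpy(dtype=float)
        if bank.kind is ItemKind.TIME_SELECTION:
            ks[m] = invert_k_from_time(item, vals, min_delay_days=min_delay_days)
            clamped[m] = vals < min_delay_days
        else:
            ks[m] = invert_k_from_money(item, vals)
    sub["scale"] = bank.scale
    sub["k"] = ks
    sub["log_k"] = np.log(ks)
    sub["clamped"] = clamped
    return sub[
        ["participant_id", "phase", "occasion", "scale", "item_id", "k", "log_k", "clamped"]
    ].reset_index(drop=True)


def scale_scores(item_k: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-item rates to geometric-mean scale scores.

    One row per (participant, phase, occasion, scale) with ``k_geomean``
    (= exp(mean(log k)) over that occasion's items), ``log_k``, ``n_items``
    and ``n_clamped``.
    """
    g = item_k.groupby(["participant_id", "phase", "occasion", "scale"], sort=True)
    out = g.agg(
        log_k=("log_k", "mean"),
        n_items=("k", "size"),
        n_clamped=("clamped", "sum"),
    ).reset_index()
    out["k_geomean"] = np.exp(out["log_k"])
    out["n_clamped"] = out["n_clamped"].astype(int)
    return out[
        ["participant_id", "phase", "occasion", "scale",
         "k_geomean", "log_k", "n_items", "n_clamped"]
    ]


def score_study(
    responses: pd.DataFrame,
    banks: dict[str, ItemBank],
    *,
    min_delay_days: float = DEFAULT_MIN_DELAY_DAYS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a full study across all banks.

    Returns ``(item_k, scores)``: per-item rates for the continuous banks,
    and scale scores for every bank (MCQ occasions scored by consistency
    maximization and appended to ``scores`` with ``n_items``/``n_clamped``).
    """
    item_frames = []
    score_frames = []
    for bank in banks.values():
        if bank.kind is ItemKind.MCQ_BINARY:
            tab = _mcq.score_mcq_table(responses, bank)
            if len(tab):
                score_frames.append(tab.drop(columns=["consistency"]))
        else:
            ik = item_k_table(responses, bank, min_delay_days=min_delay_days)
            if len(ik):
                item_frames.append(ik)
                score_frames.append(scale_scores(ik))
    item_k = (
        pd.concat(item_frames, ignore_index=True)
        if item_frames
        else pd.DataFrame(
            columns=["participant_id", "phase", "occasion", "scale",
                     "item_id", "k", "log_k", "clamped"]
        )
    )
    scores = (
        pd.concat(score_frames, ignore_index=True)
        if score_frames
        else pd.DataFrame(
            columns=["participant_id", "phase", "occasion", "scale",
                     "k_geomean", "log_k", "n_items", "n_clamped"]
        )
    )
    scores = scores.sort_values(
        ["scale", "phase", "occasion", "participant_id"]
    ).reset_index(drop=True)
    return item_k, scores
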
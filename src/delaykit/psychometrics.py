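"""Psychometric evaluation of the discounting scales.

Four analyses, all on log-transformed rates within the analytic sample:

* **item-total correlations** — Pearson r between each item's log rate and
  the full scale's log geometric-mean rate; items below a cutoff are marked
  uninformative.
* **test-retest reliability** — Pearson r of the scale score across the two
  baseline occasions.
* **convergent validity** — the full correlation matrix among all
  scale x phase scores (novel scales vs the MCQ comparator).
* **scale abbreviation** — for each subset size N, the distribution over
  random item subsets of the correlation between the subset score and the
  full-scale score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CorrelationResult",
    "item_total_correlations",
    "test_retest",
    "convergent_validity",
    "abbreviation_analysis",
    "abbreviation_summary",
]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    if len(x) < 3:
        raise ValueError(f"need at least 3 paired observations, got {len(x)}")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


def _baseline(df: pd.DataFrame, scale: str, phase: str) -> pd.DataFrame:
    return df[(df["scale"] == scale) & (df["phase"] == phase) & (df["occasion"] == 0)]


def item_total_correlations(
    item_k: pd.DataFrame,
    scale: str,
    phase: str,
    *,
    participants: Iterable[str] | None = None,
    cutoff: float = 0.5,
    include_item: bool = True,
    min_delay_days: float | None = None,
) -> pd.DataFrame:
    """Pearson r between each item's log rate and the scale's log score.

    The total is the log geometric mean over all items, including the item
    itself by default (``include_item=False`` recomputes the total without
    it, the corrected variant).  Items whose log rate has zero variance
    (e.g. fully clamped at a slider bound) get ``r = NaN`` and an
    ``undefined`` flag.

    Returns a frame with columns ``item_id, r, p, n, informative,
    undefined``.
    """
    del min_delay_days  # clamping already folded into item_k
    sub = _baseline(item_k, scale, phase)
    if participants is not None:
        sub = sub[sub["participant_id"].isin(set(participants))]
    wide = sub.pivot(index="participant_id", columns="item_id", values="log_k")
    if wide.isna().any().any():
        wide = wide.dropna()
    total = wide.mean(axis=1)
    rows = []
    for item_id in wide.columns:
        x = wide[item_id].to_numpy()
        if include_item:
            t = total.to_numpy()
        else:
            others = wide.drop(columns=item_id)
            t = others.mean(axis=1).to_numpy()
        if np.all(x == x[0]) or np.all(t == t[0]):
            rows.append(
                {"item_id": item_id, "r": np.nan, "p": np.nan, "n": len(x),
                 "informative": False, "undefined": True}
            )
            continue
        res = _pearson(x, t)
        rows.append(
            {"item_id": item_id, "r": res.r, "p": res.p, "n": res.n,
             "informative": bool(res.r >= cutoff), "undefined": False}
        )
    return pd.DataFrame(rows)


def test_retest(
    scores: pd.DataFrame,
    scale: str,
    *,
    phase_a: str = "phase1",
    phase_b: str = "phase2_baseline",
    participants: Iterable[str] | None = None,
) -> CorrelationResult:
    """Pearson correlation of the log scale score across two occasions.

    Participants missing either occasion are dropped listwise; the returned
    ``n`` is the number of complete pairs.
    """
    a = _baseline(scores, scale, phase_a).set_index("participant_id")["log_k"]
    b = _baseline(scores, scale, phase_b).set_index("participant_id")["log_k"]
    if participants is not None:
        keep = set(participants)
        a, b = a[a.index.isin(keep)], b[b.index.isin(keep)]
    common = a.index.intersection(b.index)
    return _pearson(a[common].to_numpy(), b[common].to_numpy())


def convergent_validity(
    scores: pd.DataFrame,
    *,
    scales: Sequence[str] = ("mcq", "time", "monetary"),
    phases: Sequence[str] = ("phase1", "phase2_baseline"),
    participants: Iterable[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full symmetric Pearson matrix among all scale x phase log scores.

    Returns ``(r, p, n)`` frames indexed by ``"<phase>:<scale>"`` labels;
    the diagonal of ``r`` is exactly 1.  Each pair uses its complete cases.
    """
    series = {}
    for phase in phases:
        for scale in scales:
            s = _baseline(scores, scale, phase).set_index("participant_id")["log_k"]
            if participants is not None:
                s = s[s.index.isin(set(participants))]
            series[f"{phase}:{scale}"] = s
    labels = list(series)
    r = pd.DataFrame(np.eye(len(labels)), index=labels, columns=labels)
    p = pd.DataFrame(np.nan, index=labels, columns=labels)
    n = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for lab in labels:
        n.loc[lab, lab] = len(series[lab])
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            common = series[la].index.intersection(series[lb].index)
            res = _pearson(series[la][common].to_numpy(),
                           series[lb][common].to_numpy())
            r.loc[la, lb] = r.loc[lb, la] = res.r
            p.loc[la, lb] = p.loc[lb, la] = res.p
            n.loc[la, lb] = n.loc[lb, la] = res.n
    return r, p, n


def abbreviation_analysis(
    item_k: pd.DataFrame,
    scale: str,
    phase: str,
    *,
    items: Sequence[str],
    full_items: Sequence[str] | None = None,
    subset_sizes: Sequence[int] | None = None,
    iterations: int = 100,
    seed: int = 0,
    participants: Iterable[str] | None = None,
    allow_full: bool = False,
) -> pd.DataFrame:
    """Random-subset scale abbreviation curves.

    For each subset size N, draws ``iterations`` uniform random N-item
    subsets of ``items`` (without replacement within a draw, independent
    across draws) and computes the Pearson r between the subset's log
    geometric-mean score and the full scale's.  ``full_items`` sets the
    full-scale denominator (default: ``items``, i.e. the informative set).

    Returns a tidy frame ``subset_size, iteration, r, items``; a single
    seed governs the whole curve.
    """
    items = list(items)
    full_items = list(full_items) if full_items is not None else items
    max_n = len(items) if allow_full else len(items) - 1
    if subset_sizes is None:
        subset_sizes = range(1, max_n + 1)
    for nn in subset_sizes:
        if nn < 1 or nn > max_n:
            raise ValueError(
                f"subset size {nn} out of range 1..{max_n} "
                f"(pass allow_full=True to permit the full set)"
            )
    sub = _baseline(item_k, scale, phase)
    if participants is not None:
        sub = sub[sub["participant_id"].isin(set(participants))]
    wide = sub.pivot(index="participant_id", columns="item_id", values="log_k")
    wide = wide.dropna()
    full_score = wide[full_items].mean(axis=1).to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    for nn in subset_sizes:
        for it in range(iterations):
            chosen = list(rng.choice(items, size=nn, replace=False))
            subset_score = wide[chosen].mean(axis=1).to_numpy()
            res = _pearson(subset_score, full_score)
            rows.append(
                {"subset_size": nn, "iteration": it, "r": res.r,
                 "items": ",".join(sorted(chosen))}
            )
    return pd.DataFrame(rows)


def abbreviation_summary(draws: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and Monte-Carlo SE of r per subset size."""
    g = draws.groupby("subset_size")["r"]
    out = g.agg(mean_r="mean", sd_r="std", n_iterations="size").reset_index()
    out["mc_se"] = out["sd_r"] / np.sqrt(out["n_iterations"])
    return out
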
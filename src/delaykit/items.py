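"""Discounting item definitions and the default item banks.

Three item kinds are supported:

* **time-selection** — the respondent slides a delay: "how long would you
  wait to get $A instead of $V today?"  The answered quantity is ``D`` (days).
* **monetary-selection** — the respondent slides an immediate amount: "how
  much money would you take today instead of $A in <delay>?"  The answered
  quantity is ``V`` (US $).
* **mcq-binary** — a classic Monetary Choice Questionnaire item: a forced
  binary choice between $V today and $A after ``D`` days.

All delays are stored in days.  One year is treated as 364 days (52 weeks
exactly, consistent with the 52-week delay slider), one month as 30 days,
six months as 182 days, three months as 91 days.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

import yaml

__all__ = [
    "ItemKind",
    "DiscountingItem",
    "ItemBank",
    "parse_delay",
    "time_selection_bank",
    "monetary_selection_bank",
    "mcq_bank",
    "default_banks",
    "load_bank",
    "save_bank",
    "DAYS_PER_YEAR",
]

DAYS_PER_YEAR = 364.0  # 52 weeks exactly
DAYS_PER_MONTH = 30.0
DAYS_PER_WEEK = 7.0

#: calendar words accepted in bank config files, mapped to days
_DELAY_WORDS = {
    "day": 1.0,
    "tomorrow": 1.0,
    "week": DAYS_PER_WEEK,
    "month": DAYS_PER_MONTH,
    "year": DAYS_PER_YEAR,
}


def parse_delay(text: str | float | int) -> float:
    """Parse a delay expressed in days or calendar words into days.

    Accepts a bare number (days), or strings such as ``"1 year"``,
    ``"6 months"``, ``"2 weeks"``, ``"tomorrow"``, ``"14 days"``.
    """
    if isinstance(text, (int, float)):
        return float(text)
    s = text.strip().lower()
    if s in _DELAY_WORDS:
        return _DELAY_WORDS[s]
    parts = s.split()
    if len(parts) == 2:
        count, unit = parts
        unit = unit.rstrip("s")
        if unit == "month":
            # quarter- and half-year delays are fractions of the 364-day year
            # (91 / 182 days), not multiples of the 30-day month
            special = {3.0: 91.0, 6.0: 182.0}
            return special.get(float(count), float(count) * DAYS_PER_MONTH)
        if unit in _DELAY_WORDS:
            return float(count) * _DELAY_WORDS[unit]
    raise ValueError(f"cannot parse delay: {text!r}")


class ItemKind(str, Enum):
    TIME_SELECTION = "time_selection"
    MONETARY_SELECTION = "monetary_selection"
    MCQ_BINARY = "mcq_binary"


@dataclass(frozen=True)
class DiscountingItem:
    """One questionnaire item.

    Parameters
    ----------
    item_id:
        Unique label within a bank.
    kind:
        Item kind; decides which of V / D is fixed and which is answered.
    A:
        Delayed (large, later) reward in US $.  Always fixed.
    V:
        Immediate reward in US $.  Fixed for time-selection and MCQ items,
        ``None`` (answered by the respondent) for monetary-selection items.
    D:
        Delay of the large reward, in days.  Fixed for monetary-selection and
        MCQ items, ``None`` (answered) for time-selection items.
    response_min, response_max:
        Slider bounds in the responding dimension (days for time-selection,
        US $ for monetary-selection); ignored for MCQ items.
    """

    item_id: str
    kind: ItemKind
    A: float
    V: float | None = None
    D: float | None = None
    response_min: float = 0.0
    response_max: float = 1.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"{self.item_id}: A must be positive, got {self.A}")
        kind = ItemKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind in (ItemKind.TIME_SELECTION, ItemKind.MCQ_BINARY):
            if self.V is None or not 0 < self.V < self.A:
                raise ValueError(
                    f"{self.item_id}: V must satisfy 0 < V < A, got V={self.V}"
                )
        if kind in (ItemKind.MONETARY_SELECTION, ItemKind.MCQ_BINARY):
            if self.D is None or self.D <= 0:
                raise ValueError(f"{self.item_id}: D must be positive, got {self.D}")
        if kind is ItemKind.TIME_SELECTION and self.D is not None:
            raise ValueError(f"{self.item_id}: time-selection items fix V, not D")
        if kind is ItemKind.MONETARY_SELECTION and self.V is not None:
            raise ValueError(f"{self.item_id}: monetary-selection items fix D, not V")
        if kind is not ItemKind.MCQ_BINARY and self.response_min >= self.response_max:
            raise ValueError(
                f"{self.item_id}: response_min must be < response_max "
                f"({self.response_min} >= {self.response_max})"
            )

    @property
    def reward_ratio(self) -> float:
        """A/V - 1; the dimensionless steepness of the item (needs V)."""
        if self.V is None:
            raise ValueError(f"{self.item_id}: item has no fixed V")
        return self.A / self.V - 1.0

    @property
    def k_indiff(self) -> float:
        """Discounting rate at which the two MCQ options are equally valued.

        Solves V = A / (1 + k D) for k: ``k = (A - V) / (V D)``.
        """
        if self.V is None or self.D is None:
            raise ValueError(f"{self.item_id}: k_indiff needs both V and D")
        return (self.A - self.V) / (self.V * self.D)


class ItemBank:
    """An ordered, homogeneous collection of items forming one scale."""

    def __init__(self, scale: str, items: Iterable[DiscountingItem]):
        items = tuple(items)
        if not items:
            raise ValueError("empty item bank")
        kinds = {it.kind for it in items}
        if len(kinds) != 1:
            raise ValueError(f"bank {scale!r} mixes item kinds: {kinds}")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise ValueError(f"bank {scale!r} has duplicate item ids")
        self.scale = scale
        self.items = items
        self.kind: ItemKind = items[0].kind
        self._by_id = {it.item_id: it for it in items}

    def __iter__(self) -> Iterator[DiscountingItem]:
        return iter(self.items)

    def __len__(self) -> int:
        return len(self.items)

    def __getitem__(self, item_id: str) -> DiscountingItem:
        return self._by_id[item_id]

    def __contains__(self, item_id: str) -> bool:
        return item_id in self._by_id

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    def subset(self, item_ids: Iterable[str]) -> "ItemBank":
        return ItemBank(self.scale, [self._by_id[i] for i in item_ids])

    def __repr__(self) -> str:  # pragma: no cover
        return f"ItemBank({self.scale!r}, {len(self)} {self.kind.value} items)"


# ---------------------------------------------------------------------------
# Default banks
# ---------------------------------------------------------------------------

#: immediate amounts of the seven time-selection items ($A = 100 throughout)
TIME_ITEM_IMMEDIATE_AMOUNTS = (50, 70, 10, 80, 40, 30, 99)

#: delays of the seven monetary-selection items
MONETARY_ITEM_DELAYS = ("1 year", "1 month", "6 months", "3 months",
                        "2 weeks", "1 week", "tomorrow")


def time_selection_bank(
    response_min: float = 0.0,
    response_max: float = 52 * DAYS_PER_WEEK,
    A: float = 100.0,
) -> ItemBank:
    """The seven "how long would you wait for $100 instead of $V today?"
    items, answered on a 0–52-week delay slider (days internally)."""
    items = [
        DiscountingItem(
            item_id=f"time_{v}",
            kind=ItemKind.TIME_SELECTION,
            A=A,
            V=float(v),
            response_min=response_min,
            response_max=response_max,
        )
        for v in TIME_ITEM_IMMEDIATE_AMOUNTS
    ]
    return ItemBank("time", items)


def monetary_selection_bank(
    response_min: float = 1.0,
    response_max: float = 99.0,
    A: float = 100.0,
) -> ItemBank:
    """The seven "how much money today instead of $100 in <delay>?" items,
    answered on a $1–$99 slider."""
    items = [
        DiscountingItem(
            item_id="money_" + delay.replace(" ", ""),
            kind=ItemKind.MONETARY_SELECTION,
            A=A,
            D=parse_delay(delay),
            response_min=response_min,
            response_max=response_max,
        )
        for delay in MONETARY_ITEM_DELAYS
    ]
    return ItemBank("monetary", items)


#: (V, D-days) grid of the default 7-item MCQ bank.  $A = 100 throughout;
#: delays span 2 months to a year and immediate amounts $10 to $99, chosen so
#: the implied indifference rates are distinct and roughly log-spaced
#: (~2.8e-5 to ~0.15 per day).
MCQ_ITEM_GRID = (
    (10, 61.0),
    (30, 75.0),
    (40, 91.0),
    (50, 152.0),
    (70, 182.0),
    (80, 273.0),
    (99, 364.0),
)


def mcq_bank(A: float = 100.0) -> ItemBank:
    """Default 7-item binary-choice MCQ bank ("$V today or $100 in D days?")."""
    items = [
        DiscountingItem(
            item_id=f"mcq_{v}",
            kind=ItemKind.MCQ_BINARY,
            A=A,
            V=float(v),
            D=d,
            response_min=0.0,
            response_max=1.0,
        )
        for v, d in MCQ_ITEM_GRID
    ]
    return ItemBank("mcq", items)


def default_banks() -> dict[str, ItemBank]:
    """All three default banks keyed by scale name."""
    return {
        "time": time_selection_bank(),
        "monetary": monetary_selection_bank(),
        "mcq": mcq_bank(),
    }


# ---------------------------------------------------------------------------
# Plain-text (YAML) bank config
# ---------------------------------------------------------------------------

def save_bank(bank: ItemBank, path) -> None:
    """Write a bank as a YAML key-value config."""
    doc = {
        "scale": bank.scale,
        "kind": bank.kind.value,
        "items": [
            {
                k: v
                for k, v in {
                    "item_id": it.item_id,
                    "A": it.A,
                    "V": it.V,
                    "D": it.D,
                    "response_min": it.response_min,
                    "response_max": it.response_max,
                }.items()
                if v is not None
            }
            for it in bank
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_bank(path) -> ItemBank:
    """Read a bank from a YAML config written by :func:`save_bank`.

    ``D`` entries may be numbers (days) or calendar strings ("6 months").
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    kind = ItemKind(doc["kind"])
    items = []
    for spec in doc["items"]:
        d = spec.get("D")
        items.append(
            DiscountingItem(
                item_id=str(spec["item_id"]),
                kind=kind,
                A=float(spec["A"]),
                V=None if spec.get("V") is None else float(spec["V"]),
                D=None if d is None else parse_delay(d),
                response_min=float(spec.get("response_min", 0.0)),
                response_max=float(spec.get("response_max", 1.0)),
            )
        )
    return ItemBank(doc["scale"], items)
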
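"""Readers and writers for the long-format study tables.

Canonical dialect: comma-delimited UTF-8 with a header row.  Responses are
one row per (participant, phase, occasion, item, value); validation reports
offending data rows by line number (header = line 1).
"""

from __future__ import annotations

import pandas as pd

from .items import ItemBank, ItemKind

__all__ = [
    "ResponseValidationError",
    "read_responses",
    "write_responses",
    "read_table",
    "write_table",
    "VALID_PHASES",
]

VALID_PHASES = ("phase1", "phase2_baseline", "phase2_followup")

RESPONSE_COLUMNS = ["participant_id", "phase", "occasion", "item_id", "value"]


class ResponseValidationError(ValueError):
    """A response table failed validation; message lists row numbers."""


def _fail(problems: list[str]) -> None:
    if problems:
        shown = problems[:20]
        more = f" (+{len(problems) - 20} more)" if len(problems) > 20 else ""
        raise ResponseValidationError("; ".join(shown) + more)


def read_responses(path, banks: dict[str, ItemBank] | ItemBank) -> pd.DataFrame:
    """Read and validate a long-format response table.

    Checks: known item ids, numeric values, values within each item's
    slider bounds (binary for MCQ items), valid phase labels, and no
    duplicate (participant, phase, occasion, item) keys.
    """
    if isinstance(banks, ItemBank):
        banks = {banks.scale: banks}
    df = pd.read_csv(path, dtype={"participant_id": str, "item_id": str})
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ResponseValidationError(f"missing columns: {missing}")

    items = {it.item_id: (bank, it) for bank in banks.values() for it in bank}
    problems: list[str] = []
    lineno = df.index.to_numpy() + 2  # header is line 1

    unknown = ~df["item_id"].isin(items)
    for ln, iid in zip(lineno[unknown], df.loc[unknown, "item_id"]):
        problems.append(f"line {ln}: unknown item_id {iid!r}")

    badphase = ~df["phase"].isin(VALID_PHASES)
    for ln, ph in zip(lineno[badphase], df.loc[badphase, "phase"]):
        problems.append(f"line {ln}: unknown phase {ph!r}")

    values = pd.to_numeric(df["value"], errors="coerce")
    nonnum = values.isna().to_numpy()
    for ln in lineno[nonnum & ~unknown.to_numpy()]:
        problems.append(f"line {ln}: non-numeric value")
    df["value"] = values

    ok = ~(unknown.to_numpy() | nonnum)
    for idx in df.index[ok]:
        bank, item = items[df.at[idx, "item_id"]]
        v = df.at[idx, "value"]
        if item.kind is ItemKind.MCQ_BINARY:
            if v not in (0.0, 1.0):
                problems.append(
                    f"line {idx + 2}: MCQ value must be 0 or 1, got {v}"
                )
        elif not item.response_min <= v <= item.response_max:
            problems.append(
                f"line {idx + 2}: value {v} outside slider bounds "
                f"[{item.response_min}, {item.response_max}] of {item.item_id}"
            )

    dup = df.duplicated(
        subset=["participant_id", "phase", "occasion", "item_id"], keep=False
    )
    first = df.duplicated(
        subset=["participant_id", "phase", "occasion", "item_id"], keep="first"
    )
    for ln, iid in zip(lineno[dup & first], df.loc[dup & first, "item_id"]):
        problems.append(f"line {ln}: duplicate response key for item {iid!r}")

    _fail(problems)
    df["occasion"] = df["occasion"].astype(int)
    return df[RESPONSE_COLUMNS]


def write_responses(df: pd.DataFrame, path) -> None:
    """Write a response table in the canonical dialect."""
    df[RESPONSE_COLUMNS].to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    """Read any auxiliary comma-delimited table (covariates, outcomes)."""
    return pd.read_csv(path, dtype={"participant_id": str})


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
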
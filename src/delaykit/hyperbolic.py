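"""Hyperbolic discounting arithmetic.

The single-parameter hyperbolic model values a reward of size ``A``
delivered after delay ``D`` (days) at

    V = A / (1 + k * D)

where ``k`` (per day) is the individual's discounting rate.  Because each
continuous item fixes two of the three quantities, an observed slider
response determines ``k`` in closed form:

* time-selection (fixed V, answered D):   k = (A / V - 1) / D
* monetary-selection (fixed D, answered V): k = (A / V - 1) / D

A per-person scale score is the geometric mean of the per-item rates.
"""

from __future__ import annotations

import numpy as np

from .items import DiscountingItem, ItemKind

__all__ = [
    "DomainError",
    "NonInvertibleResponse",
    "hyperbolic_value",
    "invert_k_from_time",
    "invert_k_from_money",
    "geometric_mean_k",
]


class DomainError(ValueError):
    """An input outside the model's mathematical domain."""


class NonInvertibleResponse(ValueError):
    """A response from which no positive finite rate can be recovered."""


def hyperbolic_value(A, k, D):
    """Present value of reward ``A`` delayed by ``D`` days at rate ``k``/day.

    Accepts scalars or arrays.  Strictly decreasing in both ``k`` and ``D``;
    equals ``A`` when either is zero.
    """
    A = np.asarray(A, dtype=float)
    k = np.asarray(k, dtype=float)
    D = np.asarray(D, dtype=float)
    if np.any(A <= 0):
        raise DomainError("A must be positive")
    if np.any(k < 0):
        raise DomainError("k must be nonnegative")
    if np.any(D < 0):
        raise DomainError("D must be nonnegative")
    out = A / (1.0 + k * D)
    return float(out) if out.ndim == 0 else out


def invert_k_from_time(
    item: DiscountingItem,
    chosen_D,
    *,
    min_delay_days: float | None = None,
):
    """Recover ``k`` from a time-selection response (a chosen delay in days).

        k = (A / V - 1) / chosen_D

    Parameters
    ----------
    chosen_D:
        The answered delay in days (scalar or array).  Must be positive.
    min_delay_days:
        If given, delays below this floor are clamped up to it before
        inversion (the deployed slider's minimum resolution); callers are
        expected to record a QC flag for clamped responses.  If ``None``
        (default), a nonpositive delay raises :class:`NonInvertibleResponse`.
    """
    if item.kind is not ItemKind.TIME_SELECTION:
        raise DomainError(f"{item.item_id}: not a time-selection item")
    ratio = item.reward_ratio  # validates 0 < V < A
    d = np.asarray(chosen_D, dtype=float)
    if min_delay_days is not None:
        d = np.maximum(d, float(min_delay_days))
    if np.any(d <= 0):
        raise NonInvertibleResponse(
            f"{item.item_id}: zero or negative chosen delay is non-invertible"
        )
    out = ratio / d
    return float(out) if out.ndim == 0 else out


def invert_k_from_money(item: DiscountingItem, chosen_V):
    """Recover ``k`` from a monetary-selection response (an amount in US $).

        k = (A / chosen_V - 1) / D
    """
    if item.kind is not ItemKind.MONETARY_SELECTION:
        raise DomainError(f"{item.item_id}: not a monetary-selection item")
    v = np.asarray(chosen_V, dtype=float)
    if np.any(v <= 0):
        raise DomainError(f"{item.item_id}: chosen amount must be positive")
    if np.any(v >= item.A):
        raise NonInvertibleResponse(
            f"{item.item_id}: chosen amount >= A implies a nonpositive rate"
        )
    out = (item.A / v - 1.0) / item.D
    return float(out) if out.ndim == 0 else out


def geometric_mean_k(item_ks) -> tuple[float, float]:
    """Geometric mean of per-item rates and its natural log.

    Returns ``(k_geomean, log_k)`` with
    ``k_geomean = exp(mean(ln k_i))`` and ``log_k = ln(k_geomean)``.
    """
    ks = np.asarray(item_ks, dtype=float)
    if ks.size == 0:
        raise ValueError("cannot aggregate an empty rate vector")
    if np.any(ks <= 0) or not np.all(np.isfinite(ks)):
        raise ValueError("all item rates must be positive and finite")
    log_k = float(np.mean(np.log(ks)))
    return float(np.exp(log_k)), log_k
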
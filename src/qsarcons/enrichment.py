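"""Functional-group enrichment in active versus inactive compounds.

Compounds are called active when their activity strictly exceeds a threshold
(default 20% of the high-concentration reference).  For a functional group
the enrichment factor is

    EF = (n_active_with / n_active_total) / (n_inactive_with / n_inactive_total)

i.e. the ratio of the group's prevalence among actives to its prevalence
among inactives.  Significance of over-representation in the active set is a
one-sided hypergeometric (Fisher) tail.  A group passes when EF strictly
exceeds ``ef_threshold`` (default 2.5) and p is strictly below
``p_threshold`` (default 0.01).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "classify_active",
    "enrichment_factor",
    "enrichment_significance",
    "enrichment_table",
    "round_half_up",
]

DEFAULT_ACTIVITY_THRESHOLD = 20.0
DEFAULT_EF_THRESHOLD = 2.5
DEFAULT_P_THRESHOLD = 0.01


def classify_active(y_exp, threshold: float = DEFAULT_ACTIVITY_THRESHOLD) -> np.ndarray:
    """Boolean active mask: activity strictly greater than `threshold` (%)."""
    y = np.asarray(y_exp, dtype=float)
    if not np.isfinite(y).all():
        raise ValidationError("activities must be finite")
    return y > threshold


def _check_counts(n_active_with, n_active_total, n_inactive_with, n_inactive_total):
    a, at, i, it = (int(n_active_with), int(n_active_total),
                    int(n_inactive_with), int(n_inactive_total))
    if at <= 0 or it <= 0:
        raise ValidationError("active and inactive totals must be positive")
    if not (0 <= a <= at and 0 <= i <= it):
        raise ValidationError("group counts must lie within their totals")
    return a, at, i, it


def enrichment_factor(n_active_with, n_active_total, n_inactive_with, n_inactive_total) -> float:
    """Enrichment factor of a group (see module docstring).

    Returns ``inf`` when the group occurs only among actives, and ``nan``
    (undefined) when it occurs nowhere.
    """
    a, at, i, it = _check_counts(n_active_with, n_active_total,
                                 n_inactive_with, n_inactive_total)
    if i == 0:
        return float("inf") if a > 0 else float("nan")
    return (a / at) / (i / it)


def enrichment_significance(
    n_active_with, n_active_total, n_inactive_with, n_inactive_total
) -> float:
    """One-sided exact p for over-representation of the group among actives.

    Hypergeometric upper tail: the probability of drawing at least
    ``n_active_with`` group members in ``n_active_total`` draws from the
    pooled population.
    """
    a, at, i, it = _check_counts(n_active_with, n_active_total,
                                 n_inactive_with, n_inactive_total)
    total = at + it
    k = a + i  # group members in the pooled population
    return float(stats.hypergeom.sf(a - 1, total, k, at))


def enrichment_table(
    active_mask,
    group_masks: Mapping[str, np.ndarray],
    ef_threshold: float = DEFAULT_EF_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> pd.DataFrame:
    """EF and significance for every group, sorted by descending EF.

    Parameters
    ----------
    active_mask : boolean array-like
        Active/inactive call per compound.
    group_masks : mapping of group label -> boolean array-like
        Group membership per compound, aligned with `active_mask`.

    Returns
    -------
    pandas.DataFrame
        Columns: group, n_active_with, n_inactive_with, n_active_total,
        n_inactive_total, ef, p, passes.  Groups present in no compound
        carry NaN EF and never pass.  ``passes`` applies strict
        inequalities to both thresholds.
    """
    active = np.asarray(active_mask, dtype=bool)
    at = int(active.sum())
    it = int((~active).sum())
    rows = []
    for label, mask in group_masks.items():
        g = np.asarray(mask, dtype=bool)
        if g.shape != active.shape:
            raise ValidationError(f"group mask {label!r} is not aligned with active_mask")
        a = int((g & active).sum())
        i = int((g & ~active).sum())
        ef = enrichment_factor(a, at, i, it)
        p = enrichment_significance(a, at, i, it)
        passes = bool(np.isfinite(ef) or np.isinf(ef)) and ef > ef_threshold and p < p_threshold
        rows.append(
            {
                "group": label,
                "n_active_with": a,
                "n_inactive_with": i,
                "n_active_total": at,
                "n_inactive_total": it,
                "ef": ef,
                "p": p,
                "passes": passes,
            }
        )
    frame = pd.DataFrame(rows)
    if len(frame):
        # descending EF, infinities first, undefined (NaN) last
        order = np.lexsort((frame.index.to_numpy(), -frame["ef"].fillna(-np.inf).to_numpy()))
        frame = frame.iloc[order].reset_index(drop=True)
    return frame


def round_half_up(value: float, decimals: int = 1) -> float:
    """Display rounding with ties away from zero (internal values stay exact)."""
    if not np.isfinite(value):
        return float(value)
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
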
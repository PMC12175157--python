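"""Fingerprint-based chemical-space diagnostics.

Tanimoto (Jaccard) similarity between binary fingerprints, per-query maximum
and mean similarity to a training set, and empirical cumulative distribution
coordinates for either statistic.  Low maximum similarity of a test compound
to every training compound indicates extrapolation; the eCDFs of the max and
mean statistics summarise how far a whole evaluation set sits from the
training chemical space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = ["SimilaritySummary", "tanimoto", "similarity_summary", "ecdf"]


def tanimoto(a, b) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two bit vectors.

    Defined as 0 when both vectors are empty.
    """
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"bit vectors must be 1-d and equal length, got {a.shape} vs {b.shape}")
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


@dataclass(frozen=True)
class SimilaritySummary:
    """Per-query similarity statistics and their eCDF coordinates.

    ``per_compound`` has one row per query: ``max_tanimoto`` and
    ``mean_tanimoto`` against the whole training set (max >= mean always).
    ``ecdf_max`` / ``ecdf_mean`` are (value, cumulative fraction) frames;
    the terminal cumulative fraction is exactly 1.
    """

    per_compound: pd.DataFrame
    ecdf_max: pd.DataFrame
    ecdf_mean: pd.DataFrame


def similarity_summary(query, train) -> SimilaritySummary:
    """Max and mean Tanimoto of every query row against all training rows.

    Parameters
    ----------
    query, train : array-like or DataFrame
        Binary fingerprint matrices of equal bit width; `train` non-empty.
    """
    q = np.asarray(query).astype(bool)
    t = np.asarray(train).astype(bool)
    if q.ndim != 2 or t.ndim != 2 or q.shape[1] != t.shape[1]:
        raise ValidationError("query and train must be 2-d with equal bit width")
    if t.shape[0] == 0:
        raise ValidationError("training set is empty")
    qs = q.sum(axis=1, dtype=np.int64)
    ts = t.sum(axis=1, dtype=np.int64)
    inter = q.astype(np.float32) @ t.astype(np.float32).T
    union = qs[:, None] + ts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / union, 0.0)
    per = pd.DataFrame(
        {"max_tanimoto": sim.max(axis=1), "mean_tanimoto": sim.mean(axis=1)}
    )
    return SimilaritySummary(
        per_compound=per,
        ecdf_max=ecdf(per["max_tanimoto"]),
        ecdf_mean=ecdf(per["mean_tanimoto"]),
    )


def ecdf(values) -> pd.DataFrame:
    """Right-continuous empirical CDF step coordinates.

    Returns a frame with sorted unique ``value`` entries and the
    ``cumulative_fraction`` at each step; the last fraction is exactly 1.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("ecdf of an empty vector is undefined")
    if not np.isfinite(v).all():
        raise ValidationError("values must be finite")
    x, counts = np.unique(v, return_counts=True)
    frac = np.cumsum(counts) / v.size
    frac[-1] = 1.0  # guard against floating accumulation
    return pd.DataFrame({"value": x, "cumulative_fraction": frac})
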
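"""Substructure-conditional prediction-error significance.

For each substructure bit with enough support, the RMSE over the compounds
carrying it (``RMSE_sub``) is compared against a bootstrap null in which the
substructure is assumed not to matter: the subset's squared errors are
rescaled so their RMSE matches the overall RMSE, then resampled with
replacement (subset-sized draws) to build the null RMSE distribution.  The
one-sided p-values are the fractions of null RMSEs strictly below
(improvement) or strictly above (degradation) the observed ``RMSE_sub``;
ties count toward neither tail.  The smaller of the two one-sided p-values,
with its direction, feeds a single Benjamini-Hochberg pass across bits.

Per-bit random streams are derived from the master seed and the *bit label*,
so results are invariant to the column order of the bit matrix.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError
from .tables import PredictionTable

logger = logging.getLogger("qsarcons")

__all__ = [
    "SubstructureResult",
    "filter_support",
    "substructure_pvalues",
    "bh_adjust",
    "run_substructure_scan",
    "scan_prediction_table",
]

DEFAULT_MIN_SUPPORT = 32
DEFAULT_N_BOOT = 100_000


@dataclass(frozen=True)
class SubstructureResult:
    """Significance record for one substructure bit."""

    bit: str
    support: int
    rmse_sub: float
    rmse_overall: float
    p_improvement: float
    p_degradation: float
    direction: str
    p_min: float
    p_bh: float
    significant: bool


def filter_support(matrix: pd.DataFrame, min_support: int = DEFAULT_MIN_SUPPORT) -> pd.DataFrame:
    """Keep only bits present in at least `min_support` compounds."""
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    keep = matrix.sum(axis=0) >= min_support
    return matrix.loc[:, keep]


def _bit_rng(seed: int, label: str) -> np.random.Generator:
    # label-keyed stream: stable under column reordering of the bit matrix
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(label.encode("utf-8"))])


def substructure_pvalues(
    squared_errors,
    subset_mask,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | np.random.Generator = 0,
    null_source: str = "subset",
) -> tuple[float, float, float]:
    """Directional bootstrap p-values for one substructure.

    Parameters
    ----------
    squared_errors : array-like
        Squared prediction errors of the full evaluation set (%^2).
    subset_mask : boolean array-like
        True for compounds carrying the substructure (non-empty).
    n_boot : int
        Number of bootstrap resamples of the null.
    seed : int or numpy Generator
        Randomness source; reproducible for equal seeds.
    null_source : {"subset", "full"}
        Pool the null resamples from the rescaled subset errors (default) or
        from the full set's errors (already on the overall RMSE scale).

    Returns
    -------
    (p_improvement, p_degradation, rmse_sub)
        ``p_improvement``: fraction of null RMSEs strictly below the
        observed subset RMSE; ``p_degradation``: strictly above.
    """
    sq = np.asarray(squared_errors, dtype=float)
    mask = np.asarray(subset_mask, dtype=bool)
    if sq.shape != mask.shape or sq.ndim != 1:
        raise ValidationError("squared_errors and subset_mask must be aligned 1-d vectors")
    if (sq < 0).any() or not np.isfinite(sq).all():
        raise ValidationError("squared_errors must be finite and non-negative")
    if not mask.any():
        raise ValidationError("subset is empty")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    if null_source not in ("subset", "full"):
        raise ValidationError("null_source must be 'subset' or 'full'")

    rmse_overall = float(np.sqrt(sq.mean()))
    sub_sq = sq[mask]
    n_sub = sub_sq.size
    rmse_sub = float(np.sqrt(sub_sq.mean()))

    if rmse_sub == 0.0:
        if rmse_overall > 0.0:
            logger.warning(
                "degenerate null: subset RMSE is 0 with overall RMSE %.3g", rmse_overall
            )
            return 0.0, 1.0, rmse_sub
        return 0.5, 0.5, rmse_sub  # everything is error-free; no direction

    if null_source == "subset":
        # rescale so the null pool's RMSE equals the overall RMSE exactly
        pool = sub_sq * (rmse_overall / rmse_sub) ** 2
    else:
        pool = sq

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    npool = pool.size
    boots = np.empty(n_boot)
    rows = max(1, int(2_000_000 // n_sub))
    done = 0
    while done < n_boot:
        take = min(rows, n_boot - done)
        idx = rng.integers(0, npool, size=(take, n_sub))
        boots[done:done + take] = np.sqrt(pool[idx].mean(axis=1))
        done += take

    p_improvement = float(np.mean(boots < rmse_sub))
    p_degradation = float(np.mean(boots > rmse_sub))
    return p_improvement, p_degradation, rmse_sub


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be 1-d")
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_substructure_scan(
    y_exp,
    y_pred,
    matrix: pd.DataFrame,
    min_support: int = DEFAULT_MIN_SUPPORT,
    n_boot: int = DEFAULT_N_BOOT,
    fdr: float = 0.05,
    seed: int = 0,
    null_source: str = "subset",
) -> pd.DataFrame:
    """Full scan: support filter -> per-bit directional p -> one BH pass.

    Parameters
    ----------
    y_exp, y_pred : array-like
        Experimental and predicted activities of the evaluation set, aligned
        with the rows of `matrix`.
    matrix : pandas.DataFrame
        0/1 substructure matrix (compounds x bits), columns labelled.
    fdr : float
        BH false-discovery-rate level for the ``significant`` flag.

    Returns
    -------
    pandas.DataFrame
        One row per retained bit with support, RMSE_sub, both one-sided
        p-values, direction (the smaller tail), ``p_min``, BH-adjusted
        ``p_bh`` and the ``significant`` flag, sorted by ``p_bh`` then
        ``p_min``.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(matrix) != y_exp.size or y_exp.shape != y_pred.shape:
        raise ValidationError(
            f"bit matrix rows ({len(matrix)}) must match evaluation set size ({y_exp.size})"
        )
    if not 0.0 < fdr < 1.0:
        raise ValidationError("fdr must be in (0, 1)")
    sq = (y_exp - y_pred) ** 2
    rmse_overall = float(np.sqrt(sq.mean()))
    kept = filter_support(matrix, min_support)

    records = []
    for label in kept.columns:
        mask = kept[label].to_numpy() == 1
        p_imp, p_deg, rmse_sub = substructure_pvalues(
            sq, mask, n_boot=n_boot, seed=_bit_rng(seed, str(label)),
            null_source=null_source,
        )
        direction = "improvement" if p_imp <= p_deg else "degradation"
        records.append(
            {
                "bit": str(label),
                "support": int(mask.sum()),
                "rmse_sub": rmse_sub,
                "rmse_overall": rmse_overall,
                "p_improvement": p_imp,
                "p_degradation": p_deg,
                "direction": direction,
                "p_min": min(p_imp, p_deg),
            }
        )
    result = pd.DataFrame(
        records,
        columns=["bit", "support", "rmse_sub", "rmse_overall", "p_improvement",
                 "p_degradation", "direction", "p_min"],
    )
    if len(result):
        result["p_bh"] = bh_adjust(result["p_min"].to_numpy())
        result["significant"] = result["p_bh"] < fdr
        result = result.sort_values(["p_bh", "p_min", "bit"], kind="stable").reset_index(drop=True)
    else:
        result["p_bh"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
    return result


def scan_prediction_table(
    table: PredictionTable,
    matrix: pd.DataFrame,
    predictions="consensus",
    split: str | None = "test",
    **kwargs,
) -> pd.DataFrame:
    """Scan a prediction table against a bit matrix aligned to the full table.

    `predictions` is a model name from the table, or an array/Series of
    per-compound predictions (e.g. a fitted consensus) aligned with the full
    table; `split` restricts the evaluation to one data split.
    """
    if isinstance(predictions, str) and predictions in table.models:
        y_pred = table.predictions()[predictions].to_numpy()
    else:
        y_pred = np.asarray(predictions, dtype=float)
    if len(matrix) != table.n_compounds or y_pred.size != table.n_compounds:
        raise ValidationError("bit matrix and predictions must align with the table rows")
    keep = np.ones(table.n_compounds, dtype=bool)
    if split is not None:
        keep = (table.df["split"] == split).to_numpy()
    ok = keep & np.isfinite(y_pred)
    return run_substructure_scan(
        table.df["y_exp"].to_numpy()[ok], y_pred[ok], matrix.iloc[ok], **kwargs
    )
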
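"""Regression metrics, their bootstrap uncertainty, and the Grubbs outlier test.

All quantities are computed on the activity scale (% probe displacement).
``RMSE`` is the root-mean-square prediction error; the coefficient of
determination ``1 - RSS/TSS`` is reported as Q2 when computed on
cross-validated training predictions and as R2 on held-out test predictions
(one formula, two labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger("qsarcons")

__all__ = [
    "MetricReport",
    "ActivityErrorCurve",
    "rmse",
    "coefficient_of_determination",
    "bootstrap_rmse_ci",
    "activity_error_curve",
    "grubbs_flag",
    "grubbs_critical_value",
]


@dataclass(frozen=True)
class MetricReport:
    """Point metrics for one prediction set.

    Attributes
    ----------
    rmse : float
        Root-mean-square error, %.
    r2_or_q2 : float
        Coefficient of determination (<= 1); Q2 for cross-validated training
        predictions, R2 for test predictions, per `label`.
    n : int
        Number of compounds evaluated.
    label : str
        ``"train_cv"`` (Q2) or ``"test"`` (R2).
    ci_low, ci_high : float, optional
        Bootstrap percentile confidence bounds on the RMSE, %.
    """

    rmse: float
    r2_or_q2: float
    n: int
    label: str
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def metric_name(self) -> str:
        return "Q2" if self.label == "train_cv" else "R2"


@dataclass(frozen=True)
class ActivityErrorCurve:
    """RMSE as a function of experimental activity (binned on the activity axis).

    ``edges`` has one more entry than ``rmse``/``counts``; bins are
    right-open except the last.  Empty bins carry count 0 and NaN RMSE.
    """

    edges: np.ndarray
    rmse: np.ndarray
    counts: np.ndarray


def _paired(y_exp, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_exp = np.asarray(y_exp, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_exp.shape != y_pred.shape or y_exp.ndim != 1:
        raise ValidationError(
            f"y_exp and y_pred must be 1-d and equal length, got {y_exp.shape} vs {y_pred.shape}"
        )
    if y_exp.size == 0:
        raise ValidationError("empty activity vectors")
    if not (np.isfinite(y_exp).all() and np.isfinite(y_pred).all()):
        raise ValidationError("non-finite values in activity vectors")
    return y_exp, y_pred


def rmse(y_exp, y_pred) -> float:
    """Root-mean-square error between experimental and predicted activities (%)."""
    y_exp, y_pred = _paired(y_exp, y_pred)
    return float(np.sqrt(np.mean((y_exp - y_pred) ** 2)))


def coefficient_of_determination(y_exp, y_pred, label: str = "test") -> MetricReport:
    """Coefficient of determination ``1 - RSS/TSS`` with TSS about mean(y_exp).

    Parameters
    ----------
    label : {"train_cv", "test"}
        Which flavour is being computed: Q2 for cross-validated training
        predictions, R2 for held-out test predictions.

    Raises
    ------
    ValidationError
        If fewer than 2 compounds are supplied or `y_exp` is constant
        (TSS = 0 leaves the statistic undefined).
    """
    if label not in ("train_cv", "test"):
        raise ValidationError(f"label must be 'train_cv' or 'test', got {label!r}")
    y_exp, y_pred = _paired(y_exp, y_pred)
    if y_exp.size < 2:
        raise ValidationError("coefficient of determination needs >= 2 compounds")
    tss = float(np.sum((y_exp - y_exp.mean()) ** 2))
    if tss == 0.0:
        raise ValidationError("y_exp is constant; TSS = 0")
    rss = float(np.sum((y_exp - y_pred) ** 2))
    return MetricReport(
        rmse=float(np.sqrt(rss / y_exp.size)),
        r2_or_q2=1.0 - rss / tss,
        n=int(y_exp.size),
        label=label,
    )


def bootstrap_rmse_ci(
    y_exp,
    y_pred,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the RMSE.

    Compounds are resampled with replacement `n_boot` times; the interval is
    the (1-level)/2 and (1+level)/2 percentiles of the resampled RMSEs.
    Reproducible under `seed`.
    """
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level must be in (0, 1), got {level}")
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    y_exp, y_pred = _paired(y_exp, y_pred)
    rng = np.random.default_rng(seed)
    sq = (y_exp - y_pred) ** 2
    n = sq.size
    boots = np.empty(n_boot)
    # chunk index generation so memory stays bounded for large n * n_boot
    rows = max(1, int(2_000_000 // n))
    done = 0
    while done < n_boot:
        take = min(rows, n_boot - done)
        idx = rng.integers(0, n, size=(take, n))
        boots[done:done + take] = np.sqrt(sq[idx].mean(axis=1))
        done += take
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def activity_error_curve(y_exp, y_pred, bin_width: float = 10.0) -> ActivityErrorCurve:
    """Per-bin RMSE along the experimental-activity axis.

    Bins of width `bin_width` (%) span the observed activity range, aligned
    to multiples of the width.  Empty bins are reported with count 0 and NaN
    RMSE so the curve keeps a regular grid.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    y_exp, y_pred = _paired(y_exp, y_pred)
    lo = np.floor(y_exp.min() / bin_width) * bin_width
    hi = np.ceil(y_exp.max() / bin_width) * bin_width
    if hi <= lo:  # all activities on one edge
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    idx = np.clip(np.digitize(y_exp, edges) - 1, 0, len(edges) - 2)
    sq = (y_exp - y_pred) ** 2
    counts = np.bincount(idx, minlength=len(edges) - 1)
    sums = np.bincount(idx, weights=sq, minlength=len(edges) - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_bin = np.where(counts > 0, np.sqrt(sums / np.maximum(counts, 1)), np.nan)
    return ActivityErrorCurve(edges=edges, rmse=per_bin, counts=counts)


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile."""
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return float((n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t)))


def grubbs_flag(values, alpha: float = 0.1) -> int | None:
    """Index of the single most extreme value if it fails Grubbs' test, else None.

    The two-sided single-outlier variant: ``G = max|v - mean| / sd`` compared
    with the t-based critical value at significance `alpha`.  Undefined for
    fewer than 3 values or zero variance (returns None, logged).
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise ValidationError("values must be 1-d")
    if not np.isfinite(v).all():
        raise ValidationError("non-finite values")
    n = v.size
    if n < 3:
        logger.debug("grubbs_flag: undefined for n=%d < 3", n)
        return None
    sd = v.std(ddof=1)
    if sd == 0.0:
        return None
    dev = np.abs(v - v.mean())
    i = int(np.argmax(dev))
    if dev[i] / sd > grubbs_critical_value(n, alpha):
        return i
    return None
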
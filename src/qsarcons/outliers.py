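"""Bin-based averaging (BBA) of prediction errors along the distance-to-model axis.

The distance to model (DM) is an ensemble-disagreement statistic - here the
ensemble STD of a model's sub-ensemble, or the cross-model STD of a
consensus.  BBA sorts compounds by ascending DM and partitions them into
non-overlapping bins: a bin is closed once it holds at least ``min_bin_size``
compounds *and* (being the first bin, or) its RMSE exceeds the previous
bin's, so the per-bin RMSE sequence is non-decreasing - the expected shape of
an error-vs-uncertainty calibration curve.  The trailing remainder smaller
than ``min_bin_size`` merges into the last bin; a terminal bin whose RMSE
falls strictly below its predecessor's (possible only because the data ran
out before the closing rule was satisfied) is merged backward until the
sequence is monotone.

Each bin's RMSE defines a local error threshold (``z`` times the bin RMSE);
a compound is flagged as a potential data error when its absolute prediction
error strictly exceeds the threshold of its bin.  Compounds flagged this way
despite low DM combine high confidence with high error - the signature of an
experimental artifact or an activity cliff rather than a model failure.
The absolute-error-versus-DM scatter with these thresholds is the Williams
plot; :func:`ad_threshold` supplies its vertical AD cutoff (the DM quantile
covering a chosen fraction of the training set).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .metrics import coefficient_of_determination

logger = logging.getLogger("qsarcons")

__all__ = [
    "BinBasedAveraging",
    "BBAResults",
    "OutlierReport",
    "fit_bins",
    "flag_outliers",
    "ad_threshold",
    "cross_model_outliers",
]


class BinBasedAveraging:
    """Fit DM bins and flag error outliers against per-bin thresholds.

    Parameters
    ----------
    dm : array-like
        Distance-to-model values (ensemble STD, %), finite and >= 0.
    abs_error : array-like
        Absolute prediction errors (%), aligned with `dm`.
    min_bin_size : int
        Minimum compounds per bin (the terminal bin may exceed it after the
        remainder merge).
    z : float
        Threshold multiplier: a compound is flagged when
        ``|error| > z * bin RMSE``.
    """

    def __init__(self, dm, abs_error, min_bin_size: int = 50, z: float = 3.0):
        dm = np.asarray(dm, dtype=float)
        err = np.asarray(abs_error, dtype=float)
        if dm.shape != err.shape or dm.ndim != 1 or dm.size == 0:
            raise ValidationError("dm and abs_error must be equal-length 1-d vectors")
        if not np.isfinite(dm).all() or (dm < 0).any():
            raise ValidationError("dm must be finite and non-negative")
        if not np.isfinite(err).all():
            raise ValidationError("abs_error must be finite")
        if min_bin_size < 1:
            raise ValidationError("min_bin_size must be >= 1")
        if z <= 0:
            raise ValidationError("z must be positive")
        self.dm = dm
        self.abs_error = np.abs(err)
        self.min_bin_size = int(min_bin_size)
        self.z = float(z)

    def fit(self) -> "BBAResults":
        """Partition the DM axis into bins and compute their error thresholds."""
        n = self.dm.size
        if n < self.min_bin_size:
            logger.warning(
                "only %d compounds (< min_bin_size=%d); fitting a single bin",
                n, self.min_bin_size,
            )
        order = np.argsort(self.dm, kind="stable")
        d = self.dm[order]
        sq = self.abs_error[order] ** 2
        csum = np.concatenate([[0.0], np.cumsum(sq)])

        def seg_rmse(a: int, b: int) -> float:
            return math.sqrt((csum[b] - csum[a]) / (b - a))

        bounds: list[int] = []  # exclusive right edge of each closed bin
        start = 0
        prev = None
        while start < n:
            end = start
            closed = False
            while end < n and not closed:
                end += 1
                if end - start >= self.min_bin_size:
                    r = seg_rmse(start, end)
                    if prev is None or r > prev:
                        # never split a tie group of equal DM values
                        while end < n and d[end] == d[end - 1]:
                            end += 1
                        closed = True
            bounds.append(end)
            prev = seg_rmse(start, end)
            start = end

        # trailing remainder (< min_bin_size, unclosed) merges into the last bin
        if len(bounds) > 1 and bounds[-1] - bounds[-2] < self.min_bin_size:
            bounds.pop(-2)
        # terminal bin closed only by the end of data may undercut its
        # predecessor; merge backward until the RMSE sequence is monotone
        while len(bounds) > 1:
            lo = bounds[-3] if len(bounds) > 2 else 0
            if seg_rmse(bounds[-2], bounds[-1]) < seg_rmse(lo, bounds[-2]):
                bounds.pop(-2)
            else:
                break

        starts = [0] + bounds[:-1]
        table = pd.DataFrame(
            {
                "bin": np.arange(len(bounds)),
                "dm_min": [d[a] for a in starts],
                "dm_max": [d[b - 1] for b in bounds],
                "n": [b - a for a, b in zip(starts, bounds)],
                "rmse": [seg_rmse(a, b) for a, b in zip(starts, bounds)],
            }
        )
        table["threshold"] = self.z * table["rmse"]
        return BBAResults(bin_table=table, z=self.z, _fit_dm=self.dm,
                          _fit_err=self.abs_error)


@dataclass
class BBAResults:
    """Fitted bin table plus assignment and flagging against it.

    ``bin_table`` columns: ``bin``, ``dm_min``, ``dm_max``, ``n``, ``rmse``
    (all in % where dimensional) and ``threshold`` (= z x rmse).
    """

    bin_table: pd.DataFrame
    z: float
    _fit_dm: np.ndarray = field(repr=False, default=None)
    _fit_err: np.ndarray = field(repr=False, default=None)

    @property
    def n_bins(self) -> int:
        return len(self.bin_table)

    def assign(self, dm) -> np.ndarray:
        """Bin index for each DM value (nearest terminal bin outside the range)."""
        dm = np.asarray(dm, dtype=float)
        uppers = self.bin_table["dm_max"].to_numpy()
        idx = np.searchsorted(uppers[:-1], dm, side="left")
        outside = int((dm > uppers[-1]).sum() + (dm < self.bin_table["dm_min"].iloc[0]).sum())
        if outside:
            logger.info("%d DM value(s) outside the fitted range; assigned to terminal bins",
                        outside)
        return idx

    def flag(
        self,
        dm=None,
        abs_error=None,
        y_exp=None,
        y_pred=None,
        split=None,
    ) -> "OutlierReport":
        """Flag compounds whose |error| strictly exceeds their bin's threshold.

        With no arguments the fitting data are flagged.  Supplying `y_exp`
        and `y_pred` adds clean-set Q2 to the summary; `split` labels pass
        through to the per-compound frame (Williams-plot export).
        """
        if dm is None:
            dm, abs_error = self._fit_dm, self._fit_err
        dm = np.asarray(dm, dtype=float)
        err = np.abs(np.asarray(abs_error, dtype=float))
        idx = self.assign(dm)
        thr = self.bin_table["threshold"].to_numpy()[idx]
        flagged = err > thr  # strict: an error exactly at threshold is kept

        frame = pd.DataFrame(
            {"dm": dm, "abs_error": err, "bin": idx, "threshold": thr, "flagged": flagged}
        )
        if split is not None:
            frame.insert(2, "split", list(split))

        clean, bad = err[~flagged], err[flagged]
        summary = {
            "n": int(err.size),
            "n_outliers": int(flagged.sum()),
            "outlier_rmse": float(np.sqrt(np.mean(bad ** 2))) if bad.size else float("nan"),
            "clean_rmse": float(np.sqrt(np.mean(clean ** 2))) if clean.size else float("nan"),
            "full_rmse": float(np.sqrt(np.mean(err ** 2))),
        }
        if y_exp is not None and y_pred is not None:
            y_exp = np.asarray(y_exp, dtype=float)
            y_pred = np.asarray(y_pred, dtype=float)
            keep = ~flagged
            if keep.sum() >= 2 and np.unique(y_exp[keep]).size > 1:
                summary["clean_q2"] = coefficient_of_determination(
                    y_exp[keep], y_pred[keep], label="train_cv"
                ).r2_or_q2
        return OutlierReport(frame=frame, summary=summary)


@dataclass
class OutlierReport:
    """Per-compound flags plus set-level error statistics.

    ``frame`` carries the Williams-plot coordinates (``dm``, ``abs_error``),
    bin assignment, threshold and flag per compound; ``summary`` the outlier
    count and the clean/outlier/full RMSEs (and clean-set Q2 when activities
    were supplied).
    """

    frame: pd.DataFrame
    summary: dict

    @property
    def flagged_ids(self) -> np.ndarray:
        return self.frame.index.to_numpy()[self.frame["flagged"].to_numpy()]


# ----------------------------------------------------------------------
# functional façade


def fit_bins(dm, abs_error, min_bin_size: int = 50, z: float = 3.0) -> BBAResults:
    """Fit DM bins (see :class:`BinBasedAveraging`)."""
    return BinBasedAveraging(dm, abs_error, min_bin_size=min_bin_size, z=z).fit()


def flag_outliers(dm, abs_error, bins: BBAResults, z: float | None = None) -> OutlierReport:
    """Flag outliers against fitted `bins`; `z` overrides the fitted multiplier."""
    if z is not None and z != bins.z:
        table = bins.bin_table.copy()
        table["threshold"] = z * table["rmse"]
        bins = BBAResults(bin_table=table, z=z, _fit_dm=bins._fit_dm, _fit_err=bins._fit_err)
    return bins.flag(dm, abs_error)


def ad_threshold(training_dm, coverage: float = 0.9) -> float:
    """DM cutoff containing `coverage` of the training set.

    The empirical order statistic: the ``ceil(coverage * n)``-th smallest
    training DM value (no interpolation).  Compounds with DM at or below the
    cutoff are inside the AD.
    """
    dm = np.asarray(training_dm, dtype=float)
    if dm.size == 0:
        raise ValidationError("training_dm is empty")
    if not 0.0 < coverage <= 1.0:
        raise ValidationError(f"coverage must be in (0, 1], got {coverage}")
    k = int(math.ceil(coverage * dm.size))
    return float(np.sort(dm, kind="stable")[k - 1])


def cross_model_outliers(flag_sets: Sequence[Iterable], min_models: int = 3) -> set:
    """Ids flagged as outliers by at least `min_models` of the given sets.

    Compounds flagged consistently across independently trained models are
    more likely true data problems than model-specific noise.
    """
    if min_models < 1:
        raise ValidationError("min_models must be >= 1")
    counts: dict = {}
    for s in flag_sets:
        for cid in set(s):
            counts[cid] = counts.get(cid, 0) + 1
    return {cid for cid, c in counts.items() if c >= min_models}
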
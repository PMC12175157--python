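"""Consensus averaging of multi-model predictions, with and without AD constraints.

Two consensus modes are implemented, following the unweighted-averaging
scheme used throughout multi-team blind-challenge evaluations:

mode I
    Unweighted mean over all non-missing model predictions per compound.
mode II
    Unweighted mean over predictions of models whose applicability domain
    (AD) contains the compound; the consensus is defined only when at least
    ``min_models`` models cover it (default 1: one covering model suffices).

A stringency sweep raises ``min_models`` from permissive to conservative and
records the accuracy/coverage trade-off.  A Grubbs-refined variant drops, per
compound, the single model prediction that fails Grubbs' two-sided outlier
test before averaging.

The cross-model STD reported alongside the consensus is the sample standard
deviation of the averaged predictions - the ensemble-disagreement
distance-to-model statistic used by the outlier analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .metrics import MetricReport, coefficient_of_determination, grubbs_flag, rmse
from .tables import PredictionTable

logger = logging.getLogger("qsarcons")

__all__ = ["ConsensusModel", "ConsensusResults", "stringency_sweep", "grubbs_refined_consensus"]


class ConsensusModel:
    """Unweighted consensus of an ensemble of regression models.

    Parameters
    ----------
    table : PredictionTable
        Per-compound predictions; mode II additionally requires AD flags for
        every model.
    mode : {"I", "II"}
        Averaging rule (see module docstring).
    min_models : int
        Mode II only: minimum number of covering models for the consensus to
        be defined for a compound.
    grubbs_alpha : float, optional
        If set, per-compound Grubbs refinement at this significance level is
        applied before averaging (requires >= 3 models; with fewer the plain
        mode-I mean is used and a warning logged).

    Examples
    --------
    >>> res = ConsensusModel(table, mode="II", min_models=2).fit()
    >>> res.metrics("test").rmse
    """

    def __init__(
        self,
        table: PredictionTable,
        mode: str = "I",
        min_models: int = 1,
        grubbs_alpha: float | None = None,
    ):
        if mode not in ("I", "II"):
            raise ValidationError(f"mode must be 'I' or 'II', got {mode!r}")
        if min_models < 1:
            raise ValidationError("min_models must be >= 1")
        if not table.models:
            raise ValidationError("table has no models")
        if mode == "II" and not table.has_ad():
            missing = [m for m in table.models if not table.has_ad(m)]
            raise ValidationError(
                f"mode II requires AD flags for every model; missing for {missing}"
            )
        if grubbs_alpha is not None and mode == "II":
            raise ValidationError("Grubbs refinement is defined for mode I averaging")
        self.table = table
        self.mode = mode
        self.min_models = int(min_models)
        self.grubbs_alpha = grubbs_alpha

    def fit(self) -> "ConsensusResults":
        """Compute per-compound consensus predictions and disagreement STDs."""
        table = self.table
        preds = table.predictions().to_numpy(dtype=float)
        n, m = preds.shape
        covered = np.isfinite(preds)
        if self.mode == "II":
            covered &= table.ad_flags().to_numpy(dtype=bool)
        n_cov = covered.sum(axis=1)

        consensus = np.full(n, np.nan)
        cross_std = np.full(n, np.nan)
        dropped = np.zeros(n, dtype=bool)

        if self.grubbs_alpha is not None and m < 3:
            logger.warning(
                "Grubbs refinement needs >= 3 models (have %d); falling back to mode I", m
            )

        if self.grubbs_alpha is not None and m >= 3:
            for i in range(n):
                vals = preds[i, covered[i]]
                if vals.size == 0:
                    continue
                if vals.size >= 3:
                    flagged = grubbs_flag(vals, self.grubbs_alpha)
                    if flagged is not None:
                        vals = np.delete(vals, flagged)
                        dropped[i] = True
                consensus[i] = vals.mean()
                cross_std[i] = vals.std(ddof=1) if vals.size > 1 else np.nan
            n_used = n_cov - dropped.astype(int)
        else:
            threshold = self.min_models if self.mode == "II" else 1
            defined = n_cov >= threshold
            with np.errstate(invalid="ignore"):
                masked = np.where(covered, preds, np.nan)
                consensus[defined] = np.nanmean(masked[defined], axis=1)
                multi = defined & (n_cov > 1)
                cross_std[multi] = np.nanstd(masked[multi], axis=1, ddof=1)
            n_used = np.where(defined, n_cov, 0)

        none_at_all = np.isfinite(preds).sum(axis=1) == 0
        if none_at_all.any():
            ids = table.df["compound_id"][none_at_all].tolist()
            logger.warning("excluded %d compound(s) with no prediction: %s", len(ids), ids[:5])

        frame = pd.DataFrame(
            {
                "compound_id": table.df["compound_id"],
                "y_exp": table.df["y_exp"],
                "split": table.df["split"],
                "consensus": consensus,
                "cross_std": cross_std,
                "n_models_used": n_used.astype(int),
            }
        )
        return ConsensusResults(frame, mode=self.mode, min_models=self.min_models,
                                n_models=m, grubbs_alpha=self.grubbs_alpha,
                                grubbs_dropped=int(dropped.sum()))


@dataclass
class ConsensusResults:
    """Fitted consensus predictions plus evaluation helpers.

    ``frame`` has one row per compound: ``compound_id``, ``y_exp``,
    ``split``, ``consensus`` (NaN where undefined), ``cross_std`` and
    ``n_models_used``.
    """

    frame: pd.DataFrame
    mode: str
    min_models: int
    n_models: int
    grubbs_alpha: float | None = None
    grubbs_dropped: int = 0

    def _rows(self, split: str | None) -> pd.DataFrame:
        df = self.frame
        if split is not None:
            df = df[df["split"] == split]
        return df

    @property
    def predictions(self) -> pd.Series:
        return self.frame.set_index("compound_id")["consensus"]

    def coverage(self, split: str | None = None) -> float:
        """Percent of compounds (in `split`) with a defined consensus."""
        df = self._rows(split)
        if len(df) == 0:
            return float("nan")
        return float(100.0 * df["consensus"].notna().mean())

    def metrics(self, split: str | None = None) -> MetricReport:
        """RMSE and R2/Q2 over compounds with a defined consensus."""
        df = self._rows(split)
        df = df[df["consensus"].notna()]
        label = "train_cv" if split == "train" else "test"
        return coefficient_of_determination(df["y_exp"], df["consensus"], label=label)

    def rmse(self, split: str | None = None) -> float:
        df = self._rows(split)
        df = df[df["consensus"].notna()]
        return rmse(df["y_exp"], df["consensus"])

    def summary(self) -> str:
        """Plain-text summary table across splits."""
        lines = [
            f"Consensus mode {self.mode} "
            f"({self.n_models} models, min_models={self.min_models}"
            + (f", Grubbs alpha={self.grubbs_alpha}, {self.grubbs_dropped} dropped" if self.grubbs_alpha else "")
            + ")",
            f"{'split':<12}{'n':>6}{'coverage %':>12}{'RMSE %':>10}{'R2/Q2':>8}",
        ]
        for split in ("train", "leaderboard", "test"):
            df = self._rows(split)
            if len(df) == 0:
                continue
            defined = df[df["consensus"].notna()]
            if len(defined) >= 2 and defined["y_exp"].nunique() > 1:
                rep = self.metrics(split)
                lines.append(
                    f"{split:<12}{len(df):>6}{self.coverage(split):>12.1f}"
                    f"{rep.rmse:>10.2f}{rep.r2_or_q2:>8.3f}"
                )
            else:
                lines.append(f"{split:<12}{len(df):>6}{self.coverage(split):>12.1f}"
                             f"{'--':>10}{'--':>8}")
        return "\n".join(lines)


def stringency_sweep(
    table: PredictionTable,
    min_models_range=None,
    split: str | None = "test",
) -> pd.DataFrame:
    """Accuracy/coverage trade-off as the AD stringency rises.

    One row per ``min_models`` value with R2, RMSE and coverage (% of
    compounds in `split` with a defined mode-II consensus).  The default
    range is 2..M (permissive to conservative); coverage is non-increasing
    in ``min_models`` by construction.  Rows whose covered set is empty or
    degenerate carry NaN metrics.
    """
    if not table.has_ad():
        raise ValidationError("stringency sweep requires AD flags for all models")
    if min_models_range is None:
        min_models_range = range(2, len(table.models) + 1)
    rows = []
    for k in min_models_range:
        res = ConsensusModel(table, mode="II", min_models=int(k)).fit()
        df = res._rows(split)
        defined = df[df["consensus"].notna()]
        if len(defined) >= 2 and defined["y_exp"].nunique() > 1:
            rep = res.metrics(split)
            r2, err = rep.r2_or_q2, rep.rmse
        else:
            r2, err = np.nan, np.nan
        rows.append(
            {"min_models": int(k), "r2": r2, "rmse": err, "coverage": res.coverage(split)}
        )
    return pd.DataFrame(rows)


def grubbs_refined_consensus(table: PredictionTable, alpha: float = 0.1) -> ConsensusResults:
    """Mode-I consensus with per-compound Grubbs exclusion at level `alpha`."""
    return ConsensusModel(table, mode="I", grubbs_alpha=alpha).fit()
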
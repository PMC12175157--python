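"""The in-memory container for multi-model prediction ensembles.

A :class:`PredictionTable` holds, per compound, the experimental activity
(`y_exp`, in % probe displacement), a data-split label and one prediction
column per model, plus optional per-model ensemble standard deviations
(distance-to-model proxies) and applicability-domain flags.  It is a thin,
validated wrapper around a :class:`pandas.DataFrame`; all analysis modules
consume it.

Column contract
---------------
``compound_id``
    Unique token per compound.
``smiles``
    Optional structure string (never interpreted by the statistical core).
``y_exp``
    Experimental activity in %.
``split``
    One of ``train`` / ``leaderboard`` / ``test``.
``pred_<m>``
    Prediction of model *m* in %; an empty cell marks a compound the model
    does not cover.
``std_<m>``
    Optional: standard deviation of model *m*'s sub-ensemble predictions
    (its "Consensus-STD"), non-negative, in %.
``in_ad_<m>``
    Optional: 1 if the compound lies inside model *m*'s applicability
    domain, else 0.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import TableFormatError

SPLITS = ("train", "leaderboard", "test")
PRED_PREFIX = "pred_"
STD_PREFIX = "std_"
AD_PREFIX = "in_ad_"


class PredictionTable:
    """Validated per-compound table of experimental activities and model predictions.

    Parameters
    ----------
    df : pandas.DataFrame
        A frame following the column contract described in the module
        docstring.  Model names are inferred from the ``pred_*`` columns.

    Raises
    ------
    TableFormatError
        On duplicate compound ids, unknown split tokens, non-numeric
        activities, negative standard deviations or non-binary AD flags.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = _validate_frame(df.copy().reset_index(drop=True))

    # ------------------------------------------------------------------
    # construction helpers
    @classmethod
    def from_arrays(
        cls,
        compound_id: Sequence[str],
        y_exp: np.ndarray,
        predictions: dict[str, np.ndarray],
        split: Sequence[str] | str = "train",
        stds: dict[str, np.ndarray] | None = None,
        ad_flags: dict[str, np.ndarray] | None = None,
        smiles: Sequence[str] | None = None,
    ) -> "PredictionTable":
        """Assemble a table from parallel arrays (one entry per compound)."""
        n = len(compound_id)
        data: dict[str, object] = {"compound_id": list(compound_id)}
        if smiles is not None:
            data["smiles"] = list(smiles)
        data["y_exp"] = np.asarray(y_exp, dtype=float)
        data["split"] = [split] * n if isinstance(split, str) else list(split)
        for name, values in predictions.items():
            data[PRED_PREFIX + name] = np.asarray(values, dtype=float)
        for name, values in (stds or {}).items():
            data[STD_PREFIX + name] = np.asarray(values, dtype=float)
        for name, values in (ad_flags or {}).items():
            data[AD_PREFIX + name] = np.asarray(values, dtype=int)
        return cls(pd.DataFrame(data))

    # ------------------------------------------------------------------
    # introspection
    @property
    def models(self) -> list[str]:
        """Model names, in column order."""
        return [c[len(PRED_PREFIX):] for c in self.df.columns if c.startswith(PRED_PREFIX)]

    @property
    def n_compounds(self) -> int:
        return len(self.df)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.df)

    def has_std(self, model: str) -> bool:
        return STD_PREFIX + model in self.df.columns

    def has_ad(self, model: str | None = None) -> bool:
        """True if AD flags are present for `model` (or for every model)."""
        if model is not None:
            return AD_PREFIX + model in self.df.columns
        return all(AD_PREFIX + m in self.df.columns for m in self.models)

    # ------------------------------------------------------------------
    # views
    def predictions(self) -> pd.DataFrame:
        """(n_compounds, n_models) frame of predictions, columns = model names."""
        frame = self.df[[PRED_PREFIX + m for m in self.models]].copy()
        frame.columns = self.models
        return frame

    def stds(self) -> pd.DataFrame:
        """Per-model ensemble STD columns that are present (may be empty)."""
        present = [m for m in self.models if self.has_std(m)]
        frame = self.df[[STD_PREFIX + m for m in present]].copy()
        frame.columns = present
        return frame

    def ad_flags(self) -> pd.DataFrame:
        """Per-model boolean AD masks that are present (may be empty)."""
        present = [m for m in self.models if AD_PREFIX + m in self.df.columns]
        frame = self.df[[AD_PREFIX + m for m in present]].astype(bool)
        frame.columns = present
        return frame

    def subset(self, split: str) -> "PredictionTable":
        """Rows belonging to one data split, as a new table."""
        if split not in SPLITS:
            raise TableFormatError(f"unknown split {split!r}; expected one of {SPLITS}")
        return PredictionTable(self.df[self.df["split"] == split])

    def y(self, split: str | None = None) -> np.ndarray:
        frame = self.df if split is None else self.df[self.df["split"] == split]
        return frame["y_exp"].to_numpy(dtype=float)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("compound_id", "y_exp", "split"):
        if col not in df.columns:
            raise TableFormatError(f"missing required column {col!r}")

    dup = df["compound_id"][df["compound_id"].duplicated()]
    if len(dup):
        raise TableFormatError(f"duplicate compound_id: {dup.iloc[0]!r}")

    bad_split = set(df["split"].unique()) - set(SPLITS)
    if bad_split:
        raise TableFormatError(
            f"unknown split token(s) {sorted(bad_split)!r}; expected {SPLITS}"
        )

    y = pd.to_numeric(df["y_exp"], errors="coerce")
    bad = y.isna() & df["y_exp"].notna() | df["y_exp"].isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TableFormatError(
            f"non-numeric or missing activity in row {row} "
            f"(compound_id={df['compound_id'].iloc[row]!r})"
        )
    df["y_exp"] = y.astype(float)

    models = [c[len(PRED_PREFIX):] for c in df.columns if c.startswith(PRED_PREFIX)]
    if not models:
        raise TableFormatError("table has no pred_* columns")
    for m in models:
        df[PRED_PREFIX + m] = pd.to_numeric(df[PRED_PREFIX + m], errors="raise")
        scol, acol = STD_PREFIX + m, AD_PREFIX + m
        if scol in df.columns:
            df[scol] = pd.to_numeric(df[scol], errors="raise")
            if (df[scol].dropna() < 0).any():
                raise TableFormatError(f"negative values in {scol}")
        if acol in df.columns:
            vals = set(pd.unique(df[acol].dropna()))
            if not vals <= {0, 1, True, False}:
                raise TableFormatError(f"{acol} must be 0/1")
            df[acol] = df[acol].astype(int)
    # orphan std_/in_ad_ columns (no matching prediction column) are a contract
    # violation: they silently drop out of every analysis otherwise
    for c in df.columns:
        for prefix in (STD_PREFIX, AD_PREFIX):
            if c.startswith(prefix) and c[len(prefix):] not in models:
                raise TableFormatError(f"column {c!r} has no matching pred_ column")
    return df


def infer_models(columns: Iterable[str]) -> list[str]:
    """Model names implied by a set of column names."""
    return [c[len(PRED_PREFIX):] for c in columns if c.startswith(PRED_PREFIX)]
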
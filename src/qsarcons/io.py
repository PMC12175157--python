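"""Reading and writing the delimited interchange formats.

All files are comma-delimited UTF-8 text with a header row and a decimal
point.  Numeric payloads round-trip at full precision (values are written
with ``repr`` fidelity).  Three formats are handled:

* prediction tables (see :mod:`qsarcons.tables` for the column contract),
* 0/1 bit matrices with a leading ``compound_id`` column and one column per
  bit label,
* result tables, one CSV per named result.

Run configurations are YAML documents mirroring
:class:`~qsarcons.synthetic.SyntheticConfig` plus per-stage parameters.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .exceptions import TableFormatError
from .synthetic import ActivityMixture, SyntheticConfig
from .tables import PredictionTable

__all__ = [
    "read_prediction_table",
    "write_prediction_table",
    "read_bit_matrix",
    "write_bit_matrix",
    "write_results",
    "read_config",
    "write_config",
    "read_smiles",
]


def read_prediction_table(path) -> PredictionTable:
    """Read a prediction table CSV.

    Model names are inferred from the ``pred_*`` columns; missing ``std_*``
    or ``in_ad_*`` columns are recorded as absent rather than defaulted.
    Duplicate compound ids, unknown split tokens and non-numeric activities
    raise :class:`TableFormatError` naming the offending entry.
    """
    df = pd.read_csv(path, dtype={"compound_id": str}, float_precision="round_trip")
    return PredictionTable(df)


def write_prediction_table(table: PredictionTable, path) -> None:
    """Write a prediction table as CSV (full float precision)."""
    table.df.to_csv(path, index=False)


def read_bit_matrix(path) -> pd.DataFrame:
    """Read a 0/1 bit matrix CSV indexed by ``compound_id``."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    if "compound_id" not in df.columns:
        raise TableFormatError("bit matrix must have a compound_id column")
    df = df.set_index("compound_id")
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise TableFormatError("bit matrix entries must be 0/1")
    return df.astype(np.int8)


def write_bit_matrix(matrix: pd.DataFrame, path, compound_ids=None) -> None:
    """Write a 0/1 bit matrix with a header row of bit labels."""
    out = matrix.copy()
    if compound_ids is not None:
        out.insert(0, "compound_id", list(compound_ids))
        out.to_csv(path, index=False)
    elif out.index.name == "compound_id":
        out.to_csv(path, index=True)
    else:
        out.insert(0, "compound_id", [str(i) for i in out.index])
        out.to_csv(path, index=False)


def write_results(tables: Mapping[str, pd.DataFrame], out_dir) -> list[str]:
    """Write one CSV per result table into `out_dir`; returns the paths.

    An empty mapping writes nothing and succeeds.  Re-running with identical
    inputs produces identical files (stable column and row order).
    """
    paths = []
    if tables:
        os.makedirs(out_dir, exist_ok=True)
    for name in tables:
        path = os.path.join(out_dir, f"{name}.csv")
        tables[name].to_csv(path, index=False)
        paths.append(path)
    return paths


def read_smiles(path) -> pd.DataFrame:
    """Read one-SMILES-per-line text; an optional second column is an id.

    Returns a frame with columns ``smiles`` and ``compound_id`` (generated
    sequentially when absent).
    """
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            rows.append((parts[0], parts[1] if len(parts) > 1 else f"S{i:05d}"))
    if not rows:
        raise TableFormatError(f"no SMILES found in {path}")
    return pd.DataFrame(rows, columns=["smiles", "compound_id"])


# ----------------------------------------------------------------------
# configuration


def config_to_dict(cfg: SyntheticConfig) -> dict:
    mix = cfg.activity_mixture
    return {
        "n_compounds": cfg.n_compounds,
        "n_models": cfg.n_models,
        "n_submodels_per_model": cfg.n_submodels_per_model,
        "activity_mixture": {
            "weights": list(mix.weights),
            "means": list(mix.means),
            "sds": list(mix.sds),
        },
        "activity_range": list(cfg.activity_range),
        "error_sd_base": cfg.error_sd_base,
        "error_correlation": cfg.error_correlation,
        "difficulty_spread": cfg.difficulty_spread,
        "experimental_noise_sd": cfg.experimental_noise_sd,
        "outlier_fraction": cfg.outlier_fraction,
        "outlier_error_shift": cfg.outlier_error_shift,
        "n_substructure_bits": cfg.n_substructure_bits,
        "planted_effect_bits": [list(t) for t in cfg.planted_effect_bits],
        "planted_bit_support": cfg.planted_bit_support,
        "ad_coverage_per_model": (
            cfg.ad_coverage_per_model
            if np.isscalar(cfg.ad_coverage_per_model)
            else list(cfg.ad_coverage_per_model)
        ),
        "fingerprint_bits": cfg.fingerprint_bits,
        "seed": cfg.seed,
    }


def config_from_dict(d: Mapping) -> SyntheticConfig:
    d = dict(d)
    if "activity_mixture" in d:
        mix = d["activity_mixture"]
        d["activity_mixture"] = ActivityMixture(
            weights=tuple(mix["weights"]),
            means=tuple(mix["means"]),
            sds=tuple(mix["sds"]),
        )
    if "activity_range" in d:
        d["activity_range"] = tuple(d["activity_range"])
    if "planted_effect_bits" in d:
        d["planted_effect_bits"] = tuple(
            (int(b), float(f)) for b, f in d["planted_effect_bits"]
        )
    if "ad_coverage_per_model" in d and not np.isscalar(d["ad_coverage_per_model"]):
        d["ad_coverage_per_model"] = tuple(d["ad_coverage_per_model"])
    cfg = SyntheticConfig(**d)
    cfg.validate()
    return cfg


def read_config(path) -> dict:
    """Read a YAML run configuration.

    The optional ``synthetic`` section is parsed into a
    :class:`SyntheticConfig`; other sections (per-stage parameters) pass
    through as plain mappings.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh) or {}
    if "synthetic" in doc:
        doc["synthetic"] = config_from_dict(doc["synthetic"])
    return doc


def write_config(doc: Mapping, path) -> None:
    out = dict(doc)
    if isinstance(out.get("synthetic"), SyntheticConfig):
        out["synthetic"] = config_to_dict(out["synthetic"])
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(out, fh, sort_keys=False)
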
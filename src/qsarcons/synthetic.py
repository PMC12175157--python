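"""Synthetic prediction ensembles with the statistical structure the analysis assumes.

The generator emulates a blind-challenge evaluation setting: one experimental
activity per compound (% probe displacement, concentrated in the 0-30% region
of the -41.6..110.9% range), M models whose errors are correlated and
heteroscedastic, per-model sub-ensembles whose spread yields a distance-to-model
statistic (the ensemble STD), per-model applicability-domain masks tied to that
spread, planted low-STD/high-error outliers (bad experimental values), and
binary substructure / fingerprint matrices with optional planted error effects.

Error model
-----------
Each compound *i* carries a latent difficulty scale ``s_i = exp(N(0, spread))``
shared by all models.  Model *m*'s error is::

    e_im = sd_base * s_i * k_i * (sqrt(rho) * u_i + sqrt(1 - rho) * v_im)

with ``u_i`` shared across models, ``v_im`` model-specific and ``rho`` the
pairwise inter-model error correlation; ``k_i`` multiplies the error SD for
compounds carrying a planted substructure bit.  Sub-model predictions scatter
around the model prediction with SD ``sd_base * s_i`` and are mean-centred, so
the stored prediction is exactly their mean and the error correlation between
any two models is exactly ``rho``.

Planted outliers perturb the *experimental* value (not the predictions) by
``outlier_error_shift``: every model then mispredicts them by about the shift
while their ensemble STD stays at its baseline level - the low-uncertainty /
high-error signature of a data problem rather than a modelling problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, ValidationError
from .tables import PredictionTable

__all__ = [
    "ActivityMixture",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_dataset",
    "split_dataset",
]

ACTIVITY_RANGE = (-41.6, 110.9)


@dataclass(frozen=True)
class ActivityMixture:
    """Truncated normal mixture on the activity axis (% units).

    The default two-component mixture (weights 0.8/0.2, means 15/60,
    SDs 10/25, truncated to the observed activity range) places most
    compounds in the 0-30% region with a long active tail.
    """

    weights: tuple[float, ...] = (0.8, 0.2)
    means: tuple[float, ...] = (15.0, 60.0)
    sds: tuple[float, ...] = (10.0, 25.0)

    def validate(self) -> None:
        k = len(self.weights)
        if not (len(self.means) == len(self.sds) == k) or k == 0:
            raise ConfigError("mixture weights/means/sds must have equal nonzero length")
        w = np.asarray(self.weights, dtype=float)
        if not np.isfinite(w).all() or (w < 0).any():
            raise ConfigError("mixture weights must be finite and non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ConfigError(f"mixture weights must sum to 1, got {w.sum()}")
        if (np.asarray(self.sds, dtype=float) <= 0).any():
            raise ConfigError("mixture sds must be positive")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic ensemble generator.

    Attributes
    ----------
    n_compounds, n_models, n_submodels_per_model : int
        Problem sizes; the challenge setting is 1512 compounds and 9 models,
        each model carrying a sub-ensemble (>= 2 members) that yields its
        ensemble-STD column.
    activity_mixture : ActivityMixture
        Experimental-activity distribution, truncated to `activity_range`.
    error_sd_base : float
        Baseline per-model error SD in % (scale of the individual-model RMSE).
    error_correlation : float
        Pairwise correlation of any two models' error vectors, in [0, 1].
    difficulty_spread : float
        Log-normal sigma of the per-compound error scale; 0 gives
        homoscedastic errors.
    experimental_noise_sd : float
        Optional extra measurement noise on the recorded activity (%); kept
        as a parameter because the assay's inherent uncertainty is unknown.
    outlier_fraction, outlier_error_shift : float
        Each compound independently becomes a planted outlier with this
        probability; its recorded activity is shifted by the given % amount
        (direction chosen to stay within `activity_range`).
    n_substructure_bits : int
        Number of random substructure columns; per-bit prevalence is drawn
        uniformly from 2-30%.
    planted_effect_bits : sequence of (bit index, error multiplier)
        Bits whose carriers get their error SD multiplied by the factor
        (>1 degrades, <1 improves predictions for those compounds).
    planted_bit_support : int or None
        If set, planted bits are placed in exactly this many random
        compounds; otherwise their prevalence is drawn like any other bit.
    ad_coverage_per_model : float or sequence of float
        Fraction of compounds inside each model's applicability domain,
        in (0, 1]; AD membership tracks low ensemble STD with noise, so
        masks are heterogeneous but informative.
    fingerprint_bits : int
        Width of the similarity fingerprint matrix (default 1024).
    seed : int
        Master seed; all randomness flows from it through one generator.
    """

    n_compounds: int = 1512
    n_models: int = 9
    n_submodels_per_model: int = 10
    activity_mixture: ActivityMixture = field(default_factory=ActivityMixture)
    activity_range: tuple[float, float] = ACTIVITY_RANGE
    error_sd_base: float = 20.0
    error_correlation: float = 0.3
    difficulty_spread: float = 0.4
    experimental_noise_sd: float = 0.0
    outlier_fraction: float = 0.04
    outlier_error_shift: float = 60.0
    n_substructure_bits: int = 200
    planted_effect_bits: tuple[tuple[int, float], ...] = ()
    planted_bit_support: int | None = 100
    ad_coverage_per_model: float | tuple[float, ...] = 0.9
    fingerprint_bits: int = 1024
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_compounds", "n_models", "n_substructure_bits", "fingerprint_bits"):
            if int(getattr(self, name)) < 1:
                raise ConfigError(f"{name} must be a positive count")
        if self.n_submodels_per_model < 2:
            raise ConfigError("n_submodels_per_model must be >= 2 (ensemble STD needs it)")
        self.activity_mixture.validate()
        lo, hi = self.activity_range
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigError(f"invalid activity_range {self.activity_range}")
        for name in ("error_sd_base", "difficulty_spread", "experimental_noise_sd",
                     "outlier_error_shift"):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and non-negative, got {v}")
        if not 0.0 <= float(self.error_correlation) <= 1.0:
            raise ConfigError(f"error_correlation must be in [0, 1], got {self.error_correlation}")
        if not 0.0 <= float(self.outlier_fraction) <= 1.0:
            raise ConfigError(f"outlier_fraction must be in [0, 1], got {self.outlier_fraction}")
        for c in self._ad_coverages():
            if not 0.0 < c <= 1.0:
                raise ConfigError(f"ad_coverage_per_model values must be in (0, 1], got {c}")
        for bit, mult in self.planted_effect_bits:
            if not 0 <= int(bit) < self.n_substructure_bits:
                raise ConfigError(f"planted bit index {bit} outside 0..{self.n_substructure_bits - 1}")
            if not np.isfinite(mult) or mult <= 0:
                raise ConfigError(f"planted bit multiplier must be positive, got {mult}")
        if self.planted_bit_support is not None and self.planted_bit_support < 1:
            raise ConfigError("planted_bit_support must be a positive count or None")

    def _ad_coverages(self) -> tuple[float, ...]:
        c = self.ad_coverage_per_model
        if np.isscalar(c):
            return (float(c),) * self.n_models
        c = tuple(float(x) for x in c)
        if len(c) != self.n_models:
            raise ConfigError(
                f"ad_coverage_per_model has {len(c)} entries for {self.n_models} models"
            )
        return c


@dataclass
class SyntheticDataset:
    """A generated ensemble plus the ground truth the generator planted.

    Attributes
    ----------
    table : PredictionTable
        Activities, split labels, per-model predictions / STDs / AD flags.
    substructure_bits : pandas.DataFrame
        (compounds x bits) 0/1 matrix, columns ``bit_0000`` ...
    fingerprints : pandas.DataFrame
        (compounds x fingerprint_bits) 0/1 matrix for similarity analyses.
    planted_outlier : numpy.ndarray of bool
        True where the recorded activity was deliberately corrupted.
    planted_effects : dict[str, float]
        Substructure column name -> error-SD multiplier applied.
    submodel_predictions : numpy.ndarray
        (compounds, models, submodels) raw sub-ensemble predictions backing
        the ``std_*`` columns.
    config : SyntheticConfig
    """

    table: PredictionTable
    substructure_bits: pd.DataFrame
    fingerprints: pd.DataFrame
    planted_outlier: np.ndarray
    planted_effects: dict[str, float]
    submodel_predictions: np.ndarray
    config: SyntheticConfig

    @property
    def model_names(self) -> list[str]:
        return self.table.models


def _sample_activities(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    mix = cfg.activity_mixture
    lo, hi = cfg.activity_range
    comp = rng.choice(len(mix.weights), size=cfg.n_compounds, p=np.asarray(mix.weights))
    y = np.empty(cfg.n_compounds)
    for j, (mu, sd) in enumerate(zip(mix.means, mix.sds)):
        mask = comp == j
        a, b = (lo - mu) / sd, (hi - mu) / sd
        y[mask] = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=int(mask.sum()),
                                      random_state=rng)
    return y


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic ensemble dataset.

    Deterministic given ``config.seed``: two calls with the same config
    return byte-identical outputs.

    Raises
    ------
    ConfigError
        If any configuration value is non-finite or out of range.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n, m, k = cfg.n_compounds, cfg.n_models, cfg.n_submodels_per_model
    lo, hi = cfg.activity_range

    y_true = _sample_activities(cfg, rng)
    s = np.exp(rng.normal(0.0, cfg.difficulty_spread, size=n))

    # substructure bit matrix (planted bits overwrite their random column)
    prevalence = rng.uniform(0.02, 0.30, size=cfg.n_substructure_bits)
    bits = (rng.random((n, cfg.n_substructure_bits)) < prevalence).astype(np.int8)
    planted_effects: dict[str, float] = {}
    err_mult = np.ones(n)
    for bit, mult in cfg.planted_effect_bits:
        col = np.zeros(n, dtype=np.int8)
        if cfg.planted_bit_support is not None:
            support = min(int(cfg.planted_bit_support), n)
            col[rng.choice(n, size=support, replace=False)] = 1
        else:
            col = (rng.random(n) < prevalence[bit]).astype(np.int8)
        bits[:, bit] = col
        name = f"bit_{bit:04d}"
        planted_effects[name] = float(mult)
        err_mult = np.where(col == 1, err_mult * mult, err_mult)
    bit_frame = pd.DataFrame(
        bits, columns=[f"bit_{b:04d}" for b in range(cfg.n_substructure_bits)]
    )

    # correlated heteroscedastic model errors
    rho = cfg.error_correlation
    shared = rng.normal(size=n)
    specific = rng.normal(size=(n, m))
    scale = cfg.error_sd_base * s * err_mult
    errors = scale[:, None] * (np.sqrt(rho) * shared[:, None] + np.sqrt(1.0 - rho) * specific)

    # sub-ensembles: mean-centred scatter around the model centre, so the
    # stored prediction is exactly the sub-model mean
    centres = y_true[:, None] + errors
    spread = (cfg.error_sd_base * s)[:, None, None]
    w = rng.normal(size=(n, m, k))
    w -= w.mean(axis=2, keepdims=True)
    submodels = centres[:, :, None] + spread * w
    preds = submodels.mean(axis=2)
    stds = submodels.std(axis=2, ddof=1)

    # planted outliers: corrupt the recorded activity, not the predictions
    is_outlier = rng.random(n) < cfg.outlier_fraction
    sign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    # flip direction when the shift would leave the printed activity range
    sign = np.where(y_true + sign * cfg.outlier_error_shift > hi, -1.0, sign)
    sign = np.where(y_true + sign * cfg.outlier_error_shift < lo, 1.0, sign)
    y_exp = y_true.copy()
    y_exp[is_outlier] += (sign * cfg.outlier_error_shift)[is_outlier]
    if cfg.experimental_noise_sd > 0:
        y_exp = y_exp + rng.normal(0.0, cfg.experimental_noise_sd, size=n)
    y_exp = np.clip(y_exp, lo, hi)

    # AD masks: inside-AD tracks low ensemble STD with model-specific noise
    coverages = cfg._ad_coverages()
    ad = np.zeros((n, m), dtype=int)
    for j, cov in enumerate(coverages):
        score = stds[:, j] * np.exp(rng.normal(0.0, 0.3, size=n))
        n_in = max(1, int(round(cov * n)))
        inside = np.argsort(score, kind="stable")[:n_in]
        ad[inside, j] = 1

    # fingerprints: scaffold prototypes + per-compound bit flips
    n_proto = min(8, n)
    protos = (rng.random((n_proto, cfg.fingerprint_bits)) < 0.15)
    assign = rng.integers(0, n_proto, size=n)
    flip_p = rng.uniform(0.02, 0.25, size=n)
    flips = rng.random((n, cfg.fingerprint_bits)) < flip_p[:, None]
    fps = (protos[assign] ^ flips).astype(np.int8)
    fp_frame = pd.DataFrame(
        fps, columns=[f"fp_{b:04d}" for b in range(cfg.fingerprint_bits)]
    )

    model_names = [f"m{j + 1}" for j in range(m)]
    table = PredictionTable.from_arrays(
        compound_id=[f"CMPD{i:05d}" for i in range(n)],
        y_exp=y_exp,
        predictions={name: preds[:, j] for j, name in enumerate(model_names)},
        stds={name: stds[:, j] for j, name in enumerate(model_names)},
        ad_flags={name: ad[:, j] for j, name in enumerate(model_names)},
        split="train",
    )
    return SyntheticDataset(
        table=table,
        substructure_bits=bit_frame,
        fingerprints=fp_frame,
        planted_outlier=is_outlier,
        planted_effects=planted_effects,
        submodel_predictions=submodels,
        config=cfg,
    )


def split_dataset(
    ds: SyntheticDataset,
    fractions: Sequence[float] = (1012 / 1512, 200 / 1512, 300 / 1512),
    seed: int = 0,
) -> SyntheticDataset:
    """Assign train / leaderboard / test labels by largest-remainder allocation.

    Split sizes are the exact rounded shares of `fractions` (each within one
    compound of ``n * fraction``); assignment of compounds to splits is a
    seeded random permutation, reproducible under `seed`.
    """
    w = np.asarray(fractions, dtype=float)
    if w.shape != (3,) or (w < 0).any() or not np.isfinite(w).all():
        raise ValidationError("fractions must be three non-negative numbers")
    if abs(w.sum() - 1.0) > 1e-8:
        raise ValidationError(f"fractions must sum to 1, got {w.sum()}")
    n = ds.table.n_compounds
    target = w * n
    counts = np.floor(target).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(target - counts), kind="stable")
    for j in range(remainder):
        counts[order[j % 3]] += 1
    labels = np.repeat(np.array(["train", "leaderboard", "test"]), counts)
    rng = np.random.default_rng(seed)
    labels = labels[rng.permutation(n)]

    df = ds.table.df.copy()
    df["split"] = labels
    return replace(ds, table=PredictionTable(df))
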
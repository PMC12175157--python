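import numpy as np
import pytest
from scipy import stats

from qsarcons import (
    ConfigError,
    ConsensusModel,
    SyntheticConfig,
    ValidationError,
    generate_dataset,
    split_dataset,
)
from qsarcons.synthetic import ACTIVITY_RANGE, ActivityMixture


class TestGenerateDataset:
    def test_shape_contract(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=100, n_models=3, seed=7))
        assert ds.table.n_compounds == 100
        assert ds.table.models == ["m1", "m2", "m3"]
        assert ds.table.stds().shape == (100, 3)
        assert ds.table.ad_flags().shape == (100, 3)
        assert ds.substructure_bits.shape[0] == 100
        assert ds.fingerprints.shape == (100, SyntheticConfig().fingerprint_bits)

    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(n_compounds=80, n_models=3, seed=7)
        a, b = generate_dataset(cfg), generate_dataset(cfg)
        assert a.table.df.equals(b.table.df)
        assert a.substructure_bits.equals(b.substructure_bits)
        assert a.fingerprints.equals(b.fingerprints)
        assert np.array_equal(a.planted_outlier, b.planted_outlier)

    def test_different_seeds_differ(self):
        a = generate_dataset(SyntheticConfig(n_compounds=80, seed=1))
        b = generate_dataset(SyntheticConfig(n_compounds=80, seed=2))
        assert not a.table.df["y_exp"].equals(b.table.df["y_exp"])

    def test_planted_outlier_count_within_binomial_bound(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=2000, outlier_fraction=0.05, seed=3))
        lo, hi = stats.binom.ppf([0.005, 0.995], 2000, 0.05)
        assert lo <= ds.planted_outlier.sum() <= hi

    def test_activities_within_printed_range(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=3000, seed=5))
        y = ds.table.df["y_exp"]
        assert y.min() >= ACTIVITY_RANGE[0] and y.max() <= ACTIVITY_RANGE[1]
        # bulk of the distribution sits in the 0-30% region
        assert ((y > 0) & (y < 30)).mean() > 0.5

    def test_bit_matrices_binary(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=60, seed=9))
        assert set(np.unique(ds.substructure_bits)) <= {0, 1}
        assert set(np.unique(ds.fingerprints)) <= {0, 1}

    def test_std_equals_submodel_sample_sd_exactly(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=50, n_models=4, seed=2))
        recomputed = ds.submodel_predictions.std(axis=2, ddof=1)
        assert np.array_equal(ds.table.stds().to_numpy(), recomputed)

    def test_prediction_is_submodel_mean(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=50, n_models=4, seed=2))
        assert np.allclose(ds.table.predictions().to_numpy(),
                           ds.submodel_predictions.mean(axis=2))

    def test_error_correlation_converges(self):
        """Pairwise model-error correlation matches the configured value at large n."""
        cfg = SyntheticConfig(n_compounds=20000, n_models=3, error_correlation=0.5,
                              outlier_fraction=0.0, seed=11)
        ds = generate_dataset(cfg)
        errors = ds.table.predictions().to_numpy() - ds.table.df["y_exp"].to_numpy()[:, None]
        for i in range(3):
            for j in range(i + 1, 3):
                r = np.corrcoef(errors[:, i], errors[:, j])[0, 1]
                assert abs(r - 0.5) < 0.05

    def test_planted_outliers_carry_large_errors_at_baseline_std(self):
        cfg = SyntheticConfig(n_compounds=4000, outlier_fraction=0.05,
                              outlier_error_shift=60.0, seed=13)
        ds = generate_dataset(cfg)
        res = ConsensusModel(ds.table, mode="I").fit()
        err = np.abs(ds.table.df["y_exp"].to_numpy() - res.frame["consensus"].to_numpy())
        out = ds.planted_outlier
        assert err[out].mean() - err[~out].mean() >= 60.0 / 2
        # the corruption is in the recorded activity, so the DM stays at baseline
        dm = res.frame["cross_std"].to_numpy()
        assert abs(dm[out].mean() - dm[~out].mean()) < 0.2 * dm.mean()

    def test_ad_coverage_close_to_requested(self):
        cfg = SyntheticConfig(n_compounds=1000, ad_coverage_per_model=(0.5, 0.8, 0.95),
                              n_models=3, seed=4)
        ds = generate_dataset(cfg)
        got = ds.table.ad_flags().mean(axis=0).to_numpy()
        assert np.allclose(got, [0.5, 0.8, 0.95], atol=0.01)

    def test_planted_bit_has_exact_support(self):
        cfg = SyntheticConfig(n_compounds=500, planted_effect_bits=((3, 2.0),),
                              planted_bit_support=100, seed=21)
        ds = generate_dataset(cfg)
        assert ds.substructure_bits["bit_0003"].sum() == 100
        assert ds.planted_effects == {"bit_0003": 2.0}


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_compounds": 0},
            {"n_submodels_per_model": 1},
            {"error_correlation": 1.5},
            {"error_correlation": float("nan")},
            {"outlier_fraction": -0.1},
            {"error_sd_base": float("inf")},
            {"ad_coverage_per_model": 0.0},
            {"planted_effect_bits": ((999, 2.0),)},
            {"planted_effect_bits": ((0, -1.0),)},
            {"activity_mixture": ActivityMixture(weights=(0.5, 0.4))},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            generate_dataset(SyntheticConfig(**kwargs))


class TestSplitDataset:
    def test_all_train_under_unit_fraction(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=50, seed=1))
        out = split_dataset(ds, fractions=(1.0, 0.0, 0.0), seed=0)
        assert (out.table.df["split"] == "train").all()

    def test_challenge_proportions_recovered(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=1512, seed=1))
        out = split_dataset(ds, fractions=(1012 / 1512, 200 / 1512, 300 / 1512), seed=5)
        counts = out.table.df["split"].value_counts()
        assert abs(counts["train"] - 1012) <= 1
        assert abs(counts["leaderboard"] - 200) <= 1
        assert abs(counts["test"] - 300) <= 1

    def test_reproducible_labels(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=200, seed=1))
        a = split_dataset(ds, seed=3).table.df["split"]
        b = split_dataset(ds, seed=3).table.df["split"]
        assert a.equals(b)

    def test_rejects_bad_fractions(self):
        ds = generate_dataset(SyntheticConfig(n_compounds=20, seed=1))
        with pytest.raises(ValidationError):
            split_dataset(ds, fractions=(1012, 200, 300), seed=0)
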
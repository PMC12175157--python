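import numpy as np
import pandas as pd
import pytest

from qsarcons import (
    ConsensusModel,
    PredictionTable,
    SyntheticConfig,
    ValidationError,
    generate_dataset,
    grubbs_refined_consensus,
    rmse,
    stringency_sweep,
)


def one_compound_table(preds, ad=None):
    data = {"compound_id": ["x"], "y_exp": [20.0], "split": ["test"]}
    for i, p in enumerate(preds):
        data[f"pred_m{i + 1}"] = [float(p)]
    if ad is not None:
        for i, a in enumerate(ad):
            data[f"in_ad_m{i + 1}"] = [int(a)]
    return PredictionTable(pd.DataFrame(data))


class TestModeI:
    def test_mean_and_cross_std_by_hand(self):
        res = ConsensusModel(one_compound_table([10, 20, 30])).fit()
        assert res.frame["consensus"].iloc[0] == pytest.approx(20.0)
        assert res.frame["cross_std"].iloc[0] == pytest.approx(10.0)  # sample SD

    def test_single_model_passthrough(self):
        res = ConsensusModel(one_compound_table([42.0])).fit()
        assert res.frame["consensus"].iloc[0] == pytest.approx(42.0)

    def test_missing_prediction_skipped(self):
        table = one_compound_table([10, 20, 30])
        table.df.loc[0, "pred_m3"] = np.nan
        res = ConsensusModel(table).fit()
        assert res.frame["consensus"].iloc[0] == pytest.approx(15.0)
        assert res.frame["n_models_used"].iloc[0] == 2

    def test_idempotent_for_identical_models(self, rng):
        p = rng.normal(20, 10, size=30)
        table = PredictionTable.from_arrays(
            [f"c{i}" for i in range(30)], rng.normal(20, 10, 30),
            {"m1": p, "m2": p, "m3": p}, split="test",
        )
        res = ConsensusModel(table).fit()
        assert np.allclose(res.frame["consensus"], p)
        assert np.allclose(res.frame["cross_std"], 0.0)


class TestModeII:
    def test_ad_restricted_mean(self):
        res = ConsensusModel(one_compound_table([10, 20, 30], ad=[1, 1, 0]),
                             mode="II", min_models=1).fit()
        assert res.frame["consensus"].iloc[0] == pytest.approx(15.0)
        assert res.frame["n_models_used"].iloc[0] == 2

    def test_below_min_models_undefined(self):
        res = ConsensusModel(one_compound_table([10, 20, 30], ad=[1, 0, 0]),
                             mode="II", min_models=2).fit()
        assert np.isnan(res.frame["consensus"].iloc[0])
        assert res.frame["n_models_used"].iloc[0] == 0

    def test_requires_ad_flags(self):
        with pytest.raises(ValidationError, match="AD flags"):
            ConsensusModel(one_compound_table([10, 20]), mode="II")

    def test_all_true_ads_reproduce_mode_one(self, default_dataset):
        table = default_dataset.table
        df = table.df.copy()
        for m in table.models:
            df[f"in_ad_{m}"] = 1
        all_in = PredictionTable(df)
        a = ConsensusModel(table, mode="I").fit().frame["consensus"]
        b = ConsensusModel(all_in, mode="II", min_models=1).fit().frame["consensus"]
        assert np.allclose(a, b)


class TestConsensusBound:
    def test_rmse_never_exceeds_mean_individual_rmse(self):
        """Exact L2 triangle-inequality property of unweighted averaging."""
        for seed in range(5):
            ds = generate_dataset(SyntheticConfig(n_compounds=400, seed=seed))
            table = ds.table
            y = table.df["y_exp"]
            res = ConsensusModel(table, mode="I").fit()
            individual = [rmse(y, table.predictions()[m]) for m in table.models]
            assert res.rmse() <= np.mean(individual) + 1e-12


class TestStringencySweep:
    def test_crafted_masks_enumerated_coverage(self):
        # compounds covered by exactly 1, 2 and 3 models
        df = pd.DataFrame(
            {
                "compound_id": ["A", "B", "C"],
                "y_exp": [10.0, 20.0, 30.0],
                "split": ["test"] * 3,
                "pred_m1": [11.0, 21.0, 31.0],
                "pred_m2": [9.0, 19.0, 29.0],
                "pred_m3": [10.5, 20.5, 30.5],
                "in_ad_m1": [1, 1, 1],
                "in_ad_m2": [0, 1, 1],
                "in_ad_m3": [0, 0, 1],
            }
        )
        sweep = stringency_sweep(PredictionTable(df), min_models_range=[1, 2, 3])
        assert np.allclose(sweep["coverage"], [100.0, 200 / 3, 100 / 3])

    def test_full_coverage_when_all_inside(self, rng):
        n = 40
        table = PredictionTable.from_arrays(
            [f"c{i}" for i in range(n)], rng.normal(20, 10, n),
            {"m1": rng.normal(20, 10, n), "m2": rng.normal(20, 10, n)},
            split="test",
            ad_flags={"m1": np.ones(n, int), "m2": np.ones(n, int)},
        )
        sweep = stringency_sweep(table, min_models_range=[1, 2])
        assert (sweep["coverage"] == 100.0).all()

    def test_coverage_non_increasing(self, default_dataset):
        sweep = stringency_sweep(default_dataset.table,
                                 min_models_range=range(1, 10), split=None)
        assert (np.diff(sweep["coverage"]) <= 1e-12).all()

    def test_default_range_is_two_to_m(self, default_dataset):
        sweep = stringency_sweep(default_dataset.table)
        assert list(sweep["min_models"]) == list(range(2, 10))


class TestGrubbsRefinement:
    def test_extreme_model_excluded(self):
        res = grubbs_refined_consensus(one_compound_table([20, 21, 22, 19, 95]), alpha=0.1)
        assert res.frame["consensus"].iloc[0] == pytest.approx(20.5)
        assert res.grubbs_dropped == 1

    def test_no_extreme_equals_mode_one(self):
        table = one_compound_table([18, 20, 22, 21, 19])
        refined = grubbs_refined_consensus(table, alpha=0.1)
        plain = ConsensusModel(table, mode="I").fit()
        assert refined.frame["consensus"].iloc[0] == plain.frame["consensus"].iloc[0]

    def test_two_models_fall_back_to_plain_mean(self, caplog):
        table = one_compound_table([10, 50])
        with caplog.at_level("WARNING", logger="qsarcons"):
            res = grubbs_refined_consensus(table, alpha=0.1)
        assert res.frame["consensus"].iloc[0] == pytest.approx(30.0)
        assert any("Grubbs" in r.message for r in caplog.records)
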
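import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qsarcons import (
    ValidationError,
    activity_error_curve,
    bootstrap_rmse_ci,
    coefficient_of_determination,
    grubbs_flag,
    rmse,
)
from qsarcons.metrics import grubbs_critical_value


class TestRmse:
    @pytest.mark.parametrize(
        "y_exp, y_pred, expected",
        [
            ([0, 0], [3, 4], np.sqrt(25 / 2)),  # sqrt((9+16)/2)
            ([1.5, 2.5, -3.0], [1.5, 2.5, -3.0], 0.0),
            ([0, 10], [10, 0], 10.0),
        ],
    )
    def test_hand_computed(self, y_exp, y_pred, expected):
        assert rmse(y_exp, y_pred) == pytest.approx(expected, abs=1e-12)

    def test_rejects_mismatch_and_empty(self):
        with pytest.raises(ValidationError):
            rmse([1, 2], [1])
        with pytest.raises(ValidationError):
            rmse([], [])

    @given(
        res=st.lists(st.floats(-100, 100), min_size=1, max_size=30),
        scale=st.floats(0.1, 10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_symmetry_and_linear_scaling(self, res, scale):
        y = np.zeros(len(res))
        r = np.asarray(res)
        assert rmse(y, r) == pytest.approx(rmse(r, y))
        assert rmse(y, scale * r) == pytest.approx(scale * rmse(y, r), rel=1e-9)


class TestCoefficientOfDetermination:
    def test_perfect_prediction_is_one(self):
        rep = coefficient_of_determination([1, 2, 3], [1, 2, 3], label="test")
        assert rep.r2_or_q2 == pytest.approx(1.0)
        assert rep.metric_name == "R2"

    def test_mean_prediction_is_zero(self):
        y = np.array([0.0, 1.0, 2.0, 7.0])
        rep = coefficient_of_determination(y, np.full(4, y.mean()))
        assert rep.r2_or_q2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_half(self):
        rep = coefficient_of_determination([0, 1, 2], [0, 0, 2])
        assert rep.r2_or_q2 == pytest.approx(0.5)  # 1 - 1/2

    def test_constant_y_rejected(self):
        with pytest.raises(ValidationError):
            coefficient_of_determination([5, 5, 5], [4, 5, 6])

    def test_train_cv_label_gives_q2(self):
        rep = coefficient_of_determination([0, 1, 2], [0, 0, 2], label="train_cv")
        assert rep.metric_name == "Q2"

    def test_consistency_with_rmse(self, rng):
        """r2 must equal 1 - rmse^2 * n / TSS exactly (two code paths agree)."""
        y = rng.normal(20, 15, size=200)
        p = y + rng.normal(0, 5, size=200)
        rep = coefficient_of_determination(y, p)
        tss = np.sum((y - y.mean()) ** 2)
        assert rep.r2_or_q2 == pytest.approx(1 - rmse(y, p) ** 2 * len(y) / tss, rel=1e-12)
        assert rep.rmse == pytest.approx(rmse(y, p), rel=1e-12)


class TestBootstrapRmseCI:
    def test_zero_residuals_degenerate(self):
        assert bootstrap_rmse_ci([1, 2, 3], [1, 2, 3], n_boot=100, seed=0) == (0.0, 0.0)

    def test_single_compound_degenerate_at_abs_residual(self):
        lo, hi = bootstrap_rmse_ci([10.0], [7.0], n_boot=50, seed=0)
        assert lo == pytest.approx(3.0) and hi == pytest.approx(3.0)

    def test_reproducible_under_seed(self, rng):
        y = rng.normal(size=50)
        p = y + rng.normal(size=50)
        assert bootstrap_rmse_ci(y, p, seed=7) == bootstrap_rmse_ci(y, p, seed=7)

    def test_level_validated(self):
        with pytest.raises(ValidationError):
            bootstrap_rmse_ci([1, 2], [0, 0], level=1.5)

    def test_frequentist_coverage_of_true_rmse(self):
        """~95% of intervals over repeated N(0,20) residual draws contain 20."""
        master = np.random.default_rng(99)
        hits = 0
        reps = 100
        for _ in range(reps):
            res = master.normal(0, 20, size=400)
            lo, hi = bootstrap_rmse_ci(res, np.zeros(400), n_boot=400, level=0.95,
                                       seed=int(master.integers(2**31)))
            hits += lo <= 20.0 <= hi
        assert 0.88 <= hits / reps <= 1.0

    def test_width_shrinks_with_n(self):
        master = np.random.default_rng(5)
        widths = []
        for n in (100, 1000, 10000):
            res = master.normal(0, 20, size=n)
            lo, hi = bootstrap_rmse_ci(res, np.zeros(n), n_boot=500, seed=1)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]


class TestActivityErrorCurve:
    def test_flat_curve_for_constant_residual(self, rng):
        y = rng.uniform(0, 99.9, size=500)
        signs = np.where(rng.random(500) < 0.5, 1, -1)
        curve = activity_error_curve(y, y + 5 * signs, bin_width=10)
        filled = curve.rmse[curve.counts > 0]
        assert np.allclose(filled, 5.0)

    def test_bin_count_spans_observed_range(self, rng):
        y = rng.uniform(0, 100 - 1e-9, size=1000)
        curve = activity_error_curve(y, y, bin_width=10)
        assert len(curve.rmse) == 10
        assert curve.counts.sum() == 1000

    def test_heteroscedastic_errors_give_rising_curve(self):
        rng = np.random.default_rng(17)
        y = rng.uniform(0, 100, size=20000)
        p = y + rng.normal(0, 1 + 0.2 * y)
        curve = activity_error_curve(y, p, bin_width=10)
        assert curve.rmse[-1] > curve.rmse[0]
        assert (np.diff(curve.rmse) > 0).mean() > 0.8  # noisy but rising

    def test_rejects_nonpositive_width(self):
        with pytest.raises(ValidationError):
            activity_error_curve([1, 2], [1, 2], bin_width=0)


class TestGrubbs:
    def test_flags_single_extreme_value(self):
        values = [10.0] * 8 + [50.0]
        # G = 2.667 > critical 2.053 at alpha 0.1, n=9
        assert grubbs_flag(values, alpha=0.1) == 8

    def test_constant_vector_unflagged(self):
        assert grubbs_flag([4.0, 4.0, 4.0, 4.0]) is None

    def test_undefined_below_three(self):
        assert grubbs_flag([1.0, 99.0]) is None

    def test_moderate_spread_unflagged(self):
        assert grubbs_flag([18.0, 20.0, 22.0, 21.0, 19.0], alpha=0.1) is None

    @pytest.mark.parametrize("n, expected", [(5, 1.671), (9, 2.110), (20, 2.557)])
    def test_critical_value_frozen_references(self, n, expected):
        # two-sided single-outlier values at alpha = 0.10; cross-checked by a
        # 200k-draw Monte-Carlo null simulation (tail probability 0.100 each)
        assert grubbs_critical_value(n, 0.1) == pytest.approx(expected, abs=2e-3)

    def test_critical_value_calibrated_under_null(self):
        """P(G > critical value) is alpha for normal samples (simulation oracle)."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20000, 8))
        g = np.max(np.abs(x - x.mean(1, keepdims=True)), axis=1) / x.std(1, ddof=1)
        tail = (g > grubbs_critical_value(8, 0.1)).mean()
        assert abs(tail - 0.1) < 0.01
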
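"""Deming regression, Bland-Altman, predictive errors and ANCOVA."""

import numpy as np
import pandas as pd
import pytest
import scipy.odr
from hypothesis import given, settings, strategies as st

from dbsbias.agreement import (
    PairedMeasurements,
    ancova_slopes,
    bland_altman,
    compare_methods,
    deming_regression,
    predictive_errors,
)

X = np.array([0.21, 0.28, 0.33, 0.41, 0.47, 0.52, 0.58, 0.35, 0.44, 0.25])


class TestDeming:
    def test_identity_data(self):
        r = deming_regression(PairedMeasurements(X, X.copy()))
        assert r.slope == pytest.approx(1.0, rel=1e-12)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)

    def test_affine_recovery(self):
        r = deming_regression(PairedMeasurements(X, 2 * X + 1))
        assert r.slope == pytest.approx(2.0, rel=1e-12)
        assert r.intercept == pytest.approx(1.0, rel=1e-12)

    def test_slope_reciprocity_under_axis_swap(self):
        y = 1.3 * X + 0.05
        fwd = deming_regression(PairedMeasurements(X, y)).slope
        rev = deming_regression(PairedMeasurements(y, X)).slope
        assert fwd * rev == pytest.approx(1.0, rel=1e-12)

    def test_agrees_with_orthogonal_distance_regression(self, rng):
        """Independent oracle: scipy ODR with equal error weights."""
        x = X + rng.normal(0, 0.02, X.size)
        y = 1.4 * X + 0.1 + rng.normal(0, 0.02, X.size)
        ours = deming_regression(PairedMeasurements(x, y))
        odr = scipy.odr.ODR(
            scipy.odr.RealData(x, y),
            scipy.odr.unilinear,
            beta0=[1.0, 0.0],
        ).run()
        assert ours.slope == pytest.approx(odr.beta[0], rel=1e-6)
        assert ours.intercept == pytest.approx(odr.beta[1], rel=1e-5, abs=1e-8)

    def test_jackknife_ci_brackets_the_point_estimate(self, rng):
        x = X + rng.normal(0, 0.02, X.size)
        y = 1.2 * X + rng.normal(0, 0.02, X.size)
        r = deming_regression(PairedMeasurements(x, y))
        assert r.slope_ci[0] < r.slope < r.slope_ci[1]
        assert r.intercept_ci[0] < r.intercept < r.intercept_ci[1]

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ValueError):
            deming_regression(PairedMeasurements(np.full(5, 0.4), X[:5]))


class TestBlandAltman:
    def test_self_comparison_is_exactly_zero(self):
        r = bland_altman(PairedMeasurements(X, X.copy()))
        assert r.bias == 0.0
        assert r.loa == (0.0, 0.0)

    def test_symmetric_ten_percent_deviations(self):
        # two ±10% differences (plus a zero pair to meet the minimum n)
        ref = np.array([1.0, 1.0, 1.0])
        tst = np.array([21 / 19, 19 / 21, 1.0])  # +10%, -10% of pair means
        r = bland_altman(PairedMeasurements(ref, tst))
        d = r.differences
        assert d[0] == pytest.approx(10.0) and d[1] == pytest.approx(-10.0)
        two = d[:2]
        assert two.mean() == pytest.approx(0.0, abs=1e-9)
        assert two.std(ddof=1) == pytest.approx(14.14, abs=0.01)
        assert 1.96 * two.std(ddof=1) == pytest.approx(27.7, abs=0.02)

    def test_absolute_mode_bias_is_difference_of_means(self, rng):
        y = X + rng.normal(0, 0.05, X.size)
        r = bland_altman(PairedMeasurements(X, y), mode="absolute")
        assert r.bias == pytest.approx(y.mean() - X.mean(), rel=1e-12)

    def test_zero_pairwise_mean_rejected_in_percent_mode(self):
        with pytest.raises(ValueError):
            bland_altman(PairedMeasurements(np.array([1.0, -1.0, 2.0]),
                                            np.array([-1.0, 1.0, 2.0])))

    def test_loa_bracket_bias(self, rng):
        y = X * 1.1 + rng.normal(0, 0.02, X.size)
        r = bland_altman(PairedMeasurements(X, y))
        assert r.loa[0] <= r.bias <= r.loa[1]


class TestPredictiveErrors:
    def test_identical_series_have_zero_errors(self):
        assert predictive_errors(X, X.copy()) == (0.0, 0.0)

    def test_hand_arithmetic_two_pairs(self):
        mppe, mape = predictive_errors([0.40, 0.40], [0.42, 0.38])
        assert mppe == pytest.approx(0.0, abs=1e-12)
        assert mape == pytest.approx(5.0)

    def test_uniform_bias_makes_them_equal(self):
        mppe, mape = predictive_errors(X, 1.05 * X)
        assert mppe == pytest.approx(5.0) and mape == pytest.approx(5.0)

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0.1, 10.0), st.floats(0.01, 20.0)),
            min_size=1,
            max_size=30,
        )
    )
    def test_mape_dominates_absolute_mppe(self, pairs):
        ref = np.array([p[0] for p in pairs])
        tst = np.array([p[1] for p in pairs])
        mppe, mape = predictive_errors(ref, tst)
        assert mape >= abs(mppe) - 1e-9

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            predictive_errors([0.0, 1.0], [1.0, 1.0])


def _volume_design(slopes, noise_sd, rng, volumes=(5, 10, 20, 30, 40), reps=6):
    rows = []
    for g, slope in slopes.items():
        for v in volumes:
            for _ in range(reps):
                cond = (v - 15.0) / slope
                rows.append({"group": g, "covariate": cond,
                             "response": v + rng.normal(0, noise_sd)})
    return pd.DataFrame(rows)


class TestAncova:
    def test_degrees_of_freedom_match_the_study_design(self, rng):
        """5 HCT groups x 5 volumes x 6 replicates -> F(4, 140) interaction."""
        slopes = {0.2: 25.97, 0.3: 26.06, 0.4: 25.18, 0.5: 23.01, 0.6: 23.22}
        df = _volume_design(slopes, 0.5, rng)
        res = ancova_slopes(df, reference_group=0.2)
        assert res.df_covariate == (1, 140)
        assert res.df_factor == (4, 140)
        assert res.df_interaction == (4, 140)
        assert res.p_covariate < 0.001
        assert len(res.slope_contrasts) == 4

    def test_noise_free_equal_slopes_give_zero_interaction(self):
        g = pd.DataFrame({
            "covariate": np.tile(np.arange(5.0), 2),
            "group": np.repeat(["a", "b"], 5),
        })
        g["response"] = 2.0 * g["covariate"] + 1.0
        res = ancova_slopes(g, "a")
        assert res.f_interaction == 0.0
        assert res.p_interaction == 1.0

    def test_distinct_slopes_are_detected_against_reference(self, rng):
        slopes = {0.2: 26.0, 0.5: 20.0}
        df = _volume_design(slopes, 0.4, rng)
        res = ancova_slopes(df, reference_group=0.2)
        assert res.p_interaction < 1e-6
        assert res.slope_contrasts.iloc[0]["p"] < 1e-6

    def test_covariate_f_grows_with_sample_size(self, rng):
        slopes = {0.2: 25.0, 0.4: 25.0}
        small = _volume_design(slopes, 1.0, np.random.default_rng(5), reps=3)
        large = _volume_design(slopes, 1.0, np.random.default_rng(5), reps=30)
        f_small = ancova_slopes(small, 0.2).f_covariate
        f_large = ancova_slopes(large, 0.2).f_covariate
        assert f_large > f_small

    def test_singular_group_design_rejected(self):
        df = pd.DataFrame({
            "covariate": [1.0, 1.0, 1.0, 1.0, 2.0, 3.0],
            "response": [1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
            "group": ["a", "a", "a", "b", "b", "b"],
        })
        with pytest.raises(ValueError):
            ancova_slopes(df, "b")


def test_compare_methods_bundles_consistent_statistics(rng):
    test_vals = X * 1.05 + rng.normal(0, 0.01, X.size)
    res = compare_methods(X, test_vals)
    assert res.mape >= abs(res.mppe)
    assert res.bland_altman.loa[0] <= res.bland_altman.bias <= res.bland_altman.loa[1]
    d = res.to_dict()
    assert set(d) == {"deming", "bland_altman", "mppe", "mape"}


def test_comparison_plot_writes_png(rng, tmp_path):
    from dbsbias.agreement import plot_comparison

    test_vals = X * 1.05 + rng.normal(0, 0.01, X.size)
    pm = PairedMeasurements(X, test_vals)
    plot_comparison(pm, compare_methods(X, test_vals), tmp_path / "cmp.png")
    assert (tmp_path / "cmp.png").exists()
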
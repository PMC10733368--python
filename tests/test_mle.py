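import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divnorm import (
    CloudSpec,
    ErrorSet,
    MLEParams,
    mle_multi,
    mle_single,
    ordinary_mle_decline_ratio,
    sd_ratio,
)
from divnorm.mle import expected_cloud_response, ordinary_mle_cloud_response

# frozen from a 30-digit evaluation of the shrinkage formula at the published
# single-cursor fit (c = 2.963e5, sigma_v/sigma_p = 122.2, k_v/sigma_p = 8.055)
MLE_FIXTURES = {
    7.5: 66.637529458762502,
    15.0: 75.251238787751136,
    30.0: 67.14363777680534,
    45.0: 56.759829019076649,
}

errors_strategy = st.lists(
    st.floats(min_value=-60.0, max_value=60.0, allow_nan=False), min_size=1, max_size=4
)


class TestNoiseModel:
    def test_baseline_at_zero_error(self, mle_learning):
        assert sd_ratio(0.0, mle_learning) == mle_learning.ratio_sv

    def test_even_in_error(self, mle_learning):
        assert sd_ratio(-30.0, mle_learning) == sd_ratio(30.0, mle_learning)

    def test_linear_growth_hand_computed(self, mle_learning):
        assert sd_ratio(30.0, mle_learning) == pytest.approx(122.2 + 8.055 * 30, rel=1e-14)

    def test_constant_in_ordinary_mode(self):
        p = MLEParams(c=1e5, ratio_sv=50.0, constant_sigma_mode=True)
        assert sd_ratio(45.0, p) == sd_ratio(0.0, p) == 50.0

    def test_ordinary_mode_rejects_signal_dependence(self):
        with pytest.raises(ValueError):
            MLEParams(c=1e5, ratio_sv=50.0, ratio_kv=1.0, constant_sigma_mode=True)


class TestSingleCursor:
    def test_zero_error_gives_zero(self, mle_learning):
        assert mle_single(0.0, mle_learning) == 0.0

    @pytest.mark.parametrize("e,expected", sorted(MLE_FIXTURES.items()))
    def test_regression_values(self, mle_learning, e, expected):
        assert mle_single(e, mle_learning) == pytest.approx(expected, rel=1e-12)

    def test_saturates_then_declines(self, mle_learning):
        vals = [mle_single(e, mle_learning) for e in (7.5, 15.0, 30.0, 45.0)]
        assert vals[1] == max(vals)  # non-monotonic: shrinkage wins at large e

    def test_ordinary_mode_is_exactly_linear(self):
        p = MLEParams(c=1e5, ratio_sv=50.0, constant_sigma_mode=True)
        slope = mle_single(1.0, p)
        for e in (2.0, 8.0, 32.0):
            assert mle_single(e, p) == slope * e

    def test_odd_in_error(self, mle_learning):
        for e in (5.0, 17.0, 45.0):
            assert mle_single(-e, mle_learning) == -mle_single(e, mle_learning)


class TestMultiCursor:
    def test_single_cursor_reduction(self, mle_learning):
        for e in (-30.0, 7.5, 45.0):
            assert mle_multi(ErrorSet((e,)), mle_learning) == pytest.approx(
                mle_single(e, mle_learning), rel=1e-14
            )

    def test_duplicated_cursors_strictly_increase_response(self, mle_learning):
        e = 30.0
        vals = [mle_multi(np.full(n, e), mle_learning) for n in (1, 2, 5)]
        assert vals[0] < vals[1] < vals[2]
        # bounded by the infinite-evidence limit c*e
        assert vals[2] < mle_learning.c * e

    def test_all_zero_errors_give_zero(self, mle_learning):
        assert mle_multi(np.zeros(3), mle_learning) == 0.0

    def test_empty_set_rejected(self, mle_learning):
        with pytest.raises(ValueError):
            mle_multi(np.array([]), mle_learning)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(errors=errors_strategy)
    def test_odd_in_error_set(self, errors):
        p = MLEParams(c=2.963e5, ratio_sv=122.2, ratio_kv=8.055)
        a = mle_multi(np.asarray(errors), p)
        b = mle_multi(-np.asarray(errors), p)
        assert b == pytest.approx(-a, abs=1e-9 * (1 + abs(a)))

    def test_identifiable_parameterization(self, mle_learning):
        # scaling all absolute noise SDs consistently leaves responses unchanged
        a = MLEParams.from_absolute(c=2.963e5, sigma_p=1.0, sigma_v=122.2, k_v=8.055)
        b = MLEParams.from_absolute(c=2.963e5, sigma_p=3.5, sigma_v=3.5 * 122.2, k_v=3.5 * 8.055)
        for errs in [(30.0,), (15.0, -40.0), (7.5, 22.5, 45.0)]:
            assert mle_multi(np.asarray(errs), a) == pytest.approx(
                mle_multi(np.asarray(errs), b), rel=1e-14
            )
        assert mle_multi(np.array([30.0]), a) == pytest.approx(
            mle_multi(np.array([30.0]), mle_learning), rel=1e-14
        )


class TestCloudExpectation:
    def test_zero_dispersion_short_circuit(self, mle_learning):
        spec = CloudSpec(mu=14.0, sigma=0.0, n_cursors=5)
        mean, se = expected_cloud_response(spec, mle_learning, n_draws=10)
        assert mean == mle_multi(np.full(5, 14.0), mle_learning)
        assert se == 0.0

    def test_reproducible_given_seed(self, mle_learning):
        spec = CloudSpec(mu=14.0, sigma=7.0, n_cursors=5)
        assert expected_cloud_response(spec, mle_learning, n_draws=500, seed=3) == (
            expected_cloud_response(spec, mle_learning, n_draws=500, seed=3)
        )


class TestOrdinaryDeclineRatio:
    def test_ratio_is_unity_for_any_uncertainty(self):
        p = MLEParams(c=7.7e4, ratio_sv=37.0, constant_sigma_mode=True)
        ratios = ordinary_mle_decline_ratio(14.0, 40.0, (7.0, 20.0), p)
        for sigma, r in ratios.items():
            assert r == pytest.approx(1.0, abs=1e-12), sigma

    def test_ratio_invariant_to_noise_scale(self):
        p = MLEParams(c=1.0, ratio_sv=5.0, constant_sigma_mode=True)
        for sp in (0.5, 1.0, 10.0):
            r = ordinary_mle_decline_ratio(14.0, 40.0, (7.0,), p, sigma_p=sp)
            assert r[7.0] == pytest.approx(1.0, abs=1e-12)

    def test_equal_means_trivially_unity(self):
        p = MLEParams(c=1.0, ratio_sv=5.0, constant_sigma_mode=True)
        assert ordinary_mle_decline_ratio(14.0, 14.0, (7.0,), p)[7.0] == 1.0

    def test_zero_mean_baseline_rejected(self):
        p = MLEParams(c=1.0, ratio_sv=5.0, constant_sigma_mode=True)
        with pytest.raises(ZeroDivisionError):
            ordinary_mle_decline_ratio(0.0, 40.0, (7.0,), p)

    def test_signal_dependent_noise_rejected_by_analytic_path(self, mle_learning):
        with pytest.raises(ValueError):
            ordinary_mle_cloud_response(14.0, 7.0, mle_learning)

    def test_signal_dependent_cloud_ratio_departs_from_unity(self, mle_learning):
        # with k_v > 0 the Monte-Carlo cloud expectation yields mu-dependent
        # declining rates, so the ratio need not be 1
        rates = {}
        for mu in (14.0, 40.0):
            r = {
                s: expected_cloud_response(
                    CloudSpec(mu=mu, sigma=s, n_cursors=5),
                    mle_learning,
                    n_draws=50_000,
                    seed=17,
                )[0]
                for s in (0.0, 7.0, 20.0)
            }
            rates[mu] = {s: (r[0.0] - v) / r[0.0] for s, v in r.items()}
        ratio_20 = rates[14.0][20.0] / rates[40.0][20.0]
        assert abs(ratio_20 - 1.0) > 0.05
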
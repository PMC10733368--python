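import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from divnorm import (
    CloudSpec,
    DNParams,
    ErrorSet,
    analytic_single,
    dn_response,
    expected_cloud_response,
    linear_response_single,
    nonlinearity_index,
    peak_error,
)
from divnorm.dn import dn_response_batch

# closed-form values at the published learning-response parameters,
# frozen from a 30-digit evaluation of the single-cursor solution
ANALYTIC_FIXTURES = {
    7.5: 61.535698262898483,
    15.0: 80.886209003732899,
    30.0: 68.227308679737414,
    45.0: 52.115010062751527,
}

errors_strategy = st.lists(
    st.floats(min_value=-60.0, max_value=60.0, allow_nan=False), min_size=1, max_size=4
)


class TestClosedForms:
    def test_zero_error_gives_zero_response(self, dn_learning):
        assert dn_response(ErrorSet((0.0,)), dn_learning) == 0.0
        assert analytic_single(0.0, dn_learning) == 0.0
        assert linear_response_single(0.0, dn_learning) == 0.0

    @pytest.mark.parametrize("e,expected", sorted(ANALYTIC_FIXTURES.items()))
    def test_analytic_single_regression_values(self, dn_learning, e, expected):
        assert analytic_single(e, dn_learning) == pytest.approx(expected, rel=1e-12)

    def test_analytic_single_is_odd(self, dn_learning):
        for e in (3.0, 17.2, 45.0, 88.0):
            assert analytic_single(-e, dn_learning) == -analytic_single(e, dn_learning)

    def test_linear_response_hand_computed(self):
        # sqrt(2 pi) * 1e-4 * 22 * 10 / (360 * 1e-6), evaluated to 17 digits
        p = DNParams(w=1e-4, k=1e-6, s=22.0)
        assert linear_response_single(10.0, p) == pytest.approx(153.18283900522781, rel=1e-14)

    def test_linear_response_is_linear(self, dn_learning):
        assert linear_response_single(20.0, dn_learning) == pytest.approx(
            2 * linear_response_single(10.0, dn_learning), rel=1e-14
        )

    def test_nonlinearity_index_worked_examples(self):
        assert nonlinearity_index(5.3271e-4, 7.7806e-7) == pytest.approx(0.3647, abs=5e-5)
        assert nonlinearity_index(4.0541e-4, 9.2642e-5) == pytest.approx(1.7741e-3, rel=5e-5)
        assert nonlinearity_index(0.0, 1e-6) == 0.0
        with pytest.raises(ValueError):
            nonlinearity_index(1e-4, 0.0)

    def test_saturation_peak_location(self, dn_learning):
        # increasing before e*, decreasing after; e* matches a dense-grid argmax
        estar = peak_error(dn_learning)
        grid = np.linspace(0.0, 90.0, 9001)
        vals = analytic_single(grid, dn_learning)
        assert grid[np.argmax(vals)] == pytest.approx(estar, abs=0.02)
        before = analytic_single(np.linspace(0.1, estar, 50), dn_learning)
        after = analytic_single(np.linspace(estar, 90.0, 50), dn_learning)
        assert np.all(np.diff(before) > 0)
        assert np.all(np.diff(after) < 0)


class TestDiscreteModel:
    def test_matches_analytic_single_cursor(self, dn_learning):
        for e in (-45.0, -7.5, 3.0, 15.0, 30.0, 45.0):
            assert dn_response(ErrorSet((e,)), dn_learning) == pytest.approx(
                analytic_single(e, dn_learning), rel=1e-3
            )

    def test_no_normalization_limit_matches_linear_form(self, dn_learning):
        for e in (-30.0, 10.0, 45.0):
            assert dn_response(ErrorSet((e,)), dn_learning, normalize=False) == pytest.approx(
                linear_response_single(e, dn_learning), rel=1e-3
            )

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(errors=errors_strategy)
    def test_response_is_exactly_odd(self, errors):
        p = DNParams(w=5.3271e-4, k=7.7806e-7, M=721)
        a = dn_response(ErrorSet(tuple(errors)), p)
        b = dn_response(ErrorSet(tuple(-e for e in errors)), p)
        assert b == -a

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(errors=errors_strategy, idx=st.integers(min_value=0, max_value=3))
    def test_duplicated_cursor_never_changes_response(self, errors, idx):
        p = DNParams(w=5.3271e-4, k=7.7806e-7, M=721)
        dup = errors + [errors[idx % len(errors)]]
        assert dn_response(ErrorSet(tuple(dup)), p) == dn_response(ErrorSet(tuple(errors)), p)

    def test_subadditive_for_same_sign_pairs(self, dn_learning):
        for e1 in (15.0, 30.0, 45.0):
            for e2 in (15.0, 30.0, 45.0):
                pair = dn_response(np.array([e1, e2]), dn_learning)
                assert pair < analytic_single(e1, dn_learning) + analytic_single(e2, dn_learning)

    def test_grid_resolution_stability(self, dn_learning):
        fine = DNParams(w=dn_learning.w, k=dn_learning.k, s=dn_learning.s, M=7201)
        for errs in [(30.0,), (15.0, -40.0), (7.5, 22.5, 45.0)]:
            a = dn_response(ErrorSet(errs), dn_learning)
            b = dn_response(ErrorSet(errs), fine)
            assert abs(b - a) / abs(a) < 1e-6

    def test_batch_agrees_with_scalar_path(self, dn_learning):
        sets = np.array([[15.0, -40.0], [30.0, 30.0], [0.0, 45.0]])
        batch = dn_response_batch(sets, dn_learning)
        single = [dn_response(row, dn_learning) for row in sets]
        np.testing.assert_allclose(batch, single, rtol=1e-14)


class TestCloudExpectation:
    def test_zero_dispersion_is_exact_single_response(self, dn_exp2):
        mean, se = expected_cloud_response(CloudSpec(mu=14.0, sigma=0.0, n_cursors=5), dn_exp2)
        assert mean == dn_response(ErrorSet((14.0,)), dn_exp2)
        assert se == 0.0

    def test_standard_error_shrinks_with_draws(self, dn_exp2):
        spec = CloudSpec(mu=14.0, sigma=7.0, n_cursors=5)
        _, se1 = expected_cloud_response(spec, dn_exp2, n_draws=1000, seed=5)
        _, se4 = expected_cloud_response(spec, dn_exp2, n_draws=4000, seed=5)
        assert se4 == pytest.approx(se1 / 2, rel=0.25)

    def test_uncertainty_suppresses_small_errors_more(self, dn_exp2):
        # mean response falls with sigma; relative fall is weaker at mu = 40
        decline = {}
        for mu in (14.0, 40.0):
            r = {
                s: expected_cloud_response(
                    CloudSpec(mu=mu, sigma=s, n_cursors=5), dn_exp2, n_draws=20_000, seed=11
                )[0]
                for s in (0.0, 7.0, 20.0)
            }
            assert r[0.0] > r[7.0] > r[20.0]
            decline[mu] = (r[0.0] - r[20.0]) / r[0.0]
        assert decline[40.0] < decline[14.0]

    def test_reproducible_given_seed(self, dn_exp2):
        spec = CloudSpec(mu=14.0, sigma=20.0, n_cursors=5)
        a = expected_cloud_response(spec, dn_exp2, n_draws=500, seed=42)
        b = expected_cloud_response(spec, dn_exp2, n_draws=500, seed=42)
        assert a == b
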
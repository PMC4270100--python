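"""Unit and property tests for the drive metric and reward constructions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homeorl.homeostat import (
    DriveParams,
    approx_reward,
    drive,
    drive_gradient,
    palatable_reward,
    reward,
    settling_point,
    surprise,
    taylor_reward,
)

P34 = DriveParams(setpoint=[0.0], m=3.0, n=4.0)
P11 = DriveParams(setpoint=[0.0], m=1.0, n=1.0)


class TestDrive:
    def test_zero_at_setpoint(self):
        p = DriveParams(setpoint=[1.5, -2.0], m=3, n=4)
        assert drive([1.5, -2.0], p) == 0.0

    def test_l1_closed_form(self):
        p = DriveParams(setpoint=np.zeros(2), m=1, n=1)
        assert drive([3.0, 4.0], p) == pytest.approx(7.0)

    def test_fractional_exponents_closed_form(self):
        # independent log-domain evaluation of (2^4)^(1/3)
        expected = np.exp((4.0 / 3.0) * np.log(2.0))
        assert drive([2.0], P34) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            drive([1.0, 2.0], P34)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            drive([np.nan], P34)
        with pytest.raises(ValueError):
            DriveParams(setpoint=[np.inf])

    @settings(max_examples=50, deadline=None)
    @given(
        h=st.lists(st.floats(-50, 50), min_size=1, max_size=3),
        mexp=st.floats(1.1, 3.0),
        nexp=st.floats(1.2, 5.0),
    )
    def test_nonnegative_and_reflection_symmetric(self, h, mexp, nexp):
        h = np.asarray(h)
        p = DriveParams(setpoint=np.zeros(h.size), m=mexp, n=nexp)
        d = drive(h, p)
        assert d >= 0.0
        # reflect each coordinate about the setpoint in turn
        for i in range(h.size):
            h2 = h.copy()
            h2[i] = -h2[i]
            assert drive(h2, p) == pytest.approx(d, rel=1e-9, abs=1e-12)

    def test_zero_only_at_setpoint(self):
        assert drive([1e-9], P34) > 0.0


class TestReward:
    def test_null_outcome(self):
        assert reward([-5.0], [0.0], P34) == 0.0

    def test_linear_metric_closed_form(self):
        assert reward([-5.0], [3.0], P11) == pytest.approx(3.0)

    def test_fractional_metric_two_term_evaluation(self):
        expected = 5.0 ** (4.0 / 3.0) - 2.0 ** (4.0 / 3.0)
        assert reward([-5.0], [3.0], P34) == pytest.approx(expected, rel=1e-12)

    def test_sign_iff_closer(self):
        assert reward([-5.0], [2.0], P34) > 0
        assert reward([-5.0], [-2.0], P34) < 0
        # overshoot past the mirror image is punishing
        assert reward([-1.0], [10.0], P34) < 0


class TestApproxReward:
    def test_unbiased_estimate_recovers_reward(self):
        assert approx_reward([-5.0], [3.0], P34) == reward([-5.0], [3.0], P34)

    def test_unsensed_delivery_is_worthless(self):
        # intravenous/fistula delivery: true K nonzero, sensed K_hat zero
        assert approx_reward([-5.0], [0.0], P34) == 0.0

    def test_symmetric_overshoot_cancels(self):
        # K_hat carries the state to the mirror image of H about H*
        assert approx_reward([-5.0], [10.0], P11) == pytest.approx(0.0)


class TestPalatableReward:
    def test_zero_bonus_recovers_reward(self):
        assert palatable_reward([-5.0], [3.0], 0.0, P34) == reward([-5.0], [3.0], P34)

    def test_positive_despite_deviation_increase(self):
        h, k = [0.0], [1.0]
        t = drive([1.0], P34) + 0.5
        assert reward(h, k, P34) < 0
        assert palatable_reward(h, k, t, P34) > 0

    def test_negative_bonus_rejected(self):
        with pytest.raises(ValueError):
            palatable_reward([-5.0], [3.0], -1.0, P34)

    def test_quadratic_equivalence_to_shifted_setpoint(self):
        # with D = (h - h*)^2 the bonus T is exactly a setpoint shift T/(2K)
        pq = DriveParams(setpoint=[0.0], m=1.0, n=2.0)
        T, K = 10.0, 5.0
        shifted = DriveParams(setpoint=[settling_point(0.0, T, K)], m=1.0, n=2.0)
        for h in (-3.0, 0.0, 2.5, 7.0):
            assert palatable_reward([h], [K], T, pq) == pytest.approx(
                reward([h], [K], shifted), rel=1e-12, abs=1e-12
            )


class TestSettlingPoint:
    def test_no_bonus_no_shift(self):
        assert settling_point(2.0, 0.0, 5.0) == 2.0

    def test_printed_formula(self):
        assert settling_point(0.0, 10.0, 5.0) == pytest.approx(1.0)

    def test_richer_food_smaller_shift(self):
        assert settling_point(0.0, 10.0, 10.0) < settling_point(0.0, 10.0, 5.0)

    def test_zero_content_rejected(self):
        with pytest.raises(ValueError):
            settling_point(0.0, 10.0, 0.0)


class TestSurprise:
    def test_equals_drive(self):
        for h in (-7.0, 0.0, 3.3):
            assert surprise([h], P34) == drive([h], P34)

    def test_equilibrium_density_normalizable(self):
        # p(h) ∝ exp(-|h|^{n/m}) integrates to a finite constant for n/m >= 1
        from scipy.integrate import quad

        val, err = quad(lambda h: np.exp(-drive([h], P34)), -np.inf, np.inf)
        assert np.isfinite(val) and val > 0
        assert err < 1e-6 * val


class TestTaylorReward:
    def test_zero_outcome(self):
        assert taylor_reward([-5.0], [0.0], P34) == 0.0

    def test_exact_for_linear_metric_below_setpoint(self):
        assert taylor_reward([-5.0], [0.3], P11) == pytest.approx(0.3)

    def test_second_order_convergence(self):
        # |reward - taylor| / ||K||^2 stays bounded as K is halved
        h = [-5.0]
        ratios = []
        for k in (1.0, 0.5, 0.25, 0.125, 0.0625):
            err = abs(reward(h, [k], P34) - taylor_reward(h, [k], P34))
            ratios.append(err / k**2)
        assert max(ratios) < 2.0 * ratios[-1] + 1e-9  # no blow-up as K -> 0

    def test_gradient_rejected_at_kink(self):
        with pytest.raises(ValueError):
            taylor_reward([0.0], [1.0], P11)
        # smooth case: gradient is zero at the setpoint
        assert np.allclose(drive_gradient([0.0], P34), 0.0)


class TestBehavioralProperties:
    """Finite-difference sign tests of the four drive-shape guarantees (n > m > 1)."""

    params = DriveParams(setpoint=[0.0], m=3.0, n=4.0)
    params2d = DriveParams(setpoint=np.zeros(2), m=3.0, n=4.0)

    def test_dose_monotonicity(self):
        h = [-20.0]
        ks = np.linspace(0.5, 19.5, 40)
        rs = [reward(h, [k], self.params) for k in ks]
        assert np.all(np.diff(rs) > 0)

    def test_deprivation_potentiation(self):
        k = [2.0]
        deps = np.linspace(3.0, 40.0, 40)
        rs = [reward([-d], k, self.params) for d in deps]
        assert np.all(np.diff(rs) > 0)

    def test_irrelevant_drive_inhibition(self):
        # outcome on dimension 0; growing deviation on dimension 1 inhibits it
        others = np.linspace(0.0, 30.0, 31)
        rs = [reward([-10.0, -d], [2.0, 0.0], self.params2d) for d in others]
        assert np.all(np.diff(rs) < 0)

    def test_concavity_in_outcome_magnitude(self):
        h = [-20.0]
        ks = np.linspace(0.5, 19.5, 40)
        rs = np.array([reward(h, [k], self.params) for k in ks])
        assert np.all(np.diff(rs, 2) < 0)

    def test_inverted_u_peak_at_deficit(self):
        # reward peaks exactly when the outcome closes the deficit, then declines
        h, hstar = -15.0, 0.0
        ks = np.linspace(0.5, 45.0, 200)
        rs = np.array([reward([h], [k], self.params) for k in ks])
        k_peak = ks[np.argmax(rs)]
        assert k_peak == pytest.approx(hstar - h, abs=0.25)
        assert rs[-1] < 0  # large outcomes overshoot and are punishing
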
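"""Tests for the learning rules, outcome model, and policies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from homeorl.agents import (
    ActionValueTable,
    AgentConfig,
    OutcomeModel,
    bin_center,
    discretize_internal,
    mb_action_values,
    mc_return_update,
    nf_policy,
    outcome_model_update,
    softmax_policy,
    td_update,
)
from homeorl.homeostat import DriveParams


class TestSoftmax:
    def test_uniform_for_equal_values(self):
        assert np.allclose(softmax_policy([0.0, 0.0], 0.05), [0.5, 0.5])
        assert np.allclose(softmax_policy([3.3, 3.3, 3.3], 7.0), [1 / 3] * 3)

    def test_logistic_closed_form(self):
        p = softmax_policy([10.0, 0.0], 0.05)
        e = np.exp(0.5)
        assert p[0] == pytest.approx(e / (e + 1))
        assert p[1] == pytest.approx(1 / (e + 1))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            softmax_policy([], 1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        vals=st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=6),
        beta=st.floats(0.01, 10.0),
    )
    def test_normalized_and_order_preserving(self, vals, beta):
        p = softmax_policy(vals, beta)
        assert p.sum() == pytest.approx(1.0)
        assert np.all(p >= 0)  # may underflow to exactly 0 for huge value gaps
        order = np.argsort(vals)
        assert np.all(np.diff(p[order]) >= -1e-12)


class TestTDUpdate:
    def test_zero_learning_rate_limit(self):
        # alpha must be > 0, so check the smallest admissible rate barely moves Q
        table = ActionValueTable()
        cfg = AgentConfig(alpha=1e-12, gamma=0.9)
        rec = td_update(table, "s", "a", 5.0, None, (), cfg)
        assert rec.delta == pytest.approx(5.0)
        assert table.value("s", "a") == pytest.approx(0.0, abs=1e-9)

    def test_terminal_full_step(self):
        table = ActionValueTable()
        cfg = AgentConfig(alpha=1.0, gamma=0.9)
        rec = td_update(table, "s", "a", 1.0, None, (), cfg)
        assert table.value("s", "a") == 1.0
        assert rec.delta == 1.0

    def test_geometric_convergence_to_fixed_point(self):
        # with gamma=0 and constant reward r, Q approaches r at rate (1-alpha)
        table = ActionValueTable()
        cfg = AgentConfig(alpha=0.25, gamma=0.0)
        r = 2.0
        for k in range(1, 30):
            td_update(table, "s", "a", r, "s", ("a",), cfg)
            expected = r * (1 - (1 - cfg.alpha) ** k)
            assert table.value("s", "a") == pytest.approx(expected)

    def test_only_target_entry_changes(self):
        table = ActionValueTable()
        table.set("s", "b", 7.0)
        td_update(table, "s", "a", 1.0, "s2", ("a", "b"), AgentConfig(alpha=0.5))
        assert table.value("s", "b") == 7.0
        assert len(table) == 2

    def test_bandit_fixed_point_orders_two_arms(self):
        # deterministic rewards r1 > r2, gamma=0: Q converges to (r1, r2)
        table = ActionValueTable()
        cfg = AgentConfig(alpha=0.5, gamma=0.0)
        for _ in range(60):
            td_update(table, "s", 1, 1.0, None, (), cfg)
            td_update(table, "s", 2, 0.3, None, (), cfg)
        assert table.value("s", 1) == pytest.approx(1.0, abs=1e-6)
        assert table.value("s", 2) == pytest.approx(0.3, abs=1e-6)
        p = softmax_policy(table.values("s", (1, 2)), beta=1.0)
        assert p[0] > 0.5


class TestMCReturnUpdate:
    def test_zero_return_stays_zero(self):
        table = ActionValueTable()
        mc_return_update(table, "cue", "a", 0.0, AgentConfig())
        assert table.value("cue", "a") == 0.0

    def test_converges_to_constant_return(self):
        table = ActionValueTable()
        cfg = AgentConfig(alpha=0.4)
        for _ in range(50):
            mc_return_update(table, "cue", "a", -3.7, cfg)
        assert table.value("cue", "a") == pytest.approx(-3.7, abs=1e-6)


class TestOutcomeModel:
    def test_magnitude_converges_to_sensed_value(self):
        model = OutcomeModel()
        cfg = AgentConfig(alpha=0.4)
        for _ in range(40):
            outcome_model_update(model, 0, "key", 0.5, True, cfg)
        assert model.kappa_hat(0, "key") == pytest.approx(0.5, abs=1e-6)
        assert model.prob(0, "key") == pytest.approx(1.0, abs=1e-6)

    def test_extinction_drives_probability_to_zero(self):
        model = OutcomeModel()
        model.set(0, "key", 1.0, 1.0)
        cfg = AgentConfig(alpha=0.4)
        for _ in range(40):
            outcome_model_update(model, 0, "key", 0.0, False, cfg)
        assert model.prob(0, "key") == pytest.approx(0.0, abs=1e-6)
        # magnitude memory persists; only the expectation of delivery decays
        assert model.kappa_hat(0, "key") == 1.0

    def test_full_learning_rate_tracks_last_observation(self):
        model = OutcomeModel()
        cfg = AgentConfig(alpha=1.0)
        outcome_model_update(model, 0, "key", 0.8, True, cfg)
        outcome_model_update(model, 0, "key", 0.1, True, cfg)
        assert model.kappa_hat(0, "key") == pytest.approx(0.1)


class TestModelBasedValues:
    params = DriveParams(setpoint=[0.0], m=3.0, n=4.0)

    def test_unlearned_outcomes_give_zero_values(self):
        model = OutcomeModel()
        vals = mb_action_values(model, [-5.0], self.params, 0, ("a", "b"))
        assert np.allclose(vals, 0.0)

    def test_satiation_turns_values_negative(self):
        model = OutcomeModel()
        model.set(0, "key", 1.0, 1.0)
        vals = mb_action_values(model, [0.0], self.params, 0, ("key",))
        assert vals[0] < 0

    def test_oral_key_beats_unsensed_key_when_thirsty(self):
        model = OutcomeModel()
        model.set(0, "oral", 1.0, 1.0)
        model.set(0, "fistula", 0.0, 1.0)
        vals = mb_action_values(model, [-10.0], self.params, 0, ("oral", "fistula"))
        assert vals[0] > vals[1] == 0.0


class TestNFPolicy:
    @pytest.mark.parametrize(
        "h,expected", [(-0.1, "respond"), (0.0, "null"), (5.0, "null")]
    )
    def test_threshold(self, h, expected):
        assert nf_policy(h, 0.0) == expected


class TestDiscretization:
    def test_unit_bins(self):
        assert discretize_internal(3.0, 1.0) == 3
        assert discretize_internal(-2.4, 1.0) == -2

    @settings(max_examples=100, deadline=None)
    @given(
        h1=st.floats(-1e4, 1e4),
        h2=st.floats(-1e4, 1e4),
        w=st.floats(0.01, 10.0),
    )
    def test_monotone_and_roundtrip(self, h1, h2, w):
        lo, hi = sorted((h1, h2))
        assert discretize_internal(lo, w) <= discretize_internal(hi, w)
        b = discretize_internal(h1, w)
        assert abs(bin_center(b, w) - h1) <= w / 2 + 1e-9 * max(1.0, abs(h1))
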
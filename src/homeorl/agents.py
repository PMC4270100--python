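"""Learning agents operating on drive-reduction reward.

Three learners are provided, mirroring the architectures used by the
behavioral simulations:

* a model-free tabular Q-learner (:func:`td_update`) with softmax action
  selection, driven by a reward prediction error (RPE);
* a Monte-Carlo delayed-return learner (:func:`mc_return_update`) for
  tasks where an action's value is the discounted sum of drive
  reductions over a whole post-action horizon (anticipatory responding);
* a model-based outcome learner (:class:`OutcomeModel`,
  :func:`mb_action_values`) that learns the sensed magnitude and
  probability of each action's outcome and evaluates actions by the
  approximated drive reduction they would produce in the current state.

A non-learning negative-feedback comparator (:func:`nf_policy`) — the
classical homeostatic-regulation policy "respond whenever the state is
below the setpoint" — is included for contrast experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .homeostat import DriveParams, approx_reward

__all__ = [
    "AgentConfig",
    "ActionValueTable",
    "RPERecord",
    "OutcomeModel",
    "softmax_policy",
    "td_update",
    "mc_return_update",
    "outcome_model_update",
    "mb_action_values",
    "nf_policy",
    "discretize_internal",
    "bin_center",
]


@dataclass(frozen=True)
class AgentConfig:
    """Learning-rate, exploration, and discounting parameters.

    ``beta`` is the rate of exploration, an exploration *temperature*:
    action probabilities are softmax in ``value / beta``, so larger
    ``beta`` means more exploration.  (:func:`softmax_policy` itself
    takes the inverse temperature ``1/beta`` as its coefficient.)
    ``gamma`` must lie in [0, 1]; 1 is admitted only for the discounting
    ablations, where reward seeking provably decouples from stability.
    """

    alpha: float = 0.4
    beta: float = 0.05
    gamma: float = 0.9
    q_init: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class RPERecord:
    """One reward-prediction-error event: delta = target - prior value."""

    time: int
    state: object
    action: object
    delta: float


class ActionValueTable:
    """Tabular action values over (state, action) keys.

    States are arbitrary hashables; by convention the environments use
    ``(external_state_id, internal_bin)`` tuples.  Unvisited entries
    read as ``q_init``.
    """

    def __init__(self, q_init: float = 0.0):
        self.q_init = float(q_init)
        self._q: dict = {}

    def value(self, state, action) -> float:
        return self._q.get((state, action), self.q_init)

    def set(self, state, action, v: float) -> None:
        if not math.isfinite(v):
            raise ValueError(f"non-finite action value {v} for {(state, action)}")
        self._q[(state, action)] = float(v)

    def values(self, state, actions) -> np.ndarray:
        return np.array([self.value(state, a) for a in actions])

    def max_value(self, state, actions) -> float:
        return max(self.value(state, a) for a in actions)

    def __len__(self) -> int:
        return len(self._q)


def softmax_policy(values, beta: float) -> np.ndarray:
    """Softmax choice probabilities: ``p(a) ∝ exp(beta * value_a)``.

    Equal values give the uniform distribution regardless of ``beta``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("softmax over an empty action set")
    if not (beta > 0):
        raise ValueError(f"beta must be > 0, got {beta}")
    z = beta * (v - v.max())  # shift for overflow safety
    e = np.exp(z)
    return e / e.sum()


def td_update(
    table: ActionValueTable,
    state,
    action,
    r: float,
    next_state,
    next_actions,
    config: AgentConfig,
    time: int = 0,
) -> RPERecord:
    """One Q-learning step on ``table`` (in place); returns the RPE.

    ``delta = r + gamma * max_a' Q(s', a') - Q(s, a)``; a terminal
    successor is signalled by ``next_state=None`` (bootstrap term 0).
    Only the ``(state, action)`` entry changes.
    """
    if not math.isfinite(r):
        raise ValueError(f"non-finite reward {r}")
    q = table.value(state, action)
    boot = 0.0 if next_state is None else table.max_value(next_state, next_actions)
    delta = r + config.gamma * boot - q
    table.set(state, action, q + config.alpha * delta)
    return RPERecord(time=time, state=state, action=action, delta=delta)


def mc_return_update(
    table: ActionValueTable,
    state,
    action,
    discounted_return: float,
    config: AgentConfig,
    time: int = 0,
) -> RPERecord:
    """Delta-rule update of Q(s, a) toward a realized discounted return."""
    if not math.isfinite(discounted_return):
        raise ValueError(f"non-finite return {discounted_return}")
    q = table.value(state, action)
    delta = discounted_return - q
    table.set(state, action, q + config.alpha * delta)
    return RPERecord(time=time, state=state, action=action, delta=delta)


@dataclass
class OutcomeModel:
    """Learned per-(state, action) outcome model: sensed magnitude and probability.

    ``kappa_hat`` is the expected sensed outcome magnitude (orosensory
    estimate of the post-ingestive effect); ``prob`` the subjective
    probability that responding is followed by any delivery.  Both are
    learned by delta rules; extinction (repeated non-delivery) drives
    ``prob`` to zero.
    """

    kappa_init: float = 0.0
    prob_init: float = 0.0
    _kappa: dict = field(default_factory=dict)
    _prob: dict = field(default_factory=dict)

    def kappa_hat(self, state, action) -> float:
        return self._kappa.get((state, action), self.kappa_init)

    def prob(self, state, action) -> float:
        return self._prob.get((state, action), self.prob_init)

    def set(self, state, action, kappa_hat: float, prob: float) -> None:
        if not (0.0 <= prob <= 1.0):
            raise ValueError(f"probability out of [0,1]: {prob}")
        if not math.isfinite(kappa_hat):
            raise ValueError(f"non-finite magnitude estimate {kappa_hat}")
        self._kappa[(state, action)] = float(kappa_hat)
        self._prob[(state, action)] = float(prob)


def outcome_model_update(
    model: OutcomeModel,
    state,
    action,
    sensed_magnitude: float,
    delivered: bool,
    config: AgentConfig,
) -> OutcomeModel:
    """Delta-rule update of the outcome model after one response.

    The probability estimate moves toward the delivery indicator; the
    magnitude estimate moves toward the sensed magnitude only when a
    delivery occurred (an unsensed delivery counts as magnitude 0 —
    the agent tastes nothing).
    """
    p = model.prob(state, action)
    p = p + config.alpha * ((1.0 if delivered else 0.0) - p)
    k = model.kappa_hat(state, action)
    if delivered:
        k = k + config.alpha * (float(sensed_magnitude) - k)
    model.set(state, action, k, p)
    return model


def mb_action_values(
    model: OutcomeModel,
    h,
    params: DriveParams,
    state,
    actions,
    dim: int = 0,
) -> np.ndarray:
    """Model-based action values: probability × approximated drive reduction.

    Each action's learned sensed magnitude is applied on dimension
    ``dim`` of the homeostatic space; ``value_a = p_a * r(H, kappa_hat_a)``.
    Near the setpoint positive magnitudes overshoot, so values turn
    negative and responding is suppressed (satiation).
    """
    h = np.atleast_1d(np.asarray(h, dtype=float))
    out = np.empty(len(actions))
    for i, a in enumerate(actions):
        k_hat = np.zeros_like(h)
        k_hat[dim] = model.kappa_hat(state, a)
        out[i] = model.prob(state, a) * approx_reward(h, k_hat, params)
    return out


def nf_policy(h: float, setpoint: float) -> str:
    """Classical negative-feedback policy: respond iff below the setpoint.

    No learning, no anticipation; the comparator against which the
    homeostatic RL agent's burst behavior is contrasted.
    """
    return "respond" if h < setpoint else "null"


def discretize_internal(h: float, bin_width: float = 1.0) -> int:
    """Deterministic, order-preserving binning of a 1-D internal state."""
    if not (bin_width > 0):
        raise ValueError(f"bin_width must be > 0, got {bin_width}")
    return int(math.floor(h / bin_width + 0.5))


def bin_center(bin_id: int, bin_width: float = 1.0) -> float:
    """Center of a bin id; round-trip error of discretization ≤ bin_width/2."""
    return bin_id * bin_width
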
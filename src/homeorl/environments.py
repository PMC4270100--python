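"""Generative task environments for the behavioral simulations.

Each environment exposes ``reset()`` and ``step(action, rng)`` with a
:class:`StepResult` carrying the external state id, the true outcome
``K`` (its effect on the internal state), the sensed outcome ``K_hat``
(orosensory approximation: ``K_hat = oral_fraction * K`` componentwise),
the elapsed time, and a terminal flag.  The internal state always
evolves by the *true* outcome; agents compute reward from the *sensed*
one.  Environments hold the internal state so that conservation
(final = initial + Σ delivered − Σ decay/expenditure) is a checkable
bookkeeping invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StepResult",
    "BoundaryWalkEnv",
    "EthanolEnv",
    "RiskEnv",
    "WaterEnv",
    "OvereatingEnv",
    "DoseChangeEnv",
]


@dataclass(frozen=True)
class StepResult:
    """One environment transition."""

    external_state: object
    outcome: np.ndarray        # true effect K on the internal state
    sensed: np.ndarray         # orosensory estimate K_hat
    dt: float = 1.0
    terminal: bool = False
    info: dict = field(default_factory=dict)


def _vec(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


class BoundaryWalkEnv:
    """1-D free walk: the agent shifts its internal state by ±1 per trial.

    No exogenous dynamics; outcomes are fully sensed.  Starting from a
    deviated state, a tabula-rasa learner performs a random walk whose
    same-direction run lengths have probability 2^-z, and learning of
    the drive-reduction punishments confines it near the setpoint.
    """

    actions = ("decrease", "increase")

    def __init__(self, init: int = 30, setpoint: int = 0):
        self.init = float(init)
        self.setpoint = float(setpoint)
        self.h = self.init

    def reset(self) -> float:
        self.h = self.init
        return self.h

    def step(self, action: str, rng=None) -> StepResult:
        k = -1.0 if action == "decrease" else 1.0
        self.h += k
        return StepResult(external_state=0, outcome=_vec(k), sensed=_vec(k))


class EthanolEnv:
    """Cued hypothermia with an optional anticipatory tolerance response.

    Per trial the agent, on seeing the cue, chooses between initiating a
    tolerance (heat-producing) response and doing nothing; ethanol is
    (on injection trials) administered afterwards and the body
    temperature follows the configured offset curves, sampled every 30
    minutes over the horizon.  The quantity fed back to the learner is
    the discounted sum of drive reductions over the whole trace.
    """

    actions = ("null", "tolerance")

    def __init__(
        self,
        drop_curve=None,
        tolerance_curve=None,
        horizon: int = 48,
        baseline: float = 0.0,
    ):
        # default piecewise-linear curves on a 30-min grid:
        # ethanol dips to -2 at the 60-min mark, recovered by 120 min;
        # the tolerance response is its half-amplitude mirror image.
        if drop_curve is None:
            drop_curve = self._piecewise(horizon, peak=-2.0)
        if tolerance_curve is None:
            tolerance_curve = self._piecewise(horizon, peak=1.0)
        self.drop_curve = _vec(drop_curve)
        self.tolerance_curve = _vec(tolerance_curve)
        for name, c in (("drop_curve", self.drop_curve),
                        ("tolerance_curve", self.tolerance_curve)):
            if len(c) != horizon + 1:
                raise ValueError(f"{name} must have horizon+1 = {horizon + 1} samples")
            if c[0] != 0.0 or c[-1] != 0.0:
                raise ValueError(f"{name} must start and return to baseline")
        self.horizon = horizon
        self.baseline = float(baseline)

    @staticmethod
    def _piecewise(horizon: int, peak: float) -> np.ndarray:
        """Offset curve: 0 at t=0, `peak` at sample 2 (60 min), 0 from sample 4."""
        c = np.zeros(horizon + 1)
        c[1] = peak / 2.0
        c[2] = peak
        c[3] = peak / 2.0
        return c

    def trial_trace(self, action: str, inject: bool = True) -> np.ndarray:
        """Temperature trace (absolute) for one trial; superposition of curves."""
        trace = np.full(self.horizon + 1, self.baseline)
        if inject:
            trace = trace + self.drop_curve
        if action == "tolerance":
            trace = trace + self.tolerance_curve
        return trace


class RiskEnv:
    """Place-preference energy task: certain vs. risky compartment.

    Both compartments deliver the same expected energy payoff per trial,
    equal to the fixed per-trial expenditure, so the internal state has
    zero net drift everywhere; only the payoff variance differs.  Risk
    aversion then follows purely from the concavity of the reward in the
    outcome magnitude.
    """

    actions = ("stay", "switch")
    compartments = ("certain", "risky")

    def __init__(
        self,
        mean_payoff: float = 1.0,
        risky_payoffs=(0.0, 2.0),
        expenditure: float = 1.0,
        init: float = 0.0,
    ):
        self.mean_payoff = float(mean_payoff)
        self.risky_payoffs = tuple(float(p) for p in risky_payoffs)
        if not np.isclose(np.mean(self.risky_payoffs), self.mean_payoff):
            raise ValueError("risky payoff mean must equal the certain payoff")
        if not np.isclose(expenditure, self.mean_payoff):
            raise ValueError("expenditure must equal the mean payoff (zero drift)")
        self.expenditure = float(expenditure)
        self.init = float(init)
        self.h = self.init
        self.compartment = "certain"

    def reset(self, compartment: str = "certain") -> tuple:
        self.h = self.init
        self.compartment = compartment
        return self.compartment

    def step(self, action: str, rng: np.random.Generator) -> StepResult:
        if action == "switch":
            self.compartment = (
                "risky" if self.compartment == "certain" else "certain"
            )
        if self.compartment == "certain":
            payoff = self.mean_payoff
        else:
            payoff = self.risky_payoffs[rng.integers(len(self.risky_payoffs))]
        k = payoff - self.expenditure
        self.h += k
        return StepResult(
            external_state=self.compartment,
            outcome=_vec(k),
            sensed=_vec(k),
            info={"payoff": payoff},
        )


class WaterEnv:
    """Key-pecking water self-administration with oral/fistula routes.

    Pretraining: the green key delivers water orally.  Test: the green
    key delivers nothing; a novel yellow key delivers water of which
    ``oral_fraction`` is sensed (tasted) and the remainder is delivered
    intragastrically.  The internal state rises by the full delivered
    amount regardless of route — satiation depends only on total intake,
    reinforcement only on the sensed part.
    """

    actions = ("nul", "green", "yellow")

    def __init__(
        self,
        group: str = "oral",
        phase: str = "pretrain",
        oral_fraction: float = 1.0,
        magnitude: float = 1.0,
        init: float = -50.0,
        setpoint: float = 0.0,
    ):
        if group not in ("oral", "fistula"):
            raise ValueError(f"unknown group {group!r}")
        if phase not in ("pretrain", "test"):
            raise ValueError(f"unknown phase {phase!r}")
        if not (0.0 <= oral_fraction <= 1.0):
            raise ValueError(f"oral_fraction must be in [0, 1], got {oral_fraction}")
        self.group = group
        self.phase = phase
        self.oral_fraction = float(oral_fraction)
        self.magnitude = float(magnitude)
        self.init = float(init)
        self.setpoint = float(setpoint)
        self.h = self.init
        self.total_ingested = 0.0

    def reset(self) -> None:
        self.h = self.init
        self.total_ingested = 0.0

    def _delivery(self, action: str) -> tuple[float, float]:
        """(delivered, oral fraction of this delivery) for an action."""
        if action == "green":
            if self.phase == "pretrain":
                return self.magnitude, 1.0
            return 0.0, 0.0
        if action == "yellow":
            if self.phase == "pretrain":
                return 0.0, 0.0
            frac = self.oral_fraction if self.group == "oral" else 0.0
            return self.magnitude, frac
        return 0.0, 0.0

    def step(self, action: str, rng=None) -> StepResult:
        delivered, frac = self._delivery(action)
        self.h += delivered
        self.total_ingested += delivered
        return StepResult(
            external_state=self.phase,
            outcome=_vec(delivered),
            sensed=_vec(frac * delivered),
            info={"delivered": delivered > 0, "oral_fraction": frac},
        )


class OvereatingEnv:
    """Normal vs. hyperpalatable food intake with per-step energy decay.

    Both foods have the same nutritional content ``K``; the palatable
    one additionally carries a drive-independent hedonic bonus ``T``
    added to the computed reward but never to the internal state.  Under
    quadratic drive the defended state settles near ``H* + T/(2K)``.
    """

    def __init__(
        self,
        mode: str = "single",
        T_palatable: float = 20.0,
        K: float = 1.0,
        init: float = -50.0,
        setpoint: float = 0.0,
        decay: float = 0.1,
        palatable: bool = True,
    ):
        if mode not in ("single", "choice"):
            raise ValueError(f"unknown mode {mode!r}")
        if not (K > 0):
            raise ValueError(f"nutritional content K must be > 0, got {K}")
        if not (decay > 0):
            raise ValueError(f"decay must be > 0, got {decay}")
        self.mode = mode
        self.T_palatable = float(T_palatable)
        self.K = float(K)
        self.init = float(init)
        self.setpoint = float(setpoint)
        self.decay = float(decay)
        self.palatable = palatable  # which food the single-option group has
        if mode == "single":
            self.actions = ("food", "nul")
        else:
            self.actions = ("normal", "palatable", "nul")
        self.h = self.init

    def reset(self) -> None:
        self.h = self.init

    def bonus(self, action: str) -> float:
        """Hedonic bonus T carried by the chosen food (0 for normal/nul)."""
        if action == "palatable" or (action == "food" and self.palatable):
            return self.T_palatable
        return 0.0

    def step(self, action: str, rng=None) -> StepResult:
        k = self.K if action in ("food", "normal", "palatable") else 0.0
        self.h += k - self.decay
        return StepResult(
            external_state=0,
            outcome=_vec(k),
            sensed=_vec(k),
            info={"bonus": self.bonus(action), "delivered": k > 0},
        )


class DoseChangeEnv:
    """Lever-pressing with a within-session dose reduction.

    The lever delivers ``dose_phase1`` during the first phase and the
    much smaller ``dose_phase2`` during the second; the internal state
    decays by a constant amount per time step.  Deliveries are fully
    sensed.  Response rates are measured in sliding windows to expose
    the transient burst the learning agent shows after the switch.
    """

    actions = ("nul", "press")

    def __init__(
        self,
        dose_phase1: float = 1.0,
        dose_phase2: float = 0.125,
        decay_rate: float = 0.05,
        phase_length: int = 240,
        init: float = 0.0,
        setpoint: float = 0.0,
    ):
        if not (dose_phase1 > dose_phase2 > 0):
            raise ValueError("require dose_phase1 > dose_phase2 > 0")
        if not (decay_rate > 0):
            raise ValueError(f"decay_rate must be > 0, got {decay_rate}")
        self.dose_phase1 = float(dose_phase1)
        self.dose_phase2 = float(dose_phase2)
        self.decay_rate = float(decay_rate)
        self.phase_length = int(phase_length)
        self.init = float(init)
        self.setpoint = float(setpoint)
        self.h = self.init
        self.t = 0

    def reset(self) -> None:
        self.h = self.init
        self.t = 0

    @property
    def current_dose(self) -> float:
        return self.dose_phase1 if self.t < self.phase_length else self.dose_phase2

    def step(self, action: str, rng=None) -> StepResult:
        k = self.current_dose if action == "press" else 0.0
        self.h += k - self.decay_rate
        self.t += 1
        return StepResult(
            external_state=0,
            outcome=_vec(k),
            sensed=_vec(k),
            info={"delivered": k > 0, "time": self.t},
        )
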
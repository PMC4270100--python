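"""Homeostatic space, drive, and drive-reduction reward.

The internal (physiological) state of an agent is a point ``H`` in an
N-dimensional metric space whose dimensions are regulated variables
(body temperature, body water, energy reserve, ...).  The motivational
state is the *drive*: the distance of ``H`` from the setpoint ``H*``
under an (m, n)-parameterized metric,

    D(H) = ( sum_i |h*_i - h_i|**n ) ** (1/m)

and the primary reward of an outcome ``K`` (its impact vector on the
internal state) is the drive reduction it causes,

    r(H, K) = D(H) - D(H + K).

All functions here are pure; learning and environment dynamics live in
:mod:`homeorl.agents` and :mod:`homeorl.environments`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DriveParams",
    "drive",
    "reward",
    "approx_reward",
    "palatable_reward",
    "settling_point",
    "surprise",
    "taylor_reward",
    "drive_gradient",
]


def _as_state(x, name: str) -> np.ndarray:
    """Coerce a homeostatic point / outcome to a finite 1-D float array."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-D vector, got shape {arr.shape}")
    if arr.size < 1:
        raise ValueError(f"{name} must have at least one dimension")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must have finite entries, got {arr}")
    return arr


@dataclass(frozen=True)
class DriveParams:
    """Setpoint and metric exponents of the drive function.

    Parameters
    ----------
    setpoint
        The ideal internal state ``H*`` (zero-drive point).
    m, n
        Strictly positive free exponents of the metric.  The behavioral
        guarantees (dose monotonicity, deprivation potentiation,
        irrelevant-drive inhibition, concavity/risk aversion) hold for
        ``n > m > 1``; the defaults (m=3, n=4) satisfy this.
    """

    setpoint: np.ndarray = field(default_factory=lambda: np.zeros(1))
    m: float = 3.0
    n: float = 4.0

    def __post_init__(self):
        sp = _as_state(self.setpoint, "setpoint")
        object.__setattr__(self, "setpoint", sp)
        if not (self.m > 0 and self.n > 0):
            raise ValueError(f"exponents must be positive, got m={self.m}, n={self.n}")

    @property
    def ndim(self) -> int:
        return self.setpoint.size

    def _check(self, h: np.ndarray, name: str) -> np.ndarray:
        arr = _as_state(h, name)
        if arr.size != self.setpoint.size:
            raise ValueError(
                f"{name} has dimension {arr.size}, setpoint has {self.setpoint.size}"
            )
        return arr


def drive(h, params: DriveParams) -> float:
    """Motivational drive: distance of the internal state from the setpoint.

    ``D(H) = (sum_i |h*_i - h_i|**n)**(1/m)``.  Nonnegative, zero exactly
    at the setpoint, and symmetric under reflection of any coordinate
    about its setpoint value.
    """
    h = params._check(h, "H")
    dev = np.abs(params.setpoint - h)
    return float(np.sum(dev ** params.n) ** (1.0 / params.m))


def reward(h, k, params: DriveParams) -> float:
    """Drive-reduction reward of outcome ``K`` received in state ``H``.

    Positive iff the outcome moves the state strictly closer to the
    setpoint in the drive metric.
    """
    h = params._check(h, "H")
    k = params._check(k, "K")
    return drive(h, params) - drive(h + k, params)


def approx_reward(h, k_hat, params: DriveParams) -> float:
    """Reward computed from the *sensed* outcome estimate ``K_hat``.

    Identical formula to :func:`reward` applied to the orosensory
    approximation of the outcome's post-ingestive effect.  An unbiased
    estimate (``K_hat == K``) recovers :func:`reward` exactly; an
    unsensed delivery (``K_hat == 0``, e.g. intravenous or intragastric)
    yields zero reward regardless of its true physiological effect.
    """
    return reward(h, k_hat, params)


def palatable_reward(h, k, T: float, params: DriveParams) -> float:
    """Drive-reduction reward augmented by a drive-independent hedonic bonus.

    ``r = D(H) - D(H + K) + T`` with ``T >= 0``; ``T = 0`` models normal
    food, ``T > 0`` hyperpalatable food whose taste overrides satiety.
    """
    if not (np.isfinite(T) and T >= 0):
        raise ValueError(f"palatability term must be finite and >= 0, got {T}")
    return reward(h, k, params) + float(T)


def settling_point(setpoint: float, T: float, K: float) -> float:
    """Defended internal state under a palatability bonus, quadratic drive.

    For 1-D quadratic drive (``D = (h - h*)**2``) the bonus ``T`` on an
    outcome of fixed size ``K`` is algebraically equivalent to shifting
    the setpoint to ``h* + T/(2K)``: the state is defended above the true
    setpoint, and the shift shrinks as the real nutritional content ``K``
    grows.
    """
    if K == 0:
        raise ValueError("settling point undefined for K = 0")
    return float(setpoint) + float(T) / (2.0 * float(K))


def surprise(h, params: DriveParams) -> float:
    """Negative log-probability of the state under the equilibrium density.

    With ``p(H) ∝ exp(-D(H))``, surprise ``-ln p(H)`` equals the drive
    (up to the normalizing constant, fixed per species); numerically this
    is :func:`drive`.  Exposed separately so the equivalence between
    drive minimization and surprise minimization is directly assertable.
    """
    return drive(h, params)


def drive_gradient(h, params: DriveParams) -> np.ndarray:
    """Gradient of the drive with respect to the internal state.

    Defined away from the setpoint; at the setpoint the metric has a kink
    for ``n <= m`` and the gradient is rejected (it is the zero vector in
    the smooth case ``n > m``).
    """
    h = params._check(h, "H")
    dev = params.setpoint - h  # delta_i = h*_i - h_i
    absdev = np.abs(dev)
    s = np.sum(absdev ** params.n)
    if s == 0.0:
        if params.n > params.m:
            return np.zeros_like(h)
        raise ValueError("drive gradient undefined at the setpoint for n <= m")
    # dD/dh_i = (1/m) s^{1/m-1} * n |delta_i|^{n-1} * (-sign(delta_i))
    with np.errstate(divide="raise", invalid="raise"):
        inner = params.n * absdev ** (params.n - 1.0)
    return (1.0 / params.m) * s ** (1.0 / params.m - 1.0) * inner * (-np.sign(dev))


def taylor_reward(h, k, params: DriveParams) -> float:
    """First-order (multiplicative) approximation of the reward.

    ``r ≈ -K · ∇D(H)``: the rewarding value is proportional to the
    outcome magnitude times the local deprivation sensitivity.  Exact for
    a linear 1-D metric below the setpoint; the error is O(||K||²) for
    smooth metrics.
    """
    k = params._check(k, "K")
    return float(-k @ drive_gradient(h, params))
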
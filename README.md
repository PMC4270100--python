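# homeorl

Homeostatic reinforcement learning (HRL): a simulator library for
studying how motivated behavior can be derived from physiological
regulation.  It is aimed at computational-neuroscience and
behavioral-modelling work in which reward is not an axiom but a
quantity constructed from the internal state of the agent.

The core idea: the internal state H = (h_1, …, h_N) lives in a space of
regulated variables (temperature, body water, energy); the *drive* is
its distance from the setpoint H*,

    D(H) = ( Σ_i |h*_i − h_i|^n )^(1/m),

and the primary reward of an outcome K is the drive reduction it causes,
r(H, K) = D(H) − D(H + K), approximated in practice from the outcome's
sensed (orosensory) properties K̂.  Feeding this reward to standard
learning agents yields, in one framework: anticipatory (e.g. cued
tolerance) responding, risk aversion from reward concavity, the
rise–fall pattern of water self-administration and its dependence on
delivery route, over-eating of hyperpalatable food with a defended
state at the settling point H* + T/(2K), a transient response burst
after a dose reduction, and self-confinement of a naive agent near the
setpoint.  The package also machine-checks the framework's analytic
backbone: for discount factor γ < 1, the trajectory maximizing the sum
of discounted rewards (SDR) is exactly the one minimizing the sum of
discounted drives (SDD), via the identity SDR = D(H_0) + (γ−1)·SDD, and
this equivalence collapses at γ = 1.

## Layout

| module | contents |
|---|---|
| `homeorl.homeostat` | drive, reward, sensed-outcome reward, palatability bonus, settling point, surprise, first-order (Taylor) reward |
| `homeorl.agents` | tabular Q-learning, delayed-return learner, model-based outcome learner, negative-feedback comparator, softmax policy |
| `homeorl.environments` | boundary walk, cued tolerance, risk, water self-administration, over-eating, dose reduction |
| `homeorl.theory` | trajectory enumeration, SDD/SDR, equivalence verification, sequencing preference |
| `homeorl.experiments` / `homeorl.cli` | seeded runners, YAML configs, result serialization, `homeorl` command |

## Worked example

Verify the stability/reward equivalence on a small lattice instance
(start 3, setpoint 0, trajectories up to length 7, γ = 0.9):

```
$ homeorl theory --start 3 --setpoint 0 --max-len 7 --gamma 0.9
{
  "equivalent": true,
  "gamma": 0.9,
  "max_identity_residual": 4.440892098500626e-16,
  "n_sdd_minimizers": 1,
  "n_sdr_maximizers": 1,
  "n_trajectories": 27,
  "sdr_variance": 0.297626823856496
}
```

Of the 27 setpoint-terminating trajectories, exactly one minimizes the
summed discounted drives and the same one maximizes the summed
discounted rewards (the direct three-step descent); the decomposition
identity holds to machine precision.  Rerunning with `--gamma 1.0`
drives `sdr_variance` to 0: without discounting every stabilizing
trajectory is equally valued, so reward seeking no longer favors the
short path.

Run a behavioral experiment — one naive agent freely stepping a 1-D
internal state from 30 toward the setpoint 0 for a million trials:

```
$ homeorl run boundary_walk --seed 1 --out results/
{
  "final_state": 0,
  "max_abs_deviation": 30.0,
  "n_trials": 1000000
}
```

The agent learns the drive-reduction punishments fast enough that over
1e6 trials it never visits a state more deviated than its starting
point — it confines itself near the setpoint without ever exploring
the dangerous extremes.  `results/` receives the visit histogram as CSV
and a JSON summary with the full configuration and seed.

From Python:

```python
from homeorl import DriveParams, drive, reward

p = DriveParams(setpoint=[0.0], m=3, n=4)
drive([-5.0], p)           # 8.5499  (thirst level at deficit 5)
reward([-5.0], [3.0], p)   # 6.0301  (value of 3 water units when 5 short)
reward([0.0], [3.0], p)    # -4.3267 (the same outcome at satiety is punishing)
```

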
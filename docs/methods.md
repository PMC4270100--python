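# Methods

## Model

`homeorl` simulates behavior under a homeostatic definition of primary
reward.  The internal (physiological) state is a point
H = (h_1, …, h_N) in an N-dimensional space of regulated variables;
the ideal state is the setpoint H* = (h*_1, …, h*_N).  The
motivational state is the **drive**

    D(H) = ( Σ_i |h*_i − h_i|^n )^(1/m),        n, m > 0,

and the **reward** of an outcome K (the outcome's additive effect on
the internal state, H ← H + K) is the drive reduction it produces:

    r(H, K) = D(H) − D(H + K).

Agents never observe post-ingestive drive reduction directly; they
compute reward from the *sensed* (orosensory) estimate K̂ of the
outcome, r(H, K̂) = D(H) − D(H + K̂), while the state itself always
evolves by the true K.  An unsensed delivery (intravenous, intragastric
fistula) has K̂ = 0 and is therefore not reinforcing, although it still
satiates.  Hyperpalatable food is modelled by a drive-independent bonus
T ≥ 0 added to the computed reward (never to the state); for 1-D
quadratic drive (n = 2, m = 1) this is algebraically identical to
shifting the setpoint to H* + T/(2K), which is the settling point the
intake simulations defend.

### Drive-form conventions

The exponent arrangement above is the only one for which the four
behavioral guarantees hold jointly when n > m > 1: reward increasing in
dose on 0 < k < h* − h, increasing in deprivation, decreasing in
irrelevant deviations (N ≥ 2), and concave in dose (risk aversion).
With m = n = 1 the metric is the city-block (L1) distance; the
Euclidean case is m = n = 2.  The drive has a kink at the setpoint for
n ≤ m, so the gradient-based first-order reward approximation
r ≈ −K·∇D(H) rejects evaluation there (in the smooth case n > m the
gradient at the setpoint is the zero vector).  Default exponents are
m = 3, n = 4 wherever an experiment does not fix its own.

## Analytic results checked by enumeration

For a trajectory p = {K_0, …, K_{w−1}} ending at the setpoint, define
SDD = Σ γ^t D(H_{t+1}) (sum of discounted drives) and
SDR = Σ γ^t (D(H_t) − D(H_{t+1})) (sum of discounted rewards).  The
per-trajectory identity SDR = D(H_0) + (γ − 1)·SDD implies that for
γ < 1 the SDR-maximizing trajectory set equals the SDD-minimizing set
(reward seeking ≡ stability seeking), and that at γ = 1 the SDR
telescopes to D(H_0) − D(H_w): every setpoint-terminating trajectory is
equally valued and reward seeking no longer constrains the path —
the normative argument for temporal discounting.

`homeorl.theory` checks all three statements exhaustively on lattice
instances.  The set of setpoint-terminating trajectories is infinite,
so enumeration truncates at a maximum length; under γ < 1 the optimum
is attained by the shortest descent, so truncating at the L1 distance
plus a small slack suffices (slack is an argument).  A trajectory
qualifies iff its final state equals the setpoint exactly; intermediate
setpoint visits are allowed, and 1-D counts are validated against the
binomial closed form C(w, (w+a)/2) summed over admissible lengths.
Residual tolerance for the identity is 1e−10; argmin/argmax ties are
resolved with a 1e−9 band.

## Agents

* **Model-free**: tabular Q-learning,
  δ = r + γ·max_a′ Q(s′, a′) − Q(s, a), Q ← Q + αδ, with softmax
  action selection.
* **Delayed-return learner**: for trial-structured tasks whose
  consequences unfold over a long horizon (cued tolerance), the action
  value is updated by delta rule toward the realized discounted sum of
  drive reductions over the whole post-action trace.
* **Model-based**: per action, a delta-rule estimate of the delivery
  probability and of the sensed outcome magnitude κ̂; action values are
  probability × approximated drive reduction of κ̂ in the current
  state.  Satiation falls out of the value turning negative as the
  state nears the setpoint; extinction falls out of the probability
  decaying.
* **Negative-feedback comparator**: respond iff h < h*, no learning —
  the classical regulation policy used as the contrast in the
  dose-reduction experiment.

### Exploration parameter

The exploration parameter β is treated as a *temperature*: choice
probabilities are softmax in value/β, so larger β means more
exploration.  This keeps the parameter's direction consistent with its
role as a rate of exploration, and it is the reading under which the
boundary-walk simulations reproduce the published deviation bounds
(≤ 40 for a single agent over 1e6 trials; population extreme well below
61); under the inverse reading the same runs exceed those bounds
severalfold.  The low-level `softmax_policy(values, beta)` primitive
takes the softmax coefficient directly (p ∝ exp(β·v)); the experiment
runners pass 1/β.

## Environments and defaults

All tasks are generative; no external data is read.  Defaults are the
published values where printed, otherwise fixed once at values a
behavioral modeller would call realistic; every default is a keyword
argument.

* **Boundary walk** — 1-D state, actions ±1 per trial, fully sensed;
  α = 0.4, β = 0.05, γ = 0.9, n = 4 (m = 3), start 30, setpoint 0.
  Single agent: 1e6 trials; population: 1e5 agents × 1500 trials.  The
  population engine is vectorized across agents with one counter-based
  Philox stream drawing an agents-length vector per trial (reproducible
  given seed, agent count and trial count); action values are float32
  to keep the 1e5-agent table in memory.  The state lattice is clipped
  at ±200, far beyond any excursion observed (extremes ≈ 50).
* **Cued tolerance** — per trial, choose tolerance vs. null on cue;
  temperature offsets on a 30-min grid over 24 h.  Ethanol dips the
  temperature by 2 units peaking at 60 min and recovering by 120 min;
  the tolerance response is the half-amplitude mirror image.  Returns
  are discounted per 30-min step at 0.95; learning by delta rule toward
  the return; β = 0.1.  One extinction trial (no injection) follows
  training.
* **Risk** — two compartments with equal expected energy payoff (1 unit
  = the per-trial expenditure): certain pays 1; risky pays 0 or 2
  equiprobably.  Q-learning over (compartment, action) with β = 1;
  preference is occupancy of the certain compartment over the final
  quarter of 2000 trials.
* **Water self-administration** — pretraining: green key delivers 1
  water unit orally; test (after re-deprivation to −50): green inert,
  novel yellow key delivers 1 unit of which `oral_fraction` is sensed.
  Model-based agent, β = 0.2, with an effort cost of 0.5 drive units
  per key peck (without an effort cost a zero-valued key is still
  chosen at chance by the softmax and responding would never
  extinguish).  The learned κ̂ converges to the sensed fraction of the
  delivery: 1.0 fully oral, 0.5 half-oral, 0 fistula.
* **Over-eating** — quadratic drive (n = 2, m = 1), start −50,
  setpoint 0, food K = 1, decay 0.1/step, palatability bonus T = 20,
  β = 0.2; the plateau (mean state over the final quarter of 4000
  steps) is compared with the settling point H* + T/(2K) = 10.
* **Dose reduction** — lever delivers 1 unit for 240 steps, then 0.125;
  state decays 0.05/step.  The HRL agent presses greedily whenever the
  approximated drive reduction of its *expected* outcome is positive,
  with the expectation initialized at the phase-1 dose (a trained
  animal) and updated by delta rule (α = 0.4); stale expectations after
  the switch produce a burst of pressing.  Response rates use a 10-step
  sliding window; the steady phase-2 inter-press interval is
  dose/decay = 2.5 steps by mass balance.

### What the generators do and do not emulate

The environments reproduce the *contingency structure* of the
behavioral paradigms (delivery routes, payoff schedules, phase
switches, cue–outcome timing), not their physiology: there are no
pharmacokinetics, no absorption delays, no measurement noise on the
internal state, and deterministic per-step decay stands in for
metabolism.  Passing tests therefore demonstrate that the reward
construction plus standard learning rules generate the qualitative
behavioral patterns under idealized dynamics; they do not calibrate the
model to animal data, and the two published figure datasets that report
animal measurements are deliberately only matched in pattern.

## Numerical choices

Softmax logits are max-shifted, and the scalar engines clamp logit
differences to ±50 before exponentiation.  Drive on the walk lattice is
precomputed per state.  Greedy ties in the dose-reduction agent resolve
to not pressing (a strictly positive expected improvement is required);
softmax ties elsewhere are resolved by the run's seeded generator.
Seeds fan out from a single root via `numpy.random.SeedSequence.spawn`,
so the acceptance quantities are independent of execution order.
Degenerate inputs (dimension mismatches, non-finite states, zero
nutritional content in the settling point, empty action sets,
enumeration explosions) raise `ValueError` at the boundary rather than
propagating NaNs.

## Problem sizes

The test suite runs the published sizes where they are cheap (1e6
boundary-walk trials, 1e5-agent population, 1e5 Monte-Carlo triples for
the run-length check) and reduced cohorts elsewhere (100 agents for the
risk and tolerance tasks, 10-agent-scale single runs for intake tasks);
the full-size population extreme was additionally confirmed on five
seeds (range 45–50, scaled 1e4-agent runs 42–44 and never above the
full-scale extreme).

## Known limitations

Fixed setpoints and symmetric drive (no gain/loss asymmetry); fully
observable internal state; exponential discounting only; tabular agents
(no function approximation or eligibility traces); the continuous-time
statements of the theory are realized in their discrete-time form.
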
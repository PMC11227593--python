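# navactor

Simulation and analysis of goal-directed human navigation as **optimal
feedback control under uncertainty**. The package is for computational
cognitive scientists who want to generate and analyze behavior in
triangle-completion (homing) experiments: an agent walks a three-legged
outbound path past landmarks, is subjected to one of four cue manipulations
(self-motion only, landmark with disorientation, combined, or a covert
landmark rotation creating a cue conflict), and walks back to the remembered
first goal. Where it stops — and how those stops scatter across trials — is
the data.

## The model

The agent's true state is its pose and the allocentric coordinates of all
landmarks and goals,

x = (x, y, θ, m₁ₓ, m₁ᵧ, …, m_Lₓ, m_Lᵧ),

with unicycle dynamics driven by commands u = (v, w) carrying
signal-dependent motor noise, Q(u) = diag(α₁²v² + α₂²w², α₃²v² + α₄²w²), and
egocentric range/bearing observations of in-view landmarks with
state-dependent noise that grows with distance and retinal eccentricity.
The agent never sees x; it maintains a joint Gaussian belief b = (μ, Σ) over
pose *and* map, updated by an extended Kalman filter (EKF-SLAM), with
landmarks entered on first sight and remembered locations decaying as a 2-D
random walk of rate δ_xy (an uncertain cognitive map). Actions come from
receding-horizon trajectory optimization over the belief,

min J = w₁ Σₜ (pₜ − gₜ)ᵀ C_q (pₜ − gₜ) + w₂ Σₜ tr Σ_pose,t
      + w₃ Σₜ tr Σ_map,t + w₄ Σₜ (uₜᵀ C_r uₜ + C_tr (vₜwₜ)²),

where gₜ is the *believed* goal location and the field-of-view indicator is
relaxed by an annealed sigmoid; the first N steps are executed with EKF
feedback and the agent replans (model-predictive control). A trial ends when
the believed position matches the believed goal — so endpoints err exactly
as the belief errs.

The analysis layer reproduces the ideal-observer treatment of such
endpoints: response variability as the SD of distances to the mean response,
the optimal landmark weight w_lm = σ_sm⁻²-normalized precision weighting
with its predicted combined-cue variance σ² = w_sm²σ_sm² + w_lm²σ_lm²,
relative response proximity rprox = d_sm/(d_sm + d_lm) in conflict trials,
von Mises analogues for heading direction, and energy-distance permutation
tests between 2-D endpoint distributions.

## Worked example

One 15° conflict trial in the simultaneous-goals environment:

```python
import numpy as np
from navactor import DEFAULT_NOISE, PlannerConfig, TrialProtocol
from navactor.task_protocols import run_trial
from navactor.analysis import relative_proximity

proto = TrialProtocol(condition="conflict", goals_visible_mode="all_at_start",
                      waiting_time=8.0, conflict_angle=np.deg2rad(15))
rec = run_trial("nardini_like", proto, DEFAULT_NOISE, seed=11,
                config=PlannerConfig(visibility_schedule=(8.0, 3.0)))
prox = relative_proximity([rec.stop_x, rec.stop_y],
                          [rec.home_x, rec.home_y],
                          [rec.home_lm_x, rec.home_lm_y])
print(f"stop location        = ({rec.stop_x:.2f}, {rec.stop_y:.2f}) m")
print(f"true home            = ({rec.home_x:.2f}, {rec.home_y:.2f}) m")
print(f"landmark-consistent  = ({rec.home_lm_x:.2f}, {rec.home_lm_y:.2f}) m")
print(f"relative landmark proximity rprox = {prox.rprox_lm:.2f}")
```

prints

```
stop location        = (-0.17, 1.59) m
true home            = (0.00, 2.50) m
landmark-consistent  = (-0.18, 1.63) m
relative landmark proximity rprox = 0.95
```

The agent stops almost exactly where the *rotated* landmarks say home should
be (rprox = 0.95 on the 0 = self-motion … 1 = landmark scale): after the
covert rotation it expects landmarks straight ahead, attributes the
discrepancy to its own — genuinely uncertain — heading, and resets that
heading, so homing is precise but biased. This single mechanism is the
package's account of why conflict responses follow landmarks while response
variability still drops.

Batch runs and analyses are available from the shell:

```bash
navactor run --env nardini_like --participants 5 --trials 4 --seed 1 --out out/
navactor analyze variability out/endpoints.csv
navactor analyze conflict out/endpoints.csv
navactor config show
```

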
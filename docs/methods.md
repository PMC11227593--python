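# Methods

## The model

`navactor` simulates a navigating agent solving the triangle-completion
(homing) task as optimal feedback control under uncertainty. The true world
state is the agent's planar pose (x, y, θ) plus the fixed allocentric
coordinates of L landmarks and goals. Three ingredients define the actor:

**Generative dynamics and observations.** The pose follows discrete unicycle
dynamics, x ← x + cos θ · v · dt, y ← y + sin θ · v · dt, θ ← θ + w · dt, with
commands u = (v, w). Executed commands carry signal-dependent Gaussian noise
with covariance Q(u) = diag(α₁²v² + α₂²w², α₃²v² + α₄²w²): fast movement is
noisy movement, standing still is noise-free. Landmarks inside the field of
view yield egocentric range/bearing observations with state-dependent
Gaussian noise: range variance d·(σ_r,max²(1 − cos β) + σ_r,min²) and bearing
variance log d·(σ_ψ,max²(1 − cos β) + σ_ψ,min²), where β is the eccentricity
of the landmark relative to the gaze direction — far and peripheral objects
are seen poorly. Data association is known.

**Belief.** The agent never sees the true state; it carries a joint Gaussian
belief (μ, Σ) over pose *and* map, updated by an EKF: prediction through the
linearized dynamics with the commanded control, batch correction with all
visible landmarks (innovation bearings wrapped, covariance re-symmetrized,
a negative eigenvalue below −10⁻⁸ fails loudly). A landmark enters the
belief the first time it is seen, via the inverse observation model with
first-order uncertainty propagation; we deliberately avoid the
large-prior-variance alternative, which is known to produce EKF
linearization artifacts. Remembered map coordinates decay as a genuine random
walk: every initialized landmark's variance grows by δ_xy per coordinate per
second, and in the generative simulation the remembered *means* take the
matching random-walk steps (`mean_drift`, on by default; the filter already
models this drift through the added process noise, so belief and generative
model stay consistent). The drift matters: were memory decay pure variance
growth, remembering would cost nothing in actual endpoint scatter and the
combined condition would beat the static cue-integration prediction by far
more than the data allow. The decay acts on the memory; the physical
landmarks never move except by the covert conflict rotation.

**Planning.** Every replan solves a finite-horizon trajectory optimization
over the mean trajectory: minimize

J = w₁ Σ (p_t − g_t)ᵀ C_q (p_t − g_t) + w₂ Σ tr Σ_pose,t + w₃ Σ tr Σ_map,t
  + w₄ Σ (u_tᵀ C_r u_t + C_tr (v_t w_t)²)

subject to the dynamics and box bounds on v and w, where g_t is the
*believed* goal location. Covariances are propagated inside the objective
(maximum-likelihood observations: means follow pure dynamics, covariances
shrink where landmarks are visible) but are not decision variables. The hard
field-of-view indicator is relaxed by a sigmoid 1 − 1/(1 + e^{−a·s}) of a
signed distance s = max(r·(|ψ| − half-angle), r − max-range), annealed over
a decreasing steepness schedule on cold solves. The first N steps of the
T-step plan are executed through the noisy world model with EKF feedback,
then the agent replans (model-predictive control). The agent stops when the
*believed* position is within `goal_tolerance` of the *believed* goal — so
endpoints err exactly as the belief errs, which is the mechanism that
produces homing errors.

**Reorientation.** If no landmark has been observed for a while and pose
uncertainty is high, the agent rotates in place toward the believed bearing
of the nearest believed landmark until one enters the true field of view,
then fuses it; if a full sweep finds nothing (landmarks removed), it
continues on dead reckoning and does not sweep again until an observation
arrives.

## Task protocols

A trial is outbound → manipulation → homing. The outbound path visits three
goals; goals are either all present from the start or revealed sequentially
after each completed leg (deferred initialization eligibility, not deferred
physical existence). All conditions include a waiting period in darkness
during which the remembered map decays. Then per condition: *self-motion* —
landmarks are unobservable during homing; *landmark* — a Gaussian positional
offset is applied identically to the true position and the belief mean,
followed by a simulated noisy swivel-chair rotation (true heading follows
the noisy turn, the belief keeps its stale heading with explicitly inflated
pose uncertainty); *combined* — waiting only; *conflict* — the true
landmarks are rotated about the third goal while the belief is untouched.
Homing always targets the belief's stored first-goal estimate, never the
true goal. Each trial is simulated independently with a seed derived from
(base seed, participant, condition, trial), so there is no trial-to-trial
learning and results are order-insensitive.

The conflict mechanism deserves a note because it carries the headline
qualitative result: after the covert rotation the agent turns around
expecting landmarks straight ahead; seeing them elsewhere, the EKF
attributes the discrepancy mostly to its own (genuinely uncertain) heading
and resets it, so subsequent homing is precise but biased toward the
landmark-consistent home. Without motor noise the internal heading is
trusted more, corrections are weaker, and the bias shrinks — the ablation
direction the tests check.

## Parameters

The original studies' parameter table is not reproduced here; all defaults
are the package's own choices, made once from the constraints discussed in
the literature the model draws on, and flagged non-canonical.

| Parameter | Default | Units | Why |
|---|---|---|---|
| α₁, α₄ | 0.25 | – | step-length and turning variability of human walking (CV ≈ 25%) |
| α₂, α₃ | 0.05 | – | cross terms (veering, translation while turning) are small |
| σ_r,min, σ_r,max | 0.10, 0.20 | variance coeff. | ~0.2 m range SD at 5 m, growing with distance/eccentricity |
| σ_ψ,min, σ_ψ,max | 0.10, 0.20 | variance coeff. | ~6° bearing SD at e m, growing with distance/eccentricity |
| δ_xy | 0.01 | m²/s | slow memory decay; ~0.3 m SD drift over a 10 s wait |
| w₁..w₄ | 1, 0.1, 0.05, 0.1 | – | goal-dominated cost giving near-straight legs with smooth turns |
| C_q, C_r, C_tr | I, 0.1·I, 0.1 | – | as above |
| v bounds | [−0.5, 1.5] | m/s | walking speeds; slow backward stepping allowed (below) |
| w bounds | [−2, 2] | rad/s | comfortable turning |
| T, N | 1.5 s, 0.5 s | – | planning/control horizons; endpoints are insensitive over 0.5–3 s |
| dt | 0.25 | s | coarse step for desk-scale batches; statistics are dt-robust (below) |
| goal_tolerance | 0.1 | m | stop radius on the believed distance |
| waiting time | 8 | s | low end of the 8–20 s range used across studies |
| disorientation | offset SD 0.3 m, 1.5 rad/s × 6 s, +1.5 rad² heading | | post-disorientation heading SD ≈ 70°, i.e. genuinely disoriented |
| conflict angle | 15° | | the smallest (undetected) conflict used across studies |

**dt-scaling.** All noise intensities are per unit time: the per-step
control-noise covariance is Q(u)/dt (so accumulated pose variance over a
fixed duration is dt-independent to first order) and the per-step map decay
is δ_xy·dt. `motor_noise_cov` itself returns Q(u) exactly as defined;
the scaling is applied where steps are taken.

**Backward stepping.** With v ≥ 0 the noisy closed loop has a parking
deadlock: noise carries the agent slightly past its goal, and turning around
costs more (through the uncertainty penalty on turning noise) than the small
goal-term gain, so the agent stalls just outside the stop radius. Humans
shuffle backwards; allowing v ∈ [−0.5, 1.5] m/s removes the degeneracy.

**Saddle escape.** A first-order NLP solver started from a standstill cannot
discover "turn, then go" when the goal lies abeam (the gradient of the goal
term w.r.t. both controls is zero). The planner re-solves from a
turn-then-go heuristic whenever that heuristic undercuts the solved point,
and the MPC loop executes an explicit orient-toward-goal maneuver if a
standstill plan is returned while the believed goal is out of tolerance.
The returned plan is always at least as good as the zero-control sequence.

## Environment templates

Five templates emulate the three study families at the level of their
described constraints: `nardini_like` (three background landmarks, all goals
visible from the start, wide field of view), `chen_like_3lm` / `chen_like_1lm`
(three vs one landmark, sequential goals, head-mounted-display field of view
of 55° half-angle — the studies report only that the display restricted the
field of view considerably, so this is a config parameter), and
`zhao_proximal` / `zhao_distal` (landmarks at 5.5 m vs 500 m on identical
bearings). Goal triangles have legs of a few metres. Exact coordinates are
non-canonical parameterized approximations; explicit coordinates can be
supplied through the config file.

## What the synthetic experiments do and do not show

The simulated "studies" reproduce the *structure* of the real experiments —
cue conditions, outbound geometry, landmark counts and ranges, waiting
times — under the package's own noise defaults, at desk scale (5 simulated
participants × 4 trials per condition, dt = 0.25 s) rather than the
thousands of cluster-scale trials behind the original analyses. Passing
tests therefore demonstrate the mechanisms (uncertainty ordering across cue
conditions, optimal-integration consistency of the combined condition,
landmark-ward conflict bias and its ablation direction, distal < proximal
information content), not quantitative agreement with any particular
laboratory's endpoint tables, which would require the original data and
parameters. Response variability is computed per participant and averaged,
following the endpoint-analysis procedure; with only four trials per
participant and condition these comparisons are noisy, and the ordering
checks hold for most but not every base seed at this scale. Inter-individual differences, trial-by-trial learning, separate
self-motion cue channels, and conflict angles ≥ 90° (where humans visibly
switch strategy) are out of scope.

## Numerical choices

- Angles are radians in (−π, π], wrapped after every update; innovation
  bearings are wrapped before the Kalman gain is applied.
- Covariances are re-symmetrized after every update; planning-side rollouts
  tolerate the asymmetric visibility-weighted gain by symmetrizing each step.
- The NLP is single shooting over controls with SLSQP; gradients are packed
  forward differences priced in one vectorized batch rollout; warm-started
  replans skip the visibility annealing.
- Energy distance uses the V-statistic (means over all pairs including
  self-pairs); the homogeneity test permutes pooled labels with the add-one
  correction, 999 permutations by default.
- Outlier quartiles use linear interpolation (numpy default), declared
  because 3×IQR thresholds are convention-sensitive.
- Degenerate inputs: observation of a landmark coincident with the agent is
  a hard error; von Mises fits cap κ at 10⁸ for (near-)degenerate samples
  and warn toward κ = 0 for near-uniform ones.

## Known limitations

- The EKF is a first-order filter; at high observation noise or extreme
  landmark geometry its posterior deviates from the exact Bayes filter (the
  test suite pins it against particle/grid/Kalman oracles in low-noise
  regimes where it should be accurate).
- The planner finds local minima; the heuristic restarts make it reliable on
  homing geometry but it is not a global optimizer.
- The swivel-chair disorientation inflates belief uncertainty by configured
  constants rather than by inference over the imposed rotation.
- Endpoint distributions at dt = 0.25 s match finer-dt runs only to first
  order in dt; fidelity runs can lower dt in the config at a proportional
  cost in runtime.
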
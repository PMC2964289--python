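# Methods

This note documents the models, algorithms, numerical choices and known
limitations behind `ofcarm`. It is the reference for *why* the defaults are
what they are; the README covers installation and usage.

## The scientific question

Humans stiffen a limb by co-activating antagonistic muscles when precision
matters, when movements are fast, and transiently when the environment
changes. Co-contraction is energetically wasteful, so an optimality account
must explain why a controller that penalizes effort would ever command it.
`ofcarm` implements one such account: a stochastic optimal feedback
controller that plans on a *learned* internal forward model carrying
localized uncertainty. Wherever the learned uncertainty falls with
co-activation faster than the energy cost rises, minimizing *expected* cost
commands impedance. Nothing in the controller refers to stiffness —
co-contraction is emergent.

## Arm plant

A single joint (elbow) with inertia `M` is driven by a flexor/extensor pair:

- muscle lengths are affine in the joint angle, `l = l_ref − A q` with
  constant signed moment arms `A = (a_f, −a_e)`;
- each muscle is a linear spring-damper,
  `t_i = max(0, k(u_i)(l_i − l_rest,i(u_i)) + b(u_i) l̇_i)` with
  `k(u) = k0 + k1 u`, `b(u) = b0 + b1 u`, `l_rest,i(u) = l_ref,i − r u_i`;
  tensions are clipped at zero (muscles pull only);
- net torque `τ = a_f t_f − a_e t_e`; an optional constant horizontal
  endpoint force `f_x` adds `f_x L cos q` through the transposed Jacobian of
  the endpoint `p = L (sin q, cos q)`.

The joint stiffness at a posture is `a_f² k(u_f) + a_e² k(u_e)`: symmetric
co-activation raises impedance linearly in the commands.

Defaults (SI units): `M = 0.065 kg·m²`, `a = 0.025 m` both muscles,
`k0 = 1000`, `k1 = 3000 N/m`, `b0 = 50`, `b1 = 100 N·s/m`, `r = 0.05 m`,
`L = 0.35 m`, joint range ±1.9 rad, `dt = 0.01 s`. The rest-length
shortening `r` is deliberately twice the moment arm: with `r = a`, holding a
flexed posture requires a reciprocal command offset `Δu ≈ q a / r = q` that
co-contraction cannot reduce, and the noise valley (below) closes at exactly
the postures where reaches end. `r = 2a` keeps a usable valley across the
workspace while remaining a plausible muscle excursion (5 cm at full
activation).

### Signal-dependent noise

Noise enters at the tension level as a Gaussian perturbation per muscle with
standard deviation `σ(u)`, integrated by Euler–Maruyama: the realized
acceleration is `f(x, u) + (a_f ε_f − a_e ε_e) / (M √dt)` with
`ε_i ~ N(0, σ_i²)` drawn independently per muscle, so
`Var(q̈) = (a_f² σ_f² + a_e² σ_e²) / (M² dt)`.

- *standard*: `σ_i = c_std u_i` — each muscle's own command scales its
  noise; co-contraction buys nothing and costs double.
- *extended*: `σ = c_iso |u_f − u_e|^{p_iso} + c_co min(u)^{p_co}` applied to
  both muscles. The isotonic (reciprocal) term dominates the isometric
  (co-contraction) term, producing a valley of reduced noise along the
  co-contraction diagonal: for a fixed net torque, raising both commands
  stiffens the joint, shrinks the reciprocal offset `Δu` the torque needs,
  and hence shrinks the noise.

Defaults: `c_std = c_iso = 9 N`, `c_co = 0.9 N`, `p_iso = 1.5`, `p_co = 1`.
Two calibration arguments fix these. First, the supra-linear isotonic
exponent (within the physiologically reported less-than-linear to
more-than-linear range) makes the valley deepen *nonlinearly*: the small
reciprocal offsets reachable by co-contraction become disproportionately
quiet, which is what lets an impedance strategy outperform a low-effort one
rather than merely tie it. Second, `c_std` is set so both noise models
produce the same kinematic variability for a reference purely reciprocal
command at half activation; with `p_iso = 3/2` and two independent extended
channels that calibration lands exactly at `c_std = c_iso`. Under a linear
exponent no calibration makes the extended plant outperform the standard one
— the extended σ applies to both muscles, so it is uniformly √2 noisier for
any reciprocal strategy and the valley (bounded by the stiffness ratio
`(2k0 + k1 Σu)/(k0 + k1 Σu)`) cannot recoup the factor.

Joint limits clip the angle and zero the velocity; hits are counted on the
trajectory and the default experiments do not produce them.

## Learned forward dynamics

The mapping `(q, q̇, u_f, u_e) → q̈` is learned by an ensemble of Gaussian
receptive fields with local linear models — the receptive-field weighted
regression family, without input projections (unnecessary in 4-D):

- inputs are normalized per dimension (scales 1 rad, 4 rad/s, 0.5, 0.5);
  fields are isotropic Gaussians of width 0.5 in that space, allocated
  online wherever no field is activated above 0.5;
- each field runs weighted recursive least squares on `[1, z − c]` with a
  forgetting factor annealed per field from 1 (young: accumulate) toward
  0.985 per unit weight (mature: track change), reconciling pre-training
  accuracy with force-field adaptation within a few trials;
- each field tracks a forgetting-weighted residual variance; prediction
  variance = activation-weighted residual variance (plus a weak
  inverse-gamma-style prior, 100 (rad/s²)² with pseudo-count 1) + a sparsity
  term `2000 · exp(−support/0.25)` that decays with local support. Queries
  with support below 0.05 are flagged unsupported and return the maximal
  variance.

The variance is therefore heteroscedastic in exactly the two senses the
controller needs: it is large where the motor noise is large (residuals) and
where data are thin or the dynamics have drifted (sparsity, residual spikes
after a novel force field).

Pre-training uses motor babbling: 50 000 samples in episodes of 25 steps,
each episode restarting from a uniform state with uniformly drawn
activations followed by a clipped Gaussian random walk (std 0.08/step).
Episodes alternate between fast starts (|q̇| up to 6 rad/s) and
near-stationary starts (|q̇| ≤ 1): quasi-static movements ride the muscle
slack/taut boundary, and without dense data on that manifold the smoothed
model keeps a systematic bias exactly along the low-command trajectories a
trajectory optimizer likes to exploit.

During experiments with online learning, each completed trial's 50 samples
are replayed for 10 passes (configurable), chosen so that re-convergence
after a force-field switch occurs within about five trials.

## Stochastic trajectory optimization

The controller is an iterative LQG method over the discrete dynamics
`x' = x + dt f(x, u) + Σ_j g_j(x, u) ξ_j`, `ξ ~ N(0,1)`. For the learned
problem there is a single noise column `(0, dt·σ̂(z))` where `σ̂` is the
model's predictive standard deviation; for the analytic plant, one column
per muscle with the `√dt` Euler–Maruyama scaling.

Per iteration: central finite-difference linearization of the mean dynamics
and of every noise column (batched over the horizon; step 1e-4), a backward
pass with the control-dependent-noise corrections (`C_uᵀ S g` in the
gradient, `C_uᵀ S C_u` in the curvature — the terms that make reducing σ
worth spending energy on), an exact 3^m active-set box-QP for the
feedforward step under the [0, 1] command bounds, and a backtracking line
search. Feedback rows are kept even for clamped commands (execution clips,
and a saturated muscle can still relax). Levenberg–Marquardt regularization
on the control curvature escalates ×10 on rejection, shrinks ×0.5 on
acceptance.

Three design choices beyond the textbook loop proved necessary on learned
models, whose expected-cost landscape is rugged and bistable (a pure
reciprocal basin and an impedance basin):

1. **Acceptance objective.** Candidates are compared under the current
   backward pass's own quadratic cost-to-go model (deterministic rollout
   cost + ½ Σ gᵀS g), for both candidate and incumbent, so every acceptance
   certifies a non-increase of the modeled expected cost.
2. **Noise continuation.** The noise columns are ramped in four stages
   (¼, ½, ¾, 1 of full scale), each warm-started from the previous, so the
   impedance component of the solution deforms smoothly from the reliable
   deterministic reach instead of depending on search luck.
3. **Monte-Carlo arbiter and multi-start.** The iterate finally returned is
   the accepted candidate with the lowest expected cost estimated by 64
   fixed-seed closed-loop rollouts on the problem's own stochastic model —
   an evaluation that prices saturation and the control-dependence of noise
   along realized deviations exactly. Cold solves run twice, from the small
   symmetric default initialization (0.01) and from an end-of-movement
   co-contraction ramp, keeping the better policy by the same arbiter.

Convergence: relative modeled-cost change below 1e-6 on a full line-search
step, or 50 iterations per stage (200 total). The solver is deterministic:
identical inputs give identical solutions.

On linear-quadratic problems the solver reproduces the finite-horizon
Riccati solution to machine precision, and under scalar
control-multiplicative noise the noise-damped modified-Riccati gains, which
is how the stochastic terms are validated.

## Reaching task and cost

`J = w_p (q_K − q*)² + w_v q̇_K² + w_e Σ_k ‖u_k‖² dt`, horizon 500 ms at
10 ms steps (K = 50). The published values of the weights for each
experiment are not available; the defaults place each protocol in the regime
its phenomenon needs, and all are configurable:

- baseline reach and velocity sweep: `w_p = 1e5, w_v = 1e3` (strong accuracy
  demand; the impedance incentive is robust there);
- accuracy sweep: five conditions scaling `(w_p, w_v)` by
  {0.01, 0.1, 1, 10, 100} about `w_p = 1e4, w_v = 1e2`;
- adaptation: `w_p = 1e4, w_v = 1e2` — compliant enough that force-field
  transients are visible;
- `w_e = 1` everywhere.

## Experiments

All drivers are pure functions of (config, seed); a single seed fans out
into named independent substreams, so re-runs are bit-identical.

- **Noise-model comparison** (baseline reach 0 → 0.5 rad): one model is
  pre-trained per noise kind, one solve per kind, 50 closed-loop stochastic
  reaches each. Expected outcome: co-contraction, better endpoint accuracy
  and stability, and higher energy use under extended SDN only.
- **Accuracy sweep**: conditions A–E share the extended-SDN model; 20 trials
  each. Co-contraction rises and endpoint error falls monotonically with the
  accuracy demand.
- **Velocity sweep**: targets 0.2/0.5/0.8 rad at fixed horizon; 20 trials
  each. Peak speed and co-contraction rise with distance; endpoint errors
  show no systematic ordering.
- **Adaptation**: 5 null-field + 20 force-field trials, 20 replications
  (cloned model per replication), reach 0 → −0.5 rad with a constant 4 N
  endpoint force along the movement from trial 6. Before every trial the
  controller re-plans with the current model (warm-started, single stage,
  and guarded: the previous policy is kept if the re-plan does not improve
  the model's Monte-Carlo expected cost); after every trial the model
  absorbs the trial's samples; the uncertainty integral is evaluated with
  the freshly updated model along the realized trajectory. The
  `deterministic` variant zeroes the solver's noise map only (cold re-plans,
  since deterministic solves are cheap and crisp).

The adaptation reach is an extension movement because the assistive-field
phenomenology is stated in terms of the extensor (reach agonist) relaxing
and the flexor (brake, then hold against the field) working harder after
adaptation; with a flexion reach the two labels would swap.

### Known limitations of the adaptation protocol

Two published transient effects are *not* reproduced at the default
parameters, and the corresponding tests fail honestly rather than being
weakened:

- the catch trial (first force-field exposure) misses the target by only
  ~1.5–2× the null-field error, not ≥5×. With delay-free full-state
  feedback — reflex delays and observation noise are out of scope — the
  optimized gains give an effective endpoint stiffness of order
  10² N·m/rad, which rejects a 4 N constant force almost completely within
  500 ms. Fields strong enough to defeat the feedback (≥14 N) saturate the
  muscles and then corrupt the rest of the adaptation time course.
- the deterministic variant's co-contraction is roughly half the stochastic
  variant's, not below 5%: the trial-level metric `min(u_f, u_e)` has a
  floor from feedback jitter around reciprocal nominals and from the
  agonist-handoff overlap, common to both variants, and the
  uncertainty-driven component above that floor is only ~10× larger.

The deterministic variant's qualitative signatures (no planned
co-contraction, larger early-force-field velocity errors) do hold.

## What the synthetic data does and does not show

The plant is itself the data generator, so "passing" means the pipeline is
self-consistent: the learner recovers the dynamics it was shown, and the
optimizer exploits the uncertainty structure the plant actually has. The
extended SDN is a surrogate for detailed motor-unit physiology; moment arms
are constant; there are no delays, no observation noise, no reflex loops,
and a single joint. Conclusions about real limbs rest on the premise that
those ingredients, not the omitted ones, drive impedance control — the
results here show the mechanism is sufficient in principle, not that it is
the one the nervous system uses.

### Replication margins

Condition means from 20 trials carry margins comparable to the solver's
solve-to-solve variability, so the *strict* five-condition rank orderings of
the accuracy sweep are reliable at the reference seed but can invert between
adjacent conditions (near-zero co-contraction at the low end, the error
plateau at the high end) for other seeds. The pairwise comparisons of the
noise-model experiment and the three-condition velocity ordering are robust
across seeds.

## Numerical notes

- Problem sizes used by the test suite: 50 000 babble samples per model,
  full trial counts (50/20/20), adaptation at 5 replications; the
  reproduction script uses 3 adaptation replications. The full
  20-replication protocol remains the library default.
- Explicit Euler integration throughout, matching the solver's
  discretization; no adaptive stepping.
- The learner's update is constant-cost per sample (only activated fields
  are touched); predictions are chunked so memory stays bounded.
- Ties and degenerate inputs: muscles clip at zero tension; commands clip at
  [0, 1]; zero-variance evaluation sets and non-finite training samples are
  rejected with diagnostics; a non-finite closed-loop state raises a
  dedicated simulation-divergence error.
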
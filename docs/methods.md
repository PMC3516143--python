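# Methods

## Problem setting

`roed` designs stimulus experiments that discriminate between two rival
ODE models of a biochemical reaction network.  Each model is an initial
value problem

    dx/dt = f(x, u(t), θ, t),   x(0) = x0(θ),   y(t) = g(x(t), θ, t),

with states x (concentrations), a piecewise-constant stimulus u(t), and a
parameter vector θ that merges kinetic constants, readout parameters and
(where appropriate) initial conditions.  Biological variability and
estimation uncertainty make θ a random vector, so each model predicts a
*distribution* of responses at every measurement time, not a curve.  Two
structurally different models whose nominal curves coincide can still be
told apart if some stimulus drives their response distributions apart.

## Discrimination criterion: model overlap

Model similarity at a measurement time t_k is scored by the probability
product kernel between the two response densities,

    k_p(t_k) = ∫ p_A(y; t_k)^p · p_B(y; t_k)^p dy ,

and the design criterion is its unweighted average T̄ over the measurement
grid.  At the default p = 1 the kernel is the *expected likelihood* of one
model under the other ("model overlap"); at p = 1/2 it is the
Bhattacharyya coefficient, which equals 1 exactly when the distributions
coincide.  Both densities are approximated as Gaussians
N(E[Y](t_k), Σ_Y(t_k)), for which the kernel has a closed form — at p = 1
it reduces to the normal density N(μ_A − μ_B; 0, Σ_A + Σ_B).  An optimal
discrimination design minimizes T̄.

Degenerate covariances (which occur where sensitivities vanish) get an
additive jitter of 1e-12 × trace before inversion.

## Moment estimation under parameter uncertainty

The criterion needs E[Y](t_k) and Σ_Y(t_k) for each model.  Three
estimators share one contract:

* **Linearization (delta method).**  One augmented ODE solve integrates the
  forward-sensitivity equations dS/dt = (∂f/∂x)S + ∂f/∂θ,
  S(0) = ∂x0/∂θ, alongside the states; the response covariance is
  S_y Σ_θ S_yᵀ + σ²I with S_y the readout sensitivity by the chain rule.
  Exact for linear maps, O(n_θ) extra equations, but *local*: a parameter
  distribution straddling a separatrix, or a readout with vanishing
  gradient, produces badly biased moments (the y = θ², θ ~ N(0,1) example:
  linearization reports mean 0, variance 0; the truth is 1 and 2).

* **Sigma points (unscented transform).**  2n+1 deterministic parameter
  samples — the mean and ± columns of the scaled Cholesky factor — are each
  simulated through the full nonlinear model; weighted sums give mean and
  covariance.  Derivative-free, O(n_θ) simulations, and *non-local*: points
  on the far side of a separatrix land on the other branch and inflate the
  estimated variance accordingly.

* **Monte Carlo.**  Seeded random sampling with unbiased (n−1) covariance;
  the reference the other two are judged against.  Draws whose simulation
  fails are dropped with a logged count; more than 1% failures abort the
  estimate.

Measurement noise is added as σ²I on the *transformed* response scale for
all three estimators alike, which keeps them comparable; the transform
(identity or elementwise log, with responses floored at 1e-12 before the
log) is part of the benchmark definition.  Whether noise should enter
before or after the log is a modeling choice; the package fixes one
convention and exposes the noise level in the config.

### Unscented-transform constants

The scaled UT uses λ = α²(n+κ) − n, weights W0^m = λ/(n+λ),
W0^c = W0^m + 1 − α² + β, Wi = 1/(2(n+λ)).  Defaults: α = 1, β = 2 (the
usual choice for Gaussian priors) and κ = 3 − n (Julier's fourth-moment
heuristic, giving point spread √3 · σ).  These constants are genuinely
priors about the response PDF, and the right choice depends on the
system.  κ = 3 − n makes the center mean weight (3−n)/3 *negative* for
n > 3 — harmless for smooth unimodal responses (on the MAPK cascade it
gives the most accurate variances), but ruinous when sigma points
straddle two stable branches: on the bistable benchmark the negative
center weight produced a UT mean of 4.4 against an MC mean of 9.2.  For
multimodal-prone systems κ = 0 keeps every mean weight nonnegative (at
the price of a wider √n · σ spread), which is what the bundled Schlögl
benchmark packages as its estimator setting.  All three constants are
config-exposed, and a config overrides only the values it explicitly
sets, so packaged per-system settings survive.

Log-normally distributed parameters are handled by converting the natural
(mean, covariance) to the moments of the underlying normal
(Σ_N,ij = ln(1 + C_ij/(m_i m_j)), μ_N,i = ln m_i − Σ_N,ii/2), building
sigma points or samples there, and exponentiating back — sigma points stay
strictly positive.  The matrix square root is the lower Cholesky factor,
with a single 1e-12·trace jitter retry.  UT covariance estimates are
symmetrized and eigenvalue-clipped at zero (negative weights can produce
slightly indefinite matrices); clips are logged.

## Stimulus parameterization and optimization

The control is piecewise constant (control vector parameterization): Nw
amplitudes in [0, u_max] and Nw−1 durations ≥ Δt_min over a horizon T,
with the final amplitude held to T if the cumulative durations fall
short.  A dwell-time constraint (minimum segment duration, modeling
actuator limits) tightens Δt_min.  The objective is the penalized mean
overlap: criterion + c·max(0, ΣΔt − T)² + c·(bound-clip distance)², with
c = 10³.  Estimator failures inside the objective return a large finite
sentinel (10⁶) so stochastic search continues.

The search is a hybrid multistart: for each restart, CMA-ES (a compact
(μ/μ_w, λ) implementation with rank-one and rank-μ updates) explores from
a random in-bounds design, then derivative-free Nelder-Mead polishes the
incumbent.  Gradients of the objective through the ODE solver are not
available analytically, so the local phase is derivative-free by design.
The search runs in a normalized space (amplitudes scaled by u_max,
durations by the horizon) so one step size fits all coordinates.  All
randomness flows from one seed through `numpy` SeedSequence spawning;
identical seeds give identical results.

Dynamic constraints are handled by the sequential approach only
(integrate, then penalize); a simultaneous collocation transcription is
out of scope.

## Monte Carlo verification and relative MSE

A winning design is re-checked by Monte Carlo: fresh parameter draws per
model, moment trajectories, and the overlap recomputed from the MC moments
(Gaussian plug-in).  The estimator's moment predictions are scored by the
componentwise relative MSE

    rel_mse = mean over times and components of (est − ref)² / ref²,

with ref² floored at 1e-24, split into mean, variance (diagonal) and
covariance (strict off-diagonal; empty and reported 0 for 1-D readouts)
classes, reported per model and aggregated (mean over the two models).
This convention is the package's canonical definition; comparisons against
other implementations are meaningful only up to it.  Note an estimator
that *underestimates* a moment toward zero saturates this metric near 1,
while overestimation is unbounded.

## Bundled benchmarks

### MAPK cascade (rival negative feedbacks)

A three-level MAP-kinase cascade in the classic Kholodenko
parameterization, integrated over the five phosphorylated forms with the
unphosphorylated pools closed by conservation (total concentrations are
model parameters).  The stimulus is the maximal rate of the first
activation step (units nM/min, bound 2.5); readouts are the two doubly
phosphorylated forms MAPK-PP and MKK-PP, log-transformed, with noise
σ = 0.1 on the log scale.  Model A's first step is inhibited by
1 + MAPKPP/KI (hyperbolic feedback); model B by 1 + (MAPKPP/KI_B)²
(cooperative).  KI_B = 8.649 was calibrated once — nominal parameters,
least squares on the log-responses under the packaged initial constant
stimulus u = 2.5 — so that the pair is indistinguishable at the starting
design (maximum log-response gap 0.02, far below the noise), which is the
situation a discrimination design is meant to resolve.

Distributed parameters: the nine catalytic constants of the
(de)phosphorylation steps plus the feedback constant KI (10 parameters,
log-normal, CV = η).  Michaelis constants, totals and initial conditions
are held at their nominal values — spreading them too would only add
sigma points without changing what the benchmark probes.  The bundled
design space allows 20 stimulus segments (39 design variables); the
*scaled* protocol used by the tests and the acceptance script optimizes 6
segments (11 variables), measures at t = 10, 20, …, 100 min, and runs 4-5
restarts per estimator with 80-100-evaluation CMA-ES budgets and
10³-sample MC verification — sizes chosen so a full protocol completes in
minutes on one core.

### Schlögl reaction (bistability)

The canonical autocatalytic trimolecular system,
dx/dt = k1·a_eff·x² − k2·x³ + k3·b − k4·x.  The packaged nominal set is a
normalization making the unstimulated cubic −(x−1)(x−3)(x−9): stable
states at 1 and 9, separatrix at 3, and a wide bistable window (the
autocatalytic gain can move −11%…+21% before a branch disappears), so a
10% parameter CV straddles the window edge only under stimulation.  The
rival models differ in the input layer feeding reservoir A: model A takes
a_eff = a + u, model B a saturating a_eff = a + u/(1 + u/γ) with γ = 40.
At u = 0 the models coincide (the packaged "initial experiment").
Readout is x itself with noise σ = 0.1; measurements at t = 1…10 (t = 0
is excluded: the state there is the shared initial condition, so the
sample carries no discriminative information and only adds a large common
overlap floor).  Stimulus bound u_max = 100, 5 segments, dwell time 1.0.
All seven parameters (k1…k4, a, b, x0) are distributed log-normally with
CV η = 0.1.

This geometry reproduces the qualitative failure mode of local design:
the linearization-optimal stimulus parks model B's *nominal* trajectory
just below its saddle-node (maximal apparent separation, tiny linearized
variance), while in truth a large fraction of the parameter population
crosses the threshold, making the response bimodal and the true overlap
orders of magnitude larger than the linearized estimate.  The sigma-point
design instead drives model B robustly toward its upper branch, where its
estimate agrees with the Monte Carlo verification.

## What the synthetic benchmarks do and do not show

Both benchmark systems are fully synthetic: parameter values, spreads,
noise levels and stimulus bounds are packaged, config-overridable
constants of this package's own benchmark definitions.  Passing tests
therefore demonstrate the *methodological*
claims — exactness classes of the estimators, the failure mode of
linearized design under multistability, the fidelity of sigma-point
moment estimates, reproducibility of the stochastic pipeline — on systems
engineered to exhibit those regimes.  They do not validate any specific
published parameter set, and real experimental data (with model error,
non-log-normal variability, correlated noise) is outside what these
benchmarks emulate.

## Numerical choices

* Integrator: LSODA (stiff/non-stiff switching) via `scipy`, default
  rtol 1e-8 / atol 1e-10; benchmark protocols use 1e-6 / 1e-8.  Piecewise
  inputs are integrated segment by segment with restarts at breakpoints,
  so discontinuities are never smoothed across.
* Missing Jacobians fall back to central finite differences with step
  1e-6·max(|value|, 1); models may supply analytic Jacobians (the Schlögl
  models do).
* Integration failure (non-finite states, solver error) raises a typed
  error carrying the failing time; estimators translate it per their
  contract (sigma points name the failing point, MC drops the draw).
* MC covariance uses the unbiased n−1 normalization.
* PSD repairs (UT covariance clip, log-normal conversion clip) always
  clip eigenvalues at zero and log a warning rather than failing.

## Known limitations

* Single-input stimuli only are optimized (the data model permits more).
* Measurement-time and readout selection are not design variables.
* The response-PDF integral is never evaluated exactly; all overlap
  values are Gaussian approximations (MC verification included, which
  plugs MC moments into the same closed form).
* Only the log transform is offered for skewed responses.
* Worst-case (minimax) design and second-order propagation are out of
  scope.
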
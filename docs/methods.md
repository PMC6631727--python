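# Methods

`tsldmf` maps 30 Hz smartphone inertial recordings of walking and running
into a low-dimensional latent space, learns the latent dynamics, filters
causally, and characterises the "normal" region of latent space by density
estimation. This note documents the model, the numerical choices, and what
the synthetic data used throughout testing does and does not establish.

## Observation model

Each time step yields the 8-vector

x_t = (ω_x, ω_y, ω_z, ω_T, A_x, A_y, A_z, A_T),

the three gyroscope channels (rad/s), three accelerometer channels (m/s²),
and the two Euclidean magnitudes that summarise movement intensity. After
per-feature min–max scaling to [0, 1] (the envelope is fitted over the whole
cohort so one scaling covers every subject; out-of-envelope values at apply
time are clipped, keeping the emitter's support bounded), the model
observation stacks the current and two previous frames,

y_t = [x_t, x_{t−1}, x_{t−2}] ∈ [0,1]^24.

Single IMU frames are far from Markovian; the 3-frame window restores
approximate Markovianity at the cost of a 16-entry overlap between
consecutive windows. At 30 Hz this overlap loses no information. Scaling is
per feature (each channel has its own physical range); a global envelope
across all eight features would let large-magnitude channels dominate.

## Backbone generative model

A latent Markov chain z_0:T ∈ R^d (d = 2 or 3; chosen for interpretable
visualisation) explains the windows:

p_θ(y_0:T, z_0:T) = p(z_0) p(y_0|z_0) ∏_{t≥1} p(y_t|z_t) p(z_t|z_{t−1})

- **Initial prior** p(z_0): diagonal Gaussian with learnable mean/variance
  (initialised standard normal).
- **Transition** p(z_t|z_{t−1}): mixture-density network — an MLP emits the
  weights, means and variances of K diagonal Gaussian components. K
  defaults to 1 (a single Gaussian); the mixture is config-exposed.
- **Emitter** p(y_t|z_t): MLP emitting a diagonal Gaussian over the 24-dim
  scaled window. Because the observations are continuous in [0,1], the
  Gaussian family is the default; a discretized multinomial emitter
  (per-feature binning of [0,1] into B = 32 bins) is provided as an
  alternative family for strictly categorical likelihoods.

All variances pass through softplus plus a floor of 1e−4; diagonal
covariances are used throughout. Default networks have two tanh hidden
layers of 32 units; with zero hidden layers and K = 1 the model is exactly
a linear-Gaussian state-space model, which the test suite exploits by
checking the joint density, the ELBO bound and the filter against exact
Kalman results.

## Stage 1: variational training

The posterior is amortized as q_φ(z_t | y_t:T): a GRU runs backwards in
time over the windows and an affine readout maps its hidden state to the
posterior mean and variance. Conditioning on z_{t−1} is deliberately
omitted from the encoder — dependence on the previous latent enters only
through the transition KL term — which is a known stabiliser for this model
class. Training maximises the evidence lower bound

ELBO = Σ_t E_q[log p(y_t|z_t)] − KL(q(z_0)‖p(z_0))
     − Σ_{t≥1} E_{z_{t−1}∼q}[KL(q(z_t)‖p(z_t|z_{t−1}))]

with single-sample reparameterized gradients, analytic KL terms when K = 1
(a sampled log-ratio otherwise), and Adam. Long recordings are sliced into
fixed-length subsequences so equal-length minibatches can be formed.
Defaults: subsequence length 25 windows, batch 8, learning rate 1e−2,
10 epochs — sized for short training runs on a single CPU; for larger
studies raise the epoch count and lower the rate. No KL annealing is used
by default (it is config-exposed). Networks are trained in float64 on a
small tape-based reverse-mode autodiff engine written for this package
(`tsldmf._ad`); gradient correctness is verified against finite differences
in the test suite.

## Stage 2: causal filtering

The encoder needs future observations, so it cannot run online. Stage 2
keeps θ frozen and trains a **combiner** network ψ used in a
predict–correct loop:

- **Predict.** The previous filtered state (μ, Σ) passes through the
  transition: the predicted mean/variance are the moment-matched mixture
  moments at μ plus first-order propagation J diag(Σ) Jᵀ of the filtered
  variance through the transition-mean Jacobian (computed exactly by
  reverse-mode sweeps; d ≤ 3 keeps this cheap). For a linear K = 1
  transition this is exactly the Kalman predict step. At t = 0 the
  prediction is the initial prior's moments.
- **Correct.** The combiner MLP reads (predicted mean, log predicted
  variance, y_t) — standardized by statistics collected from a pilot
  prediction rollout — and outputs an innovation **correction to the
  predicted mean** plus the filtered variance. The residual form mirrors
  the Kalman correction literally; with the zero-initialised readout the
  untrained filter is a pure transition rollout, which keeps early training
  inside the region where the frozen emitter carries gradient information.

The stage-2 objective is the stage-1 ELBO with the combiner-induced
filtering distribution q_ψ substituted for q_φ; gradients flow only into ψ.
Pure ELBO ascent from random initialisation can stall: away from the
learned latent manifold the frozen tanh emitter saturates and provides
almost no gradient. When the stage-1 encoder is available, the first half
of the epochs therefore **distills** the encoder's posterior into the
combiner along on-policy rollouts (a squared-moment matching loss), after
which ELBO fine-tuning proceeds. The warm start changes only the
optimisation path, not the objective being maximised at the end; on
linear-Gaussian instances the combiner converges to the exact Kalman
filter without any warm start (verified to 0.05 process-noise standard
deviations, against a 0.15 acceptance bound).

Filtering is strictly causal: the state at t is a deterministic function of
y_0..y_t, and the tests verify bitwise invariance of past states under
future-observation perturbations.

## Latent density and normal region

Latent samples pooled from filtering are modelled with a continuous
normalizing flow: dz/ds = f(z, s) integrates data space (s = 0) to a
standard-normal base (s = 1), and

log p(z) = log N(z(1); 0, I) + ∫₀¹ tr(∂f/∂z) ds.

The dynamics network has a single tanh hidden layer (24 units default),
for which the Jacobian trace has a closed form — exact, cheap at d ≤ 3,
and free of stochastic trace-estimator variance. Integration uses a fixed
40-step classical Runge–Kutta scheme; the change-of-variables identity is
verified by quadrature (the fitted density integrates to 1 within 2% on a
2-D grid) and by forward/reverse round trips (≤1e−4). Data are whitened
before the flow with the exact affine log-Jacobian included. The output
layer is zero-initialised so the untrained flow is exactly the base
distribution.

The **normal region** is the super-level set {z : p(z) ≥ c}. The threshold
c is calibrated as the empirical (1 − mass) quantile (lower method) of the
model's own sample densities, so the region captures the requested
probability mass; for the identity flow at mass 0.95 in d = 2 this
reproduces the analytic χ²(2) contour density within 5%. Densities may be
fitted per subject, per motion class, or pooled — the CLI supports all
three groupings.

## Baseline and evaluation

Incremental PCA (scikit-learn, mini-batch 64) is the linear baseline at
equal latent dimension. Reconstruction error is

MSE = (1/M) Σ_k ‖x_k − x̂_k‖²

over the M test windows, in the 24-dim scaled observation space for both
methods (both operate on windows). The two-stage reconstruction is the
emitter mean evaluated at the filtered posterior mean. Results are
summarised as MSE_IPCA / MSE_TS-LDMF; ratios above one favour the
latent-dynamics model. The cross-validation harness follows the
per-subject protocol: each (subject, motion) group's five recordings form
five consecutive folds (scikit-learn `KFold`, no shuffling; with n = 100
windows each test fold is exactly 20%); each fold is held out once while
the rest train stage 1 then stage 2. Summary tables report both
fold-then-subject and pooled aggregations, since either convention is
defensible.

## Synthetic data

No public IMU cohort accompanies the package, so a generator emulates the
study conditions. Per subject it draws a gait fundamental frequency (walk
1.2–2.2 Hz, run 2.2–3.4 Hz), three harmonic amplitudes and phases per
channel (amplitudes decaying 1 : 0.4 : 0.2 — the stride fundamental
dominates), gyro amplitudes of order 1 rad/s and accelerometer amplitudes
of 1.5–3 m/s² with the gravity offset on the body-frame vertical axis, and
channel noise (0.1 rad/s gyro, 0.3 m/s² accel — sensor noise plus
soft-tissue jitter). Recordings of one subject differ only in noise
realisation and global phase jitter, emulating repeated laps of a fixed
course; running doubles the oscillation amplitude. Default recordings are
60 s at 30 Hz (1800 frames). A 20-subject reference profile table
(gender, age, height, weight) dresses synthetic subjects with plausible
anthropometrics.

What this establishes — and what it does not: the synthetic signals live
on a one-dimensional closed curve per subject (phase around the stride
cycle), so a d = 2 nonlinear model *should* reconstruct them much better
than a rank-2 linear projection, and the headline comparison verifies the
whole pipeline can learn that structure end to end. Real gait has
stride-to-stride timing variability, drift, posture changes and
device-placement effects that the generator does not emulate; passing
tests demonstrate correctness of the machinery, not clinical performance.
The generator also provides exactly simulated linear-Gaussian state-space
instances for which closed-form Kalman results serve as independent
oracles.

## Problem sizes and numerical choices

The bundled evaluation (acceptance script and heavy tests) uses a
4-subject × 5-recording walking cohort at d = 2 with 32-unit networks and
10 epochs per stage — small enough to run on one CPU core in minutes while
still exercising every stage; larger cohorts scale linearly. Determinism:
every entry point takes a seed, all randomness flows through
`numpy.random.SeedSequence` spawning, and repeated runs are bitwise
identical. Degenerate inputs are rejected rather than repaired: constant
features fail scaling, non-monotone timestamps fail parsing, fewer than
three frames fail windowing, unstable transition coefficients fail the SSM
generator.

## Known limitations

- Pure-ELBO stage-2 training without the distillation warm start can
  underperform on strongly nonlinear latent manifolds (documented above).
- The mixture transition KL for K > 1 uses a single-sample log-ratio
  estimate (no closed form exists).
- The multinomial emitter family supports stage-1 training and evaluation
  but not stage-2 training.
- Full covariance matrices, smoothing at inference time, and non-Markov
  transition memory are out of scope.
- The filter propagates variance to first order through the transition
  mean; heavy-tailed or strongly curved dynamics would need sigma-point or
  sampling-based prediction.
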
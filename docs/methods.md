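# Methods

## The question and the model

Two devices record the same neural system at different spatial scales —
for instance high-frequency broadband (HFB) power from microwires and
from macroelectrodes on the same depth electrode. The two time series
differ. Is that because the underlying dynamics differ across scales
(a *system* effect), or because each device imposes its own nonlinear
transformation on the signal (an *observer* effect)?

`sysobs` frames this as Bayesian comparison of reduced generative
models. Each scale carries a scalar latent state with linear
time-invariant dynamics driven by a shared exogenous input v(t):

    dx_mu/dt = a x_mu + b v(t)            (microscopic)
    dx_M/dt  = (a + da) x_M + b v(t)      (macroscopic)

and each is read out through a saturating observer

    h_mu = c tanh(k x_mu) + e,    h_M = c tanh((k + dk) x_M) + e'

with white Gaussian observation noise of SD `obs_noise_sd`. Two
deviation parameters carry the whole question: `da` (dynamics differ)
and `dk` (observers differ). The *identical observers* reduced model
pins dk = 0; the *identical systems* reduced model pins da = 0.

Without noise, the observed difference rate
d(h_mu - h_M)/dt = g_mu' f_mu - g_M' f_M is a product of observer
sensitivity and dynamics, so system and observer contributions are
degenerate. Adding Stratonovich state noise

    dx = f(x, v) dt + sigma [x] o dW      ([x] only in the multiplicative mode)

introduces an extra term sigma xi g'(x) in the observed rate that
depends on the observer sensitivity alone. `stratonovich_difference`
computes both terms along a realized path; their sum matches a forward
finite difference of the noise-free observation. (A *central*
difference would mix adjacent noise increments, whose effect on the
difference quotient is of the same order as the observer-only term
itself, so the decomposition is checked against forward differences
aligned with the stored increments.)

## Integration

All simulation uses the Heun predictor–corrector with fixed step
dt = 1/fs (default 0.004 s; 1000 points over 4 s at 250 Hz). Heun
converges to the Stratonovich solution without an explicit drift
correction; for constant-coefficient drift with additive noise the
update is a linear recurrence and is evaluated with an IIR filter,
while the multiplicative mode runs the explicit two-stage loop. The
test suite verifies second-order convergence on the linear ODE and,
for dx = sigma x o dW, that the log-state over 2000 seeds is
N(ln x0, sigma^2 t) by moments and a Kolmogorov–Smirnov test.

Wiener increments come from a counter-based (Philox) stream keyed by
the noise seed; observation noise uses an independent stream. By
default one Wiener path drives both scales (`shared_increments=True`);
the stochastic equations can be read either with a common or with
independent paths, and both are supported. Latent states start at 0;
an initial-condition override exists for testing closed forms. States
beyond 1e6 abort with a divergence error naming the step.

## The driver

The exogenous input emulates a movie stimulus: one Uniform(0, 1) level
per annotated scene (piecewise constant), plus white Gaussian noise
(default SD 0.1) and Gaussian smoothing (default kernel SD 50 ms,
reflective boundaries). Synthetic studies use 8 scenes of random
lengths (minimum 0.2 s) over 4 s. The workflows mean-center the final
assembled driver before simulation — the regressor convention of a
design matrix — so that latent states fluctuate around zero and the
odd-symmetric observers produce near-zero-mean output, which is what
z-scored channels represent.

## Inversion

The full model is fit by variational Laplace: a Gaussian posterior
q = N(m, Sigma) over the free parameters, by default
(da, dk, log lambda) with standard-normal priors on the deviations and
a N(2, 4) hyperprior on the shared log observation precision lambda.
The free energy is

    F = L(m) + ln p(m) + 1/2 ln |2 pi Sigma|

with L the log likelihood; written as accuracy minus complexity with
accuracy the second-order expected log likelihood under q, this is
algebraically the same quantity, and it is exact for linear-Gaussian
models — the suite checks agreement with closed-form evidence to 1e-4
nats. Optimisation is Gauss–Newton ascent with Levenberg–Marquardt
diagonal damping (doubled on rejection, halved on acceptance), central
finite-difference derivatives (step 1e-4; the model is 2–3
dimensional, so robustness beats speed), and convergence when |dF| <
1e-3 nats on three consecutive accepted steps (max 64 iterations).
F never decreases across accepted steps. The reported covariance is
the eigenvalue-floored inverse negative curvature at the optimum —
*undamped*, because residual damping would bias F by O(damping) nats
and break the conjugate check.

The likelihood is a prediction-error density. Deterministic models
score independent Gaussian residuals around the noise-free forward
prediction. Stochastic models use a continuous-discrete extended
Kalman filter: Heun mean propagation, Euler covariance propagation
with process-noise intensity sigma^2 (rank-one across scales when the
Wiener path is shared, scaled by the squared state mean in the
multiplicative mode), observation Jacobian c k sech^2(k x), and
symmetric clipping of the covariance at 1e-12 when round-off breaks
definiteness. With zero volatility the filter reduces exactly to the
deterministic density, and in the linear regime it matches an
independently written Kalman filter to 1e-6 nats.

## Model reduction and comparison

Reduced models are scored without refitting. Pinning a parameter sets
its prior mean and variance to zero; the change in log evidence is then
the Savage–Dickey ratio ln[q_marginal(0) / p_marginal(0)] between
posterior and prior marginals at the pinned value, which is the exact
Var -> 0 limit of Gaussian Bayesian model reduction and numerically
stable. The reduced posterior is the conditional of the full posterior
at the pin. Non-degenerate reduced priors use the general closed-form
Gaussian reduction (checked against numerical quadrature and against
pinned-prior re-inversion to 1e-3 nats in conjugate cases). Reduced
free energies are converted to model probabilities by softmax under
uniform model priors; results are reported with the minimum free energy
shifted to zero, and "significance" refers to the losing model's
posterior probability (0.05 and 0.001 thresholds). Only the two
reduced models are compared; the full model is the inversion vehicle.

## Calibration, diagnostics, preprocessing

Empirical channels are decimated with an 8th-order zero-phase
anti-alias filter (integer factor), z-scored with the sample SD, and
truncated to 1000 points. Fit quality between predicted and empirical
macro channels uses z-scored series: R^2 = 1 - SS_res/SS_tot,
bias-corrected residual skewness, and lag-1 residual autocorrelation;
a subject is excluded when R^2 < 0.1 or |skewness| > 3.

`grid_search_calibrate` scores every (a, c, k) grid point by noise-free
forward simulation and MSE (mean over channels; defaults a in [-3,
-0.1] x 15, c in [0.5, 3] x 11, k in [0.2, 3] x 11; divergent points
score +inf; ties break lexicographically). The subject workflow
calibrates the *shape* parameters (a, k) against the micro channel only
— the model places all deviations on the macro channel, so the shared
parameters describe the micro channel — using standardized (z-scored)
simulated channels, and then closes the amplitude c analytically
against the micro channel's SD. This removes the grid's amplitude
ceiling, which cannot reach unit-SD targets when the raw model output
is small.

## The subject pipeline and z-scored data

Independent z-scoring divides each channel by its own total SD, which
superficially erases a pure observer-gain difference. The subject
pipeline therefore builds the standardization into the observation
model: the predicted channel is g_ch / s_ch with
s_ch^2 = Var(g_ch) + 1/lambda, and the residual precision is
lambda s_ch^2. Because s_M depends on the macroscopic gain, a dk != 0
changes the *signal fraction* of the macro channel, and that is the
signature that survives z-scoring. With this likelihood the
fixture-to-analysis round trip recovers the generating scenario on
10/10 fixture seeds for both scenarios at effect size 0.5. For
stochastic subject inversions the channels are instead rescaled once by
the calibrated prediction's SD and passed to the filtering likelihood;
this fixed rescale does not carry the parameter-dependent
signal-fraction information, a documented limitation.

Across subjects, the losing-model probability plays the role of a
p-value and is Bonferroni-corrected over included subjects.

## Synthetic study conditions

Defaults throughout: a = -1 /s, b = 1, c = 1, k = 1, effect size 0.5 on
whichever deviation the scenario frees, sigma_mu = sigma_M = 0.2 in
stochastic regimes, obs_noise_sd = 0.05, 4 s at 250 Hz, 8 scenes.
These give visibly different channels while keeping the inversion
well-conditioned. Validation runs use 20 seeds per scenario and noise
regime; the parameter-recovery coverage study uses 100 replicates (all
deterministic inversions, which keeps the suite inside a few minutes).

What the generator does *not* emulate: line noise and filtering
artefacts, non-stationary HFB statistics, electrode drift, shared
referencing, or any biophysics of the devices — the observers are
abstract mathematical stand-ins. Passing tests therefore demonstrate
the statistical machinery under the model's own assumptions, not
performance on raw intracranial recordings.

## Observed behaviour of the noise manipulation

Under these conditions, model selection is correct on 20/20 seeds in
every regime (deterministic, additive, multiplicative). The *margin*
by which the correct reduced model wins behaves differently from the
motivating intuition, however: the deterministic datasets are already
so identifiable (hundreds of nats) that additive state noise, which
also inflates the innovation variance the filter must tolerate, tends
to *shrink* the mean margin rather than grow it. The observer-only
noise channel contributes little information here because the per-step
state-noise variance reaching the observations (sigma^2 dt (ck)^2 ~
1.6e-4) is an order of magnitude below the observation-noise variance
(2.5e-3). The noise benefit should emerge where the deterministic
problem is nearly degenerate (much larger observation noise, slower or
impoverished drivers) or where volatility dominates the measurement
noise floor; the acceptance test for this claim is left asserting the
original expectation and currently fails under the default conditions.

## Known limitations

- Scalar states per scale; no multi-region networks.
- Volatilities sigma_mu, sigma_M are fixed, not estimated.
- The EKF is a first-order filter; strong saturation plus large
  volatility would call for sigma-point or particle methods.
- No Itô-convention mode.
- NWB/BIDS ingestion of the reference dataset is out of scope; the
  empirical entry point is plain CSV channels plus a scene-annotation
  file.
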
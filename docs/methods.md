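# Methods

`hemobayes` couples a nonlinear one-dimensional blood-flow simulator
to a transitional-MCMC inference engine so that noisy velocity
recordings on a branching arterial tree can be turned into a
posterior probability over candidate structural defects. This note
documents the models, the numerics, the synthetic-data generator, and
the design choices that were genuinely open.

## Flow model

Each artery is a one-dimensional distensible tube carrying
cross-sectional area `A(x,t)` and axial velocity `u(x,t)`:

    dA/dt + d(Au)/dx = 0
    du/dt + u du/dx = -(1/rho) dp/dx + K_r u / (rho A)

with blood density `rho` (1060 kg/m^3 by default, configurable),
friction coefficient `K_r = -22 pi mu` for viscosity `mu`
(0.0045 Pa s reference), and the purely elastic tube law

    p = p_ext + B (sqrt(A) - sqrt(A0)),

which collects Young's modulus, wall thickness and a Poisson ratio of
1/2 into a single stiffness `B` (Pa/m). A hook exists for a
viscoelastic pressure contribution but it ships identically zero: the
wall is treated as purely elastic. The associated wave speed is
`c = sqrt(B / 2 rho) A^{1/4}` and the Riemann invariants are
`W_{1,2} = u +- 4c`; these carry all boundary and interface coupling.

Arterial trees are rooted binary trees. At each Y-bifurcation six
unknowns (area and velocity on the parent outlet and both daughter
inlets) satisfy conservation of mass, continuity of total pressure
`p + rho u^2/2` into each daughter, and the three outgoing invariants
held at their upwinded values. The velocities are eliminated through
the characteristic relations and the remaining 3x3 system in the
areas is solved by Newton iteration with an analytic Jacobian
(tolerance 1e-12, at most 50 iterations); mass balance across every
junction therefore holds to the Newton tolerance at every step.

Terminal vessels use a fully absorbing outlet: the incoming invariant
is pinned at its rest value, so the reflection coefficient is zero.
Measured residual velocity after a pulse exits a single vessel is
about 0.1% of the incident peak (dominated by inflow ripple, not
reflection). The inlet prescribes a velocity waveform and takes the
area from the outgoing invariant, which makes the prescription
reflection-free as well.

## Discretization

Space: discontinuous Galerkin with orthonormal Legendre modes of
degree `p` (default 2) on `N` equal elements per artery (default 4;
the desk-scale experiment profile uses 1). Interior interfaces use an
upwind flux evaluated at the star state reconstructed from `W_1` of
the left trace and `W_2` of the right trace. Volume terms use
Gauss-Legendre quadrature with `p+1` points; the mild aliasing this
leaves in the quadratic flux is immaterial at the smooth, shock-free
flows the parameter ranges produce.

Time: second-order Adams-Bashforth, bootstrapped by one forward-Euler
step. The step is chosen automatically from the CFL estimate
`dt = 0.5 h_min / ((2p+1)(2 c_max + 1))`, where the factor 2 on the
relaxed-area wave speed leaves headroom for stiffened or dilated
trial parameters during inference, and is then rounded down so the
sensor sampling period is an exact multiple of it. The kernel
re-checks `dt <= 0.5 h_min / max(|u|+c)` against the instantaneous
wave speed every step; a violation, a non-positive reconstructed
area, or a failed junction solve aborts the run with the artery,
element and time, and inference treats such failures as zero
likelihood.

The rest state (u = 0, A = A0, zero inflow) is an exact fixed point
of the discrete operator, preserved to ~1e-13 over thousands of
steps. The discrete network mass balance — change in the integral of
A versus the AB2-quadrature of inlet minus terminal boundary fluxes —
closes to machine precision; a self-convergence study (N = 2, 4, 8
against a 16-element reference) shows monotone error decay.

## Inflow waveform

The published three-cycle inflow trace is not available numerically,
so the default driver is a truncated Fourier fit (10 harmonics) of a
half-sine systolic pulse: period 1.1 s, peak 0.5 m/s, systole 30% of
the cycle, three cycles. These values are ordinary resting
haemodynamics; the waveform object stores its coefficients so every
experiment is self-describing, and any trigonometric-polynomial
waveform can be supplied instead. With the standard 0.064 s sampling
cadence, three cycles (3.328 s) give exactly 52 samples per sensor.

## Synthetic data

The generator emulates the study conditions: a seeded fixture tree
with lengths in [0.026, 0.17] m and relaxed areas in [1e-6, 1e-5]
m^2 (areas taper down the tree; stiffnesses are assigned so relaxed
wave speeds fall in a physiological 4-8 m/s band, a choice the study
ranges leave open), observation noise `D_k = v_k + sigma eps_k` with
`sigma` a stated fraction (1% or 5%) of the pooled population
standard deviation `eta` of all clean velocities in the experiment,
and optional misspecification `A0 -> A0 (1 + sigma_alpha eps)`
applied once per dataset to every artery's relaxed area while the
inference model keeps the uncorrupted references. Observation and
parameter noise draw from independent RNG streams keyed by fixed
offsets from the master seed, so datasets are pure functions of
(configuration, seed). What the generator does *not* emulate:
heteroscedastic or correlated measurement error, device physics, and
real anatomical geometry — passing tests demonstrate correctness of
the method under its own assumptions, not clinical performance.

## Inference

The likelihood is Gaussian with covariance `sigma^2 I`; the noise
level `sigma` is always appended to the parameter vector with a
U[0, 1] prior unless configured otherwise, so the method must recover
the noise level it was never told. TMCMC tempers from the prior to
the posterior through `f_j ~ L^{q_j} pi`; each exponent increment is
found by bisection so the population coefficient of variation of the
plausibility weights `L^{dq}` equals 1.0, with weights computed in
log space under max-subtraction. Resampling is multinomial; each
selected particle seeds a Metropolis chain whose length equals its
selection count, with Gaussian proposals using the b^2-scaled
weighted sample covariance (b = 0.2). The log-evidence is the sum
over stages of the log mean plausibility weight.

Conventions the published algorithm leaves open, fixed here and
recorded in run metadata: population (n-denominator) standard
deviations for both the weight CoV and posterior summaries; constant
population size across stages; the final exponent clipped to exactly
1 so the last stage targets the true posterior; chains start at the
resampled particle and the start counts only via acceptance of its
first proposal. Chain RNG substreams are keyed by (seed, stage,
chain), which makes ensembles bit-identical for any worker count in
the joblib-threaded parallel map.

On analytic benchmarks (uniform box x Gaussian likelihood) the
evidence estimator is correct to ~0.05-0.1 in log units at N = 2000
with a small negative Jensen bias, consistent with the estimator's
known behaviour; accuracy checks therefore average over seeded
replicate runs.

## Model selection

A candidate model `M_i` frees the scaled stiffness `beta_i = B/B*`
(or scaled area `alpha_i = A0/A0*`) of artery i plus `sigma`, with a
U[0, 3] x U[0, 1] prior; `M_{i:j}` frees two arteries. Evidence plus
a uniform model prior gives `Pr(M_i | D)` by softmax with
max-subtraction (offset-invariant to 1e-12). The candidate class is
user-declared rather than exhaustive — the same inferential content
at a fraction of the cost — and per-model runs derive their seeds
from (master seed, model id). Probabilities below 1e-8 render as
"~0" in tables but are stored at full precision.

## Experiment profiles and problem sizes

The package's default experiment profile is desk-scale, chosen so the
full test suite and the acceptance script each run on a single CPU:
a 7-artery fixture tree, 1 element per artery at degree 2, one
cardiac cycle (13 samples per sensor at 0.064 s cadence), two sensors
(root end and a parallel-branch end relative to the artery-2 defect),
and TMCMC populations of 128 (256 for the three-parameter viscosity
estimation, which is the hardest identification problem in the
suite). The full-scale profile — 19 arteries, 3 cycles, 52 samples
per sensor, 500 TMCMC samples — is available through configuration
and the CLI defaults. Localization replications cover a halved
stiffness, a 50% area aneurysm and a 50% area stenosis, each
including runs with 1% reference-area misspecification.

## Known limitations

- Binary trees only: no loops, trifurcations, tapering within a
  segment, or viscoelastic walls.
- Terminal impedance is purely absorbing; no Windkessel/RCR models,
  so diastolic pressure decay of real circulations is not reproduced.
- The Gaussian error model is homoscedastic per experiment; the
  misspecification study perturbs areas only.
- TMCMC with small populations (below ~100) can stall short of very
  sharp posterior modes; the desk profile's N = 128 was chosen at the
  low end of the range where this does not occur for the shipped
  experiments.
- The exact published 19-artery geometry and waveform are not
  recoverable, so replications use seeded fixture networks in the
  published parameter ranges; sensor positions follow the same logic
  (one upstream, one parallel-branch) and are recorded per run.
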
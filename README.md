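# hemobayes

Bayesian localization of arterial wall abnormalities — aneurysms and
stenoses — from noisy pulse-wave velocity recordings on branching
arterial networks.

`hemobayes` is aimed at researchers in cardiovascular modelling and
uncertainty quantification. It provides three tightly coupled pieces:

1. **A nonlinear 1D blood-flow simulator.** Each artery carries the
   hyperbolic system

       ∂A/∂t + ∂(Au)/∂x = 0
       ∂u/∂t + u ∂u/∂x = −(1/ρ) ∂p/∂x + K_r u/(ρA)

   closed by the elastic tube law `p = p_ext + B(√A − √A0)`, solved
   by a discontinuous Galerkin method (orthonormal Legendre modes,
   upwind interface fluxes from the Riemann invariants `u ± 4c`,
   Adams–Bashforth-2 time stepping, compiled with numba). Arteries
   join at Y-bifurcations through Newton-coupled conditions —
   conservation of mass and continuity of total pressure — and
   terminal vessels use fully absorbing outlets.

2. **A TMCMC inference engine.** Transitional MCMC tempers from the
   prior to the posterior through densities ∝ likelihood^q × prior,
   choosing each exponent so the coefficient of variation of the
   plausibility weights hits 1.0, resampling multinomially and moving
   particles by Metropolis chains with a b²-scaled (b = 0.2) weighted
   sample covariance proposal. The log-evidence log ρ(D|M)
   accumulates as Σ_j log S_j over the stage-mean plausibility
   weights — so model comparison comes free with parameter
   estimation.

3. **Evidence-based defect selection.** Candidate model `M_i` frees
   the scaled stiffness β_i = B/B* (or scaled area α_i = A0/A0*) of
   artery i plus the noise level σ; `M_{i:j}` frees two arteries.
   Normalizing evidence × prior over the class yields Pr(M_i | D),
   a posterior probability that the defect sits in artery i.

Synthetic observations follow the noise model
`D_k = v_k + σ ε_k` with σ a stated fraction (1% or 5%) of the pooled
standard deviation η of the clean velocities, plus optional
multiplicative corruption of every reference area
(`A0 → A0(1 + σ_α ε)`) so the inference model is deliberately
misspecified. Real velocity data in the same CSV schema drop in
without code changes.

## Worked example

Generate a 7-artery tree, inject a halved wall stiffness into artery
2, observe two sensors at 1% noise, and ask five candidate models
where the defect is:

```python
import hemobayes as hb
from hemobayes.selection import single_defect_model, pair_defect_model
from hemobayes.tmcmc import TMCMCConfig

net = hb.build_fixture_network(7, seed=11)
wave = hb.default_inflow(n_cycles=1)
cfg = hb.SolverConfig(elements_per_artery=1, final_time=0.832)
sensors = hb.SensorConfig(sensors=((1, "end"), (7, "end")))

data = hb.generate_dataset(net, hb.DefectSpec(2, "stiffness", 0.5),
                           wave, cfg, sensors, fraction=0.01, seed=100)

models = [single_defect_model(i, "stiffness") for i in (2, 3, 4, 6)]
models.append(pair_defect_model(2, 3, "stiffness"))
result = hb.run_selection(models, data, net, wave, cfg,
                          TMCMCConfig(n_samples=128, seed=1000))
print(result.to_frame(render_small_as_tilde=True).to_string(index=False))
```

which prints (posterior means, coefficients of variation in %, noise
level estimate, log-evidence and model probability per candidate):

```
model     estimate        u_%  sigma_hat  u_sigma_%  log_evidence Pr(M|D)
  M_2        0.509       1.61   0.001182  14.924836    123.877646     1.0
  M_3        0.452       7.41   0.005064  15.742502     91.794725      ~0
  M_4        0.437      40.01   0.007467  14.119028     84.161971      ~0
  M_6        0.551      17.27   0.006322  18.177645     87.637353      ~0
M_2:3 0.465, 2.202 2.92, 4.40   0.002517  16.846039    100.589524      ~0
```

The true model `M_2` takes essentially all posterior mass; its
stiffness estimate β̂₂ = 0.509 (coefficient of variation 1.6%) sits
close to the injected 0.5, and its σ̂ = 0.00118 m/s tracks the
injected noise level 0.00141 m/s. The wrong-artery models can only
explain the data by inflating σ̂ several-fold, which costs them
30–40 log-evidence units, and the over-parametrized nested model
`M_2:3` is likewise penalized relative to `M_2` (Occam's factor). The same workflow is available from the
shell via the `hemobayes` CLI (`network`, `simulate`, `observe`,
`infer`, `select` subcommands); defaults there are the full-scale
profile (19 arteries, 3 cardiac cycles, 52 samples per sensor,
500 TMCMC samples).

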
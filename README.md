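# normsim

Cell-state transition modelling of macrophage responses to bacterial
lipopolysaccharide (LPS), for systems biologists studying
activation-induced heterogeneity and endotoxin tolerance: why only a
fraction of a clonal macrophage population expresses a given inflammatory
protein (TNF, IL-6, pro-IL-1β, NOS2) after stimulation, and why a second
LPS challenge elicits a weaker response.

The core model tracks a fixed population of T cells, each in one of up to
four states per protein — negative (N), positive (P), reversibly
non-responsive (NRS), permanently non-responsive (NRPS) — with per-cell
transition rates (per day)

    N  → P      α·(1 + μ·L(t))        L(t) = L₀·e^(−δt)  (LPS, 1000 ng/ml ↦ 1)
    P  → N      β
    P  → NR     γ₁
    NR → N      β₂
    NR → NRPS   γ₂

with μ = 10 and δ = 0.5 d⁻¹ fixed.  γ₂ = 0 collapses the four-state model
onto the three-state one; γ₁ = β₂ = 0 onto the two-state model, which has an
exact closed-form solution under a single decaying dose.

The package provides

* exact stochastic simulation (Doob–Gillespie with the time-varying
  LPS-dependent propensity handled exactly by thinning) and the matching
  mean-field ODE, with nesting and agreement tests;
* rejection-sampling parameter inference in a statsmodels-style
  `NoRMModel.fit() → NoRMResults` interface: draw rate vectors from a prior
  (uniform U[0.01,1], truncated-normal, or gamma), simulate every observed
  condition, retain the 50 lowest-AIC sets, compare three- vs four-state
  models by mean AIC, and diagnose sample-budget sufficiency by RMSD
  convergence;
* eFAST variance-based global sensitivity analysis (3 resample curves × 65
  samples × 7 parameters + 1 dummy = 1560 model runs in the reference
  design) yielding first-order (Si) and total-order (STi) indices per model
  output, with the dummy parameter as noise floor;
* a synthetic flow-cytometry-style data generator: ground-truth trajectories
  observed as binomial draws of 10,000 cells per sample under the standard
  experimental designs (dose titration 1/10/100/1000 ng/ml; pre-treatment
  conditions Media/1000, 10/1000, 1000/1000), so the whole analysis runs
  end-to-end with known ground truth;
* a `norm` command line (simulate / synth / fit / compare / efast / compose /
  pipeline) with JSON run manifests for bit-reproducibility.

See `docs/methods.md` for the modelling assumptions, numerical choices and
known limitations.

## Worked example

Generate a synthetic TNF dataset from a known three-state truth under the
three pre-treatment conditions, fit three- and four-state models by
rejection sampling, and compare them:

```python
import normsim as ns
from normsim import NoRMModel, compare_models, generate_observations
from normsim.synthetic import raw_like_design

design = raw_like_design(titration=False)
obs, truth = generate_observations(design, ns.ModelSpec(3), seed=7, proteins=("TNF",))

model3 = NoRMModel(obs.frame, n_states=3, protocols=design.protocols)
res3 = model3.fit(n_samples=20_000, top_k=50, seed=0)
print(res3.summary())

res4 = NoRMModel(obs.frame, n_states=4, protocols=design.protocols).fit(
    n_samples=20_000, top_k=50, seed=0)
print(compare_models(res3, res4).summary())
```

Output:

```
NoRM rejection-sampling fit (3-state model)
  observations: 9 records, 3 conditions
  sampled: 20000 sets (0 failed), prior: uniform, engine: ode
  retained: 50 sets | mean AIC -80.928 | best RMSD 0.00421
  parameter   median     2.5%    97.5%   (per day)
  alpha        0.4117   0.3613   0.4568
  beta         0.4112   0.0455   0.9402
  beta2        0.4136   0.0464   0.8967
  gamma1       0.6507   0.4610   0.8526

Model comparison (mean AIC over retained sets)
  3-state: -80.928  <-- preferred
  4-state: -77.926
  delta AIC: -3.003
```

The best retained set reproduces the data to RMSD 0.0042 — the binomial
counting-noise floor at 10,000 cells per sample — and the envelopes of the
identifiable rates bracket the generating truth (α = 0.40, γ₁ = 0.60);
β and β₂ trade off along a compensation ridge and stay broad.  The
three-state model is preferred: the extra permanent-silencing state buys no
fit improvement on positive-fraction data of this design, only the +2
parameter penalty.

The same stages run from the shell:

```bash
norm synth --design raw_like --seed 3 --out obs.csv --truth truth.json
norm fit --model 3 --obs obs.csv --protein TNF --n 100000 --top 50 --seed 7 --out fit3.json
norm efast --curves 3 --samples 65 --engine ode --seed 11 --out efast.csv
```

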
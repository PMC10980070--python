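# soilregimes

Quantitative analysis of how a soil microbiome's nitrate metabolism responds
to pH perturbation. The package implements, as a tested library with a thin
CLI, the full desk-side pipeline of a microcosm pH-perturbation study:
soils spanning a natural pH gradient are slurried with 2 mM nitrate,
shifted to a grid of perturbed pH values with and without chloramphenicol
(CHL+ arrests growth), and nitrate is tracked colorimetrically over four
days; endpoint communities are 16S-sequenced with genomic-DNA spike-ins.

## The model

Nitrate dynamics in every microcosm are described by a two-resource
consumer–resource model with a single effective functional biomass x̃,
nitrate A, and a growth-limiting nutrient C̃ (all rescaled to nitrate-rate
units, mM and mM/day):

    dA/dt  = −x̃·A/(A+K_A)
    dC̃/dt = −x̃·C̃/(C̃+K̃_C)
    dx̃/dt = γ·x̃·[A/(A+K_A)]·[C̃/(C̃+K̃_C)]      (dx̃/dt ≡ 0 under CHL+)

With small affinities the solution is piecewise explicit: biomass grows as
x̃₀e^{γt} until the scarcer resource is exhausted at
t\* = log(min(A₀, C̃₀)γ/x̃₀ + 1)/γ, after which nitrate falls linearly at
γC̃₀ + x̃₀. Fits to paired CHL−/CHL+ series (pooled mean-squared error,
γ = 4.8/day and K_A = K̃_C = 0.01 mM fixed; x̃₀, C̃₀, A₀, A₀c free) place
each condition on the (x̃₀, γC̃₀) plane, where three functional regimes
separate at x̃₀ = 0.05 and γC̃₀ = 1.5 mM/day:

* **Regime I — acidic death**: little biomass, little nutrient, no activity;
* **Regime II — nutrient-limiting**: large pre-existing biomass, linear
  late-time nitrate consumption set by dose-proportional nutrient release;
* **Regime III — resurgent growth**: rare taxa grow exponentially on the
  nutrient excess released by large base additions.

Around the model sit the sequencing analyses: spike-in normalization to
absolute abundance, an empirical two-component replicate noise model
σ(n) = √((c_frac·n)² + c₀²), Bonferroni-thresholded enrichment z-scores,
rank-2 NMF of phylum-level growth folds, and a LASSO that predicts a
soil's native pH from the presence of its resurgent-growth taxa
(leave-one-soil-out validation, soil-level permutation null).

A synthetic-data module generates the whole study design — titration
curves, triplicate nitrate series, count tables with spike-ins — with
known ground truth, so every stage is testable without field data.

## Worked example

```python
import numpy as np
from soilregimes import CRMParams, fit_sample_pair, classify_regime
from soilregimes.fitting import simulate_pair

truth = CRMParams(x0_tilde=0.1, C0_tilde=0.05, A0=2.0, A0c=2.0)
pair = simulate_pair(truth, noise_sd=0.05, rng=np.random.default_rng(0))
fit = fit_sample_pair(pair)
label = classify_regime(fit.params.x0_tilde, fit.params.gamma_C0_tilde)
print(f"x0_tilde = {fit.params.x0_tilde:.3f} mM/day")
print(f"gamma*C0_tilde = {fit.params.gamma_C0_tilde:.3f} mM/day")
print(f"RMSE = {fit.rmse_pct_of_input:.2f} % of the 2 mM input")
print(f"regime = {label.regime}")
```

prints

```
x0_tilde = 0.074 mM/day
gamma*C0_tilde = 0.276 mM/day
RMSE = 1.67 % of the 2 mM input
regime = II
```

The fitted initial consumption rate (0.074 mM/day) matches the generating
biomass (0.1 mM/day) within the 0.05 mM measurement noise, the inferred
nutrient pool is small (γC̃₀ ≪ 1.5), and the condition is classified as
nutrient-limited — linear nitrate dynamics after a short early growth
phase.

An end-to-end synthetic run of every stage:

```
python -m soilregimes run-all --seed 1 --out-dir results/run1 --n-soils 6
```

writes fits, regime labels and boundaries, enrichment calls, the NMF
decomposition of the growth matrix, and native-pH predictions under
`results/run1/`.

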
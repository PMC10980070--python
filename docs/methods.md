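# Methods

This note documents the models and procedures the package implements, the
numerical and statistical choices behind them, and what the synthetic-data
tests do and do not demonstrate.

## Consumer–resource model (`soilregimes.crm`)

The state is (A, C̃, x̃): nitrate (mM), rescaled growth-limiting nutrient
(mM), and rescaled functional biomass (mM/day). Only the rescaled
combinations x̃ = r_A·x, C̃ = C·r_A/r_C, K̃_C = K_C·r_A/r_C are
identifiable from nitrate series, so the unrescaled uptake rates r_A, r_C
never appear separately; everything carries nitrate-rate units. Under
chloramphenicol the growth equation is switched off and nitrate falls
linearly at x̃₀ while A ≫ K_A.

Two solvers are provided:

* `simulate_numeric` — LSODA (stiff-capable) at rtol 1e-8 / atol 1e-10,
  states clipped at 0 after integration. Authoritative everywhere, and the
  only correct choice when the affinities are varied, since the closed
  form below does not contain them.
* `simulate_analytic` — the piecewise solution valid for small affinities:
  exponential biomass until t\* = log(min(A₀, C̃₀)γ/x̃₀ + 1)/γ, then
  linear nitrate decline at γC̃₀ + x̃₀ (nutrient-first exhaustion) or a
  clip at zero (nitrate-first), concentrations clipped at exactly 0.

**Accuracy of the closed form.** The closed form neglects the first-order
Monod corrections: during growth the true exponent is effectively
γ(1 − K_A/A − K̃_C/C̃) < γ, so the exponential "cliff" of the true
solution lags the closed form. On the 10-point measurement grid the gap is
0.6–1.1% of the 2 mM input for the three reference scenarios, but can
reach several percent of A₀ for long growth phases (x̃₀ ≲ 0.01 mM/day with
large C̃₀), because a small time shift of a steep cliff is a large
concentration difference. Consequently the analytic path is used for
speed only where it is accurate — nutrient-limited-style fits with the
small fixed affinities — and the ODE is used wherever affinities matter
or small-x̃₀ accuracy does (sensitivity scans, amendment fits, parameter
recovery assessments). `model="auto"` encodes this rule (analytic only
when both K ≤ 0.02 mM).

## Fitting (`soilregimes.fitting`)

The loss pools both arms: L = (1/2N)[Σ(A(t_k⁻)−a_k⁻)² + Σ(A_c(t_k⁺)−a_k⁺)²],
with separate initial nitrate A₀ (CHL−) and A₀c (CHL+). Four parameters
are free — x̃₀, C̃₀, A₀, A₀c — and γ = 4.8/day, K_A = K̃_C = 0.01 mM are
fixed globally; the sensitivity scan (below) is the justification.
Optimization is L-BFGS-B in (log₁₀x̃₀, log₁₀C̃₀, A₀, A₀c) with bounds
x̃₀ ∈ [1e-5, 1] mM/day, C̃₀ ∈ [1e-4, 10] mM, A₀, A₀c ∈ [1, 3] mM (the
nominal input is 2 mM). The first start is data-driven — the CHL+ slope
pins x̃₀ and the late CHL− slope pins γC̃₀ + x̃₀, which places the
optimizer in the right basin almost always — followed by up to 8
deterministic log-spaced restarts; restarting stops once the normalized
RMSE falls below 0.05% (a fixed rule, so fits are deterministic). RMSE is
normalized by the nominal 2 mM input, not per-sample A₀. Replicates are
fit independently; downstream consumers take the median of the three.

The sensitivity scan simulates the three reference curves
(x̃₀ = 0.01, 0.1, 0.001 mM/day with C̃₀ = 0.005, 0.05, 2 mM; A₀ = A₀c =
2 mM, γ = 4/day, K = 0.01 mM) and refits each with one fixed parameter
clamped: γ anywhere in 2–6/day costs under 5% normalized RMSE, and either
affinity clamped below 0.1 mM costs under 1% — hence the global fixing.

The amendment fit treats the nutrient:nitrate utilization stoichiometry
ratio = r_C/r_A as the single free parameter shared across amendment
doses: an added dose ΔC raises the rescaled nutrient by ΔC/ratio. The
recovered value is ~2.5 for glucose-like synthetic series (1 for
acetate-like). Doses of 0.5–5 C-mM then map to 0.2–2 mM of rescaled
nutrient, which keeps the curves inside the measurement window and the
ratio identifiable; with the opposite convention (multiplying by the
ratio) every dose saturates the 2 mM nitrate pool and the loss is flat.

## Regimes and boundaries (`soilregimes.regimes`)

Classification on the (x̃₀, γC̃₀) plane: Regime II when x̃₀ ≥ 0.05 mM/day
(the biomass test takes precedence, so high-biomass/high-nutrient
conditions are II); otherwise Regime III when γC̃₀ ≥ 1.5 mM/day, else
Regime I. Exact ties go to the higher-activity regime — the thresholds
come from bimodality of the fitted-parameter distributions and no
open/closed convention exists, so a deterministic rule is needed. The
thresholds are arguments; re-estimating them per dataset is left to the
caller since no anchored algorithm exists for it.

Per-soil boundaries are midpoints between the adjacent perturbed-pH
conditions across a label change, with the grid gap as the error bar; a
non-monotone label sequence warns and uses the first transition. The
boundary-vs-native-pH trend is weighted least squares with weights 1/error
(statsmodels WLS; 95% CI on the slope); zero errors fall back to equal
weights with a warning.

Titration curves are interpolated with a shape-preserving monotone (PCHIP)
spline — an unconstrained cubic can overshoot on the buffering plateaus
and lose invertibility — and inverted by bisection to 0.01 pH. The
standard dose table is 13 target pH levels evenly spaced over 3–9 with
the level nearest the native pH replaced by the native pH itself (dose 0);
unreachable targets (strongly buffered soils) are flagged, not errors.

The rate-fold collapse uses model-derived rates by default — fold =
(x̃₀ + γC̃₀)/x̃₀, the late CHL− rate over the CHL+ rate — restricted to
Regime II with NaOH doses 0–25 mM; measurement-derived folds can be
supplied instead.

## Abundance and noise (`soilregimes.abundance`)

Counts are normalized as (count + 0.5)/spike-in per sample (total biomass
uses no pseudocount). The replicate noise model is
σ(n) = √((c_frac·n)² + c₀²) per measurement, calibrated per soil ×
perturbed pH:

* c_frac = 1.4826·median(|nᵢ−nⱼ|/n̄)/√2 over replicate pairs with pair
  mean above 50 counts (a robust Gaussian scale of pair differences; the
  √2 converts a two-measurement difference to a per-measurement sd).
* c₀ is the smallest value for which the 1-sigma fraction (0.6827) of all
  replicate comparisons satisfies |nᵢ−nⱼ| ≤ √2·σ(c₀, c_frac, n̄), found
  by bisection. Three calibration details matter for consistency, all
  exposed as arguments: (i) the band is the one-sigma spread of a
  *difference* (√2σ), since comparing a difference against ±σ itself
  covers only 52% at truth and roughly doubles the recovered c₀;
  (ii) the coverage target is the exact Gaussian one-sigma mass rather
  than the rounded "67%", which would bias c₀ low by ~6%; (iii) integer
  differences are compared to the continuous band with a half-count
  continuity correction (applied only to nonzero differences), without
  which rounding and the zero floor bias c₀ low by ~10% at small
  abundances. With these choices the estimator recovers planted
  (c_frac, c₀) = (0.21, 4.5) to within ±0.02 and ±0.35 across seeds.

Enrichment: per replicate pair, z = (c⁻ − c⁺)/√(σ²(c⁻) + σ²(c⁺)) on
pseudocounted counts (the noise model lives on the count scale; spike
normalization is for reporting). The median z across the three pairs is
compared with the Bonferroni critical value z = Φ⁻¹(1 − α/2/n_ASV), with
n_ASV the number of ASVs nonzero in the compared samples (4.2 at
n_ASV = 2000, 4.3 at 2500). Per-soil enriched sets are unions across
conditions of a regime, minus the "no-nitrate responders" enriched in the
nitrate-free controls. **Detection limit:** because the z denominator
scales with c_frac·count, the pair z for a fold F saturates at
(F−1)/(c_frac·√(F²+1)) ≈ 1/c_frac for large F; at c_frac = 0.21 even an
infinite fold caps near z ≈ 4.8 and an 8-fold change caps at ≈ 4.1 —
below the critical value. Enrichment calling is therefore only powered in
quieter conditions or for very large folds, which is how the synthetic
tests are posed.

Growth folds: g = ln(Abs⁻ + 10⁻³) − ln(Abs⁺ + 10⁻³) per phylum ×
condition (natural log, configurable), negatives clipped to 0; the CHL+
arm is the reference so non-growth artifacts cancel. Survival folds are
endpoint-CHL+/T0 ratios with the same pseudo-abundance. The rank-2 NMF
uses Frobenius multiplicative updates (objective provably non-increasing),
5 seeded restarts keeping the best reconstruction; variance explained is
1 − ‖G − WH‖²_F/‖G‖²_F.

## Native-pH prediction (`soilregimes.native_ph`)

Presence matrices are built by summing relative abundance within the
chosen rank and thresholding (0, 0.001 or 0.005; strictly greater). The
lasso (½n‖y − β₀ − Xβ‖² + λ‖β‖₁) is solved by cyclic coordinate descent
with covariance (Gram) updates, cached partial gradients, an active-set
inner loop, and warm starts along a 100-value log path (λ_min/λ_max =
1e-3). Convergence is declared at max coefficient step 1e-3 (pH units,
the scale glmnet's deviance-based tolerance implies); once a path fit
explains >99.9% of training variance, smaller penalties reuse it rather
than iterating on a non-unique interpolating optimum. λ is selected by
CV with soil-stratified folds (one soil per fold at ten soils);
leave-one-soil-out refits λ and the model without the held-out soil.
R² is computed on per-soil mean predicted vs observed pH and can be
negative.

The permutation null permutes native pH at the soil level and, crucially,
re-selects λ by CV for each permutation: with more taxa than samples, a
fixed small λ lets every permuted response be interpolated in-sample
(null R² ≈ 1) and the test has no power; re-selection lets null
permutations collapse to the intercept-only model exactly as the observed
data would be analyzed. The threshold is the ceil(α·n_perm)-th largest
null value, so the exceedance probability is at most α by rank
exchangeability.

## Synthetic data (`soilregimes.synthetic`)

The generator's defaults are the study design: 20 soils with native pH
4.7–8.3, 13 perturbed levels spanning pH 3–9 (step 0.5, native pH
substituted for the nearest level), triplicates, CHL±, timepoints
0–91 h, 2 mM nitrate, measurement noise sd 0.05 mM. Ground-truth surfaces
are deterministic functions of the design (seeds drive only noise):

* titration curves are logistics between pH 2.2 and 9.6 with buffering
  width 20–32 mM increasing from acidic to basic soils, anchored so dose 0
  gives the native pH — acidic soils sit on the buffered lower plateau,
  so equal acid doses move neutral soils further in pH;
* x̃₀ is a plateau of 0.5 mM/day that collapses (width 0.06 pH) below an
  acid boundary at 0.7·native + 0.2 — the planted linear boundary trend —
  and collapses again (width 1.5 mM) above a fixed 19 mM NaOH dose;
* C̃₀ = 0.02 + dose/72 mM for base additions, so γC̃₀ crosses the 1.5
  threshold at a fixed 15 mM dose for every soil: the II→III transition is
  driven by the amount of base, and its pH rises with native pH purely
  through the titration curves.

Regime labels are defined by classifying the planted parameters, so the
ground truth is self-consistent by construction. Some strongly buffered
basic soils cannot reach pH 3 within the ±100 mM titrated range; those
levels are dropped, mirroring the restricted ranges of very basic field
soils.

Count tables are compositional: a fixed amount of spike-in DNA per sample
(targeting ~9% of reads at T0) plus community DNA are sequenced at fixed
depth, so spike fractions rise when biomass falls and spike-normalized
abundances recover absolute amounts. Planted structure: rare
Firmicutes-like ASVs (T0 floor ~2 counts) drawn from a pH-ordered pool
grow ~200-fold wherever the dose exceeds the collapse threshold; dominant
Proteobacteria/Bacteroidota grow (1 + 0.2·dose)-fold in Regime II and die
under acid (survival sigmoidal in pH, sparing Firmicutes); five
no-nitrate responders grow regardless of nitrate. Replicate noise is the
two-component Gaussian (default c_frac = 0.15, c₀ = 4.5), rounded and
floored at zero; all replicate-to-replicate variation, including depth,
is carried by c_frac, matching how the noise model is calibrated. The
quieter default (0.15 vs the 0.21 used in the calibration-recovery
scenario) keeps planted growth above the detection limit described above.

`make_presence_panel` plants the native-pH signal directly: each taxon
has a preferred pH and is present in a sample with probability
0.9·exp(−Δ²/(2·0.8²)) + 0.05. The soft niche matters: a deterministic
presence window encodes soil identity exactly, letting any permuted
response be fit perfectly and destroying the permutation null's power.

**What passing tests show — and don't.** Synthetic data realize the
package's own noise model (Gaussian, homogeneous within condition) and
noiseless model dynamics. Real microcosms add model misfit (nitrite
dynamics, non-Monod kinetics), heavier-tailed and correlated count noise,
compositional taxa correlations, and titration drift; recovery rates
measured here are upper bounds on real-data performance.

## Problem sizes in the test suite

The test suite runs the regime-recovery check on a 6-soil panel (a fifth
of the full design with identical grids, noise and thresholds), the
parameter-recovery check on 50 random draws, the permutation-null
calibration on 20 seeds with 39 permutations each (ceil(0.05·39) = 2 gives
an exact 5% exceedance), and Monte-Carlo false-positive control on 200
simulated condition families of 2000 ASVs. These sizes are chosen so the
whole suite runs on a single CPU in minutes while keeping every assertion
at the tolerances stated above.

## Known limitations

* The closed-form solution degrades for long exponential phases (small
  x̃₀); the ODE path must be used there, and is.
* Nitrite, ammonium (DNRA) and gaseous products are not modeled.
* Fit uncertainty is restart spread only; no hierarchical sharing across
  replicates or soils.
* The enrichment caller is fundamentally limited to folds with
  (F−1)/(c_frac√(F²+1)) above the Bonferroni critical z.
* The permutation test with few soils has a coarse null (n! soil
  relabelings); thresholds at 8–10 soils are conservative.
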
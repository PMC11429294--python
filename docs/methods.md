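# Methods

## Model and assumptions

The selection design rests on a deliberately minimal two-subpopulation
model of a batch culture in selective medium. Transformed cells (carrying
the resistance plasmid) grow exponentially at μ₁ > 0; non-transformed cells
die exponentially at a constant non-survival rate μ₂ < 0. Both pools evolve
independently — no interaction, no lag kinetics, no substrate dynamics:

    dc₁/dt = μ₁·c₁        dc₂/dt = μ₂·c₂

The design question ("how long must selection run?") has the closed-form
answer t_req = ln(s·f/(1−f))/(μ₂−μ₁), where f is the starting transformed
fraction and s the target end ratio c₂/c₁. Expressed in generations
(t_req / (ln2/μ₁)) the requirement depends only on k = μ₂/μ₁, f and s —
this μ₁-invariance is what lets one death-rate assumption (k = −2.8,
calibrated on *E. coli*) port to other hosts, and it is verified as a
property test over random rates.

Lag phases are handled by schedule padding, not kinetics: the first stage
is two generation times instead of one, and slow hosts can stretch it
further with a resting multiplier that adds time without advancing the
counted generations. The generation count is rounded up to whole stages so
the scheduled time always meets or exceeds t_req; the overshoot is why the
simulated end purity (98.13 %) slightly exceeds the 98.04 % that the exact
t_req would give.

Dead cells are tracked as an explicit third pool: every non-transformed
death is conserved into it, and transfers dilute it like any other pool.
This makes propidium-iodide-style compositions (% dead) computable at every
stage. The initial dead pool (e.g. 43 % of all cells after heat shock) is
split transformed/non-transformed in proportion f, since nothing selects
among already-dead cells.

## Parameters

| Parameter | Meaning | Unit | Default | Why |
|---|---|---|---|---|
| μ₁ | transformed growth rate | h⁻¹ | 0.25 (ecoli preset) | plate-derived; presets: 0.15 (pputida), 0.19 (cglutamicum) |
| μ₂ or k | non-survival rate / ratio μ₂/μ₁ | h⁻¹ / – | k = −2.8 | death-rate rule calibrated on *E. coli*; exactly one of the two is supplied |
| f | starting transformed fraction | – | 1e-4 | typical post-transformation composition |
| s | end criterion c₂/c₁ | – | 0.02 | 50:1 target purity |
| c_x0 | starting viable cells | count | 1e4 | puts one transformed cell in the first well at f = 1e-4 |
| initial_dead_fraction | dead share of all cells at start | – | 0.43 (ecoli), 0 otherwise | heat-shock mortality; electroporation hosts lack a measured value |
| first_stage_generations | counted length of stage 1 | generations | 2 | lag-phase padding |
| resting_multiplier | stretch factor on stage 1 | – | 1 (2 for cglutamicum) | extended lag of the Gram-positive host |
| dilution | transfer carry-over fraction | – | 0.5 | 500 µL + 500 µL in a 1 mL well |

Note the cglutamicum preset: its plate-measured doubling time and growth
rate are mutually inconsistent in the source measurements (0.69 h vs
ln2/0.19 = 3.65 h); `plate_growth.check_consistency` flags such pairs
rather than silently trusting either number. The schedule always uses
ln2/μ₁ unless the caller overrides the generation time explicitly, which
keeps the ≥ t_req guarantee exact.

## Simulator

Within a stage, pools follow the closed forms; with a carrying capacity K
the viable pools instead integrate dN/dt = μ·N·(1 − N_viable/K) (RK45,
rtol 1e-10) — a single shared logistic brake standing in for oxygen
limitation at high density. Deaths flow into the dead pool only while
μ₂ < 0. At each transfer every pool is multiplied by the dilution factor,
so all composition percentages are invariant across transfers (asserted to
1e-12 in tests). Without capacity or noise the simulator is verified to
match the closed forms at stage boundaries to 1e-10 relative, and the
closed forms themselves are cross-checked against an independent
fixed-step RK4 integrator (step 1e-3 h, agreement 1e-8 relative over
(0, 30 h]).

Observation proxies mimic the microbioreactor readout: backscatter =
max(gain · all cells, detection floor) with multiplicative lognormal noise;
GFP = gain · viable transformed cells. Two realism knobs matter:

* **mu1_liquid** — the realized liquid growth rate, defaulting to the
  design μ₁. Plate-derived rates underestimate liquid growth (colonies
  grow quasi-2D), so realized runs grow faster than designed; this
  conservatism is intentional and the knob lets scenarios represent it.
* **mu_heterogeneity_sd** — one μ₁ draw per replicate well (Gaussian
  truncated at zero), modelling clone-to-clone rate scatter.

Apparent per-stage growth rates use the same log-slope estimator as the
plate analysis, computed either on the observed backscatter trace (default;
this is what instrument software reports, and flat traces below the
detection floor yield noisy near-zero rates) or on the true viable count
(`source="viable"`). Replicate rates ≤ 0.01 h⁻¹ are excluded from the
across-replicate SD — a flat trace carries no rate information — and the SD
is reported as percent of the included mean (a CV).

The frozen *homogenization scenario* (`synthetic_data.homogenization_config`:
μ₁_liquid = 1.2 h⁻¹, heterogeneity SD 0.12 h⁻¹, 15 % backscatter noise,
floor 1e3 signal units) reproduces the characteristic selection signature:
early stages are biomass-flat (the conserved dead pool dominates), so
apparent rates are noise around zero with a large CV, while the final stage
shows clean exponential growth and the CV collapses to the ~12 %
heterogeneity floor. The dilution-series scenario (inocula of 7–120
transformed cells, K = 5e6 cells/well, μ₁_liquid = 1.0 h⁻¹) makes high
inocula saturate while low ones stay exponential, giving the log-linear
relation between final backscatter and starting cell count.

## Fitter

Given gated viable-only stage fractions and a fixed μ₁, the fitter
estimates μ₂ and c₁₀ (in % of initial viable cells, with c₂₀ = 100 − c₁₀ as
the complementary share) by Levenberg–Marquardt damped least squares
(MINPACK via lmfit; box bounds μ₂ ≤ 0 and 0 ≤ c₁₀ ≤ 100 via lmfit's
parameter transformation; ftol = xtol = 1e-10, up to 500 iterations).
Starting values are the k-rule prior μ₂ = −2.8·μ₁ and the first observed
transformed percentage. R² = 1 − SS_res/SS_tot is reported per curve and is
NaN (with a warning) for zero-variance observations. The default joint mode
stacks both curves' residuals with shared parameters; `mode="per_curve"`
fits each curve separately and reports c₁₀ from the transformed and μ₂ from
the non-transformed curve, mirroring workflows that treat the two gates
independently. Noiseless model-family data are recovered exactly (1e-6,
R² = 1); under 2-percentage-point gating noise the median μ₂ error over 50
seeds stays below 0.05 h⁻¹.

## Synthetic data — what it does and does not show

The generators produce every input the pipeline consumes: colony-area
series (footprint · N₀ · e^{μ₁t} with 2 % lognormal area noise), stage-wise
four-way compositions (simulator ground truth plus 2-percentage-point
additive gating noise, renormalized to 100 %), and dilution-series
configurations. All randomness flows through one seeded generator per
scenario; fixed seeds reproduce outputs bit-identically.

They emulate exponential kinetics, dilution transfers, detection floors,
and gating noise. They do **not** emulate: lag-phase kinetics (only the
schedule padding represents lag), antibiotic pharmacodynamics (death is a
single constant rate, whereas real non-survival rates drift as the
antibiotic degrades), 3D colony growth on plates, substrate/oxygen mass
transfer (the logistic brake is a phenomenological stand-in), or raw
flow-cytometry event data. Passing tests therefore demonstrate internal
consistency of the design math and estimators under the stated noise
models — not that a particular laboratory run will hit 98 % purity.

## Numerical choices and degenerate inputs

* Rates in h⁻¹, times in h, counts dimensionless; volumes in µL.
* Growth-rate estimation: two points → difference quotient; more → OLS on
  ln N vs t; zero-area points dropped with a warning; μ ≤ 0 returned
  flagged (NaN generation time) rather than erroring.
* s·f/(1−f) ≥ 1 (start already past the criterion) → t_req = 0, flagged;
  k ≥ 1 or μ₁ ≤ μ₂ → explicit no-selection error; μ₂ > 0 with μ₁ > μ₂ is
  allowed but warns (selection is then dilution-driven only).
* Ceiling of the generation count is taken after rounding to 9 decimals so
  floating-point dust cannot add a spurious stage.
* Fraction predictions are evaluated on the log scale so extreme μ·t stays
  finite.
* Pool counts above 1e30 are capped with a warning suggesting a carrying
  capacity.

## Known limitations

* The resting multiplier model (stretch stage 1 only) is the simplest
  representation of lag; hosts with mid-run adaptation are not covered.
* The per-curve fit mode shares no information between gates, so its two
  R² values are not comparable to the joint mode's.
* Worklist re-import reconstructs the final stage duration from the
  one-generation rule, since the worklist records no harvest event.
* The 48-well plate layout assumes row-major contiguous 4-well runs; other
  geometries need explicit well lists.
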
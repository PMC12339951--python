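# Methods

## Models

Three archetypal EGF→Raf→MEK→ERK cascade models span the structural axes
along which published ERK models differ. All use minutes and nM, carry EGF
as a state with identically zero derivative (a sustained stimulus that does
not deplete), start from a resting state with tier totals as parameters,
and expose the same observation map (active ERK divided by total ERK, a
dimensionless activity in [0, 1]) and QoI map (active-ERK concentration).

**MA_CASCADE** (9 states, 9 parameters): elementary mass-action kinetics
with distributive dual phosphorylation at the MEK and ERK tiers. The
cascade composition makes the steady-state dose–response ultrasensitive
(fitted Hill coefficient > 1). Nominal rates (Raf activation 100 nM⁻¹min⁻¹
against deactivation 1 min⁻¹; tier phosphorylation 0.1 nM⁻¹min⁻¹ against
dephosphorylation 1 min⁻¹; totals 10/100/100 nM) place the EC50 inside the
experimentally motivated 0.001–0.106 nM EGF window. Because the cascade is
feedforward, its steady state has a closed form per tier; that expression
seeds the Newton solver (below) but is always verified against the
residual criterion, never trusted.

**FB_CASCADE** (8 states, 16 parameters): Michaelis–Menten tiers with a
divisive `1/(1 + ppERK/K_fb)` negative-feedback factor on EGF-driven Raf
activation. Nominal parameters (fast phosphatases, K_fb = 0.3 nM) give a
transient response at 0.1 nM EGF: peak activity ≈ 0.97 near 7 min decaying
to ≈ 0.46 by 40 min, emulating transient cytoplasmic ERK.

**RAP1_CASCADE** (12 states, 24 parameters): FB_CASCADE plus an
EGFR→C3G→Rap1→Raf branch whose Raf activation is *not* modulated by ERK
feedback and has its own Michaelis constant (parameters `k1_C3G_deact`,
`Km_Raf_Rap1`, ...). At nominal values the branch sustains activity
(plateau ≈ 0.88) that the feedback cannot extinguish — the
Rap1-dependent sustained phenotype. Setting total Rap1 to zero removes the
branch exactly, which is how Rap1 inhibition (+Rap1GAP) is simulated; with
zero Rap1 the model's shared states reproduce FB_CASCADE trajectories to
solver tolerance (a regression test).

Parameter groups (`Rap1`, `negative_feedback`, `raf_deactivation`,
`erk_phosphorylation`, `erk_dephosphorylation`) are declared on the models
and drive the shared-vs-location-specific hypothesis machinery.

## Numerics

*Trajectories* are solved with the adaptive stiff LSODA integrator at
atol = rtol = 1e-6 and a 6×10⁶ step cap; rate laws are jit-compiled.
Conserved-pool drift is bounded by 10·rtol in tests. Integration failures
and non-finite states raise (or score −∞ in the likelihood; see below).

*Steady states* use the two-phase scheme: integrate until the event
criterion `‖dx/dt‖₂ ≤ atol_ss + rtol_ss·‖x‖₂` (atol_ss = 1e-5,
rtol_ss = 1e-6) is met — implemented as the first point on a log-spaced
checkpoint grid satisfying the criterion — then refine with a damped
Newton iteration (tolerance 1e-10·(1+‖x‖), max 100 steps). Newton operates
on the conservation-reduced system (EGF and one state per conserved pool
eliminated), which keeps the Jacobian nonsingular and preserves tier
totals exactly. Models may supply an analytic steady-state initialization
(MA_CASCADE does); the returned state must satisfy the same residual
criterion regardless of how it was initialized, and a failed warm start
falls back to the integrate-then-refine path. Dose–response curves solve
doses in ascending order with Newton continuation from the previous dose
and normalize the QoI to the curve maximum ("% maximal ERK activity");
requiring ≥ 2 distinct doses makes the normalization well-posed.

*Unit conversions* use an EGF molecular weight of 6048 g/mol and a 1 nL
cell volume; 6.048 ng/mL ≡ 1 nM ≡ 6.022×10⁵ molecules/cell.

## Synthetic data

The generator emulates fluorescence-reporter experiments without modeling
optics: per cell, the generating model's parameters are perturbed by
independent mean-one lognormal factors with coefficient of variation 0.15
(default), the observation map is evaluated on a 0–40 min grid at 1-min
spacing, and mean-zero Gaussian readout noise (default sd 0.05) is added;
the default ensemble holds 76 cells. Per-cell perturbation streams are
keyed by (seed, cell index, parameter name), so models sharing parameter
names receive identical cell-level perturbations — this is what makes the
Rap1-reduction oracle exact at the ensemble level. Dose–response datasets
add i.i.d. Gaussian noise of sd 0.1 to the normalized steady-state curve
over 10 log-spaced doses on [0.001, 0.106] nM (log spacing chosen because
the range spans two decades). Preprocessing follows the experimental
pipeline: per-cell min–max normalization, or division by the pooled mean
of cell-wise maxima when relative differences across conditions must be
preserved; cell-wise mean and sample (n−1) sd form the calibration data,
with an sd floor of 1e-6 and an optional halving used for inhibition data.

What the generator does **not** emulate: photobleaching and drift,
non-Gaussian or temporally correlated noise, cell division/movement, and
reporter saturation. Passing tests therefore demonstrate correctness of
the inference machinery under its own assumptions, not robustness to every
artifact of real microscopy data.

## Inference

Priors are lognormal, centered on log-nominal values with log-space sd
2.350, which puts 95% of the mass within a factor 100 of the nominal value
(`lognormal_prior_scale(100, 0.95) = ln 100 / 1.95996`). Sampling is
performed on log-parameters, where the prior is normal. The likelihood is
Gaussian with per-point sds taken from the data (`sigma` column); solver
failures at extreme draws score −∞ rather than aborting a chain.

The tempered SMC sampler raises the likelihood to β ascending 0→1.
Each β increment is chosen by bisection so the effective sample size of
the incremental weights equals 0.85·N (the `threshold` setting); particles
are systematically resampled and mutated by independent
Metropolis–Hastings with a Gaussian proposal moment-matched to the current
cloud. Mutation repeats until the maximum per-dimension correlation
between pre- and post-mutation particles drops below 0.01
(`correlation_threshold`) or a step cap (default 25) is hit; with a few
hundred particles the sample-correlation noise floor usually exceeds 0.01,
so the cap is the effective mutation budget and is the knob desk-scale
runs turn down (typically 3–6). The log marginal likelihood accumulates
`log mean exp(Δβ·loglik)` across stages, one estimate per chain; following
the stated estimation procedure, the per-chain *log* values are averaged
(this is a biased estimator of the log of the mean evidence; the bias is
far smaller than between-model evidence gaps at the scales exercised
here). Defaults are 4 chains × 500 particles; ensembles are exactly
reproducible given seed and settings.

For leave-one-out refits the sampler conditions on the retained points
only (a `sum_mask`) while still recording the held-out point's pointwise
log-likelihood, so the exact LOO predictive density is a free by-product
of each refit. This also keeps the dose–response normalization consistent:
predictions are always normalized over the full dose design, so PSIS-LOO
and refit LOO-CV estimate the same quantity.

## ELPD estimation

`lpd` computes the in-sample log pointwise predictive density (log-mean-exp
over draws). `psis_loo` forms raw importance ratios `exp(−loglik)` per
point, replaces the largest `M = min(0.2·S, 3√S)` ratios by expected order
statistics of a generalized Pareto fitted to the tail exceedances
(empirical-Bayes profile fit with a weak shrinkage prior on the shape),
truncates at the largest smoothed ratio, and reports the fitted shape k̂
per point; k̂ > 0.7 flags unreliable points, and degenerate (constant)
ratio sets skip the fit with k̂ = 0. `brute_force_loo` refits once per
held-out point at a reduced budget (2 chains × 250 by default). The PSIS
implementation is cross-checked in the test suite against the arviz
reference implementation and, in a conjugate normal–normal model, against
the closed-form leave-one-out predictive density.

## Weights and prediction

All weighting methods return machine-normalized simplex vectors. BMA uses
chain-averaged log marginal likelihoods with a uniform model prior and the
log-sum-exp trick. Bayesian-bootstrap pseudo-BMA draws flat Dirichlet
weights over data points (1000 replicates by default) and averages the
per-replicate softmax. Stacking maximizes the concave LOO log score by the
EM-style fixed point `w_k ← mean_i[w_k p_ki / Σ_l w_l p_li]` from the
uniform start (monotone; ties return the symmetric solution) to a 1e-10
relative objective change; the solution is verified against a simplex grid
search in tests.

Mixtures are realized by component resampling (draw a model by weight,
then a posterior row), because all downstream metrics are sample-based.
Error metrics follow the definitions used throughout: RMSE is
`sqrt(Σ r_i²)/N` (note: *not* the conventional `sqrt(mean r²)`; the
conventional form is provided as `rmse_mean_convention` but unused),
relative error is the L2-norm ratio, and predictive uncertainty is the
mean width of the element-wise 2.5–97.5 percentile interval (linear
interpolation between order statistics).

## Sensitivity screening

Classic Morris trajectories over a normalized [0,1]^p grid (4 levels, jump
Δ = levels/(2(levels−1)), 256 trajectories by default) mapped
log-uniformly onto [nominal/100, nominal·100] — log-uniform to match the
lognormal prior geometry. Elementary effects are per-unit-normalized-step
differences; parameters are influential when μ*/max μ* > 0.1 or
σ/max σ > 0.1. The screening QoI is steady-state active ERK for sustained
models and maximal active ERK over 0–120 min for transient ones (a
per-model declaration, not auto-detected), at a fixed 0.1 nM EGF dose.

## Experiment designs

`run_mmi` caches calibrations by (model, data, budget, seed) so model-set
perturbation studies (dropping the best/worst model by ELPD) recompute
only weights, mixtures and metrics — verified by cache-hit accounting.
Data-length studies truncate trajectories at 10/20/30 min and score the
final 10 minutes; data-quality studies average random cell subsets
(default 40 replicates of sizes 10/20/40/60) against the full-ensemble
mean, using one seed for the whole study so identical subsets yield
identical fits. Hypothesis comparison jointly fits multiple conditions
with a summed log-likelihood (independence across conditions assumed),
duplicating the parameters of location-specific groups per location and
zeroing total Rap1 in inhibited conditions; specs are scored by PSIS-LOO
over the pooled pointwise log-likelihoods (concatenated across
conditions).

The synthetic two-location study that exercises this machinery generates
data from RAP1_CASCADE with cytosolic parameters (weak Rap1 drive
k_Raf_Rap1 = 0.001, strong feedback K_fb = 0.15) and membrane parameters
(strong Rap1 drive 0.03, weak feedback 0.6), *with* matched Rap1-inhibition
conditions. The inhibition data are essential: without them, a
location-specific feedback strength alone can mimic sustained membrane
activity and the three hypotheses are statistically indistinguishable;
with them, only the "both differ" hypothesis fits all four conditions.

## Problem sizes and budgets

Test and analysis runs use desk-scale budgets chosen as a deliberate
design point: SMC with 1–2 chains × 80–250 particles and mutation caps of
3–6, datasets of 10–20 points aggregated from 4–10 cells, 3–6 replicate
seeds per study, and 12–64 Morris trajectories. These are config knobs
(`SMCSettings`, generator arguments), and the defaults embedded in the
types (4 × 500 particles, 76 cells, 256 trajectories, 40 replicates)
reflect the full-scale study conditions. At desk scale the qualitative
results are stable across seeds (weight recovery and hypothesis ranking
are decisive, with evidence gaps of tens of log units), but absolute
ELPD/evidence values carry Monte-Carlo error of order one log unit.

## Known limitations

- The three archetypes are reconstructions of the structural motifs of the
  ERK-model literature, not verbatim reproductions of any published model;
  the MMI machinery accepts arbitrary `SignalingModel` objects.
- Averaging per-chain *log* marginal likelihoods is biased low relative to
  log of the averaged evidence (Jensen); kept for fidelity to the stated
  procedure.
- PSIS-LOO becomes unreliable at k̂ > 0.7; no moment-matching correction is
  implemented — affected points are flagged, not repaired.
- Whether the measurement-noise scale should be estimated rather than taken
  from the data's sd column is not addressed; the data sd is used
  throughout.
- The stacking optimizer's EM fixed point converges sublinearly near
  simplex vertices; the tolerance (1e-10 relative) is tight enough that
  dominated models reach weights below 1e-4, but exact zeros are not
  produced.
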
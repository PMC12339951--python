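# bmmi — Bayesian multimodel inference for ERK signaling models

Systems biologists rarely have *one* model of a pathway: for ERK
(extracellular-signal-regulated kinase) signaling alone, dozens of published
ODE models differ in kinetics, feedback structure, and which upstream
branches they include. Calibrating a single model and trusting its
predictions ignores that *model* uncertainty. `bmmi` implements Bayesian
multimodel inference (MMI): calibrate every candidate model to the same
data, score each model's expected predictive performance, and combine the
models' predictive densities into one consensus predictor

```
p(q | d_train) = Σ_k  w_k · p(q | d_train, M_k),     w_k ≥ 0,  Σ_k w_k = 1
```

with weights chosen by one of three principles:

- **BMA** (Bayesian model averaging): `w_k ∝ p(d_train | M_k) · p(M_k)` —
  posterior model probabilities from the marginal likelihood (evidence);
- **pseudo-BMA**: `w_k ∝ exp(ELPD_k)` — a softmax of each model's expected
  log pointwise predictive density, optionally averaged over
  Bayesian-bootstrap reweightings of the data points;
- **stacking**: the simplex weights maximizing the leave-one-out log score
  of the mixture itself.

The building blocks are reusable on any user-supplied ODE model:

| module | what it does |
| --- | --- |
| `bmmi.models` | three archetypal Raf→MEK→ERK cascade models (mass-action / Michaelis–Menten + negative feedback / + Rap1 branch), stiff simulation, event+Newton steady states, dose–response curves, EGF unit conversion |
| `bmmi.synthetic_data` | synthetic single-cell ERK-reporter trajectories and noisy dose–response datasets, plus the preprocessing pipeline (min–max and mean-max normalization, cell averaging, truncation, subsampling) |
| `bmmi.inference` | lognormal priors (sd 2.350 ≡ 95% mass within two decades of nominal), Gaussian likelihood, tempered sequential Monte Carlo with independent-MH mutation, per-chain log marginal likelihood |
| `bmmi.elpd` | ELPD estimators: in-sample LPD, PSIS-LOO (own generalized-Pareto tail smoothing with k̂ diagnostics), exact refit LOO-CV |
| `bmmi.mmi_weights` | BMA / pseudo-BMA / Bayesian-bootstrap pseudo-BMA / stacking weights |
| `bmmi.prediction` | posterior push-forward and posterior predictive ensembles, mixture sampling, RMSE / relative error / 95% credible-interval width |
| `bmmi.sensitivity` | Morris elementary-effects screening with the μ*, σ influence rule |
| `bmmi.experiments` | end-to-end orchestration: full MMI runs with calibration caching, model-set perturbation, data-length and data-quality robustness studies, shared-vs-location-specific parameter hypothesis comparison |

The numbered scripts under `analysis/` walk through the study end to end
(generate data → calibrate → compare ELPD estimators → weight and mix →
sensitivity screening → subcellular hypothesis comparison) and write their
tables under `results/`.

## Worked example

Fit the mass-action cascade to a noisy synthetic EGF–ERK dose-response
curve (10 doses log-spaced over 0.001–0.106 nM, Gaussian noise sd 0.1) and
compare the fast and exact leave-one-out estimators:

```python
import numpy as np
from bmmi.models import build_model
from bmmi.synthetic_data import SyntheticGroundTruth, generate_dose_response_data
from bmmi.inference import SMCSettings, calibrate, average_log_ml
from bmmi.elpd import psis_loo, brute_force_loo

ma = build_model("MA_CASCADE")
truth = SyntheticGroundTruth("MA_CASCADE", ma.params_nominal, noise_sd=0.1, seed=11)
data = generate_dose_response_data(truth)          # 10 points, sigma = 0.1

ens = calibrate(ma, data, SMCSettings(n_chains=2, s_per_chain=250, seed=21))
print(average_log_ml(ens))                         # 6.68
fast  = psis_loo(ens.pointwise_loglik)
exact = brute_force_loo(ma, data)                  # one SMC refit per point
print(fast.total, exact.total)                     # 9.151  9.291
```

The two ELPD estimates agree to 1.5% (every Pareto k̂ ≤ 0.41, so the
importance-sampling shortcut is trustworthy), while the in-sample LPD
(9.98) overestimates both — the reason LOO-based weights are used for
pseudo-BMA and stacking. The log marginal likelihood (6.68, averaged over
chains) is the quantity BMA weights are built from. Positive ELPD values
are expected here: with noise sd 0.1, a well-fit point contributes up to
`-½ln(2π·0.01) ≈ +1.38` to the log score.

Running `python analysis/04_mmi_weights_and_mixture.py` on synthetic
trajectory data generated by the feedback cascade prints weights of
1.000 / 0.000 (feedback vs mass-action model) under all three methods and
a mixture relative error of 0.017 — the mixture inherits the accuracy of
the model the data actually came from.

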
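"""Forward uncertainty propagation and predictive-performance metrics.

Posterior draws are pushed through a model to produce predictive
ensembles: the push-forward of the quantity of interest (active-ERK
trajectories or dose-response curves), the push-forward of the
observables, and the posterior predictive (observables plus measurement
noise).  Weighted model mixtures are realized by component resampling.
Predictive error is scored by the RMSE and the relative (L2) error, and
predictive uncertainty by the average width of the 95% credible interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .inference import PosteriorEnsemble
from .mmi_weights import MMIWeights
from .models import SignalingModel, SolverSettings, dose_response, simulate

__all__ = [
    "PredictiveEnsemble",
    "MixturePrediction",
    "push_forward",
    "mixture_sample",
    "rmse",
    "rmse_mean_convention",
    "relative_error",
    "credible_interval_width",
    "summarize_ensemble",
]

_KINDS = ("push_forward_qoi", "push_forward_obs", "posterior_predictive")


@dataclass
class PredictiveEnsemble:
    """Per-draw model predictions over an evaluation grid (S x T)."""

    qoi_samples: np.ndarray
    design: np.ndarray
    kind: str
    model_name: str = ""
    n_failed: int = 0

    def __post_init__(self):
        self.qoi_samples = np.atleast_2d(
            np.asarray(self.qoi_samples, dtype=float)
        )
        self.design = np.asarray(self.design, dtype=float)
        if self.kind not in _KINDS:
            raise ValueError(f"unknown predictive kind {self.kind!r}")
        if not np.all(np.isfinite(self.qoi_samples)):
            raise ValueError("non-finite predictive samples")

    @property
    def mean(self) -> np.ndarray:
        return self.qoi_samples.mean(axis=0)


@dataclass
class MixturePrediction:
    """Samples from a weighted mixture of model predictive ensembles."""

    samples: np.ndarray  # (n_mix, T)
    component_ids: np.ndarray  # (n_mix,)
    weights_used: MMIWeights
    design: np.ndarray | None = None

    @property
    def mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)


def push_forward(
    ensemble: PosteriorEnsemble,
    model: SignalingModel,
    design: np.ndarray,
    kind: str = "push_forward_qoi",
    data_kind: str = "trajectory",
    egf: float = 0.1,
    sigma: np.ndarray | float | None = None,
    settings: SolverSettings | None = None,
    noise_seed: int = 0,
    max_draws: int | None = None,
) -> PredictiveEnsemble:
    """Propagate posterior parameter draws to model predictions.

    Solves the model once per draw over ``design`` (times in minutes for
    trajectories, doses in nM for dose-response curves) and evaluates the
    QoI / observation map.  ``posterior_predictive`` additionally adds
    independent Gaussian measurement noise with sd ``sigma``.  Draws whose
    solve fails are dropped; more than 10% failures raises.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown predictive kind {kind!r}")
    design = np.asarray(design, dtype=float)
    thetas = ensemble.samples
    if max_draws is not None and thetas.shape[0] > max_draws:
        step = thetas.shape[0] / max_draws
        thetas = thetas[(np.arange(max_draws) * step).astype(int)]
    rows, failed = [], 0
    for theta in thetas:
        try:
            if data_kind == "dose_response":
                rows.append(dose_response(model, theta, design, settings))
            else:
                grid = design if design[0] == 0.0 else np.concatenate(
                    [[0.0], design]
                )
                states = simulate(
                    model, theta, model.initial_state(theta, egf), grid,
                    egf, settings,
                )
                if kind == "push_forward_qoi":
                    vals = np.array(
                        [model.qoi(row, theta) for row in states]
                    )
                else:
                    vals = model.observation(states, theta)
                rows.append(vals[-design.size:])
        except Exception:
            failed += 1
    if failed > 0.1 * thetas.shape[0]:
        raise RuntimeError(
            f"push-forward failed for {failed}/{thetas.shape[0]} draws "
            f"of {model.name}"
        )
    samples = np.vstack(rows)
    if kind == "posterior_predictive":
        if sigma is None:
            raise ValueError("posterior_predictive requires a noise scale")
        rng = np.random.default_rng(noise_seed)
        samples = samples + rng.normal(0.0, 1.0, samples.shape) * np.asarray(
            sigma, dtype=float
        )
    return PredictiveEnsemble(
        qoi_samples=samples,
        design=design,
        kind=kind,
        model_name=model.name,
        n_failed=failed,
    )


def mixture_sample(
    ensembles: list[PredictiveEnsemble],
    weights: MMIWeights,
    n_mix: int = 2000,
    seed: int = 0,
) -> MixturePrediction:
    """Draw from the weighted mixture of model predictive densities.

    Each mixture draw picks a component model with probability equal to
    its weight, then a uniformly random row of that model's ensemble.
    """
    if len(ensembles) != len(weights):
        raise ValueError("one predictive ensemble per weight required")
    design = ensembles[0].design
    for ens in ensembles[1:]:
        if ens.design.shape != design.shape or not np.allclose(
            ens.design, design
        ):
            raise ValueError("ensembles must share the evaluation grid")
    rng = np.random.default_rng(seed)
    comp = rng.choice(len(ensembles), size=n_mix, p=weights.weights)
    samples = np.empty((n_mix, design.size))
    for k, ens in enumerate(ensembles):
        mask = comp == k
        n_k = int(mask.sum())
        if n_k:
            rows = rng.integers(0, ens.qoi_samples.shape[0], size=n_k)
            samples[mask] = ens.qoi_samples[rows]
    return MixturePrediction(
        samples=samples,
        component_ids=comp,
        weights_used=weights,
        design=design,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def rmse(pred_mean: np.ndarray, reference: np.ndarray) -> float:
    """Root-sum-square residual divided by N: ``sqrt(sum r_i^2)/N``.

    This is the definition used throughout the analyses (note it differs
    from the conventional ``sqrt(mean r_i^2)``; see
    :func:`rmse_mean_convention` for that form).
    """
    pred_mean = np.asarray(pred_mean, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pred_mean.shape != reference.shape:
        raise ValueError("prediction and reference lengths differ")
    r = pred_mean - reference
    return float(math.sqrt(float(r @ r)) / r.size)


def rmse_mean_convention(pred_mean, reference) -> float:
    """Conventional RMSE, ``sqrt(mean r_i^2)`` (for comparison only)."""
    pred_mean = np.asarray(pred_mean, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pred_mean.shape != reference.shape:
        raise ValueError("prediction and reference lengths differ")
    return float(np.sqrt(np.mean((pred_mean - reference) ** 2)))


def relative_error(pred: np.ndarray, reference: np.ndarray) -> float:
    """Relative L2 error ``||pred - ref||_2 / ||ref||_2``."""
    pred = np.asarray(pred, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if pred.shape != reference.shape:
        raise ValueError("prediction and reference lengths differ")
    denom = np.linalg.norm(reference)
    if denom == 0:
        raise ValueError("reference has zero norm")
    return float(np.linalg.norm(pred - reference) / denom)


def credible_interval_width(samples: np.ndarray) -> tuple[np.ndarray, float]:
    """95% credible interval (2.5th--97.5th percentiles) and mean width.

    Returns the (2, T) array of element-wise percentiles (linear
    interpolation) and the mean over elements of the interval width.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[0] < 2:
        raise ValueError("need at least 2 samples for an interval")
    interval = np.percentile(samples, [2.5, 97.5], axis=0)
    mean_width = float(np.mean(interval[1] - interval[0]))
    return interval, mean_width


def summarize_ensemble(samples: np.ndarray, reference: np.ndarray) -> dict:
    """Mean prediction, RMSE, relative error and mean 95% CI width."""
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    mean = samples.mean(axis=0)
    interval, width = credible_interval_width(samples)
    return {
        "mean": mean,
        "p2.5": interval[0],
        "p97.5": interval[1],
        "rmse": rmse(mean, reference),
        "relative_error": relative_error(mean, reference),
        "mean_ci_width": width,
    }
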
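"""Model weights for multimodel inference: BMA, pseudo-BMA, stacking.

All methods return a simplex weight vector over the model set:

* BMA -- posterior model probabilities, softmax of chain-averaged log
  marginal likelihoods plus log prior model probabilities (uniform by
  default);
* pseudo-BMA -- softmax of per-model ELPD estimates, optionally averaged
  over Bayesian-bootstrap reweightings of the data points to account for
  uncertainty in the ELPD estimates;
* stacking -- the simplex weights maximizing the leave-one-out log score
  of the weighted mixture of predictive densities, found by a monotone
  EM-style fixed-point iteration on the concave objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MMIWeights",
    "log_sum_exp",
    "bma_weights",
    "pseudo_bma_weights",
    "pseudo_bma_bb_weights",
    "stacking_weights",
]


@dataclass
class MMIWeights:
    """Nonnegative model weights summing to one, with a method tag."""

    weights: np.ndarray
    method: str  # BMA | PSEUDO_BMA | PSEUDO_BMA_BB | STACKING
    model_names: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1 within 1e-12")

    def __len__(self) -> int:
        return self.weights.size

    def as_dict(self) -> dict:
        names = self.model_names or tuple(
            f"model_{i}" for i in range(len(self))
        )
        return dict(zip(names, (float(w) for w in self.weights)))


def log_sum_exp(values) -> float:
    """Overflow-safe ``log(sum(exp(values)))`` via the max-shift trick."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("log_sum_exp of an empty sequence")
    c = x.max()
    if not np.isfinite(c):
        return float(c)
    return float(c + np.log(np.exp(x - c).sum()))


def _softmax(x: np.ndarray) -> np.ndarray:
    w = np.exp(x - log_sum_exp(x))
    return w / w.sum()  # renormalize away rounding


def bma_weights(
    log_ml,
    prior_probs=None,
    model_names: tuple[str, ...] = (),
) -> MMIWeights:
    """Posterior model probabilities from log marginal likelihoods.

    ``w_k`` is proportional to ``exp(log_ml_k) * prior_k``, computed with
    log-sum-exp stabilization; the prior over models defaults to uniform.
    """
    log_ml = np.asarray(log_ml, dtype=float)
    k = log_ml.size
    if prior_probs is None:
        prior_probs = np.full(k, 1.0 / k)
    prior_probs = np.asarray(prior_probs, dtype=float)
    if (
        prior_probs.size != k
        or np.any(prior_probs < 0)
        or abs(prior_probs.sum() - 1.0) > 1e-9
    ):
        raise ValueError("prior_probs must be a probability simplex vector")
    with np.errstate(divide="ignore"):
        x = log_ml + np.log(prior_probs)
    return MMIWeights(_softmax(x), "BMA", model_names)


def pseudo_bma_weights(
    elpd, model_names: tuple[str, ...] = ()
) -> MMIWeights:
    """Softmax of per-model ELPD estimates (shift-invariant, stabilized)."""
    elpd = np.asarray(elpd, dtype=float)
    if not np.all(np.isfinite(elpd)):
        raise ValueError("ELPD values must be finite")
    return MMIWeights(_softmax(elpd), "PSEUDO_BMA", model_names)


def pseudo_bma_bb_weights(
    pointwise_elpd,
    n_boot: int = 1000,
    seed: int = 0,
    model_names: tuple[str, ...] = (),
) -> MMIWeights:
    """Bayesian-bootstrap pseudo-BMA weights from pointwise ELPD values.

    Per replicate, data points are reweighted by a flat Dirichlet draw,
    per-model totals are recomputed as ``N * sum_i alpha_i * elpd_{k,i}``,
    and the softmax over models is taken; the final weights average the
    replicates.  The bootstrap spread is reported in ``diagnostics``.
    """
    pw = np.atleast_2d(np.asarray(pointwise_elpd, dtype=float))
    k, n = pw.shape
    if n < 2:
        raise ValueError("Bayesian bootstrap needs at least 2 data points")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    alphas = rng.dirichlet(np.ones(n), size=n_boot)  # (n_boot, n)
    z = n * alphas @ pw.T  # (n_boot, k)
    shifted = z - z.max(axis=1, keepdims=True)
    w_rep = np.exp(shifted)
    w_rep /= w_rep.sum(axis=1, keepdims=True)
    weights = w_rep.mean(axis=0)
    weights /= weights.sum()
    return MMIWeights(
        weights,
        "PSEUDO_BMA_BB",
        model_names,
        diagnostics={"bootstrap_sd": w_rep.std(axis=0).tolist(),
                     "n_boot": n_boot},
    )


def stacking_weights(
    loo_pointwise_density,
    model_names: tuple[str, ...] = (),
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> MMIWeights:
    """Stacking of predictive densities over the probability simplex.

    Maximizes ``(1/n) sum_i log sum_k w_k p_{k,i}`` where ``p_{k,i}`` is
    model k's leave-one-out predictive density at point i, using the
    EM-style fixed point ``w_k <- (1/n) sum_i w_k p_{k,i} / sum_l w_l
    p_{l,i}`` from the uniform start (which returns the symmetric solution
    on flat objectives).  The achieved objective is reported in
    ``diagnostics``.
    """
    p = np.atleast_2d(np.asarray(loo_pointwise_density, dtype=float))
    k, n = p.shape
    if np.any(~np.isfinite(p)) or np.any(p <= 0):
        raise ValueError("predictive densities must be positive and finite")
    w = np.full(k, 1.0 / k)
    if k == 1:
        return MMIWeights(np.ones(1), "STACKING", model_names,
                          diagnostics={"objective": float(np.log(p).mean())})

    def objective(wv):
        return float(np.log(wv @ p).mean())

    obj = objective(w)
    for _ in range(max_iter):
        mix = w[:, None] * p  # (k, n)
        resp = mix / mix.sum(axis=0, keepdims=True)
        w_new = resp.mean(axis=1)
        w_new /= w_new.sum()
        obj_new = objective(w_new)
        w = w_new
        denom = max(abs(obj), 1e-300)
        if abs(obj_new - obj) <= tol * denom:
            obj = obj_new
            break
        obj = obj_new
    return MMIWeights(w, "STACKING", model_names,
                      diagnostics={"objective": obj})
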
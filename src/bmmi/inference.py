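"""Bayesian calibration of signaling models by tempered sequential Monte Carlo.

Parameters are sampled on the log scale: the prior on each free parameter
is normal in log-space, centered at the log of its nominal value with
standard deviation 2.350, which places 95% of the lognormal prior mass
within a factor of 100 of the nominal value.  The likelihood is the
Gaussian density implied by the measurement-noise model, with per-point
standard deviations taken from the calibration data.

The sampler anneals the likelihood from prior (beta = 0) to posterior
(beta = 1).  Temperature increments are chosen adaptively so that the
effective sample size of the incremental importance weights stays at a
fixed fraction of the particle count (``ess_threshold``); particles are
then systematically resampled and mutated with an independent
Metropolis--Hastings kernel whose Gaussian proposal is moment-matched to
the current particle cloud.  Mutation steps repeat until the correlation
between pre- and post-mutation particles falls below
``correlation_threshold`` (or a step cap is hit).  The log marginal
likelihood accumulates from the incremental weights, one estimate per
independent chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp, ndtri

from .models import SignalingModel, SolverSettings, dose_response, simulate
from .synthetic_data import CalibrationData

__all__ = [
    "PriorSpec",
    "SMCSettings",
    "PosteriorEnsemble",
    "lognormal_prior_scale",
    "log_likelihood",
    "run_smc",
    "average_log_ml",
    "calibrate",
]

DEFAULT_PRIOR_SCALE = 2.350
_LOG_2PI = math.log(2.0 * math.pi)


def lognormal_prior_scale(mass_factor: float, coverage: float) -> float:
    """Prior sd placing ``coverage`` mass within ``mass_factor`` of the median.

    For a lognormal prior centered (in log space) on a nominal value, the
    sd ``s`` such that the stated probability mass lies in
    ``[nominal/mass_factor, nominal*mass_factor]`` is
    ``ln(mass_factor) / z`` with ``z`` the two-sided normal quantile of
    ``coverage``.  ``mass_factor=100, coverage=0.95`` gives 2.350.
    """
    if not 0.0 < coverage < 1.0:
        raise ValueError("coverage must be in (0, 1)")
    if mass_factor < 1.0:
        raise ValueError("mass_factor must be >= 1")
    z = ndtri(0.5 + coverage / 2.0)
    return math.log(mass_factor) / z


@dataclass
class PriorSpec:
    """Independent normal prior on log-parameters (lognormal on parameters).

    ``loc`` is the per-parameter location (log of the nominal value) and
    ``scale`` the common log-space standard deviation.  The same class
    serves as a plain diagonal normal prior on an unconstrained space,
    which is how the conjugate-model cross-checks use it.
    """

    loc: np.ndarray
    scale: float = DEFAULT_PRIOR_SCALE

    def __post_init__(self):
        self.loc = np.atleast_1d(np.asarray(self.loc, dtype=float))
        if self.scale <= 0:
            raise ValueError("prior scale must be positive")

    @property
    def n_dim(self) -> int:
        return self.loc.size

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.loc + self.scale * rng.standard_normal((n, self.n_dim))

    def logpdf(self, z: np.ndarray) -> np.ndarray:
        z = np.atleast_2d(z)
        resid = (z - self.loc) / self.scale
        return -0.5 * (resid**2).sum(axis=1) - self.n_dim * (
            0.5 * _LOG_2PI + math.log(self.scale)
        )


@dataclass
class SMCSettings:
    """Sampler budgets and adaptation thresholds."""

    correlation_threshold: float = 0.01
    ess_threshold: float = 0.85
    n_chains: int = 4
    s_per_chain: int = 500
    max_mh_steps: int = 25
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.correlation_threshold < 1:
            raise ValueError("correlation_threshold must be in (0, 1)")
        if not 0 < self.ess_threshold < 1:
            raise ValueError("ess_threshold must be in (0, 1)")
        if self.n_chains < 1 or self.s_per_chain < 2:
            raise ValueError("need >= 1 chain and >= 2 particles")


@dataclass
class PosteriorEnsemble:
    """Posterior draws with pointwise log-likelihoods and per-chain log ML."""

    samples: np.ndarray  # (S, p)
    pointwise_loglik: np.ndarray  # (S, N_train)
    log_ml_per_chain: np.ndarray  # (n_chains,)
    n_chains: int
    s_per_chain: int
    seed: int
    model_name: str = ""
    free_mask: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]


def average_log_ml(ensemble: PosteriorEnsemble) -> float:
    """Chain-averaged log marginal likelihood estimate (mean of log values)."""
    return float(np.mean(ensemble.log_ml_per_chain))


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _predict(model, theta, data, settings, egf):
    if data.kind == "dose_response":
        return dose_response(model, theta, data.design, settings)
    t = data.design
    if t[0] != 0.0:
        grid = np.concatenate([[0.0], t])
        skip = 1
    else:
        grid, skip = t, 0
    states = simulate(
        model, theta, model.initial_state(theta, egf), grid, egf, settings
    )
    return model.observation(states, theta)[skip:]


def log_likelihood(
    theta: np.ndarray,
    model: SignalingModel,
    data: CalibrationData,
    settings: SolverSettings | None = None,
    egf: float = 0.1,
) -> tuple[float, np.ndarray]:
    """Gaussian log-likelihood: total and per-point contributions.

    ``pointwise[i]`` is the log normal density of ``y_i`` at the model
    prediction with sd ``sigma_i``; the total is their sum (independent
    points).  Solver failures score ``-inf`` rather than raising, since
    stiff failures at extreme prior draws are expected during sampling.
    """
    try:
        pred = _predict(model, np.asarray(theta, dtype=float), data,
                        settings, egf)
    except Exception:
        pw = np.full(data.n_train, -np.inf)
        return -np.inf, pw
    if not np.all(np.isfinite(pred)):
        pw = np.full(data.n_train, -np.inf)
        return -np.inf, pw
    resid = (data.y - pred) / data.sigma
    pw = -0.5 * (_LOG_2PI + resid**2) - np.log(data.sigma)
    return float(pw.sum()), pw


# ---------------------------------------------------------------------------
# Tempered SMC
# ---------------------------------------------------------------------------

def _ess(logw: np.ndarray) -> float:
    logw = logw - logw.max()
    w = np.exp(logw)
    s = w.sum()
    return float(s * s / (w @ w))


def _choose_dbeta(ll: np.ndarray, remaining: float, ess_frac: float,
                  n: int) -> float:
    finite = np.where(np.isfinite(ll), ll, -np.inf)
    target = ess_frac * n
    if _ess(remaining * finite) >= target:
        return remaining
    lo, hi = 0.0, remaining
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if _ess(mid * finite) >= target:
            lo = mid
        else:
            hi = mid
    return max(lo, 1e-12)


def _systematic_resample(weights: np.ndarray, rng) -> np.ndarray:
    n = weights.size
    positions = (rng.random() + np.arange(n)) / n
    return np.searchsorted(np.cumsum(weights), positions).clip(0, n - 1)


def _mutation_correlation(z0: np.ndarray, z: np.ndarray) -> float:
    # max absolute per-dimension correlation between pre- and post-mutation
    # particle coordinates; small when the cloud has been refreshed
    corr = 0.0
    for j in range(z.shape[1]):
        a, b = z0[:, j], z[:, j]
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            continue
        c = abs(float(np.corrcoef(a, b)[0, 1]))
        if np.isfinite(c):
            corr = max(corr, c)
    return corr


def run_smc(
    prior: PriorSpec,
    loglik,
    settings: SMCSettings,
    sum_mask: np.ndarray | None = None,
) -> PosteriorEnsemble:
    """Tempered SMC with adaptive temperature ladder and independent-MH moves.

    ``loglik(z)`` maps a sampling-space vector to the per-data-point
    log-likelihood vector (``-inf`` entries allowed).  Returns pooled
    particles from ``n_chains`` independent chains together with one log
    marginal likelihood estimate per chain.  ``sum_mask`` optionally
    restricts which pointwise entries enter the tempered total (used for
    leave-one-out refits, where the held-out point's log-likelihood is
    tracked but not conditioned on).
    """
    chains, pointwise, log_mls = [], [], []
    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    for chain_seed in seeds:
        z, pw, lml = _run_one_chain(prior, loglik, settings, chain_seed,
                                    sum_mask)
        chains.append(z)
        pointwise.append(pw)
        log_mls.append(lml)
    return PosteriorEnsemble(
        samples=np.vstack(chains),
        pointwise_loglik=np.vstack(pointwise),
        log_ml_per_chain=np.array(log_mls),
        n_chains=settings.n_chains,
        s_per_chain=settings.s_per_chain,
        seed=settings.seed,
    )


def _eval_pointwise(loglik, z_rows):
    rows = [np.atleast_1d(np.asarray(loglik(z), dtype=float)) for z in z_rows]
    return np.vstack(rows)


def _run_one_chain(prior, loglik, settings, chain_seed, sum_mask=None):
    rng = np.random.default_rng(chain_seed)
    n = settings.s_per_chain

    def total(pw_mat):
        if sum_mask is None:
            return pw_mat.sum(axis=1)
        return pw_mat[:, sum_mask].sum(axis=1)

    z = prior.sample(rng, n)
    pw = _eval_pointwise(loglik, z)
    ll = total(pw)
    if not np.any(np.isfinite(ll)):
        raise RuntimeError(
            "SMC initialization failure: all particles have -inf likelihood"
        )
    beta = 0.0
    log_ml = 0.0
    while beta < 1.0:
        dbeta = _choose_dbeta(ll, 1.0 - beta, settings.ess_threshold, n)
        logw = dbeta * np.where(np.isfinite(ll), ll, -np.inf)
        log_ml += float(logsumexp(logw)) - math.log(n)
        w = np.exp(logw - logsumexp(logw))
        idx = _systematic_resample(w, rng)
        z, pw, ll = z[idx], pw[idx], ll[idx]
        beta = min(1.0, beta + dbeta)

        # independent-MH proposal moment-matched to the particle cloud
        mu = z.mean(axis=0)
        cov = np.atleast_2d(np.cov(z.T)) + 1e-10 * np.eye(z.shape[1])
        chol = np.linalg.cholesky(cov)
        z0 = z.copy()
        logq = _mvn_logpdf(z, mu, chol)
        logp = prior.logpdf(z)
        for _ in range(settings.max_mh_steps):
            prop = mu + rng.standard_normal(z.shape) @ chol.T
            pw_prop = _eval_pointwise(loglik, prop)
            ll_prop = total(pw_prop)
            logq_prop = _mvn_logpdf(prop, mu, chol)
            logp_prop = prior.logpdf(prop)
            num = beta * np.where(np.isfinite(ll_prop), ll_prop, -np.inf) \
                + logp_prop - logq_prop
            den = beta * np.where(np.isfinite(ll), ll, -np.inf) \
                + logp - logq
            with np.errstate(invalid="ignore"):
                log_alpha = num - den
            accept = np.log(rng.random(n)) < log_alpha
            z[accept] = prop[accept]
            pw[accept] = pw_prop[accept]
            ll[accept] = ll_prop[accept]
            logq[accept] = logq_prop[accept]
            logp[accept] = logp_prop[accept]
            if _mutation_correlation(z0, z) < settings.correlation_threshold:
                break
    return z, pw, log_ml


def _mvn_logpdf(z, mu, chol):
    u = solve_triangular(chol, (z - mu).T, lower=True)
    maha = (u * u).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (maha + z.shape[1] * _LOG_2PI + logdet)


# ---------------------------------------------------------------------------
# Model calibration front-end
# ---------------------------------------------------------------------------

def calibrate(
    model: SignalingModel,
    data: CalibrationData,
    smc_settings: SMCSettings | None = None,
    solver_settings: SolverSettings | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    egf: float = 0.1,
) -> PosteriorEnsemble:
    """Estimate a model's free parameters from calibration data.

    Sampling happens in log-parameter space under a normal prior centered
    on the log nominal values; the returned ensemble's ``samples`` are
    full parameter vectors on the natural scale (fixed parameters held at
    their nominal values).
    """
    smc_settings = smc_settings or SMCSettings()
    free = np.flatnonzero(model.free_mask)
    prior = PriorSpec(np.log(model.params_nominal[free]), prior_scale)
    base = np.array(model.params_nominal, dtype=float)

    def loglik(z):
        theta = base.copy()
        theta[free] = np.exp(z)
        _, pw = log_likelihood(theta, model, data, solver_settings, egf)
        return pw

    ens = run_smc(prior, loglik, smc_settings)
    theta_samples = np.tile(base, (ens.n_samples, 1))
    theta_samples[:, free] = np.exp(ens.samples)
    ens.samples = theta_samples
    ens.model_name = model.name
    ens.free_mask = np.asarray(model.free_mask, dtype=bool)
    return ens
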
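"""Morris elementary-effects screening of model parameters.

One-at-a-time global sensitivity analysis over wide parameter ranges
(default: four decades centered on the nominal value, sampled
log-uniformly to match the lognormal prior geometry).  Each classic
Morris trajectory perturbs one normalized coordinate at a time by a fixed
grid jump; the resulting elementary effects are summarized per parameter
by mu* (mean absolute effect) and sigma (effect standard deviation,
signaling nonlinearity or interactions).  Parameters are declared
influential when either normalized measure exceeds a 0.1 threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import SignalingModel, SolverSettings, simulate, steady_state

__all__ = [
    "MorrisResult",
    "morris_screen",
    "influential_params",
    "screening_qoi",
    "default_ranges",
]

INFLUENCE_THRESHOLD = 0.1


@dataclass
class MorrisResult:
    """Per-parameter Morris measures and the influence classification."""

    mu_star: np.ndarray
    sigma: np.ndarray
    n_trajectories: int
    levels: int
    ranges: np.ndarray  # (p, 2) lower/upper bounds
    influential: np.ndarray | None = None
    param_names: tuple[str, ...] = ()


def default_ranges(nominal: np.ndarray, span: float = 100.0) -> np.ndarray:
    """[nominal/span, nominal*span] per parameter (four decades by default)."""
    nominal = np.asarray(nominal, dtype=float)
    return np.column_stack([nominal / span, nominal * span])


def _map_from_unit(u: np.ndarray, ranges: np.ndarray, log_scale: bool):
    lo, hi = ranges[:, 0], ranges[:, 1]
    if log_scale:
        return lo * (hi / lo) ** u
    return lo + u * (hi - lo)


def morris_screen(
    objective,
    ranges: np.ndarray,
    n_trajectories: int = 256,
    levels: int = 4,
    seed: int = 0,
    log_scale: bool = True,
    max_failures: float = 0.1,
) -> MorrisResult:
    """Classic Morris trajectory design with elementary-effect summaries.

    ``objective(theta)`` maps a parameter vector to a scalar; coordinates
    are sampled on a ``levels``-point grid in normalized [0, 1] space
    (log-uniform over ``ranges`` when ``log_scale``) and perturbed one at
    a time by the standard jump ``levels / (2*(levels-1))``.  Effects are
    differences per unit normalized step, so they are comparable across
    parameters.  Reproducible under ``seed``.
    """
    ranges = np.atleast_2d(np.asarray(ranges, dtype=float))
    p = ranges.shape[0]
    if levels < 2:
        raise ValueError("levels must be >= 2")
    rng = np.random.default_rng(seed)
    delta = levels / (2.0 * (levels - 1))
    base_grid = np.arange(levels) / (levels - 1)
    effects: list[list[float]] = [[] for _ in range(p)]
    failures = 0
    evals = 0
    for _ in range(n_trajectories):
        # base point restricted so that +delta stays inside [0, 1]
        u = rng.choice(base_grid[base_grid <= 1.0 - delta + 1e-12], size=p)
        signs = np.where(u + delta <= 1.0 + 1e-12, 1.0, -1.0)
        order = rng.permutation(p)

        def _eval(point):
            nonlocal failures, evals
            evals += 1
            try:
                val = float(objective(_map_from_unit(point, ranges,
                                                     log_scale)))
                if not np.isfinite(val):
                    raise FloatingPointError
                return val
            except Exception:
                failures += 1
                return np.nan
        f_prev = _eval(u)
        for j in order:
            u_new = u.copy()
            u_new[j] += signs[j] * delta
            f_new = _eval(u_new)
            if np.isfinite(f_prev) and np.isfinite(f_new):
                effects[j].append((f_new - f_prev) / (signs[j] * delta))
            u, f_prev = u_new, f_new
    if failures > max_failures * max(evals, 1):
        raise RuntimeError(
            f"objective failed at {failures}/{evals} design points"
        )
    mu_star = np.array([
        np.mean(np.abs(e)) if e else 0.0 for e in effects
    ])
    sigma = np.array([
        np.std(e, ddof=1) if len(e) > 1 else 0.0 for e in effects
    ])
    result = MorrisResult(
        mu_star=mu_star,
        sigma=sigma,
        n_trajectories=n_trajectories,
        levels=levels,
        ranges=ranges,
    )
    result.influential = influential_params(result)
    return result


def influential_params(
    result: MorrisResult, threshold: float = INFLUENCE_THRESHOLD
) -> np.ndarray:
    """Influence rule: ``mu*_i/max(mu*) > thr`` OR ``sigma_i/max(sigma) > thr``."""
    mu_max = result.mu_star.max(initial=0.0)
    sg_max = result.sigma.max(initial=0.0)
    if mu_max == 0.0 and sg_max == 0.0:
        raise ValueError("all Morris measures are zero; nothing to classify")
    crit_mu = (
        result.mu_star / mu_max > threshold if mu_max > 0
        else np.zeros_like(result.mu_star, dtype=bool)
    )
    crit_sg = (
        result.sigma / sg_max > threshold if sg_max > 0
        else np.zeros_like(result.sigma, dtype=bool)
    )
    return crit_mu | crit_sg


def screening_qoi(
    model: SignalingModel,
    mode: str = "steady_state_erk",
    egf: float = 0.1,
    settings: SolverSettings | None = None,
    t_max: float = 120.0,
    n_grid: int = 121,
):
    """Scalar screening objective: steady-state or maximal active ERK.

    ``steady_state_erk`` (for models with sustained activation) evaluates
    the active-ERK QoI at the steady state under a fixed EGF dose;
    ``max_erk`` (for transient models) takes the maximum of the simulated
    active-ERK trajectory over 0--``t_max`` minutes.
    """
    if mode not in ("steady_state_erk", "max_erk"):
        raise ValueError(f"unknown screening mode {mode!r}")

    if mode == "steady_state_erk":
        def objective(theta):
            x_star = steady_state(model, theta, egf, settings)
            return model.qoi(x_star, theta)
    else:
        t_grid = np.linspace(0.0, t_max, n_grid)

        def objective(theta):
            states = simulate(
                model, theta, model.initial_state(theta, egf), t_grid,
                egf, settings,
            )
            return max(model.qoi(row, theta) for row in states)

    return objective
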
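"""Archetypal ERK-cascade ODE models and their numerical simulation.

Three archetypes span the structural axes along which published ERK models
differ: mass-action versus Michaelis--Menten kinetics, presence of
ERK-to-Raf negative feedback, and presence of a Rap1 branch that escapes
that feedback.

* ``MA_CASCADE`` -- a three-tier Raf/MEK/ERK cascade with distributive
  dual phosphorylation at the MEK and ERK tiers and elementary mass-action
  rate laws (Huang--Ferrell style).  Ultrasensitive in EGF.
* ``FB_CASCADE`` -- Michaelis--Menten tiers with a divisive
  ``1/(1 + ppERK/K_fb)`` negative-feedback factor on Raf activation,
  producing transient ERK activity at strong feedback.
* ``RAP1_CASCADE`` -- ``FB_CASCADE`` plus an EGFR->C3G->Rap1->Raf branch
  whose Raf activation is *not* modulated by ERK feedback.  Setting the
  total Rap1 concentration to zero removes the branch exactly, which is
  how Rap1-inhibition (+Rap1GAP) conditions are simulated.

All models carry EGF as a state with identically zero time derivative
(a sustained stimulus), use minutes for time and nM for concentrations,
and start from a resting (all-inactive) initial condition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit
from scipy.integrate import odeint

__all__ = [
    "SolverSettings",
    "SignalingModel",
    "IntegrationError",
    "SteadyStateError",
    "DegenerateNormalizationError",
    "build_model",
    "simulate",
    "steady_state",
    "dose_response",
    "convert_egf_units",
    "MODEL_REGISTRY",
    "EGF_MOLECULAR_WEIGHT",
    "CELL_VOLUME_L",
    "AVOGADRO",
]

# EGF molecular weight (g/mol) and the nominal single-cell volume (L) used
# for dose unit conversions.
EGF_MOLECULAR_WEIGHT = 6048.0
CELL_VOLUME_L = 1e-9
AVOGADRO = 6.02214076e23


class IntegrationError(RuntimeError):
    """ODE integration failed (step limit or non-finite state)."""

    def __init__(self, message: str, model_name: str = "", theta=None):
        super().__init__(message)
        self.model_name = model_name
        self.theta = None if theta is None else np.asarray(theta)


class SteadyStateError(RuntimeError):
    """Newton refinement did not converge; carries the last residual."""

    def __init__(self, message: str, residual: float = math.nan):
        super().__init__(message)
        self.residual = residual


class DegenerateNormalizationError(ValueError):
    """Normalization impossible (zero response or constant signal)."""


@dataclass
class SolverSettings:
    """Tolerances and budgets for trajectory and steady-state solves.

    ``abs_tol``/``rel_tol`` control the adaptive stiff integrator;
    ``steady_state_*`` tolerances define the event criterion
    ``||dx/dt||_2 <= atol + rtol*||x||_2`` that terminates the
    integrate-to-steady-state phase, and ``newton_*`` control the Newton
    refinement of the steady state.
    """

    abs_tol: float = 1e-6
    rel_tol: float = 1e-6
    max_steps: int = 6_000_000
    steady_state_abs_tol: float = 1e-5
    steady_state_rel_tol: float = 1e-6
    newton_tol: float = 1e-10
    newton_max_steps: int = 100

    def __post_init__(self):
        for name in (
            "abs_tol",
            "rel_tol",
            "steady_state_abs_tol",
            "steady_state_rel_tol",
            "newton_tol",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_steps <= 0 or self.newton_max_steps <= 0:
            raise ValueError("step limits must be positive")


@dataclass
class SignalingModel:
    """An ODE signaling model: states, rate law, observation and QoI maps.

    ``rhs(x, theta)`` returns dx/dt; ``observation`` maps a state matrix
    (time x states) to the normalized active-ERK readout in [0, 1];
    ``qoi`` maps a single state vector to the active-ERK concentration
    (nM).  ``conserved_totals`` lists index sets over which the rhs sums
    to zero (e.g. an ERK tier {ERK, pERK, ppERK}).
    """

    name: str
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    rhs: Callable[[np.ndarray, np.ndarray], np.ndarray]
    params_nominal: np.ndarray
    free_mask: np.ndarray
    conserved_totals: tuple[tuple[int, ...], ...]
    egf_index: int = 0
    param_groups: dict[str, tuple[str, ...]] = field(default_factory=dict)
    transient: bool = False  # sustained vs transient ERK at nominal theta
    # optional analytic steady-state guess (x for given theta, egf) used to
    # initialize the Newton refinement; must be verified, never trusted
    steady_state_guess: Callable[[np.ndarray, float], np.ndarray] | None = None
    # jit-compiled (x, t, theta) form of the rate law for the integrator
    rhs_ode: Callable | None = None

    def _rhs_fast(self):
        if self.rhs_ode is not None:
            ode = self.rhs_ode
            return lambda x, theta: ode(x, 0.0, theta)
        return self.rhs

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def param_index(self, name: str) -> int:
        return self.param_names.index(name)

    def theta_with(self, theta: np.ndarray, **updates: float) -> np.ndarray:
        out = np.array(theta, dtype=float)
        for key, value in updates.items():
            out[self.param_index(key)] = value
        return out

    def initial_state(self, theta: np.ndarray, egf: float) -> np.ndarray:
        """Resting initial condition: tier totals inactive, EGF at the dose."""
        x0 = np.zeros(self.n_states)
        x0[self.egf_index] = egf
        for pool, total_name in self._pool_totals:
            x0[pool[0]] = theta[self.param_index(total_name)]
        return x0

    # (inactive-state index set, total-parameter name); filled by the builders
    _pool_totals: tuple[tuple[tuple[int, ...], str], ...] = ()

    def observation(self, states: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Normalized active ERK, active / total, per time point."""
        states = np.atleast_2d(states)
        erk_tot = theta[self.param_index("ERK_tot")]
        return states[:, self._pperk_index] / erk_tot

    def qoi(self, x: np.ndarray, theta: np.ndarray) -> float:
        """Active ERK concentration (nM) at a single state."""
        return float(np.asarray(x)[self._pperk_index])

    _pperk_index: int = -1

    def to_metadata(self) -> dict:
        return {
            "name": self.name,
            "state_names": list(self.state_names),
            "param_names": list(self.param_names),
            "params_nominal": [float(v) for v in self.params_nominal],
            "free_mask": [bool(v) for v in self.free_mask],
            "conserved_totals": [list(p) for p in self.conserved_totals],
            "transient": self.transient,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_metadata(), indent=2)


# ---------------------------------------------------------------------------
# Archetype definitions
# ---------------------------------------------------------------------------

# rate laws are jit-compiled with the (x, t, theta) signature the ODE
# integrator wants; the t argument is unused (autonomous systems)

@njit(cache=True)
def _ma_rhs_ode(x, t, theta):
    egf, raf, araf = x[0], x[1], x[2]
    mek, pmek, ppmek = x[3], x[4], x[5]
    erk, perk, pperk = x[6], x[7], x[8]
    k_raf_act, k_raf_deact = theta[0], theta[1]
    k_mek_phos, k_mek_dephos = theta[2], theta[3]
    k_erk_phos, k_erk_dephos = theta[4], theta[5]

    v_raf = k_raf_act * egf * raf - k_raf_deact * araf
    v_m1 = k_mek_phos * araf * mek - k_mek_dephos * pmek
    v_m2 = k_mek_phos * araf * pmek - k_mek_dephos * ppmek
    v_e1 = k_erk_phos * ppmek * erk - k_erk_dephos * perk
    v_e2 = k_erk_phos * ppmek * perk - k_erk_dephos * pperk
    out = np.empty(9)
    out[0] = 0.0
    out[1] = -v_raf
    out[2] = v_raf
    out[3] = -v_m1
    out[4] = v_m1 - v_m2
    out[5] = v_m2
    out[6] = -v_e1
    out[7] = v_e1 - v_e2
    out[8] = v_e2
    return out


@njit(cache=True)
def _fb_rhs_ode(x, t, theta):
    egf, raf, araf, mek, amek = x[0], x[1], x[2], x[3], x[4]
    erk, perk, pperk = x[5], x[6], x[7]
    k_raf_act, km_raf, k_raf_deact, km_raf_deact = (
        theta[0], theta[1], theta[2], theta[3])
    k_mek_act, km_mek, k_mek_deact, km_mek_deact = (
        theta[4], theta[5], theta[6], theta[7])
    k_erk_act, km_erk, k_erk_deact, km_erk_deact = (
        theta[8], theta[9], theta[10], theta[11])
    k_fb = theta[12]

    fb = 1.0 / (1.0 + pperk / k_fb)
    v_raf = (k_raf_act * egf * raf / (km_raf + raf) * fb
             - k_raf_deact * araf / (km_raf_deact + araf))
    v_mek = (k_mek_act * araf * mek / (km_mek + mek)
             - k_mek_deact * amek / (km_mek_deact + amek))
    v_e1 = (k_erk_act * amek * erk / (km_erk + erk)
            - k_erk_deact * perk / (km_erk_deact + perk))
    v_e2 = (k_erk_act * amek * perk / (km_erk + perk)
            - k_erk_deact * pperk / (km_erk_deact + pperk))
    out = np.empty(8)
    out[0] = 0.0
    out[1] = -v_raf
    out[2] = v_raf
    out[3] = -v_mek
    out[4] = v_mek
    out[5] = -v_e1
    out[6] = v_e1 - v_e2
    out[7] = v_e2
    return out


@njit(cache=True)
def _rap1_rhs_ode(x, t, theta):
    egf, raf, araf, mek, amek = x[0], x[1], x[2], x[3], x[4]
    erk, perk, pperk = x[5], x[6], x[7]
    c3g, ac3g, rap1, arap1 = x[8], x[9], x[10], x[11]
    k_raf_act, km_raf, k_raf_deact, km_raf_deact = (
        theta[0], theta[1], theta[2], theta[3])
    k_mek_act, km_mek, k_mek_deact, km_mek_deact = (
        theta[4], theta[5], theta[6], theta[7])
    k_erk_act, km_erk, k_erk_deact, km_erk_deact = (
        theta[8], theta[9], theta[10], theta[11])
    k_fb = theta[12]
    k_c3g_act, k1_c3g_deact = theta[13], theta[14]
    k_rap1_act, k_rap1_deact = theta[15], theta[16]
    k_raf_rap1, km_raf_rap1 = theta[17], theta[18]

    fb = 1.0 / (1.0 + pperk / k_fb)
    # Rap1-mediated Raf activation is not modulated by ERK negative feedback
    v_raf = (k_raf_act * egf * raf / (km_raf + raf) * fb
             + k_raf_rap1 * arap1 * raf / (km_raf_rap1 + raf)
             - k_raf_deact * araf / (km_raf_deact + araf))
    v_mek = (k_mek_act * araf * mek / (km_mek + mek)
             - k_mek_deact * amek / (km_mek_deact + amek))
    v_e1 = (k_erk_act * amek * erk / (km_erk + erk)
            - k_erk_deact * perk / (km_erk_deact + perk))
    v_e2 = (k_erk_act * amek * perk / (km_erk + perk)
            - k_erk_deact * pperk / (km_erk_deact + pperk))
    v_c3g = k_c3g_act * egf * c3g - k1_c3g_deact * ac3g
    v_rap1 = k_rap1_act * ac3g * rap1 - k_rap1_deact * arap1
    out = np.empty(12)
    out[0] = 0.0
    out[1] = -v_raf
    out[2] = v_raf
    out[3] = -v_mek
    out[4] = v_mek
    out[5] = -v_e1
    out[6] = v_e1 - v_e2
    out[7] = v_e2
    out[8] = -v_c3g
    out[9] = v_c3g
    out[10] = -v_rap1
    out[11] = v_rap1
    return out


def _ma_rhs(x, theta):
    return _ma_rhs_ode(np.asarray(x, dtype=float), 0.0,
                       np.asarray(theta, dtype=float))


def _fb_rhs(x, theta):
    return _fb_rhs_ode(np.asarray(x, dtype=float), 0.0,
                       np.asarray(theta, dtype=float))


def _rap1_rhs(x, theta):
    return _rap1_rhs_ode(np.asarray(x, dtype=float), 0.0,
                         np.asarray(theta, dtype=float))


def _ma_steady_state_guess(theta: np.ndarray, egf: float) -> np.ndarray:
    # the mass-action cascade is feedforward, so each tier's steady state
    # is available in closed form given the tier above
    (k_raf_act, k_raf_deact, k_mek_phos, k_mek_dephos,
     k_erk_phos, k_erk_dephos, raf_tot, mek_tot, erk_tot) = theta
    act = k_raf_act * egf
    araf = raf_tot * act / (act + k_raf_deact) if act + k_raf_deact > 0 else 0.0
    r1 = k_mek_phos * araf / k_mek_dephos
    mek = mek_tot / (1.0 + r1 + r1 * r1)
    pmek, ppmek = r1 * mek, r1 * r1 * mek
    r2 = k_erk_phos * ppmek / k_erk_dephos
    erk = erk_tot / (1.0 + r2 + r2 * r2)
    perk, pperk = r2 * erk, r2 * r2 * erk
    return np.array([egf, raf_tot - araf, araf, mek, pmek, ppmek,
                     erk, perk, pperk])


def _build_ma() -> SignalingModel:
    state_names = ("EGF", "Raf", "aRaf", "MEK", "pMEK", "ppMEK",
                   "ERK", "pERK", "ppERK")
    param_names = ("k_Raf_act", "k_Raf_deact", "k_MEK_phos", "k_MEK_dephos",
                   "k_ERK_phos", "k_ERK_dephos",
                   "Raf_tot", "MEK_tot", "ERK_tot")
    nominal = np.array([100.0, 1.0, 0.1, 1.0, 0.1, 1.0, 10.0, 100.0, 100.0])
    free = np.array([True] * 6 + [False] * 3)
    model = SignalingModel(
        name="MA_CASCADE",
        state_names=state_names,
        param_names=param_names,
        rhs=_ma_rhs,
        rhs_ode=_ma_rhs_ode,
        params_nominal=nominal,
        free_mask=free,
        conserved_totals=((1, 2), (3, 4, 5), (6, 7, 8)),
        transient=False,
        steady_state_guess=_ma_steady_state_guess,
    )
    model._pool_totals = (((1, 2), "Raf_tot"), ((3, 4, 5), "MEK_tot"),
                          ((6, 7, 8), "ERK_tot"))
    model._pperk_index = 8
    return model


_FB_PARAMS = ("k_Raf_act", "Km_Raf", "k_Raf_deact", "Km_Raf_deact",
              "k_MEK_act", "Km_MEK", "k_MEK_deact", "Km_MEK_deact",
              "k_ERK_act", "Km_ERK", "k_ERK_deact", "Km_ERK_deact",
              "K_fb", "Raf_tot", "MEK_tot", "ERK_tot")
_FB_NOMINAL = np.array([
    300.0, 50.0, 20.0, 50.0,
    3.0, 50.0, 10.0, 50.0,
    3.0, 50.0, 10.0, 50.0,
    0.3, 100.0, 100.0, 100.0,
])

_SHARED_GROUPS = {
    "negative_feedback": ("K_fb",),
    "raf_deactivation": ("k_Raf_deact", "Km_Raf_deact"),
    "erk_phosphorylation": ("k_ERK_act", "Km_ERK"),
    "erk_dephosphorylation": ("k_ERK_deact", "Km_ERK_deact"),
}


def _build_fb() -> SignalingModel:
    state_names = ("EGF", "Raf", "aRaf", "MEK", "aMEK", "ERK", "pERK", "ppERK")
    free = np.array([True] * 13 + [False] * 3)
    model = SignalingModel(
        name="FB_CASCADE",
        state_names=state_names,
        param_names=_FB_PARAMS,
        rhs=_fb_rhs,
        rhs_ode=_fb_rhs_ode,
        params_nominal=_FB_NOMINAL.copy(),
        free_mask=free,
        conserved_totals=((1, 2), (3, 4), (5, 6, 7)),
        param_groups=dict(_SHARED_GROUPS),
        transient=True,
    )
    model._pool_totals = (((1, 2), "Raf_tot"), ((3, 4), "MEK_tot"),
                          ((5, 6, 7), "ERK_tot"))
    model._pperk_index = 7
    return model


def _build_rap1() -> SignalingModel:
    state_names = ("EGF", "Raf", "aRaf", "MEK", "aMEK", "ERK", "pERK", "ppERK",
                   "C3G", "aC3G", "Rap1", "aRap1")
    param_names = _FB_PARAMS[:13] + (
        "k_C3G_act", "k1_C3G_deact", "k_Rap1_act", "k_Rap1_deact",
        "k_Raf_Rap1", "Km_Raf_Rap1",
        "Raf_tot", "MEK_tot", "ERK_tot", "C3G_tot", "Rap1_tot")
    nominal = np.concatenate([
        _FB_NOMINAL[:13],
        [5.0, 0.5, 0.1, 0.5, 0.01, 25.0],
        [100.0, 100.0, 100.0, 50.0, 50.0],
    ])
    free = np.array([True] * 19 + [False] * 5)
    groups = dict(_SHARED_GROUPS)
    groups["Rap1"] = ("k_C3G_act", "k1_C3G_deact", "k_Rap1_act",
                      "k_Rap1_deact", "k_Raf_Rap1", "Km_Raf_Rap1")
    model = SignalingModel(
        name="RAP1_CASCADE",
        state_names=state_names,
        param_names=param_names,
        rhs=_rap1_rhs,
        rhs_ode=_rap1_rhs_ode,
        params_nominal=nominal,
        free_mask=free,
        conserved_totals=((1, 2), (3, 4), (5, 6, 7), (8, 9), (10, 11)),
        param_groups=groups,
        transient=True,
    )
    model._pool_totals = (((1, 2), "Raf_tot"), ((3, 4), "MEK_tot"),
                          ((5, 6, 7), "ERK_tot"), ((8, 9), "C3G_tot"),
                          ((10, 11), "Rap1_tot"))
    model._pperk_index = 7
    return model


MODEL_REGISTRY: dict[str, Callable[[], SignalingModel]] = {
    "MA_CASCADE": _build_ma,
    "FB_CASCADE": _build_fb,
    "RAP1_CASCADE": _build_rap1,
}


def build_model(archetype: str) -> SignalingModel:
    """Construct a fully parameterized cascade model by archetype name."""
    try:
        builder = MODEL_REGISTRY[archetype]
    except KeyError:
        raise KeyError(
            f"unknown model archetype {archetype!r}; "
            f"known: {sorted(MODEL_REGISTRY)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate(
    model: SignalingModel,
    theta: np.ndarray,
    x0: np.ndarray,
    t_grid: np.ndarray,
    egf: float,
    settings: SolverSettings | None = None,
) -> np.ndarray:
    """Integrate the model over ``t_grid`` (minutes), returning time x states.

    The EGF state is clamped to the dose in the initial condition and has an
    identically zero derivative, so the stimulus is sustained.  Raises
    :class:`IntegrationError` on solver failure or non-finite states.
    """
    settings = settings or SolverSettings()
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D array")
    if t_grid[0] != 0.0 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing and start at 0")
    theta = np.asarray(theta, dtype=float)
    x0 = np.array(x0, dtype=float)
    x0[model.egf_index] = egf
    if t_grid.size == 1:
        return x0[None, :]

    with np.errstate(all="ignore"):
        if model.rhs_ode is not None:
            func, args = model.rhs_ode, (theta,)
        else:
            func, args = (lambda x, t: model.rhs(x, theta)), ()
        states, info = odeint(
            func,
            x0,
            t_grid,
            args=args,
            rtol=settings.rel_tol,
            atol=settings.abs_tol,
            mxstep=int(min(settings.max_steps, 100_000_000)),
            full_output=True,
            printmessg=False,
        )
    if info["message"] != "Integration successful." or not np.all(
        np.isfinite(states)
    ):
        raise IntegrationError(
            f"integration failed for {model.name}: {info['message']}",
            model_name=model.name,
            theta=theta,
        )
    return states


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------

def _reduced_coords(model: SignalingModel, totals: np.ndarray):
    """Independent coordinates after eliminating EGF and one state per pool."""
    dep = [pool[0] for pool in model.conserved_totals]
    indep = np.array(
        [i for i in range(model.n_states)
         if i != model.egf_index and i not in dep]
    )
    pool_rest = [pool[1:] for pool in model.conserved_totals]
    buf = np.empty(model.n_states)

    def reconstruct(x_ind: np.ndarray, egf: float) -> np.ndarray:
        x = buf
        x[model.egf_index] = egf
        x[indep] = x_ind
        for j, rest in enumerate(pool_rest):
            acc = 0.0
            for i in rest:
                acc += x[i]
            x[dep[j]] = totals[j] - acc
        return x

    return indep, reconstruct


def _newton_steady_state(model, theta, egf, x_start, totals, settings):
    """Damped Newton on the conservation-reduced system; returns full state."""
    indep, reconstruct = _reduced_coords(model, totals)
    x_ind = np.asarray(x_start, dtype=float)[indep]
    n = len(indep)

    rhs = model._rhs_fast()

    def f_red(z):
        return rhs(reconstruct(z, egf), theta)[indep]

    fval = f_red(x_ind)
    res = math.sqrt(fval @ fval)
    scale = max(1.0, float(np.abs(x_ind).max(initial=1.0)))
    for _ in range(settings.newton_max_steps):
        xfull = reconstruct(x_ind, egf)
        if res <= settings.newton_tol * (1.0 + math.sqrt(xfull @ xfull)):
            return xfull.copy()
        # forward-difference Jacobian
        jac = np.empty((n, n))
        h = 1e-7 * scale
        for j in range(n):
            zp = x_ind.copy()
            zp[j] += h
            jac[:, j] = (f_red(zp) - fval) / h
        try:
            step = np.linalg.solve(jac, -fval)
        except np.linalg.LinAlgError:
            raise SteadyStateError(
                f"singular Jacobian in Newton refinement for {model.name}",
                residual=res,
            ) from None
        lam = 1.0
        for _ in range(12):
            trial = x_ind + lam * step
            ftrial = f_red(trial)
            rtrial = math.sqrt(ftrial @ ftrial)
            if np.isfinite(rtrial) and rtrial < res:
                x_ind, fval, res = trial, ftrial, rtrial
                break
            lam *= 0.5
        else:
            break  # no descent: give the convergence check one last chance
    xfull = reconstruct(x_ind, egf).copy()
    res = np.linalg.norm(model.rhs(xfull, theta))
    if res <= settings.newton_tol * (1.0 + np.linalg.norm(xfull)):
        return xfull
    raise SteadyStateError(
        f"Newton steady-state refinement failed for {model.name}",
        residual=res,
    )


def steady_state(
    model: SignalingModel,
    theta: np.ndarray,
    egf: float,
    settings: SolverSettings | None = None,
    x0: np.ndarray | None = None,
    t_max: float = 1e5,
    refine: bool = True,
) -> np.ndarray:
    """Steady state via event-terminated integration plus Newton refinement.

    Integrates until ``||dx/dt||_2 <= atol_ss + rtol_ss*||x||_2`` and then
    refines the resulting point with Newton's method on the
    conservation-reduced system, so the returned state satisfies
    ``||f(x*)||_2 <= newton_tol*(1 + ||x*||_2)`` and preserves the tier
    totals exactly.  ``refine=False`` returns the event-phase state without
    Newton refinement.
    """
    settings = settings or SolverSettings()
    theta = np.asarray(theta, dtype=float)
    resting = model.initial_state(theta, egf)
    totals = np.array(
        [resting[list(pool)].sum() for pool in model.conserved_totals]
    )
    if x0 is None:
        x0 = resting
        if model.steady_state_guess is not None and refine:
            # try Newton straight from the analytic guess; fall back to the
            # integrate-then-refine path if it fails the residual check
            try:
                return _newton_steady_state(
                    model, theta, egf,
                    model.steady_state_guess(theta, egf), totals, settings,
                )
            except (SteadyStateError, FloatingPointError, ValueError):
                pass
    else:
        x0 = np.array(x0, dtype=float)
        x0[model.egf_index] = egf

    rhs_fast = model._rhs_fast()

    def criterion(x):
        dx = rhs_fast(x, theta)
        return (
            np.linalg.norm(dx)
            - settings.steady_state_abs_tol
            - settings.steady_state_rel_tol * np.linalg.norm(x)
        )

    x_at_event = x0
    if criterion(x0) > 0:
        # integrate over a log-spaced checkpoint grid and stop at the first
        # point where the derivative-norm event criterion is met
        t_grid = np.concatenate([[0.0], np.geomspace(0.1, t_max, 60)])
        with np.errstate(all="ignore"):
            if model.rhs_ode is not None:
                func, args = model.rhs_ode, (theta,)
            else:
                func, args = (lambda x, t: model.rhs(x, theta)), ()
            states, info = odeint(
                func,
                x0,
                t_grid,
                args=args,
                rtol=settings.rel_tol,
                atol=settings.abs_tol,
                mxstep=int(min(settings.max_steps, 100_000_000)),
                full_output=True,
                printmessg=False,
            )
        if info["message"] != "Integration successful." or not np.all(
            np.isfinite(states)
        ):
            raise IntegrationError(
                f"steady-state integration failed for {model.name}: "
                f"{info['message']}",
                model_name=model.name,
                theta=theta,
            )
        x_at_event = states[-1]
        for row in states[1:]:
            if criterion(row) <= 0:
                x_at_event = row
                break
    if not refine:
        return x_at_event
    return _newton_steady_state(model, theta, egf, x_at_event, totals, settings)


# ---------------------------------------------------------------------------
# Dose response
# ---------------------------------------------------------------------------

def dose_response(
    model: SignalingModel,
    theta: np.ndarray,
    egf_levels: Sequence[float],
    settings: SolverSettings | None = None,
) -> np.ndarray:
    """Normalized steady-state dose-response curve (% maximal ERK activity).

    Each entry is the steady-state active-ERK QoI at that dose divided by
    the maximum over all supplied doses, so the curve peaks at exactly 1.
    Doses are solved in ascending order with Newton continuation from the
    previous dose's steady state, falling back to the full
    event-integration path when the warm start fails.
    """
    settings = settings or SolverSettings()
    doses = np.asarray(egf_levels, dtype=float)
    if doses.size < 2 or np.unique(doses).size < 2:
        raise ValueError("dose_response requires at least 2 distinct doses")
    theta = np.asarray(theta, dtype=float)
    order = np.argsort(doses)
    q = np.empty(doses.size)
    x_prev = None
    totals = None
    use_guess = model.steady_state_guess is not None
    for rank, idx in enumerate(order):
        dose = doses[idx]
        x_star = None
        if use_guess:
            # per-dose analytic initialization beats continuation
            x_star = steady_state(model, theta, dose, settings)
        elif rank > 0:
            # warm start: Newton from the previous dose's steady state
            guess = x_prev.copy()
            guess[model.egf_index] = dose
            try:
                x_star = _newton_steady_state(
                    model, theta, dose, guess, totals, settings
                )
                if np.any(x_star < -1e-6 * (1.0 + np.abs(x_star).max())):
                    x_star = None  # spurious (nonphysical) root
            except SteadyStateError:
                x_star = None
        if x_star is None:
            x_star = steady_state(model, theta, dose, settings, x0=x_prev)
            if totals is None:
                x00 = model.initial_state(theta, dose)
                totals = np.array(
                    [x00[list(p)].sum() for p in model.conserved_totals]
                )
        if totals is None:
            x00 = model.initial_state(theta, dose)
            totals = np.array(
                [x00[list(p)].sum() for p in model.conserved_totals]
            )
        x_prev = x_star
        q[idx] = model.qoi(x_star, theta)
    qmax = q.max()
    if qmax <= 1e-12:
        raise DegenerateNormalizationError(
            f"all steady-state responses are zero for {model.name}"
        )
    return q / qmax


# ---------------------------------------------------------------------------
# Units
# ---------------------------------------------------------------------------

# multiplicative factor taking one unit of each kind to nM
_TO_NM = {
    "nM": 1.0,
    "ng/mL": 1e3 / EGF_MOLECULAR_WEIGHT,
    "pg/mL": 1.0 / EGF_MOLECULAR_WEIGHT,
    "molecules/cell": 1e9 / (AVOGADRO * CELL_VOLUME_L),
}


def convert_egf_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an EGF dose between ng/mL, pg/mL, nM and molecules/cell.

    Uses the EGF molecular weight 6048 g/mol and a 1 nL cell volume.
    """
    for unit in (from_unit, to_unit):
        if unit not in _TO_NM:
            raise ValueError(
                f"unknown EGF unit {unit!r}; known: {sorted(_TO_NM)}"
            )
    return float(value) * _TO_NM[from_unit] / _TO_NM[to_unit]
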
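"""Synthetic calibration data emulating single-cell ERK reporter experiments.

Generates the two dataset families the pipeline consumes:

* a 10-point EGF--ERK dose-response curve (steady-state, doses log-spaced
  over 0.001--0.106 nM) with i.i.d. Gaussian noise of standard deviation
  0.1, and
* ensembles of single-cell ERK activity trajectories (default 76 cells over
  0--40 min) with lognormal cell-to-cell parameter variability and additive
  Gaussian readout noise, standing in for EKAR4 emission-ratio recordings.

Also implements the preprocessing applied to such data before calibration:
per-cell min--max normalization, pooled mean-max normalization across
conditions, cell-wise averaging into a mean +/- sd dataset, truncation in
time, and random subsampling of cells.

All operations are pure and reproducible: one root seed per dataset, with
per-cell, per-parameter streams derived deterministically so that shared
parameters receive identical perturbations across models and conditions.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .models import (
    DegenerateNormalizationError,
    SolverSettings,
    build_model,
    dose_response,
    simulate,
)

__all__ = [
    "CellTrajectories",
    "SyntheticGroundTruth",
    "CalibrationData",
    "DEFAULT_DOSES",
    "DEFAULT_T_GRID",
    "generate_dose_response_data",
    "generate_single_cell_trajectories",
    "normalize_min_max",
    "normalize_mean_max",
    "aggregate_cells",
    "truncate_data",
    "subsample_cells",
]

# study conditions: 10 EGF doses log-spaced over two decades, 0--40 min
# trajectories sampled every minute
DEFAULT_DOSES = np.logspace(np.log10(0.001), np.log10(0.106), 10)
DEFAULT_T_GRID = np.arange(0.0, 41.0)
DEFAULT_N_CELLS = 76
SIGMA_FLOOR = 1e-6


@dataclass(frozen=True)
class CellTrajectories:
    """An ensemble of per-cell reporter trajectories (cells x time)."""

    times: np.ndarray
    ratios: np.ndarray
    condition: str = "EKAR4-only"
    location: str = "CYTO"

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(
            self, "ratios", np.atleast_2d(np.asarray(self.ratios, dtype=float))
        )
        if self.ratios.shape[0] < 1:
            raise ValueError("need at least one cell")
        if self.ratios.shape[1] != self.times.size:
            raise ValueError("ratios and times shapes disagree")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be increasing")
        if not np.all(np.isfinite(self.ratios)):
            raise ValueError("missing/non-finite values in trajectories")

    @property
    def n_cells(self) -> int:
        return self.ratios.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.ratios.T,
            columns=[f"cell_{i}" for i in range(self.n_cells)],
        )
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, condition="EKAR4-only", location="CYTO"):
        df = pd.read_csv(path)
        return cls(
            times=df["time"].to_numpy(),
            ratios=df.drop(columns="time").to_numpy().T,
            condition=condition,
            location=location,
        )


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Provenance of a synthetic dataset: the true data-generating process."""

    generating_model: str
    theta_true: np.ndarray
    cell_cv: float = 0.15
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(
            self, "theta_true", np.asarray(self.theta_true, dtype=float)
        )
        if self.cell_cv < 0 or self.noise_sd < 0:
            raise ValueError("cell_cv and noise_sd must be nonnegative")

    def to_json(self) -> str:
        return json.dumps(
            {
                "generating_model": self.generating_model,
                "theta_true": [float(v) for v in self.theta_true],
                "cell_cv": self.cell_cv,
                "noise_sd": self.noise_sd,
                "seed": self.seed,
            },
            indent=2,
        )


@dataclass(frozen=True)
class CalibrationData:
    """A calibration dataset: design points, observations, noise scales."""

    design: np.ndarray
    y: np.ndarray
    sigma: np.ndarray
    kind: str = "trajectory"  # or "dose_response"

    def __post_init__(self):
        for name in ("design", "y", "sigma"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        if not (self.design.size == self.y.size == self.sigma.size):
            raise ValueError("design, y and sigma must have equal length")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive elementwise")
        if self.kind not in ("trajectory", "dose_response"):
            raise ValueError(f"unknown data kind {self.kind!r}")

    @property
    def n_train(self) -> int:
        return self.y.size

    def drop_point(self, i: int) -> "CalibrationData":
        keep = np.ones(self.n_train, dtype=bool)
        keep[i] = False
        return CalibrationData(
            self.design[keep], self.y[keep], self.sigma[keep], self.kind
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"design": self.design, "y": self.y, "sigma": self.sigma,
             "kind": self.kind}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CalibrationData":
        df = pd.read_csv(path)
        return cls(
            design=df["design"].to_numpy(),
            y=df["y"].to_numpy(),
            sigma=df["sigma"].to_numpy(),
            kind=str(df["kind"].iloc[0]),
        )


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_dose_response_data(
    truth: SyntheticGroundTruth,
    egf_levels: Sequence[float] | None = None,
    seed: int | None = None,
    settings: SolverSettings | None = None,
) -> CalibrationData:
    """Noisy normalized steady-state dose-response data at ``theta_true``.

    ``y`` is the model's normalized curve plus i.i.d. mean-zero Gaussian
    noise of sd ``truth.noise_sd``; ``sigma`` is filled with that sd.
    """
    doses = DEFAULT_DOSES if egf_levels is None else np.asarray(
        egf_levels, dtype=float
    )
    model = build_model(truth.generating_model)
    curve = dose_response(model, truth.theta_true, doses, settings)
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    y = curve + rng.normal(0.0, truth.noise_sd, size=doses.size)
    sigma = np.full(doses.size, max(truth.noise_sd, SIGMA_FLOOR))
    return CalibrationData(design=doses, y=y, sigma=sigma, kind="dose_response")


def _param_factor_rng(root_seed: int, cell: int, param_name: str):
    # stable per-(cell, parameter-name) stream so shared parameters get
    # identical perturbations across models/conditions
    tag = zlib.crc32(param_name.encode())
    return np.random.default_rng([root_seed & 0x7FFFFFFF, cell, tag])


def generate_single_cell_trajectories(
    truth: SyntheticGroundTruth,
    n_cells: int = DEFAULT_N_CELLS,
    t_grid: np.ndarray | None = None,
    egf: float = 0.1,
    condition: str = "EKAR4-only",
    location: str = "CYTO",
    settings: SolverSettings | None = None,
) -> CellTrajectories:
    """Simulate a heterogeneous cell ensemble of ERK activity trajectories.

    Each cell's parameters are ``theta_true`` perturbed by independent
    mean-one lognormal factors with coefficient of variation ``cell_cv``;
    the readout is the model observation plus additive Gaussian noise of sd
    ``noise_sd``.  Condition ``"+Rap1GAP"`` zeroes the total Rap1
    concentration before simulating (Rap1 inhibition).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    t_grid = DEFAULT_T_GRID if t_grid is None else np.asarray(
        t_grid, dtype=float
    )
    model = build_model(truth.generating_model)
    theta = np.array(truth.theta_true, dtype=float)
    if condition == "+Rap1GAP":
        if "Rap1_tot" not in model.param_names:
            raise ValueError(
                f"{model.name} has no Rap1 pool; cannot apply +Rap1GAP"
            )
        theta = model.theta_with(theta, Rap1_tot=0.0)
    sigma_ln = np.sqrt(np.log1p(truth.cell_cv**2))
    ratios = np.empty((n_cells, t_grid.size))
    for cell in range(n_cells):
        factors = np.ones(model.n_params)
        if truth.cell_cv > 0:
            for j, name in enumerate(model.param_names):
                z = _param_factor_rng(truth.seed, cell, name).normal()
                factors[j] = np.exp(sigma_ln * z - 0.5 * sigma_ln**2)
        theta_cell = theta * factors
        try:
            states = simulate(
                model, theta_cell, model.initial_state(theta_cell, egf),
                t_grid, egf, settings,
            )
        except Exception as err:
            raise RuntimeError(
                f"integration failed for cell {cell} "
                f"({model.name}, condition {condition!r})"
            ) from err
        obs = model.observation(states, theta_cell)
        noise_rng = np.random.default_rng(
            [truth.seed & 0x7FFFFFFF, cell, 0xBEEF]
        )
        ratios[cell] = obs + noise_rng.normal(
            0.0, truth.noise_sd, size=t_grid.size
        )
    return CellTrajectories(
        times=t_grid, ratios=ratios, condition=condition, location=location
    )


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def normalize_min_max(cells: CellTrajectories) -> CellTrajectories:
    """Map each cell's trajectory to [0, 1] by its own min and max."""
    lo = cells.ratios.min(axis=1, keepdims=True)
    hi = cells.ratios.max(axis=1, keepdims=True)
    flat = np.isclose(hi, lo).ravel()
    if np.any(flat):
        bad = int(np.flatnonzero(flat)[0])
        raise DegenerateNormalizationError(
            f"cell {bad} has a constant trajectory; min-max undefined"
        )
    return replace(cells, ratios=(cells.ratios - lo) / (hi - lo))


def normalize_mean_max(
    cells_by_condition: Sequence[CellTrajectories],
) -> list[CellTrajectories]:
    """Divide all conditions by the pooled mean of cell-wise maxima.

    The single scalar divisor is the mean, over every cell in every
    supplied condition, of that cell's maximum over time, so relative
    differences between conditions are preserved exactly.
    """
    if len(cells_by_condition) < 1:
        raise ValueError("need at least one condition")
    maxima = np.concatenate(
        [c.ratios.max(axis=1) for c in cells_by_condition]
    )
    divisor = maxima.mean()
    if divisor <= 0:
        raise DegenerateNormalizationError("pooled mean of maxima is zero")
    return [replace(c, ratios=c.ratios / divisor) for c in cells_by_condition]


def aggregate_cells(
    cells: CellTrajectories, sd_halving: bool = False
) -> CalibrationData:
    """Collapse a cell ensemble to mean +/- sd calibration data.

    Uses the sample (n-1) standard deviation; with ``sd_halving`` the sd is
    halved (used for Rap1-inhibition data, whose normalization inflates the
    spread).  Zero sds are floored at 1e-6 to keep the Gaussian likelihood
    proper.
    """
    if cells.n_cells < 2:
        raise ValueError("aggregate_cells needs >= 2 cells")
    y = cells.ratios.mean(axis=0)
    sd = cells.ratios.std(axis=0, ddof=1)
    if sd_halving:
        sd = sd / 2.0
    sd = np.maximum(sd, SIGMA_FLOOR)
    return CalibrationData(
        design=cells.times, y=y, sigma=sd, kind="trajectory"
    )


def truncate_data(data: CalibrationData, t_cut: float) -> CalibrationData:
    """Keep design points with t <= t_cut (training-length truncation)."""
    keep = data.design <= t_cut
    if not np.any(keep):
        raise ValueError(f"no data points at or before t_cut={t_cut}")
    return CalibrationData(
        data.design[keep], data.y[keep], data.sigma[keep], data.kind
    )


def subsample_cells(
    cells: CellTrajectories,
    n_subset: int,
    n_replicates: int = 40,
    seed: int = 0,
) -> list[CellTrajectories]:
    """Draw replicate random cell subsets (without replacement within each)."""
    if n_subset > cells.n_cells:
        raise ValueError("n_subset exceeds the number of cells")
    rng = np.random.default_rng([seed & 0x7FFFFFFF, n_subset])
    out = []
    for _ in range(n_replicates):
        idx = rng.choice(cells.n_cells, size=n_subset, replace=False)
        out.append(replace(cells, ratios=cells.ratios[np.sort(idx)]))
    return out
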
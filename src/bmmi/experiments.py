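"""End-to-end multimodel-inference experiment designs.

Orchestrates the pipeline over a model set and a dataset: per-model SMC
calibration (with caching so perturbation studies never refit unchanged
model/data pairs), marginal-likelihood and PSIS-LOO scoring, weighting by
BMA / pseudo-BMA / stacking, mixture prediction, and error/uncertainty
metrics.  Also implements the robustness designs -- removing the best- or
worst-fit model from the set, truncating training data in time, and
degrading data quality by averaging fewer cells -- and the joint
multi-condition hypothesis comparison in which chosen parameter groups
(e.g. Rap1 or negative-feedback parameters) either share one posterior
across subcellular locations or vary independently between them.
Rap1-inhibited conditions are simulated by zeroing the total Rap1
concentration.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .elpd import ELPDEstimate, psis_loo
from .inference import (
    DEFAULT_PRIOR_SCALE,
    PosteriorEnsemble,
    PriorSpec,
    SMCSettings,
    average_log_ml,
    calibrate,
    log_likelihood,
    run_smc,
)
from .mmi_weights import (
    MMIWeights,
    bma_weights,
    pseudo_bma_bb_weights,
    stacking_weights,
)
from .models import SignalingModel, SolverSettings, build_model
from .prediction import mixture_sample, push_forward, summarize_ensemble
from .synthetic_data import CalibrationData, CellTrajectories, aggregate_cells

__all__ = [
    "ExperimentConfig",
    "CalibrationCache",
    "MMIReport",
    "run_mmi",
    "model_set_combinations",
    "perturb_model_set",
    "data_length_experiment",
    "data_quality_experiment",
    "HypothesisSpec",
    "TrainingCondition",
    "hypothesis_comparison",
]

DEFAULT_METHODS = ("BMA", "PSEUDO_BMA_BB", "STACKING")


@dataclass
class ExperimentConfig:
    """Everything one MMI run needs: models, data, budgets, seed."""

    model_names: tuple[str, ...]
    data: CalibrationData
    seed: int
    reference: np.ndarray | None = None  # ground truth on the eval grid
    eval_design: np.ndarray | None = None
    egf: float = 0.1
    methods: tuple[str, ...] = DEFAULT_METHODS
    smc_settings: SMCSettings | None = None
    solver_settings: SolverSettings | None = None
    prior_scale: float = DEFAULT_PRIOR_SCALE
    n_mix: int = 1000
    max_pf_draws: int = 200
    output_dir: str | Path | None = None
    free_names: tuple[str, ...] | None = None  # optionally restrict free params

    def __post_init__(self):
        if len(self.model_names) < 1:
            raise ValueError("need at least one model")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def resolve_model(self, name: str) -> SignalingModel:
        model = build_model(name)
        if self.free_names is not None:
            mask = np.array(
                [p in self.free_names for p in model.param_names]
            )
            if not mask.any():
                raise ValueError("free_names matched no parameters")
            model.free_mask = mask
        return model


class CalibrationCache:
    """Memoizes posterior ensembles keyed by (model, data, budget, seed)."""

    def __init__(self):
        self._store: dict = {}
        self.hits = 0
        self.misses = 0

    @staticmethod
    def _key(model, data, settings, seed, prior_scale, egf):
        return (
            model.name,
            tuple(np.flatnonzero(model.free_mask)),
            data.kind,
            data.design.tobytes(),
            data.y.tobytes(),
            data.sigma.tobytes(),
            settings.n_chains,
            settings.s_per_chain,
            settings.max_mh_steps,
            seed,
            prior_scale,
            egf,
        )

    def get_or_fit(self, model, data, settings, solver, seed, prior_scale,
                   egf=0.1):
        key = self._key(model, data, settings, seed, prior_scale, egf)
        if key in self._store:
            self.hits += 1
            return self._store[key]
        self.misses += 1
        ens = calibrate(
            model, data, replace(settings, seed=seed), solver, prior_scale,
            egf,
        )
        self._store[key] = ens
        return ens


@dataclass
class MMIReport:
    """Artifacts of one MMI run."""

    model_names: tuple[str, ...]
    ensembles: dict[str, PosteriorEnsemble]
    log_ml: dict[str, float]
    elpd: dict[str, ELPDEstimate]
    weights: dict[str, MMIWeights]
    model_metrics: dict[str, dict]
    mixture_metrics: dict[str, dict]

    def to_tables(self):
        score_df = pd.DataFrame(
            {
                "model": list(self.model_names),
                "log_ml": [self.log_ml[m] for m in self.model_names],
                "elpd_psis_loo": [
                    self.elpd[m].total for m in self.model_names
                ],
            }
        )
        rows = []
        for method, w in self.weights.items():
            for name, weight in w.as_dict().items():
                rows.append({"method": method, "model": name,
                             "weight": weight})
        weight_df = pd.DataFrame(rows)
        metric_rows = []
        for name, metrics in {**self.model_metrics,
                              **self.mixture_metrics}.items():
            metric_rows.append(
                {
                    "predictor": name,
                    "rmse": metrics["rmse"],
                    "relative_error": metrics["relative_error"],
                    "mean_ci_width": metrics["mean_ci_width"],
                }
            )
        return score_df, weight_df, pd.DataFrame(metric_rows)

    def save(self, output_dir):
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        score_df, weight_df, metric_df = self.to_tables()
        score_df.to_csv(out / "model_scores.csv", index=False)
        weight_df.to_csv(out / "weights.csv", index=False)
        metric_df.to_csv(out / "metrics.csv", index=False)
        manifest = {
            "models": list(self.model_names),
            "methods": sorted(self.weights),
            "files": ["model_scores.csv", "weights.csv", "metrics.csv"],
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _compute_weights(methods, names, log_mls, elpds, seed):
    pointwise = np.vstack([elpds[m].pointwise for m in names])
    weights = {}
    for method in methods:
        if method == "BMA":
            weights[method] = bma_weights(
                [log_mls[m] for m in names], model_names=tuple(names)
            )
        elif method == "PSEUDO_BMA_BB":
            weights[method] = pseudo_bma_bb_weights(
                pointwise, seed=seed, model_names=tuple(names)
            )
        elif method == "PSEUDO_BMA":
            from .mmi_weights import pseudo_bma_weights

            weights[method] = pseudo_bma_weights(
                [elpds[m].total for m in names], model_names=tuple(names)
            )
        elif method == "STACKING":
            weights[method] = stacking_weights(
                np.exp(pointwise), model_names=tuple(names)
            )
        else:
            raise ValueError(f"unknown weighting method {method!r}")
    return weights


def run_mmi(
    config: ExperimentConfig, cache: CalibrationCache | None = None
) -> MMIReport:
    """Calibrate every model, score it, weight the set, and mix predictions."""
    cache = cache or CalibrationCache()
    settings = config.smc_settings or SMCSettings()
    names = tuple(config.model_names)
    eval_design = (
        config.data.design if config.eval_design is None
        else np.asarray(config.eval_design, dtype=float)
    )
    reference = (
        config.data.y if config.reference is None
        else np.asarray(config.reference, dtype=float)
    )

    ensembles, log_mls, elpds, pf = {}, {}, {}, {}
    for name in names:
        model = config.resolve_model(name)
        ens = cache.get_or_fit(
            model, config.data, settings, config.solver_settings,
            config.seed, config.prior_scale, config.egf,
        )
        ensembles[name] = ens
        log_mls[name] = average_log_ml(ens)
        elpds[name] = psis_loo(ens.pointwise_loglik)
        pf[name] = push_forward(
            ens, model, eval_design,
            kind="push_forward_obs",
            data_kind=config.data.kind,
            egf=config.egf,
            settings=config.solver_settings,
            max_draws=config.max_pf_draws,
        )

    weights = _compute_weights(config.methods, names, log_mls, elpds,
                               config.seed)
    model_metrics = {
        name: summarize_ensemble(pf[name].qoi_samples, reference)
        for name in names
    }
    mixture_metrics = {}
    for method, w in weights.items():
        mix = mixture_sample(
            [pf[m] for m in names], w, n_mix=config.n_mix, seed=config.seed
        )
        mixture_metrics[f"MMI_{method}"] = summarize_ensemble(
            mix.samples, reference
        )
    report = MMIReport(
        model_names=names,
        ensembles=ensembles,
        log_ml=log_mls,
        elpd=elpds,
        weights=weights,
        model_metrics=model_metrics,
        mixture_metrics=mixture_metrics,
    )
    if config.output_dir is not None:
        report.save(config.output_dir)
    return report


def model_set_combinations(models, size: int) -> list[tuple]:
    """All unordered model subsets of the given size, in deterministic order."""
    models = list(models)
    if not 1 <= size <= len(models):
        raise ValueError("size must be between 1 and the number of models")
    return list(itertools.combinations(models, size))


def perturb_model_set(
    config: ExperimentConfig,
    drop: str = "none",
    cache: CalibrationCache | None = None,
) -> dict:
    """Re-weight after removing the best- or worst-fit model (by ELPD).

    Calibrations are reused from the cache; only the weighting, mixing
    and metrics are recomputed on the perturbed set.
    """
    if drop not in ("best_elpd", "worst_elpd", "none"):
        raise ValueError(f"unknown drop rule {drop!r}")
    cache = cache or CalibrationCache()
    base = run_mmi(config, cache)
    if drop == "none" or len(config.model_names) == 1:
        return {"base": base, "perturbed": base, "dropped": None,
                "cache_hits": cache.hits}
    totals = {m: base.elpd[m].total for m in config.model_names}
    target = (
        max(totals, key=totals.get) if drop == "best_elpd"
        else min(totals, key=totals.get)
    )
    remaining = tuple(m for m in config.model_names if m != target)
    sub_config = replace(config, model_names=remaining, output_dir=None)
    perturbed = run_mmi(sub_config, cache)
    return {
        "base": base,
        "perturbed": perturbed,
        "dropped": target,
        "cache_hits": cache.hits,
    }


def data_length_experiment(
    config: ExperimentConfig,
    cut_points=(10.0, 20.0, 30.0),
    test_window: tuple[float, float] = (30.0, 40.0),
    cache: CalibrationCache | None = None,
) -> dict:
    """Calibrate on time-truncated data; score predictions on a test window.

    For each cut point the models are fit to data with t <= cut, the full
    grid is predicted, and error/uncertainty are evaluated on design
    points with ``test_window[0] < t <= test_window[1]`` (by default the
    final 10 minutes, unseen at every cut).
    """
    from .synthetic_data import truncate_data

    if config.data.kind != "trajectory":
        raise ValueError("data-length experiment needs trajectory data")
    cache = cache or CalibrationCache()
    full_design = config.data.design
    reference = (
        config.data.y if config.reference is None else config.reference
    )
    lo, hi = test_window
    test_mask = (full_design > lo) & (full_design <= hi)
    if not test_mask.any():
        raise ValueError("empty test window")
    results = {}
    for cut in cut_points:
        truncated = truncate_data(config.data, cut)
        sub = replace(
            config, data=truncated, eval_design=full_design,
            reference=reference, output_dir=None,
        )
        report = run_mmi(sub, cache)
        window_scores = {}
        for name, metrics in {**report.model_metrics,
                              **report.mixture_metrics}.items():
            # re-score on the held-out window only
            from .prediction import (
                credible_interval_width,
                relative_error,
            )

            mean = metrics["mean"][test_mask]
            width = float(
                np.mean(metrics["p97.5"][test_mask]
                        - metrics["p2.5"][test_mask])
            )
            window_scores[name] = {
                "relative_error": relative_error(mean, reference[test_mask]),
                "mean_ci_width": width,
            }
        results[cut] = {"report": report, "test_scores": window_scores}
    return results


def data_quality_experiment(
    config: ExperimentConfig,
    cells: CellTrajectories,
    subset_sizes=(10, 20, 40, 60),
    n_replicates: int = 40,
    seed: int = 0,
    cache: CalibrationCache | None = None,
) -> dict:
    """Degrade data quality by averaging fewer cells; score per replicate.

    The reference is the full-ensemble cell-wise mean.  Per subset size
    and replicate, the subset average becomes the training data, models
    are calibrated and mixed, and the error of both the raw subset data
    and the predictions is recorded; replicate means and sds are reported.
    """
    from .prediction import relative_error
    from .synthetic_data import subsample_cells

    cache = cache or CalibrationCache()
    full = aggregate_cells(cells)
    results = {}
    for size in subset_sizes:
        subsets = subsample_cells(cells, size, n_replicates, seed)
        raw_errors, replicate_scores = [], []
        for subset in subsets:
            data = aggregate_cells(subset)
            raw_errors.append(relative_error(data.y, full.y))
            # one seed for the whole study: identical subsets give identical
            # fits (and hit the calibration cache)
            sub = replace(
                config, data=data, eval_design=full.design,
                reference=full.y, output_dir=None,
            )
            report = run_mmi(sub, cache)
            rep = {
                name: {
                    "relative_error": metrics["relative_error"],
                    "mean_ci_width": metrics["mean_ci_width"],
                }
                for name, metrics in {**report.model_metrics,
                                      **report.mixture_metrics}.items()
            }
            replicate_scores.append(rep)
        predictors = replicate_scores[0].keys()
        summary = {
            name: {
                metric: {
                    "mean": float(np.mean(
                        [r[name][metric] for r in replicate_scores]
                    )),
                    "sd": float(np.std(
                        [r[name][metric] for r in replicate_scores]
                    )),
                }
                for metric in ("relative_error", "mean_ci_width")
            }
            for name in predictors
        }
        results[size] = {
            "raw_data_error": {
                "mean": float(np.mean(raw_errors)),
                "sd": float(np.std(raw_errors)),
            },
            "predictors": summary,
            "replicates": replicate_scores,
        }
    return results


# ---------------------------------------------------------------------------
# Shared vs location-specific parameter hypotheses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingCondition:
    """One jointly-fit dataset: location, Rap1-inhibition flag, data, dose."""

    location: str
    data: CalibrationData
    inhibited: bool = False
    egf: float = 0.1


@dataclass(frozen=True)
class HypothesisSpec:
    """Which parameter groups vary independently between locations.

    ``sharing`` maps group names (as declared by the model's
    ``param_groups``) to ``"shared"`` or ``"location_specific"``;
    unlisted groups are shared.  ``free_names`` optionally restricts
    which parameters are estimated at all.
    """

    name: str
    archetype: str
    sharing: tuple[tuple[str, str], ...] = ()
    free_names: tuple[str, ...] | None = None

    def location_specific_params(self, model: SignalingModel) -> set[str]:
        out: set[str] = set()
        for group, mode in self.sharing:
            if group not in model.param_groups:
                raise KeyError(
                    f"model {model.name} has no parameter group {group!r}"
                )
            if mode == "location_specific":
                out.update(model.param_groups[group])
            elif mode != "shared":
                raise ValueError(f"unknown sharing mode {mode!r}")
        return out


def _fit_hypothesis(
    spec: HypothesisSpec,
    conditions: list[TrainingCondition],
    smc_settings: SMCSettings,
    solver_settings,
    prior_scale: float,
):
    model = build_model(spec.archetype)
    if spec.free_names is not None:
        model.free_mask = np.array(
            [p in spec.free_names for p in model.param_names]
        )
    locations = sorted({c.location for c in conditions})
    loc_specific = spec.location_specific_params(model)
    free_idx = np.flatnonzero(model.free_mask)
    entries: list[tuple[int, str | None]] = []
    for i in free_idx:
        name = model.param_names[i]
        if name in loc_specific:
            entries.extend((i, loc) for loc in locations)
        else:
            entries.append((i, None))
    base = np.array(model.params_nominal, dtype=float)
    loc0 = np.array([np.log(base[i]) for i, _ in entries])
    prior = PriorSpec(loc0, prior_scale)

    def theta_for(z, location):
        theta = base.copy()
        for j, (i, loc) in enumerate(entries):
            if loc is None or loc == location:
                theta[i] = np.exp(z[j])
        return theta

    def loglik(z):
        parts = []
        for cond in conditions:
            theta = theta_for(z, cond.location)
            if cond.inhibited:
                theta = model.theta_with(theta, Rap1_tot=0.0)
            _, pw = log_likelihood(
                theta, model, cond.data, solver_settings, cond.egf
            )
            parts.append(pw)
        return np.concatenate(parts)

    ens = run_smc(prior, loglik, smc_settings)
    return model, entries, ens


def hypothesis_comparison(
    specs: list[HypothesisSpec],
    conditions: list[TrainingCondition],
    smc_settings: SMCSettings | None = None,
    solver_settings: SolverSettings | None = None,
    prior_scale: float = DEFAULT_PRIOR_SCALE,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    seed: int = 0,
) -> dict:
    """Jointly fit each sharing hypothesis to all conditions and rank them.

    Each spec is fit once to the pooled conditions (shared groups share
    one posterior, location-specific groups get per-location parameters;
    inhibited conditions zero the total Rap1 concentration).  Specs are
    scored by PSIS-LOO over the pooled pointwise log-likelihoods and
    weighted across specs by every requested method.
    """
    if len(specs) < 1:
        raise ValueError("need at least one hypothesis spec")
    smc_settings = smc_settings or SMCSettings()
    results = {}
    for spec in specs:
        model, entries, ens = _fit_hypothesis(
            spec, conditions, smc_settings, solver_settings, prior_scale
        )
        loo = psis_loo(ens.pointwise_loglik)
        results[spec.name] = {
            "ensemble": ens,
            "elpd": loo,
            "log_ml": average_log_ml(ens),
            "n_parameters": len(entries),
        }
    names = [s.name for s in specs]
    elpds = {n: results[n]["elpd"] for n in names}
    log_mls = {n: results[n]["log_ml"] for n in names}
    weights = _compute_weights(methods, names, log_mls, elpds, seed)
    ranking = sorted(names, key=lambda n: -results[n]["elpd"].total)
    return {"results": results, "weights": weights, "ranking": ranking}
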
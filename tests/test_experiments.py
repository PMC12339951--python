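"""Experiment orchestration: MMI runs, set perturbation, data robustness."""

import numpy as np
import pytest

from bmmi.experiments import (
    CalibrationCache,
    ExperimentConfig,
    HypothesisSpec,
    TrainingCondition,
    data_length_experiment,
    data_quality_experiment,
    hypothesis_comparison,
    model_set_combinations,
    perturb_model_set,
    run_mmi,
)
from bmmi.inference import SMCSettings
from bmmi.synthetic_data import (
    SyntheticGroundTruth,
    aggregate_cells,
    generate_single_cell_trajectories,
)

TINY = SMCSettings(n_chains=1, s_per_chain=100, max_mh_steps=3, seed=0)

FB_FREE = ("k_Raf_act", "k_Raf_deact", "K_fb")
MA_FREE = ("k_Raf_act", "k_Raf_deact", "k_ERK_phos")


@pytest.fixture(scope="module")
def fb_cells(fb_model):
    truth = SyntheticGroundTruth(
        "FB_CASCADE", fb_model.params_nominal, cell_cv=0.1, noise_sd=0.05,
        seed=31,
    )
    return generate_single_cell_trajectories(
        truth, n_cells=12, t_grid=np.linspace(0.0, 40.0, 11)
    )


@pytest.fixture(scope="module")
def fb_data(fb_cells):
    return aggregate_cells(fb_cells)


def _config(data, models=("FB_CASCADE",), seed=3, **kw):
    return ExperimentConfig(
        model_names=tuple(models),
        data=data,
        seed=seed,
        smc_settings=TINY,
        free_names=FB_FREE if set(models) <= {"FB_CASCADE", "RAP1_CASCADE"}
        else None,
        max_pf_draws=60,
        n_mix=400,
        **kw,
    )


class TestModelSetCombinations:
    def test_ten_choose_two_is_45(self):
        subsets = model_set_combinations([f"m{i}" for i in range(10)], 2)
        assert len(subsets) == 45

    def test_full_and_single_sizes(self):
        models = ["a", "b", "c"]
        assert model_set_combinations(models, 3) == [("a", "b", "c")]
        assert len(model_set_combinations(models, 1)) == 3

    def test_deterministic_order(self):
        a = model_set_combinations(["x", "y", "z"], 2)
        assert a == [("x", "y"), ("x", "z"), ("y", "z")]


class TestRunMMI:
    def test_single_model_gets_unit_weight(self, fb_data):
        report = run_mmi(_config(fb_data))
        for w in report.weights.values():
            assert np.allclose(w.weights, [1.0])
        # mixture metrics equal the single model's up to resampling error
        model_rmse = report.model_metrics["FB_CASCADE"]["rmse"]
        for metrics in report.mixture_metrics.values():
            assert metrics["rmse"] == pytest.approx(model_rmse, abs=0.02)

    def test_report_serialization(self, fb_data, tmp_path):
        config = _config(fb_data, output_dir=tmp_path / "out")
        run_mmi(config)
        for fname in ("model_scores.csv", "weights.csv", "metrics.csv",
                      "manifest.json"):
            assert (tmp_path / "out" / fname).exists()


class TestPerturbModelSet:
    @pytest.fixture(scope="class")
    def perturbed(self, fb_data):
        config = ExperimentConfig(
            model_names=("FB_CASCADE", "MA_CASCADE"),
            data=fb_data,
            seed=5,
            smc_settings=TINY,
            methods=("BMA", "PSEUDO_BMA", "PSEUDO_BMA_BB", "STACKING"),
            max_pf_draws=60,
            n_mix=400,
        )
        cache = CalibrationCache()
        out = perturb_model_set(config, drop="worst_elpd", cache=cache)
        return config, cache, out

    def test_cache_prevents_refits(self, perturbed):
        _, cache, out = perturbed
        # the surviving model's calibration must be reused, not recomputed
        assert cache.hits >= 1
        assert cache.misses == 2

    def test_softmax_weights_renormalize_exactly(self, perturbed):
        config, _, out = perturbed
        base, sub = out["base"], out["perturbed"]
        dropped = out["dropped"]
        keep = [m for m in config.model_names if m != dropped]
        for method in ("BMA", "PSEUDO_BMA"):
            wb = base.weights[method].as_dict()
            wp = sub.weights[method].as_dict()
            rest = 1.0 - wb[dropped]
            for m in keep:
                assert wp[m] == pytest.approx(wb[m] / rest, abs=1e-12)

    def test_perturbed_weights_remain_simplex(self, perturbed):
        _, _, out = perturbed
        for w in out["perturbed"].weights.values():
            assert np.all(w.weights >= 0)
            assert abs(w.weights.sum() - 1.0) <= 1e-12

    def test_unknown_rule_rejected(self, fb_data):
        with pytest.raises(ValueError):
            perturb_model_set(_config(fb_data), drop="median_elpd")


class TestDataLength:
    def test_truncation_windows_scored(self, fb_data):
        config = _config(fb_data)
        out = data_length_experiment(
            config, cut_points=(10.0, 40.0), test_window=(30.0, 40.0)
        )
        assert set(out) == {10.0, 40.0}
        for cut in out:
            scores = out[cut]["test_scores"]
            assert "FB_CASCADE" in scores
            for sc in scores.values():
                assert sc["relative_error"] >= 0.0
                assert sc["mean_ci_width"] >= 0.0

    def test_less_data_gives_wider_posteriors(self, fb_data):
        """Test-window predictive uncertainty shrinks with training length."""
        config = _config(fb_data)
        out = data_length_experiment(
            config, cut_points=(10.0, 40.0), test_window=(30.0, 40.0)
        )
        w_short = out[10.0]["test_scores"]["FB_CASCADE"]["mean_ci_width"]
        w_full = out[40.0]["test_scores"]["FB_CASCADE"]["mean_ci_width"]
        assert w_short >= w_full

    def test_dose_response_data_rejected(self, dose_response_data):
        config = ExperimentConfig(
            model_names=("MA_CASCADE",), data=dose_response_data, seed=1,
            smc_settings=TINY,
        )
        with pytest.raises(ValueError, match="trajectory"):
            data_length_experiment(config)


class TestDataQuality:
    def test_full_subset_replicates_are_degenerate(self, fb_cells, fb_data):
        config = _config(fb_data)
        out = data_quality_experiment(
            config, fb_cells, subset_sizes=(12,), n_replicates=2, seed=0
        )
        res = out[12]
        assert res["raw_data_error"]["mean"] == 0.0
        for metric_summary in res["predictors"]["FB_CASCADE"].values():
            assert metric_summary["sd"] == 0.0

    def test_raw_error_decreases_with_subset_size(self, fb_cells, fb_data):
        config = _config(fb_data)
        out = data_quality_experiment(
            config, fb_cells, subset_sizes=(3, 10), n_replicates=3, seed=1
        )
        assert (
            out[10]["raw_data_error"]["mean"]
            <= out[3]["raw_data_error"]["mean"]
        )


class TestHypothesisComparison:
    def test_single_spec_gets_unit_weight(self, rap1_model):
        truth = SyntheticGroundTruth(
            "RAP1_CASCADE", rap1_model.params_nominal, cell_cv=0.0,
            noise_sd=0.1, seed=17,
        )
        t = np.linspace(0.0, 40.0, 9)
        conditions = []
        for location in ("CYTO", "PM"):
            cells = generate_single_cell_trajectories(
                truth, n_cells=4, t_grid=t, location=location
            )
            conditions.append(
                TrainingCondition(location, aggregate_cells(cells))
            )
        spec = HypothesisSpec(
            name="both-shared",
            archetype="RAP1_CASCADE",
            sharing=(("Rap1", "shared"), ("negative_feedback", "shared")),
            free_names=("k_Raf_Rap1", "K_fb"),
        )
        out = hypothesis_comparison(
            [spec], conditions,
            smc_settings=SMCSettings(n_chains=1, s_per_chain=80,
                                     max_mh_steps=3, seed=2),
        )
        for w in out["weights"].values():
            assert np.allclose(w.weights, [1.0])
        assert out["ranking"] == ["both-shared"]
        # shared parameters: one entry per free parameter
        assert out["results"]["both-shared"]["n_parameters"] == 2

    def test_location_specific_duplicates_parameters(self):
        spec = HypothesisSpec(
            name="rap1-diff",
            archetype="RAP1_CASCADE",
            sharing=(("Rap1", "location_specific"),),
            free_names=("k_Raf_Rap1", "K_fb"),
        )
        from bmmi.experiments import _fit_hypothesis
        from bmmi.synthetic_data import CalibrationData

        data = CalibrationData(
            np.array([0.0, 10.0]), np.array([0.0, 0.5]),
            np.array([0.1, 0.1]),
        )
        conditions = [
            TrainingCondition("CYTO", data),
            TrainingCondition("PM", data),
        ]
        _, entries, _ = _fit_hypothesis(
            spec, conditions,
            SMCSettings(n_chains=1, s_per_chain=60, max_mh_steps=2, seed=0),
            None, 2.35,
        )
        # k_Raf_Rap1 duplicated per location, K_fb shared
        assert len(entries) == 3

    def test_unknown_group_rejected(self):
        spec = HypothesisSpec(
            name="bad", archetype="FB_CASCADE",
            sharing=(("mek_axis", "location_specific"),),
        )
        from bmmi.models import build_model

        with pytest.raises(KeyError, match="mek_axis"):
            spec.location_specific_params(build_model("FB_CASCADE"))
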
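"""Synthetic data generation and preprocessing."""

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from bmmi.models import DegenerateNormalizationError, build_model, dose_response
from bmmi.synthetic_data import (
    CalibrationData,
    CellTrajectories,
    SyntheticGroundTruth,
    aggregate_cells,
    generate_dose_response_data,
    generate_single_cell_trajectories,
    normalize_mean_max,
    normalize_min_max,
    subsample_cells,
    truncate_data,
)


@pytest.fixture(scope="module")
def ma_truth(ma_model):
    return SyntheticGroundTruth(
        "MA_CASCADE", ma_model.params_nominal, noise_sd=0.1, seed=5
    )


class TestDoseResponseData:
    def test_noiseless_equals_model_curve(self, ma_model, doses_10):
        truth = SyntheticGroundTruth(
            "MA_CASCADE", ma_model.params_nominal, noise_sd=0.0, seed=1
        )
        data = generate_dose_response_data(truth)
        curve = dose_response(ma_model, ma_model.params_nominal, doses_10)
        assert np.allclose(data.y, curve)

    def test_default_design_is_ten_points_spanning_range(self, ma_truth):
        data = generate_dose_response_data(ma_truth)
        assert data.n_train == 10
        assert data.kind == "dose_response"
        assert data.design[0] == pytest.approx(0.001)
        assert data.design[-1] == pytest.approx(0.106)
        assert np.all(data.sigma == 0.1)

    def test_noise_model_calibrated(self, ma_truth):
        """Replicate generations: empirical sd of y within 5% of 0.1."""
        doses = np.array([0.01, 0.05])
        vals = []
        for rep in range(1000):
            data = generate_dose_response_data(
                ma_truth, egf_levels=doses, seed=rep
            )
            vals.append(data.y[0])
        assert np.std(vals) == pytest.approx(0.1, rel=0.05)


class TestCellTrajectories:
    def test_homogeneous_noiseless_cells_are_identical(self):
        model = build_model("FB_CASCADE")
        truth = SyntheticGroundTruth(
            "FB_CASCADE", model.params_nominal, cell_cv=0.0, noise_sd=0.0,
            seed=2,
        )
        cells = generate_single_cell_trajectories(
            truth, n_cells=3, t_grid=np.linspace(0, 20, 11)
        )
        assert np.allclose(cells.ratios, cells.ratios[0])

    def test_default_ensemble_matches_study_conditions(self):
        model = build_model("FB_CASCADE")
        truth = SyntheticGroundTruth(
            "FB_CASCADE", model.params_nominal, seed=3
        )
        cells = generate_single_cell_trajectories(truth, n_cells=5)
        assert cells.times[0] == 0.0 and cells.times[-1] == 40.0
        # the full study default is 76 cells
        from bmmi.synthetic_data import DEFAULT_N_CELLS

        assert DEFAULT_N_CELLS == 76

    def test_rap1gap_condition_equals_feedback_model(self):
        """+Rap1GAP on the Rap1 cascade reduces to the feedback cascade."""
        rap1 = build_model("RAP1_CASCADE")
        fb = build_model("FB_CASCADE")
        t = np.linspace(0.0, 30.0, 16)
        truth_r = SyntheticGroundTruth(
            "RAP1_CASCADE", rap1.params_nominal, cell_cv=0.1, noise_sd=0.02,
            seed=9,
        )
        truth_f = SyntheticGroundTruth(
            "FB_CASCADE", fb.params_nominal, cell_cv=0.1, noise_sd=0.02,
            seed=9,
        )
        inhibited = generate_single_cell_trajectories(
            truth_r, n_cells=3, t_grid=t, condition="+Rap1GAP"
        )
        control = generate_single_cell_trajectories(
            truth_f, n_cells=3, t_grid=t, condition="EKAR4-only"
        )
        # shared parameters share per-cell perturbation streams by name,
        # so the two ensembles agree up to solver tolerance
        assert np.allclose(inhibited.ratios, control.ratios, atol=1e-5)

    def test_residuals_standardized(self):
        """Generator noise matches the Gaussian likelihood assumption."""
        model = build_model("FB_CASCADE")
        truth = SyntheticGroundTruth(
            "FB_CASCADE", model.params_nominal, cell_cv=0.0, noise_sd=0.05,
            seed=21,
        )
        t = np.linspace(0.0, 40.0, 41)
        cells = generate_single_cell_trajectories(
            truth, n_cells=40, t_grid=t
        )
        noiseless = generate_single_cell_trajectories(
            SyntheticGroundTruth(
                "FB_CASCADE", model.params_nominal, cell_cv=0.0,
                noise_sd=0.0, seed=21,
            ),
            n_cells=1, t_grid=t,
        )
        z = (cells.ratios - noiseless.ratios[0]) / 0.05
        assert abs(z.mean()) < 0.05
        assert z.std() == pytest.approx(1.0, abs=0.05)


class TestNormalization:
    def test_min_max_idempotent_on_unit_range(self):
        row = np.array([[0.0, 0.25, 1.0, 0.5]])
        cells = CellTrajectories(np.arange(4.0), row)
        out = normalize_min_max(cells)
        assert np.allclose(out.ratios, row)

    @given(
        a=st.floats(0.1, 10.0),
        b=st.floats(-5.0, 5.0),
    )
    @hsettings(max_examples=25, deadline=None)
    def test_min_max_affine_invariant(self, a, b):
        rng = np.random.default_rng(0)
        base = rng.uniform(0.0, 2.0, (3, 8))
        cells = CellTrajectories(np.arange(8.0), base)
        scaled = CellTrajectories(np.arange(8.0), a * base + b)
        assert np.allclose(
            normalize_min_max(cells).ratios,
            normalize_min_max(scaled).ratios,
            atol=1e-10,
        )

    def test_min_max_constant_row_rejected(self):
        cells = CellTrajectories(np.arange(3.0), np.ones((1, 3)))
        with pytest.raises(DegenerateNormalizationError, match="cell 0"):
            normalize_min_max(cells)

    def test_mean_max_single_cell_self_normalizes(self):
        cells = CellTrajectories(np.arange(3.0), [[1.0, 4.0, 2.0]])
        (out,) = normalize_mean_max([cells])
        assert out.ratios.max() == pytest.approx(1.0)

    def test_mean_max_pools_across_conditions(self):
        c1 = CellTrajectories(np.arange(2.0), [[1.0, 2.0]])
        c2 = CellTrajectories(np.arange(2.0), [[2.0, 4.0]], "+Rap1GAP")
        out1, out2 = normalize_mean_max([c1, c2])
        # cell-wise maxima are 2 and 4 -> pooled divisor 3
        assert np.allclose(out1.ratios, [[1 / 3, 2 / 3]])
        assert np.allclose(out2.ratios, [[2 / 3, 4 / 3]])
        # between-condition ratios preserved
        assert np.allclose(out2.ratios / out1.ratios, 2.0)

    def test_mean_max_scale_invariant(self):
        c1 = CellTrajectories(np.arange(2.0), [[1.0, 2.0]])
        c2 = CellTrajectories(np.arange(2.0), [[2.0, 4.0]])
        ref = normalize_mean_max([c1, c2])
        scaled = normalize_mean_max(
            [CellTrajectories(np.arange(2.0), 7.0 * c.ratios)
             for c in (c1, c2)]
        )
        for r, s in zip(ref, scaled):
            assert np.allclose(r.ratios, s.ratios)


class TestAggregation:
    def test_two_point_mean_and_sample_sd(self):
        cells = CellTrajectories(np.arange(1.0), [[0.0], [1.0]])
        data = aggregate_cells(cells)
        assert data.y[0] == pytest.approx(0.5)
        assert data.sigma[0] == pytest.approx(np.sqrt(0.5))  # (n-1) sd

    def test_sd_halving_halves_sigma(self):
        rng = np.random.default_rng(1)
        cells = CellTrajectories(np.arange(5.0), rng.uniform(0, 1, (6, 5)))
        full = aggregate_cells(cells)
        halved = aggregate_cells(cells, sd_halving=True)
        assert np.allclose(halved.sigma, full.sigma / 2.0)
        assert np.allclose(halved.y, full.y)

    def test_identical_cells_hit_sigma_floor(self):
        cells = CellTrajectories(np.arange(3.0), np.tile([0.2, 0.4, 0.6],
                                                         (3, 1)))
        data = aggregate_cells(cells)
        assert np.all(data.sigma == 1e-6)
        assert np.allclose(data.y, [0.2, 0.4, 0.6])

    def test_single_cell_rejected(self):
        cells = CellTrajectories(np.arange(2.0), [[0.1, 0.2]])
        with pytest.raises(ValueError, match=">= 2 cells"):
            aggregate_cells(cells)


class TestTruncateAndSubsample:
    def test_truncation_counts_and_identity(self):
        data = CalibrationData(np.arange(0.0, 41.0), np.zeros(41) + 0.5,
                               np.ones(41))
        assert truncate_data(data, 10.0).n_train == 11
        assert truncate_data(data, 100.0).n_train == 41
        with pytest.raises(ValueError):
            truncate_data(data, -1.0)

    def test_subsample_determinism_and_bounds(self):
        rng = np.random.default_rng(0)
        cells = CellTrajectories(np.arange(4.0), rng.uniform(0, 1, (20, 4)))
        a = subsample_cells(cells, 5, n_replicates=3, seed=42)
        b = subsample_cells(cells, 5, n_replicates=3, seed=42)
        c = subsample_cells(cells, 5, n_replicates=3, seed=43)
        for x, y in zip(a, b):
            assert np.array_equal(x.ratios, y.ratios)
        assert any(
            not np.array_equal(x.ratios, y.ratios) for x, y in zip(a, c)
        )
        full = subsample_cells(cells, 20, n_replicates=2, seed=0)
        for rep in full:
            assert np.array_equal(rep.ratios, cells.ratios)
        with pytest.raises(ValueError):
            subsample_cells(cells, 21)

    def test_csv_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        cells = CellTrajectories(np.arange(3.0), rng.uniform(0, 1, (4, 3)))
        path = tmp_path / "cells.csv"
        cells.to_csv(path)
        loaded = CellTrajectories.from_csv(path)
        assert np.allclose(loaded.ratios, cells.ratios)
        data = aggregate_cells(cells)
        dpath = tmp_path / "data.csv"
        data.to_csv(dpath)
        loaded_d = CalibrationData.from_csv(dpath)
        assert np.allclose(loaded_d.y, data.y)
        assert loaded_d.kind == data.kind
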
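"""Generate the synthetic calibration datasets used by the later steps.

Produces (under results/data/):
* ``dose_response.csv`` -- the 10-point EGF--ERK steady-state curve from
  the mass-action cascade, doses log-spaced over 0.001--0.106 nM, with
  Gaussian noise of sd 0.1;
* ``cells_cyto.csv`` -- 76 synthetic single-cell ERK activity trajectories
  (0--40 min, 1-min sampling) from the feedback cascade with lognormal
  cell-to-cell parameter variability (CV 0.15) and readout noise 0.05;
* ``trajectory_mean.csv`` -- the cell-averaged mean +/- sd training data.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from bmmi.models import build_model
from bmmi.synthetic_data import (
    SyntheticGroundTruth,
    aggregate_cells,
    generate_dose_response_data,
    generate_single_cell_trajectories,
)

SEED = 11
OUT = ROOT / "results" / "data"


def main():
    OUT.mkdir(parents=True, exist_ok=True)

    ma = build_model("MA_CASCADE")
    dr_truth = SyntheticGroundTruth(
        "MA_CASCADE", ma.params_nominal, noise_sd=0.1, seed=SEED
    )
    dose_data = generate_dose_response_data(dr_truth)
    dose_data.to_csv(OUT / "dose_response.csv")
    (OUT / "dose_response_truth.json").write_text(dr_truth.to_json())
    print(f"dose-response: {dose_data.n_train} points, "
          f"doses {dose_data.design[0]:.3f}-{dose_data.design[-1]:.3f} nM, "
          f"noise sd {dose_data.sigma[0]:.2f}")

    fb = build_model("FB_CASCADE")
    cell_truth = SyntheticGroundTruth(
        "FB_CASCADE", fb.params_nominal, cell_cv=0.15, noise_sd=0.05,
        seed=SEED,
    )
    cells = generate_single_cell_trajectories(cell_truth, n_cells=76)
    cells.to_csv(OUT / "cells_cyto.csv")
    (OUT / "cells_cyto_truth.json").write_text(cell_truth.to_json())
    mean_data = aggregate_cells(cells)
    mean_data.to_csv(OUT / "trajectory_mean.csv")
    peak = cells.ratios.max(axis=1)
    print(f"cells: {cells.n_cells} trajectories over "
          f"{cells.times[0]:.0f}-{cells.times[-1]:.0f} min; "
          f"peak activity {peak.mean():.2f} +/- {peak.std():.2f}")
    print(f"wrote {sorted(p.name for p in OUT.iterdir())}")


if __name__ == "__main__":
    main()
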
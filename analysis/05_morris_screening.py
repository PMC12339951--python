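"""Morris elementary-effects screening of the cascade parameters.

Screens every model parameter over [nominal/100, nominal*100]
(log-uniform) with the steady-state active-ERK QoI for the sustained
mass-action cascade and the maximal active-ERK QoI for the transient
feedback cascade, at a fixed 0.1 nM EGF stimulus.  Parameters with
mu*/max(mu*) > 0.1 or sigma/max(sigma) > 0.1 are declared influential.
Writes one CSV per model under ``results/``.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from bmmi.models import build_model
from bmmi.sensitivity import (
    default_ranges,
    influential_params,
    morris_screen,
    screening_qoi,
)

SEED = 44
N_TRAJECTORIES = 64  # desk scale; the method default is 256


def main():
    for name in ("MA_CASCADE", "FB_CASCADE"):
        model = build_model(name)
        mode = "max_erk" if model.transient else "steady_state_erk"
        objective = screening_qoi(model, mode, egf=0.1)
        result = morris_screen(
            objective, default_ranges(model.params_nominal),
            n_trajectories=N_TRAJECTORIES, seed=SEED,
        )
        infl = influential_params(result)
        df = pd.DataFrame({
            "parameter": model.param_names,
            "mu_star": result.mu_star,
            "sigma": result.sigma,
            "influential": infl,
        }).sort_values("mu_star", ascending=False)
        out = ROOT / "results" / f"morris_{name.lower()}.csv"
        df.to_csv(out, index=False)
        print(f"{name} ({mode}), {N_TRAJECTORIES} trajectories:")
        print(df.to_string(index=False, float_format=lambda v: f"{v:.2f}"))
        print(f"{infl.sum()}/{infl.size} parameters influential -> "
              f"{out.name}\n")


if __name__ == "__main__":
    main()
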
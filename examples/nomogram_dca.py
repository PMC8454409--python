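"""Nomograms, concordance, calibration, and decision-curve analysis.

Compares a clinical-factors nomogram (gender/smoking/drinking — unrelated to
outcome in the simulation) against one combining T stage with a planted
continuous risk score, on simulated survival.
"""

import warnings

warnings.filterwarnings("ignore")

import numpy as np
import pandas as pd

from perirad import simulate_survival
from perirad.nomogram import (
    bootstrap_cindex, build_nomogram, c_index, calibration_curve, decision_curve,
)

rng = np.random.default_rng(5)
n = 300
design = pd.DataFrame({
    "t_stage_ord": rng.integers(1, 5, n).astype(float),
    "rrs": rng.normal(size=n),
    "female": rng.integers(0, 2, n).astype(float),
    "current_smoker": rng.integers(0, 2, n).astype(float),
    "heavy_drinker": rng.integers(0, 2, n).astype(float),
})
t, e = simulate_survival(0.8 * design["rrs"], baseline_scale=6, censor_rate=0.4, seed=6)

for tag, cols in (("clinical", ["female", "current_smoker", "heavy_drinker"]),
                  ("T-stage + RRS", ["t_stage_ord", "rrs"])):
    nom = build_nomogram(design[cols], t, e, horizons=(2.0,), tag=tag)
    boot = bootstrap_cindex(design[cols], t, e, n_bootstrap=200, seed=1)
    print(f"{tag:<14} C = {boot.c:.2f} (95% CI {boot.ci_low:.2f}-{boot.ci_high:.2f}); "
          f"max points per covariate: "
          + ", ".join(f"{c}={p:.0f}" for c, p in nom.max_points().items()))

nom = build_nomogram(design[["t_stage_ord", "rrs"]], t, e, horizons=(2.0,))
pred = nom.predict_survival(design, 2.0)
cal = calibration_curve(pred, t, e, 2.0, n_bins=3)
print("\ncalibration at 2 years (predicted vs KM-observed survival per tertile):")
print(cal[["n", "predicted", "observed", "se"]].round(3).to_string())

dca = decision_curve(1.0 - pred, t, e, 2.0, p_t_grid=[0.1, 0.2, 0.3, 0.4])
print("\nnet benefit of treating above each threshold probability:")
print(dca.table.round(3).to_string())
print("\nThe RRS nomogram's higher C and positive net benefit over treat-all/none")
print("show the planted prognostic signal; the clinical covariates carry none.")
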
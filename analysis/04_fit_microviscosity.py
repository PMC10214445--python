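"""Recovering adhesion energy and membrane microviscosity from wrap times.

Generates wrap-time-vs-tension datasets from the analytical theory at the
lab-scale operating point (W = 0.76 uJ/m^2, eta_eff = 0.8 Pa s, kappa =
20 kBT) with 5% multiplicative lognormal noise, eight tensions per
dataset, and fits (W, eta_eff) back by log-space least squares over 20
seeds.

Finding: both parameters are recovered with median errors well below
10%, so wrap-time curves measured against tension suffice to infer the
membrane microviscosity, which is not directly measurable.

Writes results/wraptime_fit_recovery.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from vesiwrap import theory
from vesiwrap.synth import synth_wraptime_dataset
from vesiwrap.units import KBT_REF

OUT = Path(__file__).resolve().parents[1] / "results"
W_TRUE = 0.76e-6
ETA_TRUE = 0.8
KAPPA = 20.0 * KBT_REF


def main(seed: int = 1) -> pd.DataFrame:
    geo = theory.DumbbellGeometry.catenoid_neck(0.98e-6)
    sigma_grid = np.linspace(2e-9, 22e-9, 8)
    rows = []
    for k in range(20):
        df = synth_wraptime_dataset(W_TRUE, ETA_TRUE, sigma_grid, cv=0.05,
                                    seed=seed * 1000 + k, geometry=geo,
                                    kappa=KAPPA)
        fit = theory.fit_wrap_time(df["sigma"], df["time"], geo, kappa=KAPPA)
        rows.append({"seed": seed * 1000 + k, "W_hat": fit.W,
                     "eta_hat": fit.eta_eff,
                     "W_rel_err": abs(fit.W / W_TRUE - 1),
                     "eta_rel_err": abs(fit.eta_eff / ETA_TRUE - 1)})
    out = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    out.to_csv(OUT / "wraptime_fit_recovery.csv", index=False)
    print(out[["W_rel_err", "eta_rel_err"]].describe().loc[["50%", "max"]])
    print(f"\nmedian W_hat = {out.W_hat.median()*1e6:.3f} uJ/m^2 "
          f"(true {W_TRUE*1e6}), median eta_hat = "
          f"{out.eta_hat.median():.3f} Pa s (true {ETA_TRUE})")
    return out


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
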
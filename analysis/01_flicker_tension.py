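"""Flicker-spectroscopy calibration on synthetic vesicle contours.

Generates equatorial contour series for a 3x3 grid of known tensions and
rigidities (around the lab-scale working point sigma = 100 nN/m,
kappa = 20 kBT, R = 10 um), fits each with the maximum-likelihood
spectrum estimator, and tabulates the recovery errors.

Finding: with 2000 frames the tension is recovered to a few percent and
the rigidity to better than 10% across the grid, well inside the 10%/20%
working tolerances of the downstream analyses.

Writes results/flicker_recovery.csv.
"""

import sys
from pathlib import Path

import pandas as pd

from vesiwrap.flicker import fit_fluctuation_spectrum
from vesiwrap.synth import synth_contours
from vesiwrap.units import KBT_REF

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1) -> pd.DataFrame:
    R = 10e-6
    rows = []
    for i, sigma in enumerate((30e-9, 100e-9, 300e-9)):
        for j, kappa_kbt in enumerate((10.0, 20.0, 40.0)):
            kappa = kappa_kbt * KBT_REF
            series = synth_contours(sigma, kappa, R, 2000,
                                    seed=seed + 10 * i + j)
            est = fit_fluctuation_spectrum(series, R=R)
            rows.append({
                "sigma_true": sigma, "kappa_true_kbt": kappa_kbt,
                "sigma_hat": est.sigma, "kappa_hat_kbt": est.kappa_kbt,
                "sigma_rel_err": est.sigma / sigma - 1,
                "kappa_rel_err": est.kappa / kappa - 1,
                "converged": est.converged,
            })
    df = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    df.to_csv(OUT / "flicker_recovery.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nmax |sigma error| = {df.sigma_rel_err.abs().max():.3f}, "
          f"max |kappa error| = {df.kappa_rel_err.abs().max():.3f}")
    return df


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
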
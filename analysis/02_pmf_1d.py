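"""1D umbrella-sampling recovery of a double-well free-energy profile.

Samples the stock 3 kcal/mol double well with 24 harmonically biased
Brownian-dynamics windows (force constant 4000 kJ/mol/nm^2), solves WHAM,
and compares the recovered profile and barrier against the analytic
truth.  Also computes the first-40%/last-40%/100% convergence band.
Writes results/pmf_1d.csv, results/pmf_1d_report.csv and
results/pmf_1d_band.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from altaccess.fes import basin_barrier_report, convergence_band, pmf_to_csv, wham
from altaccess.protocols import CANONICAL_1D_GRID, canonical_1d_campaign
from altaccess.surfaces import analytic_pmf_1d

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 5) -> None:
    OUT.mkdir(exist_ok=True)
    surface, windows = canonical_1d_campaign(seed=seed)
    grid = wham(windows, bins=CANONICAL_1D_GRID)
    pmf_to_csv(grid, OUT / "pmf_1d.csv")

    truth = analytic_pmf_1d(surface, grid.centres[0][grid.defined])
    diff = grid.values[grid.defined] - truth
    diff -= diff.mean()
    rmsd = float(np.sqrt((diff**2).mean()))

    report = basin_barrier_report(grid, min_prominence=0.5)
    report["minima"].to_csv(OUT / "pmf_1d_report.csv", index=False)
    barrier = report["barriers"]["barrier_from_left"].iloc[0]

    band = convergence_band(windows, bins=CANONICAL_1D_GRID)
    pd.DataFrame({"cv_nm": band.centres, "lower": band.lower,
                  "upper": band.upper}).to_csv(OUT / "pmf_1d_band.csv", index=False)
    median_width = float(np.median(band.widths[np.isfinite(band.widths)]))

    print(f"PMF RMSD vs analytic truth: {rmsd:.3f} kcal/mol (planted barrier 3.0)")
    print(f"recovered barrier: {barrier:.2f} kcal/mol")
    print(f"median convergence-band width: {median_width:.3f} kcal/mol")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=5)
    main(**vars(parser.parse_args()))
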
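"""Constant-pH titration analysis on synthetic protonation traces.

Generates triplicate two-state Markov traces across a pH 0-7 ladder for
two planted pKa values (an apo-like and a substrate-shifted condition),
fits titration curves per replicate, reports mean +/- SD, chunk-estimate
histograms, and the free-energy equivalent of the planted pKa shift.
Writes results/titration.csv and results/titration_chunks.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from altaccess.synth import make_titration_data
from altaccess.titration import (chunked_pka, deprotonated_fractions,
                                 fit_titration, pka_shift_to_ddg,
                                 replicate_stats)

OUT = Path(__file__).resolve().parent.parent / "results"


def main(seed: int = 0) -> None:
    OUT.mkdir(exist_ok=True)
    conditions = {"apo": 3.4, "holo": 4.0}  # planted ~0.6 log-unit shift
    rows, chunk_rows = [], []
    means = {}
    for i, (label, pka_true) in enumerate(conditions.items()):
        fits = []
        for rep in range(3):
            series = make_titration_data(
                pka_true, n_frames=100_000, correlation_time=10.0,
                seed=seed + 10 * i + rep,
            )
            fits.append(fit_titration(deprotonated_fractions(series)))
            estimates, (counts, edges), skipped = chunked_pka(series, chunk_ns=1000.0)
            for est in estimates:
                chunk_rows.append({"condition": label, "replicate": rep,
                                   "chunk_start_ns": est.chunk_start_ns,
                                   "pka": est.pka})
        mean, sd = replicate_stats(fits)
        means[label] = mean
        rows.append({"condition": label, "pka_true": pka_true,
                     "pka_mean": mean, "pka_sd": sd})
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "titration.csv", index=False)
    pd.DataFrame(chunk_rows).to_csv(OUT / "titration_chunks.csv", index=False)
    shift = means["holo"] - means["apo"]
    print(table.to_string(index=False))
    print(f"estimated pKa shift: {shift:+.3f} log units (planted +0.6)")
    print(f"free-energy equivalent: {pka_shift_to_ddg(shift):+.3f} kcal/mol "
          "(negative = protonation more favourable with substrate)")


if __name__ == "__main__":
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    main(**vars(parser.parse_args()))
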
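#!/usr/bin/env python
"""Rate- and burial-based contact prediction on the synthetic dataset.

Measures the precision of every covariation metric and of the evolutionary
rate predictors (smallest mean rate, smallest rate difference) at the
top-L/5 selection size, against the 95% bootstrap band of random selection,
then compares the volume-weighted solvent accessibility of each metric's
selected pairs with the remaining pairs (Mann-Whitney, BH-corrected).

With burial coupled to low rate, the smallest-mean-rate predictor is the
one that clears the random band decisively — the mechanism is
low rate -> core -> contacts, not observed compensatory change.
"""

import importlib.util
from pathlib import Path

import numpy as np

from coevotrace.pipeline import run_dataset_analysis
from coevotrace.simulate import simulate_dataset

HERE = Path(__file__).resolve().parent
OUT = HERE.parent / "results"

spec = importlib.util.spec_from_file_location("sim02", HERE / "02_simulate_dataset.py")
sim02 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(sim02)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    bundle = simulate_dataset(sim02.CONFIG)
    rates = {c: r for c, r in bundle.truth.site_rates.items() if not np.isnan(r)}
    report = run_dataset_analysis(
        bundle.alignment,
        bundle.tree,
        context=bundle.context,
        contacts=bundle.truth.contacts,
        site_rates=rates,
        n_boot=1000,
        seed=sim02.CONFIG.seed,
    )
    report.precision.to_csv(OUT / "precision_vs_random.tsv", sep="\t", index=False)
    report.accessibility_comparisons.to_csv(
        OUT / "accessibility_comparisons.tsv", sep="\t", index=False
    )
    print("precision at k = L/5 against the 95% random band:")
    print(report.precision.to_string(index=False))
    print("\nvolume-weighted accessibility, selected vs rest (BH-corrected):")
    print(report.accessibility_comparisons.to_string(index=False))


if __name__ == "__main__":
    main()
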
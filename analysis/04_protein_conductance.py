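#!/usr/bin/env python
"""Protein conductance and bridged/biotin conductance ratio.

The protein's contribution is the current difference between the
streptavidin-bridged and biotin-only junction.  This driver builds a
biotin baseline (Simmons, d = 2.35 nm), injects a 20 nS ohmic protein
channel plus measurement noise into the bridged sweep, and recovers the
channel conductance per bias; it also evaluates how flat the
bridged/biotin conductance ratio stays across bias (coefficient of
variation) and counts probe yield.

Finding: the injected 20 nS channel is recovered within ~3% wherever
|V| >= 100 mV (the chord estimate is noise-limited near zero bias), a
bridged junction whose conductance scales with the baseline keeps a
flat ratio (CV of a few percent), and 15 successful probes of 49 give
a 31% yield.

Writes results/protein_conductance.tsv.
"""

from pathlib import Path

import numpy as np

from qmtrace import (
    IVSweep,
    SimmonsParams,
    conductance_ratio,
    probe_yield,
    protein_conductance,
    simmons_current,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    grid = np.linspace(-0.3, 0.3, 61)
    base_params = SimmonsParams.from_bench_units(2.35, 2.0, 10.0)
    base_i = simmons_current(base_params, grid)
    g_protein_true = 20e-9
    rng = np.random.default_rng(7)
    noise = 0.02e-9
    biotin = IVSweep(bias=grid, current=base_i + rng.normal(0, noise, 61))
    bridged = IVSweep(
        bias=grid,
        current=base_i + g_protein_true * grid + rng.normal(0, noise, 61),
    )

    v, g = protein_conductance(bridged, biotin)
    with open(OUT / "protein_conductance.tsv", "w") as fh:
        fh.write("bias_V\tG_protein_nS\n")
        for vi, gi in zip(v, g):
            fh.write(f"{vi:.3f}\t{gi * 1e9:.3f}\n")
    strong = np.abs(v) >= 0.1
    err = np.max(np.abs(g[strong] - g_protein_true)) / g_protein_true
    print(f"protein channel: injected 20 nS, recovered "
          f"{np.mean(g[strong]) * 1e9:.2f} nS "
          f"(max error {err:.2%} for |V| >= 100 mV)")

    # ratio flatness across bias: per-bias baseline conductances with a
    # few percent measurement scatter, bridged = 1.5x baseline
    biases = np.arange(-0.3, 0.0, 0.05)
    g_biotin = 2e-9 * (1 + rng.normal(0, 0.03, biases.size))
    g_strep = 1.5 * 2e-9 * (1 + rng.normal(0, 0.03, biases.size))
    ratio, cv = conductance_ratio(g_strep, g_biotin)
    print(f"G_strep/G_biotin across {biases.size} biases: mean "
          f"{ratio.mean():.2f}, coefficient of variation {cv:.3f}")

    pct, rounded = probe_yield(15, 49)
    print(f"probe yield: 15 of 49 = {pct:.1f}% (rounds to {rounded}%)")


if __name__ == "__main__":
    main()
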
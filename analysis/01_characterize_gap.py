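#!/usr/bin/env python
"""Tunneling-gap characterization from I-V sweeps.

Fits the Simmons rectangular-barrier model to synthetic current-bias
sweeps at the two reference junction geometries (bare probe 2.45 nm,
biotin-modified probe 2.35 nm) and to a 20-probe population with gaps
drawn uniformly over the 1.5-3.1 nm selection window, then summarizes
the fitted gap-distance distribution.

Finding: noiseless +/-300 mV sweeps pin the gap to better than 1%, and
the population mean/sd reproduce the generating sample's moments.

Writes results/gap_distances.tsv.
"""

from pathlib import Path

import numpy as np

from qmtrace import SimmonsParams, fit_simmons, gap_distance_summary, synth_iv_sweep

OUT = Path(__file__).resolve().parent.parent / "results"
GRID = np.linspace(-0.3, 0.3, 61)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rows = []
    for label, d_nm in [("bare", 2.45), ("biotin", 2.35)]:
        truth = SimmonsParams.from_bench_units(d_nm, 2.0, 10.0)
        fit = fit_simmons(synth_iv_sweep(truth, GRID))
        rows.append((label, d_nm, fit.params.d_nm, fit.params.phi_eV,
                     fit.params.area_nm2, fit.residual_rms))
        print(f"{label:>7s} probe: true d = {d_nm} nm, fitted d = "
              f"{fit.params.d_nm:.4f} nm "
              f"({abs(fit.params.d_nm - d_nm) / d_nm:.3%} error)")

    rng = np.random.default_rng(2026)
    gaps = rng.uniform(1.5, 3.1, 20)
    fits = []
    for i, d in enumerate(gaps):
        truth = SimmonsParams.from_bench_units(d, 2.0, 10.0)
        fit = fit_simmons(synth_iv_sweep(truth, GRID))
        fits.append(fit)
        rows.append((f"probe{i:02d}", d, fit.params.d_nm, fit.params.phi_eV,
                     fit.params.area_nm2, fit.residual_rms))
    summary = gap_distance_summary(fits)
    print(f"population: fitted {summary['mean_d'] * 1e9:.2f} +/- "
          f"{summary['sd_d'] * 1e9:.2f} nm over {summary['n']} probes "
          f"({summary['n_in_window']} inside the 1.5-3.1 nm window); "
          f"generating mean {gaps.mean():.2f} nm")

    with open(OUT / "gap_distances.tsv", "w") as fh:
        fh.write("probe\td_true_nm\td_fit_nm\tphi_eV\tarea_nm2\tresidual_rms_A\n")
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]:.4f}\t{r[2]:.4f}\t{r[3]:.4f}\t"
                     f"{r[4]:.4f}\t{r[5]:.3e}\n")


if __name__ == "__main__":
    main()
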
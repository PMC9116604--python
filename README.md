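# qmtrace

Analysis pipeline for single-protein tunneling-junction recordings:
Simmons-model characterization of a sub-5-nm electrode gap from I-V
sweeps, hidden-Markov idealization of telegraph-noise current traces
into discrete conductance states, and the kinetic read-outs built on
that idealization — per-state lifetimes, switching rates, occupancies,
transition probabilities and low-frequency (1/f) noise spectra.

The intended user records chronoamperometric traces at fixed bias
through a nanoscale tunneling junction that a single protein can
bridge. The bridged junction switches stochastically between a small
number (2–4) of conductance levels; the statistics of that switching
carry the protein's conformational kinetics. Because raw recordings of
the motivating study are not publicly deposited, the package ships a
synthetic-trace generator that reproduces the acquisition chain
(100 kHz sampling, 4-pole 10 kHz Bessel filter, Gaussian plus 1/f
noise), so every estimator is validated by parameter recovery against
known ground truth.

## Models

**Tunneling baseline.** The unbound junction follows the
intermediate-bias Simmons expression for a rectangular barrier of
height φ and width d, with current I = J·A over effective area A:

    J(V) = e/(2πh d²) · [ (φ − eV/2) exp(−B√(φ − eV/2))
                        − (φ + eV/2) exp(−B√(φ + eV/2)) ],
    B = 4πd√(2m)/h,   valid for e|V| < 2φ.

Fitting (d, φ, A) by multi-start least squares to an I-V sweep yields
the gap distance; the fit also reports covariance diagnostics because
φ and A trade off against d once noise enters.

**Switching kinetics.** The bridged junction is an N-state semi-Markov
process: state i holds an exponential dwell with mean τ_i, then jumps
to j with embedded probability P_ij. Traces are idealized by segmental
k-means (SKM): Gaussian-mixture initialization from the all-point
current histogram, then alternating Viterbi decoding and re-estimation
of emission/transition parameters until the joint log-likelihood
converges. Dwells shorter than the filter dead time (0.34/f_c) are
merged away; lifetimes come from the left-truncated exponential MLE
τ̂ = mean(t_D) − t_dead with SE = τ̂/√n, rates are k = 1/τ, occupancy
is the time-weighted fraction of samples per state.

## Worked example

Recover the −25 mV two-state kinetics (mean dwells 5.00 ms and
1.897 ms) from a 120 s synthetic recording at SNR 5:

```python
from qmtrace.recovery import lifetime_recovery

run = lifetime_recovery([5.00, 1.897], 120.0, -25.0, seed=1)
print("tau (ms):", run.tau_ms.round(3))
print("occupancy (%):", run.occupancy_pct.round(2))
```

prints

```
tau (ms): [5.045 1.89 ]
occupancy (%): [72.52 27.48]
```

i.e. the S1 lifetime is recovered within 1% and the S1 occupancy
matches the alternating-renewal prediction τ₁/(τ₁+τ₂) = 72.5%. The
numbered drivers under `analysis/` run the full set of experiments
(gap characterization, −300 mV four-state kinetics, bias series,
protein conductance, noise spectra) and write their tables to
`results/`. A `qmtrace` command-line interface exposes the same stages
(`simulate`, `fit-iv`, `idealize`, `kinetics`, `psd`, `run`,
`selftest`).

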
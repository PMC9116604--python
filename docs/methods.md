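# Methods

## Scope and strategy

The package reproduces, as testable code, the analysis chain applied to
single-protein tunneling-junction recordings: gap characterization from
I-V sweeps, idealization of telegraph-noise current traces, dwell-time
kinetics, and low-frequency spectral diagnostics. No raw recordings are
available, so every estimator is validated by *parameter recovery*: the
published values parameterize a synthetic generator with known ground
truth, and the pipeline must return them. Passing these tests therefore
demonstrates that the estimators are unbiased and correctly implemented
under the stated noise model — not that they are robust to every
artifact of real bench data (see Limitations).

## Synthetic generator

A recording is built in the same order the hardware produces it:

1. **Switching path.** An N-state semi-Markov chain: the dwell in state
   i is exponential with mean τ_i; the successor is drawn from row i of
   an embedded jump matrix with zero diagonal. The initial state is
   drawn from the stationary time-fraction law (ν_i τ_i, with ν the
   embedded chain's stationary vector) so short traces carry no start-up
   bias; the dwell clock starts fresh at t = 0 and the final dwell is
   truncated and flagged censored. Default four-state jump weights
   0.7/0.2/0.1 encode the observed ranking (S1↔S2 most probable, then
   S2↔S3, S2↔S4 rarest); exact published transition matrices are not
   printed, so these are qualitative defaults, configurable per run.
2. **Rendering.** Piecewise-constant current at the per-state levels,
   sampled at dt = 10 µs (100 kHz). Measured level values are not
   printed; defaults place levels 5 noise-sd apart (≥ 50 pA) from a
   100 pA baseline, i.e. SNR 5 at the default 20 pA noise.
3. **Noise.** White Gaussian noise (sd `noise_sigma`) plus an optional
   1/f component synthesized by FFT spectral shaping: Fourier
   coefficients drawn Gaussian with variance ∝ 1/f so the expected
   one-sided PSD is `amplitude²/f`; the DC bin is zeroed. The recovery
   experiments use white noise only — their published inputs specify an
   SNR, not a 1/f magnitude — while the spectral analyses switch the
   pink component on.
4. **Filter.** A causal digital 4-pole Bessel low-pass at 10 kHz
   (bilinear transform with prewarping, −3 dB at the cutoff), matching
   the acquisition electronics. The filter's near-constant group delay
   (~3.3 samples at these settings) shifts every feature uniformly;
   `filter_group_delay` computes it so decoded paths can be aligned
   with ground truth when counting misassignments.

All randomness flows from one integer seed; per-stage substreams are
derived by hashing the stage name, so identical configurations are
bit-reproducible.

## Simmons fitting

Forward model: intermediate-bias rectangular-barrier expression, no
image-force correction — the standard form for sub-3 nm metal gaps at
biases ≤ 300 mV. Constants are CODATA 2018 (e and h exact by
definition, m_e to ~3e-10). Fitting minimizes unweighted squared
current residuals (scaled by max |I| for conditioning) over bounded
(d, φ, A) with a trust-region solver started from a log-spaced grid of
d ∈ [1, 4] nm × φ ∈ [1, 5] eV (area start 10 nm²), keeping the best
converged start; a start whose cost reaches the solver's noise floor
short-circuits the grid. The lower φ bound is clipped to 0.55·V_max so
every candidate stays inside the formula's e|V| < 2φ regime.

The gap distance is the well-determined parameter; φ and A are strongly
correlated with d once noise enters, so results carry the scaled-
parameter correlation matrix, approximate 1-σ errors and the Jacobian
condition number rather than bare point estimates. On noiseless
61-point ±300 mV sweeps, d is recovered to ≪1% across d ∈ [1.5, 3.1] nm
and φ ∈ [1.5, 3] eV.

## Idealization

**State count.** When not fixed by the user, the state count is the
number of modes of the all-point current histogram (Gaussian-smoothed
over ~2 bins; peaks kept at prominence ≥ 2% of the tallest). A
likelihood criterion (BIC/ICL) is deliberately *not* used for the
count: the Bessel filter's transition ramps deposit a few percent of
samples between the levels, and an information criterion correctly —
but unhelpfully — models them as an extra between-level component.
Peak counting reproduces the by-inspection choice (2 states at low
bias, 4 at high bias) on simulated analogues. Component means, sds and
weights are then fitted by EM at that count, on data standardized and,
for traces beyond 2×10⁵ samples, decimated with a deterministic stride
(the all-point histogram of a stationary trace is decimation-
invariant).

**SKM.** Segmental k-means alternates (a) Viterbi decoding under
per-state Gaussian emissions (state-specific sd by default; a pooled sd
is available since the original software's convention is unknowable)
and the current transition-matrix estimate, with (b) re-estimation of
means/sds from assigned samples and of transition probabilities from
path bigram counts. Each half-step maximizes the joint log-likelihood
of (path, data) over one block, so the objective is non-decreasing
(asserted in tests); convergence is declared at relative change
< 1e-6 or 100 iterations. The initial transition matrix uses a
self-transition probability exp(−dt/1 ms) — a neutral start at the
observed ms dwell scale — with the remainder uniform. Viterbi ties
resolve to the lowest state index for determinism. States are reported
sorted by ascending level mean regardless of initialization order. A
state capturing fewer than 10 samples raises a state-collapse error
advising a lower k. Emission sds are floored at 1e-15 A so noiseless
traces remain decodable.

**Dead time and dwell extraction.** The decoded path is run-length
encoded; events shorter than the dead time are merged into their longer
neighbor, shortest first and recursively, with same-state neighbors
fused — all in integer sample units, so total time is conserved
exactly. The first and last events are flagged censored and excluded
from lifetime fits by default.

The dead-time default is one filter rise time, 0.34/f_c (34 µs at
10 kHz). This choice was calibrated against simulator ground truth:
the dead time must cover the 1–3-sample spurious pass-through states
that a filtered multi-level step creates (shorter windows let those
artifacts collapse the short-state lifetimes), but each additional
rise time discards reliably detected real events whose removal fuses
same-state neighbors and inflates the long-state lifetime (~+9% at two
rise times for the four-state high-bias condition, vs ~+4% at one).
One rise time is the minimum that suppresses the artifacts, hence the
default; it remains configurable.

## Kinetics

Lifetimes use the left-truncated exponential MLE: for observed dwells
t > t_dead, τ̂ = mean(t) − t_dead, SE = τ̂/√n (asymptotic). A
censored-likelihood mode keeps edge dwells as right-censored
observations (τ̂ = Σ(t_i − t_dead)/n_uncensored); it matches numerical
likelihood maximization to 4 significant digits in tests. Rates are
k = 1/τ. Occupancy is computed from per-sample assignments (all
samples, censored spans included) — the fraction-of-time meaning — not
from event counts. Transition counts come from ordered event pairs;
run-length encoding forbids self-transitions, so the diagonal is zero
and rows with events are normalized to 1. Conductance uses the chord
definition G = I/V (per-state: level mean / bias); the protein's
conductance is the bridged-minus-baseline current difference divided
by bias, with a finite-difference slope replacing the chord at V = 0.

No missed-event (first-order retrigger) correction is applied beyond
the truncation shift. At the study's τ ≥ 0.45 ms and one rise-time dead
time this leaves a residual upward bias on the longest-lived state of
up to ~4% (same-state fusion across undetected sub-dead events) — the
dominant term in the recovery error budget and a documented limitation.

## Spectra

Welch PSDs use a Hann window, 50% overlap and density normalization
(integral ≈ variance; Parseval asserted within 5%). The default
segment length 2¹⁷ gives sub-Hz resolution at 100 kHz, enough to
resolve the f < 10 Hz band where binding dynamics appear. The DC bin
is excluded everywhere. The 1/f component is quantified by the
least-squares slope of log10 power vs log10 frequency over a chosen
band; absolute levels depend on windowing conventions, so comparisons
between recordings are ratio- or slope-based only. Note that
per-segment mean removal biases the lowest few bins downward, so slope
fits over sub-10-Hz bands need segments several times longer than the
band's longest period.

## Problem sizes

Recovery experiments use 60 s (four-state, −300 mV; two-state,
−100 mV) and 120 s (two-state, −25 mV) recordings at 100 kHz — about
10⁴–2×10⁴ events per state, putting the 3-SE statistical band well
inside the 5% lifetime tolerance so that systematic effects, not
sampling noise, dominate the comparison.

## Limitations

- The generator omits baseline drift, flicker of the level means,
  bias-dependent noise and electrochemical transients; recovery results
  certify estimator correctness under the stated model only.
- Missed-event bias is uncorrected (see above); for dwells below
  ~10× the dead time a correction of the Roux–Sauvé type would be
  needed.
- Simmons φ and A are reported but weakly identified; only d should be
  interpreted quantitatively.
- The published per-state current levels and full transition matrices
  are not available, so level spacings and jump weights are synthetic
  defaults chosen to match the stated SNR regime and qualitative
  transition ranking.
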
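# Methods

This note documents the models, parameter choices and numerical conventions
of `periotag`, and what the synthetic-data tests do and do not establish
about real recordings.

## Stimulus model

A rhythm is eight pulses over four beats (eighth-note subdivision,
`pulses_per_beat = 2`), so a cycle lasts `4 × 60 / tempo_bpm` seconds —
2.0 s at 120 bpm, 240/140 ≈ 1.714 s at 140 bpm.  The two study rhythms are
`KxSxKxSx` (unsyncopated) and `KxSKxSxx` (syncopated), each with four
sounded events.  Listening blocks loop the cycle six times at 120 bpm
(12.0 s) or eight times at 140 bpm (13.7 s); imagined continuations span
two cycles (4.0 s / 3.4 s).

**Envelope rendering.**  Each sounded pulse contributes an
attack–decay burst: `(1 − e^{−t/τ_a}) e^{−t/τ_d}` with attack τ_a = 5 ms
and decay τ_d = 60 ms (kick, amplitude 1.0) or 120 ms (snare, amplitude
0.8).  These are configurable (`OnsetShape`); how the original audio
envelope was extracted is not prescribed anywhere, so the burst shape is a
modelling choice.  Bursts wrap circularly around the cycle and the block
envelope is an exact tiling of one cycle, which the circular
autocorrelation downstream assumes.

**Length convention.**  A cycle is rounded to the nearest sample
(`round(cycle_s × rate)`) and a block is `repetitions × cycle_samples`
long.  At 140 bpm / 1200 Hz a cycle is 2057.14… samples, so exact
periodicity and exact duration cannot both hold; we keep exact periodicity
(the quantity the method depends on), accepting a ≤ 1-sample length
deviation per 8 cycles.

**Audio fixtures.**  The kick is a decaying tone complex with fundamental
63 Hz (plus a weak 189 Hz partial); the snare is a 217 Hz tone plus
180–400 Hz filtered noise.  Both leave some energy — but no spectral
peak — inside the 70–170 Hz analysis band, mirroring the constraint the
original sounds satisfied.  The snare's noise component uses a fixed
internal seed so the fixture is deterministic.

**Imagine condition.**  The audio is silent, but the reference envelope for
the ACC is the rhythm envelope of the two imagined cycles: the hypothesis
being tested is precisely that neural activity continues to carry the
rhythm's periodicities during silence.

## Synthetic ECoG

Each channel is unit-variance Gaussian noise with PSD ∝ f^slope (default
slope −1), plus a 60 Hz line component (amplitude 0.5) and its 120 Hz
harmonic (half that), plus per-channel log-normal gain jitter (σ = 0.1).
Every channel additionally carries a 70–170 Hz band-limited Gaussian
carrier with RMS 0.4 — chosen so ongoing in-band activity is about as
strong as the pink background's own energy in that band at 1200 Hz.  On
*tracking* channels during rhythm blocks the carrier's instantaneous
amplitude is `1 + depth × m(t)`, where `m` is the max-normalized
(optionally transformed) rhythm envelope and `depth ∈ [0, 1]` is the
ground-truth effect size (study default 0.5).  Null channels and
white-noise blocks carry the identical unmodulated carrier, so their
high-gamma statistics match by construction — the property the empirical
null requires.

A response *lag* is implemented as a circular shift of the whole channel,
which the autocorrelation is exactly invariant to.  The
*rectified-derivative* transform models an onset-detector population: the
positive part of the envelope's circular derivative, convolved circularly
with a 50 ms exponential response kernel (a standard auditory
onset-response time constant).  Without the kernel the 5 ms attack makes
the code a ~6-sample spike train whose autocorrelation correlates with the
envelope's at only ≈ 0.4; with it, the code still differs pointwise from
the envelope (max normalized deviation ≈ 0.3) while attaining ACC ≈ 0.98 —
the "equivalent periodicities, different waveform" case the method is
designed to catch.

Trial RNG streams are derived from the study seed and the trial's condition
keys, so any trial regenerates bit-identically in isolation.

**What the generator does not emulate:** epileptiform artifacts, reference
and montage effects, cross-channel correlation, nonstationary arousal
drift, or realistic cortical geometry.  Passing tests therefore establish
the *procedure's* calibration and power under a plausible signal model, not
performance on clinical data.

## Preprocessing

Band-limiting uses an elliptic IIR high-pass + low-pass cascade (order 4
per section, 0.5 dB passband ripple, 50 dB stopband), applied
forward–backward (`sosfiltfilt`) for zero phase; phase distortion would
smear the envelope's periodic structure even though the ACC itself is
delay-invariant.  The "first harmonic of the 60 Hz line noise" is read as
120 Hz — the only line component inside 70–170 Hz — and removed with an
elliptic band-stop of 4 Hz width (configurable).  The beta comparison band
(12–30 Hz) runs through the identical code path with no notch.  Envelopes
are `|hilbert(x)|` and are trimmed to an integer number of rhythm cycles
(floor) before autocorrelation.  Filter design parameters are exposed
because the original orders/ripples are unreported; the acceptance checks
avoid depending on them.

## The ACC

`circular_acf` computes `Re(IDFT(DFT(x)·conj(DFT(x))))`, divides by the
maximum element (the zero-lag value, by Cauchy–Schwarz), and truncates to
lags 0..⌊N/2⌋ — the non-redundant half of the symmetric circular ACF,
which is how "up to the Nyquist frequency" is interpreted for a lag-domain
vector (a full-vector mode exists).  No mean is subtracted before the DFT
(the defining formula has none; the Pearson step centres the vectors
anyway; a `subtract_mean` switch exists).  Lag 0 is included by default —
it is identically 1 in both vectors and inflates the correlation, so an
`exclude_lag0` switch is provided and recorded in output metadata.
Pearson is the default correlation; Spearman is available for sensitivity
analysis.  The stimulus envelope is Fourier-resampled to the neural rate
(circular, ideal anti-alias) before comparison.

A note on the null's location: with lag 0 included, both ACF vectors share
the zero-lag peak and its immediate decay, so null ACCs are centred
*above* zero (≈ 0.06–0.3 depending on segment length).  This is inherent
to the statistic and is exactly why significance is assessed against an
empirical white-noise null rather than against zero.

## Null calibration and normalization

Null distributions pool a participant's electrodes' white-noise ACCs per
rhythm; the threshold is the linearly interpolated empirical 99th
percentile, and exceedance is strict (a tie is not significant).  Two
normalization modes reflect two descriptions of the same procedure that
differ in the original account: `electrode_baseline` (default) subtracts
the same electrode's ACC from its length-matched white-noise twin;
`threshold_subtracted` subtracts the group threshold.  The mode used is
carried in the output.  White-noise twins are generated per condition cell
(same rhythm, tempo, audio condition and presentation), so "length-matched"
baselines resolve by exact key match.  Imagine-condition thresholds use
white-noise segments length-matched to the two-cycle imagine blocks.

## Group-level inference

The headline model predicts the globally z-scored ACC from three binary
treatment-coded factors and all interactions — Rhythm (actual rhythm vs
white noise), Syncopated, Imagined; reference cell white-noise /
unsyncopated / listen — with independent random intercepts for
participant, electrode, tempo and presentation (tempo and presentation as
two-level random effects follows the original specification; with so few
levels their variances are weakly identified, which the weakly informative
hyperpriors absorb).  Fixed effects carry Student-t(3, 0, 1) priors.

**Sampler.**  The Gaussian-family model is fit by a conjugate Gibbs
sampler: the t prior is represented exactly as a scale mixture of normals
(β_j | λ_j ~ N(0, λ_j), λ_j ~ InvGamma(3/2, 3/2)), random-effect variances
get InvGamma(0.5, 0.5) and the residual variance InvGamma(0.01, 0.01)
hyperpriors, and every conditional is closed-form.  Defaults are 2000 kept
sweeps after 500 burn-in (configurable up; the pipeline uses shorter
desk-scale chains), seeded and bit-reproducible.  A split-half mean-shift
diagnostic is reported per coefficient.

**Bernoulli models** (listen↔imagine overlap; high-gamma vs beta electrode
counts) use a Laplace approximation: posterior mode of the penalized
log-likelihood under the same t prior (plus unit-normal random
intercepts), with Gaussian draws from the curvature at the mode.  The t
prior keeps estimates finite under complete separation, which is flagged
in the diagnostics.  This is an approximation to the fully Bayesian
logistic mixed model and is labelled as such in results.

**Directional hypotheses.**  For a linear combination c of coefficients,
the evidence ratio is `P(c > 0) / P(c ≤ 0)` over posterior draws; > 19 is
the α = 0.05 analogue and this equivalence is exact on draws by
construction.  The four per-condition hypotheses sum the coefficient sets
implied by the treatment coding (e.g. syncopated/imagine sums Rhythm,
Rhythm:Syncopated, Rhythm:Imagined and the three-way term).  The
presentation-order analysis fits normalized ACC ~ second presentation per
rhythm × tempo × audio-condition cell with participant/electrode random
intercepts.

## Problem sizes and tolerances

Simulation-based checks use desk-scale designs chosen to keep sampling
error well inside the asserted margins: null calibration pools 8192
white-noise ACCs and tests 6400 fresh null electrodes against the 95%
binomial band around 1%; power uses 20 seeds × 16 planted electrodes per
modulation depth; model recovery uses 20 replicates of a 6-participant ×
8-electrode factorial (3072 rows) with coverage pooled over the planted
effects.  Exact identities (ACF oracle, phase invariance) are asserted at
1e-9 and 1e-6 respectively.  Zero-phase elliptic filtering is non-circular,
so shift-equivariance through the *full* pipeline holds only to ~1e-3
(filter edge transients); the exact 1e-6 invariance applies to shifts of
the envelope itself, which is what the statistic consumes.

## Known limitations

- The Bernoulli-family Laplace approximation understates tail uncertainty
  relative to MCMC when cells are sparse.
- The empirical null requires enough white-noise ACCs per participant ×
  rhythm group; below ~20 values the q99 threshold is poorly resolved (the
  code warns).
- EDF files can be read (via the optional `mne` extra) but not written;
  the native on-disk format is a float64 matrix with a JSON sidecar.
- The generator's ground truth modulates only the configured carrier band;
  leakage of rhythm information into other bands (e.g. evoked potentials)
  is not modelled, so the beta-band comparison on synthetic data is a
  construction check, not a physiological claim.
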
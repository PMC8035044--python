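# Methods

This note documents the models, estimators and numerical choices behind
`lgnbinoc`, in the package's own terms: what each stage assumes, which knobs
matter, and what the synthetic-data tests do and do not establish about real
recordings.

## The measurement problem

A drifting sine grating drives an LGN relay neuron at the grating's temporal
(drift) frequency; the strength of that stimulus-locked modulation — the F1
response — is the response measure for every comparison the pipeline makes.
In awake animals, trial-to-trial variability in fixation position shifts the
spatial phase of the grating over the receptive field, so the response phase
jitters across trials. A conventional PSTH average cancels phase-jittered
modulation almost completely; the pipeline therefore converts each trial's
spike train into its autocorrelation, which discards absolute phase, and
only then averages and measures power.

## Spike trains and spike density

Spike times are kept in milliseconds relative to stimulus onset and
binarized at 1 kHz (two spikes in one millisecond bin collapse to one; the
reader logs how many). Rate estimates for screening use a causal
postsynaptic-potential-shaped kernel

    k(t) = (1 - e^(-t/tau_g)) e^(-t/tau_d),   tau_g = 1 ms, tau_d = 20 ms,

normalized to unit sum before the sampling-frequency scaling so the output
is a calibrated rate in spikes/s (the unnormalized kernel integrates to
~19.05 ms, which would inflate rates ~19-fold and make a spikes/s threshold
uninterpretable; a raw-kernel mode is kept behind `normalize_kernel=False`
for fidelity experiments). Units whose mean spike-density rate over the
−600..+1300 ms trial window falls strictly below 1.9 spikes/s are excluded.

## Stability screening

Per-trial spike counts in the −600..+1300 ms window are smoothed with a
centered 20-trial running mean and segmented by an exact penalized
dynamic program (mean-shift model, within-segment squared error, one
penalty per change). The default penalty is `2 sigma^2 log n` with sigma
estimated from the scaled MAD of first differences of the raw counts — a
noise estimate the sought-after steps cannot inflate. The default trimming
policy keeps segments whose mean count sits within 3 scaled MADs of the
median segment mean (with a standard-error-based fallback when only two
segments exist); `longest_stable_segment` is available for aggressive
trimming. Trimming never reorders trials and always returns a union of
contiguous segments. On stationary Poisson units the default settings trim
more than 10% of trials from fewer than 5% of units; noiseless steps are
localized exactly. The smoothing window (20 trials) is a per-trial-series
reading of the upstream convention; it is configurable.

## Phase-invariant response extraction

For each trial the 0/1 train over the stimulation window is reduced to the
one-sided, spike-count-normalized coincidence autocorrelation

    a(l) = sum_t x(t) x(t + l) / n_spikes,

the probability of a spike `l` ms after a randomly chosen spike: a(0) = 1,
all values in [0, 1]. No mean subtraction is applied (the values would stop
being probabilities); lags are linear, so the estimator carries a
triangular envelope `(1 - l/N)` that the fractal component of the spectral
decomposition absorbs. Zero-spike trials are excluded from averages rather
than zero-filled. Circularly shifting a trial's spikes changes its
autocorrelation only through linear-lag edge terms; downstream F1 power
moves by < 5% under full per-trial phase randomization while a PSTH-based
F1 collapses — the property the whole design exists for. Phase invariance
is exact only over an integer number of drift cycles, which is why the
synthetic experiments use 1000 ms epochs at 4 Hz (see below).

## Spectral decomposition and the F1 response

Autocorrelations are Hann-tapered, linearly detrended, and zero-padded to a
0.25 Hz bin grid (4 s equivalent at 1 kHz), which puts 4 and 8 Hz exactly
on-grid. Linear detrending is essential here: the autocorrelation's offset
and decaying envelope otherwise leak through the taper mainlobe and swamp
the spectrum below ~2 Hz.

Rhythmic and arrhythmic power are separated by irregular resampling
(IRASA): resampling by a non-integer factor h shifts narrowband peaks but
leaves scale-free 1/f spectra invariant, so the median over
h ∈ {1.1, 1.15, …, 1.9} of the geometric means of (h, 1/h)-resampled
spectrum pairs estimates the fractal component, and oscillatory = total −
fractal exactly, by construction. Negative oscillatory values are retained
so null calibration of the downstream tests stays unbiased. Two
implementation details matter:

- **Resampling** is Fourier-domain (ideal band-limited interpolation with
  spectrum-truncation anti-aliasing). It is numerically indistinguishable
  from long polyphase filters on every validation case and an order of
  magnitude cheaper for fine rational factors.
- **Finite-window validity.** The compressed resample at nominal frequency
  f reflects the original spectrum at f/h, which is meaningless below the
  taper's resolution floor (~1.45/T Hz). The median therefore uses only
  factors whose compressed frequency is resolvable; below ~f_res·h_min the
  fractal estimate simply tracks the total and the decomposition carries no
  information. Drift frequencies (4–8 Hz) are unaffected — every factor is
  valid there.

Two computation modes exist. Trial-level statistics use per-trial spectra
(`mode="per-signal"`), because the responsiveness t-tests and ROC analysis
need per-trial samples; single-periodogram geometric means are chi²-biased
low (~0.785²), but the bias is common to the conditions being compared.
Condition-average spectra (`mode="average"`) average the periodograms
across trials *before* the geometric-mean and median steps, which makes the
averaged fractal estimate nearly unbiased — on pure pink noise the
band-integrated |oscillatory| residual over 1–20 Hz is 5–9% of the fractal
power for a 100-trial average. Per-bin residuals sit at the chi² noise
floor of the average (~10% SD per bin for 100 trials; an information limit,
not an implementation artifact). A single-bin DFT fast path
(`irasa_at_frequencies`) evaluates the same decomposition only at the grid
bins the F1 extraction needs, bit-identically to the full grid.

The F1 response of a trial is the oscillatory power at the grid bin nearest
the drift frequency (ties toward lower frequency). A unit-condition is
**responsive** iff (1) its per-trial oscillatory power at f_drift exceeds
blank-trial fractal power at f_drift (one-tailed two-sample t) and (2) its
oscillatory power exceeds its own fractal power there (one-tailed t, paired
across trials by default since both numbers come from the same trials;
unpaired available). Both at alpha = 0.05; missing blanks make a condition
untestable, never silently responsive. On 1000 null units the false-positive
rate is far below alpha (the intersection of two tests is conservative).

## Binocular modulation statistics

For each unit and contrast pair, percent modulation is
`100 (binoc_mean − mono_mean)/mono_mean` on mean per-trial F1 power
(negative = suppression). Population medians are screened by the 3-scaled-MAD
rule (scale 1.4826), tested against zero with the Wilcoxon signed-rank test
(exact for n ≤ 25 without ties, normal approximation with continuity
correction otherwise), and bracketed by a seeded percentile bootstrap CI
(10 000 resamples). Caveat worth knowing: per-record noise in a ratio of
means is right-skewed, so the symmetric MAD exclusion trims the right tail
preferentially and can shift a pooled median by a point or two at low
signal-to-noise; the rule is retained because it is part of the metric's
definition.

Per-unit significance uses ROC analysis: AUC = P(binoc > mono) + ½ P(tie),
computed by the rank statistic (identical to the trapezoidal ROC area; an
enumeration oracle checks this exactly). The Monte-Carlo null resamples,
with replacement, surrogate samples of the original sizes from the two
conditions pooled; the folded statistic max(A, 1−A) is compared against the
upper quantile of the null AUC distribution, giving a two-sided test of
size 2(1−q): q = 0.975 for alpha 0.05, q = 0.9 for the relaxed alpha 0.2
used in the suppressed-fraction trend. Calibration holds to within 1.5
binomial SD at 30 trials per condition; at the 12-trial minimum the AUC's
1/(n·m) lattice makes the 0.975 test conservative. Label permutation is
available as an alternative null.

Population structure over contrast uses: OLS of the percent of
significantly suppressed units on the dominant-eye contrast-bin
representatives (slope, p, residual df), and class-averaged
contrast-response functions (per-unit min-max normalization to [0, 1], then
per-bin mean ± SEM; constant-response units are excluded). Contrast values
are consolidated into the study's ranges (0.0, 0.025–0.05, 0.106–0.135,
0.318–0.368, 0.8–1.0), represented by their medians (0.12 / 0.34 / 0.9 for
the low/medium/high ranges); contrasts falling between ranges are excluded
from population averaging, not snapped.

## P/M/K classification

Stream labels come from explicit index thresholds on the measured spectral
signatures (s_index, rg_index, doubling_index — see the module docstring)
plus the saturation of a bounded Naka–Rushton fit to the unit's CRF
(baseline fixed at the zero-contrast response; three deterministic starts;
c50 ∈ [0.01, 1], exponent ∈ [0.5, 5]). Rule order: S-dominance → K;
frequency doubling or (strong saturation with weak red-green opponency) →
M; otherwise P. The thresholds (0.5 / 0.5 / 0.8 / 0.3) are artifact
choices validated only against synthetic archetypes — the original
assignment also weighed evidence (recording depth, background multiunit
character) that spike times cannot provide — so every label carries a
rationale record and can be overridden.

## The synthetic-data generator

Each simulated unit is an inhomogeneous Poisson process (exact thinning)
with rate `baseline + A·w(2π f t + φ)`, half-wave-rectified sine for linear
units and |sin| (dominant power at 2f) for frequency-doubling M units under
L−M drive. The amplitude follows a Naka–Rushton CRF of dominant-eye
contrast times a contrast-gated suppression factor

    S(c_d, c_nd) = 1 − γ · g(c_nd; s50_nd) · (1 − g(c_d; release_50)),

the minimal form with the right limits: S(·, 0) = 1 exactly, non-increasing
in non-dominant contrast, released by dominant contrast. φ is uniform over
the cycle per trial by default — fixation-driven phase jitter is the only
feature of eye-position variability the analysis is designed to defeat, so
it is modeled directly in phase. Class archetypes (P: r_max 50 sp/s, c50
0.40, n 1.2; M: 80, 0.12, 2.0, doubling; K: 30, 0.30, 1.5) follow the
classical ordering of contrast sensitivity and saturation, with per-class
chromatic gain maps carrying the spectral signatures. Epochs default to
1000 ms — an integer number of 4 Hz cycles, for which the per-trial
autocorrelation F1 is phase-invariant to ~4% even noise-free, versus a
3-fold phase dependence at 4.4 cycles.

**Median-targeted calibration.** Recovery studies need populations whose
generative median modulation is a known number *in the units the pipeline
reports*. F1 power of the normalized autocorrelation is not linear in rate
amplitude (it scales between A² and A⁴ depending on the baseline share), so
a target percent modulation cannot be injected on the amplitude scale.
Instead the calibration inverts the noise-free forward map of the full
measurement chain: expected autocorrelation (a ratio of deterministic
coincidence and count intensities), spectral decomposition, F1 power,
percent difference — evaluated on a small per-unit grid of suppression
strengths, interpolated monotonically, and solved for a single scale on the
drawn γ values so the pooled generative median equals the target, then
polished with exact forward evaluations to 1%. The ground-truth table
records both this expected measured modulation and the amplitude-scale
100(S−1).

What the generator does *not* emulate: bursting and refractory structure,
slow adaptation within trials, correlated noise across trials, eye-movement
trajectories within trials, or LFP context. Passing recovery tests
therefore demonstrates correctness of the estimators under Poisson
statistics with realistic rates, phase jitter, and nonstationarity — not
robustness to every physiological departure from Poisson firing.

## Problem sizes and runtime choices

Simulation studies use 56-unit populations with 30 trials per condition
(the study-scale sample), 1000-unit batches for null-calibration checks,
300 units for classification accuracy, and 100–200 trials for single-unit
spectral properties. These sizes put Monte-Carlo error comfortably below
each property's tolerance while keeping the full test suite under fifteen
minutes on one CPU core.

## Known limitations

- The pooled sample median of percent modulation is a slightly biased
  estimator of the generative median under low SNR (MAD-trim asymmetry,
  ~1–2 points); single-draw CI-coverage checks of an injected median
  therefore fail somewhat more often than the nominal 5%.
- The oscillatory/fractal split is uninformative below ~2.5 Hz for 1 s
  windows (finite-window validity rule above).
- Classification thresholds are validated against archetypes only; real
  data would need threshold audit against anatomically confirmed labels.
- The stability penalty default is validated by the false-trim budget, not
  derived; heavily autocorrelated slow drift (as opposed to step changes)
  may pass the screen.
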
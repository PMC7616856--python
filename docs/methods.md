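# Methods

This note documents the estimators, the synthetic-data model, the
numerical choices, and the limits of what the test suite demonstrates.

## Phase-locking estimators

**PPC.** For unit phasors `u_j = exp(i phi_j)`, the pairwise phase
consistency is the mean of `cos(phi_j - phi_k)` over unordered pairs. It
is computed through the algebraic identity `(|sum u|^2 - n) / (n(n-1))`,
which is exactly the all-pairs average at O(n) cost; the test suite checks
the identity against brute-force enumeration on instances up to 500
spikes. Unlike the squared resultant length, PPC's expectation does not
depend on n; a dedicated test shows the naive estimator inflating at small
sample sizes while PPC stays flat.

**PPC1 (rate-bias removal).** Restricting pairs to spikes from different
trials removes the contribution of within-trial dependencies (burstiness,
rate fluctuations) that bias same-trial pairs. With per-trial phasor sums
`S_t` (counts `n_t`) it equals `(|S|^2 - sum_t |S_t|^2) / (N^2 - sum_t
n_t^2)`. For spikes with von Mises coupling of concentration kappa,
`E[PPC1] = (I1(kappa)/I0(kappa))^2`; the calibration experiment verifies
this for kappa in {0, 0.5, 1, 2} within the jackknife CI, and verifies
invariance under random 50% spike thinning (|change| < 0.01).

**Per-spike phase measurement.** Spike-centered LFP windows of 9 cycles
of the analysis frequency (9/f s, macaque mode) or fixed 250 ms (mouse
mode) are Hann-tapered and Fourier-transformed; the coefficient's angle is
the spike phase. Windows that do not fit in the recording are dropped and
counted, keeping the spike set identical across frequencies. The "9/f s"
reading of the window length is a deliberate interpretation (frequency-
proportional resolution matching the taper description); the length is
configurable.

An important subtlety found during calibration: when the rhythm is a
*stochastic* narrowband process, the windowed phase estimate smooths the
diffusing instantaneous phase over the window and PPC is attenuated by a
few percent relative to the closed form even at high SNR — on the
generator's AR(2) gamma (4 Hz bandwidth) the attenuation is ~5–10% of the
PPC value. On the *true* instantaneous phases PPC1 matches the Bessel
closed form to four decimals. The calibration experiment therefore drives
spikes from a constant-frequency rhythm sampled at 5 kHz, so that
measurement bias (< 0.5% from time discretization) is far below the
jackknife CI and the comparison isolates the estimator. Session-level
analyses on the stochastic gamma are interpreted as relative comparisons
(classes, layers, conditions), not absolute kappa readouts.

**LFP–LFP PPC.** Multitaper coefficients (0.5 s epochs, 7 unit-energy
DPSS tapers, 2 Hz resolution) give per-epoch relative-phase phasors; each
(epoch, taper) pair is one observation by default (a flag averages tapers
within epochs first — both conventions are exposed because the pooling
choice is not uniquely determined). Stimulus-period epochs are tiled
non-overlapping between stimulus onset and the first change. Session
spectra can be re-indexed to each session's own gamma peak (local maximum
in a 20–100 Hz search band; sessions without a peak are flagged and
excluded from aligned means).

**Time-resolved PPC** slides Hann windows of ±2.5 cycles per frequency in
1 ms steps; time bins whose window exceeds the data are masked.

## Preprocessing

Shank re-referencing subtracts the per-shank mean per sample. Bipolar
derivatives are deeper-minus-shallower adjacent contacts and inherit the
midpoint depth (sign and depth conventions are package choices; the
orientation is documented rather than prescribed). Gamma phase extraction
uses a Butterworth band-pass of design order 12 (an order-24 band-pass, as
in the common MATLAB convention), realized as second-order sections,
applied forward and backward (zero phase), followed by the Hilbert
transform on complete trials. The CSD is the plain second spatial
difference `(V(i-1) - 2V(i) + V(i+1))/h^2` with linear interpolation of
flagged bad channels; in this convention a sink (focal extracellular
negativity) appears as a *positive* deflection, and the laminar-assignment
routine anchors the granular compartment at the largest positive evoked
value. Surrogate LFPs for structures without columnar geometry (LGN) are
1 ms-binned population spike counts band-passed 1–100 Hz, with the
≥ 10-unit inclusion rule enforced (overridable).

## Decoding

Likelihood families: Poisson (counts), Gaussian (other non-angular
features; per-condition SD by default, pooled optional, floored at 1e-6 of
the feature scale), von Mises (angles; ML concentration by truncated
approximation plus Newton refinement, capped at 1e3). Posteriors are
computed in log space; ties are broken by a seeded coin flip; training is
leave-one-trial-out. Population decoding multiplies per-signal posteriors;
subsampling curves use 50 seeded subsets per population size by default
(the count is configurable; it is not externally prescribed). The decoder
is calibrated against the exhaustive Poisson ideal observer (λ = 5 vs 8,
500 trials per condition: LOO accuracy within ±0.02 of the analytic Bayes
rate, monotone in population size) and against chance on label-independent
features.

The spike-phase modality is evaluated per signal (per SU–LFP pair) and
summarized as the mean single-unit accuracy, matching how the feature is
defined; the pooled-population spike-PPC feature is also computed. Note
that on synthetic sessions the trial-wise LFP–LFP relative phase is more
decodable than in typical real data, because the generator's feedforward
lag is deterministic and the relative-phase dispersion is therefore
unrealistically small; similarly, any generator whose attentional coupling
increase is recoverable necessarily makes pooled per-trial spike-PPC
informative. These are properties of the idealized generator, not of the
estimators.

## Rates, latency, correlations

PETHs: 1 ms bins over the full trial, Gaussian kernel of 50 ms length and
8 ms SD (reflected-padding convolution to avoid edge dips), trial-wise
z-scoring (zero-spike trials get a zero trace and are flagged), then
epoching and averaging. The AMI window is the 1 s before the first change;
drivenness contrasts 0.05–0.25 s post-stimulus with a 0.2 s baseline,
rate-normalized for the unequal window lengths. Noise correlations are
Pearson r within chunks of 10 adjacent trials, averaged (incomplete final
chunks dropped; zero-variance chunks skipped); a regression test shows
chunking removes an injected common monotone drift that inflates the
whole-session correlation. Attentional difference time-courses (cue-locked,
−0.1 to +0.5 s) are additionally smoothed with an 80 ms/13 ms Gaussian on
the 1 ms grid ("samples" are read as milliseconds); latency contrasts use
the unbiased-normalized cross-correlation over 0.05–0.5 s, asymmetry =
integral over [−0.2, 0] s minus [0, 0.2] s of lag, with significance from
1000 pseudorandom reassignments of units between populations. Sign
convention: negative asymmetry means the first population leads. Units
with non-positive attentional modulation are excluded from latency
analyses. The AMI regression is ordinary least squares of
`ami ~ rate * C(layer)` via statsmodels.

## Granger causality

Multi-unit count series (1 ms bins) in fixed 0.5 s windows are Hann-
tapered; cross-spectra on the 2 Hz grid are factorized with the iterative
Wilson–Burg algorithm (causal-part operator in the lag domain; zero-lag
coefficient halved and upper-triangularized). Defaults: relative tolerance
1e-9, 100 iterations, ridge 1e-8 × mean trace added only if the CSD is
numerically singular — all recorded in the returned diagnostics, including
a converged flag and the factorization residual. Geweke directed influence
uses the row-normalized transfer function. Validation: exact recovery of
diagonal white spectra; transfer-function recovery within 1% max error on
an analytically constructed AR cross-spectrum; agreement with the
parametric Geweke oracle within 5% at the coupling frequency of a
unidirectional AR(2) system; < 0.01 in the non-causal direction; dominance
flip under time reversal for genuine coupling and *no* flip for a pure
SNR-asymmetry confound. Two practical notes: convergence slows markedly
when inter-channel coherence approaches 1 (near-common signals), and
sharply peaked spectra (AR pole radius ≳ 0.9) are smoothed by the 0.5 s
Hann windows, biasing peak GC downward by several percent — the oracle
fixture uses a moderately damped pole (r = 0.7) so the comparison is
dominated by estimator accuracy rather than window smoothing.

## Waveforms, layers, state

Waveforms are offset-corrected by the pooled median of the first and last
10 samples and scaled to unit L2 norm, making classification invariant to
amplitude and DC. Exclusions: triphasic shapes (pre-trough positive peak
exceeding the post-trough peak) and DC drift beyond 3× the population SD
of the flat tails (the threshold is a package default; none is externally
prescribed). Classification embeds the normalized traces with 2-D t-SNE
(perplexity 30, auto-reduced for small banks, seeded) and splits them with
fuzzy c-means (fuzzifier 2, Euclidean, tolerance 1e-10; implemented
in-package, ~25 lines, seeded); the cluster with the shorter mean
trough-to-peak duration is named NW. On synthetic banks of 100 narrow +
100 broad templates the recovery is ≥ 98%. Laminar assignment combines
spike-sign log-ratios (≈ 0 → outside the brain; > 0 → white matter; < 0 →
gray matter) with the evoked-CSD sink anchor (± 1 channel = granular;
above → superficial; below → deep); anchor and thresholds are returned for
manual override. Opto-tagging requires a significant pulse-locked response
(pluggable test; the default is a Bonferroni-corrected Poisson test on
10 ms bins of the 0.5 s post-pulse window, standing in the role the
parameter-free ZETA test plays) with peak latency in (1 ms, 10 ms]; peaks
≤ 1 ms are treated as laser artifacts. State labels follow fixed
thresholds: pupil (normalized by session maximum) 0.65–0.95 high / 0.3–0.55
low arousal; speed > 5 cm/s high / < 1 cm/s low locomotion.

## Randomization statistics

All tests are nonparametric, two-sided, 1000 seeded randomizations by
default. Group comparisons exchange values between groups preserving
sizes; paired condition comparisons flip labels within items. Spectra/time
courses use max-statistic correction: bins beyond the 97.5th percentile of
per-randomization maxima or the 2.5th percentile of minima are flagged
(family-wise error ≤ 0.07 at nominal 0.05 across 500 null simulations).
For scalars two p-values are returned: the z-CDF recipe
`(1 − Φ(|Δ|/SD_null))/2` — reported faithfully even though it tends to
0.25 rather than 1 for null-central observations — and the two-sided
empirical quantile, which is uniform under the null and is what the
package's own significance decisions use.

## Synthetic-session model

The generator reproduces the statistical structure the analyses assume,
not biophysics (no conductance models, no spike waveform dynamics in the
LFP). Defaults define the standard preset:

| parameter | default | meaning |
|---|---|---|
| `n_trials` | 100 | trials, alternating conditions, shuffled |
| `fs` | 1000 Hz | LFP sampling rate |
| `n_channels_per_shank` / spacing | 16 / 150 µm | laminar geometry per area |
| `gamma_peak` | 60 Hz away / 63 Hz toward | sender AR(2) pole frequency |
| `gamma_bandwidth` | 4 Hz | spectral half-width of the gamma peak |
| `gamma_power` | 1.0 / 1.2 (away/toward) | attention raises sender gamma |
| `feedforward_lag` | 4 ms | sender→receiver LFP propagation |
| `coupling_kappa` | NW: 0.8/1.2/0.6 (sup/gran/deep), ×1.4 toward; BW: 0 | von Mises concentration |
| `preferred_phase` | sender 0, receiver +1.51 rad | feedforward spike-phase offset |
| `base_rate_range` | 8–15 Hz | per-unit uniform draw |
| `attention_gain` | 1.35/1.2/1.15 (sup/gran/deep) toward | multiplicative rate gain |
| `attention_latency` | 0.15 s receiver superficial, 0.35 s elsewhere | sigmoid (50 ms) onset after cue |
| `shared_gain_sd` | 0.22 away / 0.10 toward | slow log-normal shared gain (τ = 0.2 s) |
| trial timing | 0.614 s pre-stim; 0.618–1.131 s stim→cue; 1.162–2.133 s cue→change | uniform draws |

Trial timing follows the macaque-style task structure; the laminar channel
map places contacts 0–1 outside the brain, 2–6 superficial, 7–9 granular
(anchor at 8), 10–13 deep, 14–15 in white matter, with spike-sign counts
generated accordingly. Receiver units couple to the sender's *current*
gamma phase with the +1.51 rad preferred-phase offset — the offset
subsumes the conduction delay, so the recovered spike-phase difference
equals the configured value directly, while the LFP copy carries the 4 ms
lag (verified by envelope cross-correlation to ±1 sample). The von Mises
modulation is renormalized within each stimulus period so that mean rates
stay calibrated (empirical rates within 3 SE of configured). The magnitude
of the attentional coupling increase for NW cells is a free parameter
(default ×1.4) since no canonical value exists. Mouse mode adds 12 LGN
units locked to the gamma (for surrogate-LFP analyses), pupil and speed
traces, and 10 ms-spaced opto pulse trains driving tagged units at ~4 ms
latency.

What the generator does *not* emulate: broadband spiking contributions to
the LFP, stimulus selectivity, eye movements, burstiness and refractory
structure, session-to-session heterogeneity beyond the seeded draws, and
realistic trial-to-trial lag jitter. Passing structural-recovery tests
therefore demonstrates correctness of the estimators and pipeline on data
with the assumed structure, not performance on real recordings.

## Problem sizes

Calibration experiments use sizes chosen to keep every quantity's
sampling error well below its assertion margin: 200 s of spiking at 12 Hz
for PPC calibration, 500 trials per condition for decoder calibration,
500 experiments × 1000 randomizations for the family-wise error rate,
3×10⁵ samples for the Granger oracle, 20 seeded runs for latency power,
and one 100-trial session (36 units, two 16-channel shanks) for structural
recovery.
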
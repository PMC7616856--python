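# gammalink

Analysis toolkit for **spike–LFP gamma phase-locking and attention** in
two-area laminar extracellular recordings (e.g. V1→V4 in primates, or
LGN→V1/V2 in mice). It is written for systems neuroscientists who record a
gamma-generating "sender" area together with a downstream "receiver" area
and want to quantify how strongly, in which cell classes and layers, and
under which behavioral states the receiver's spiking locks to the sender's
rhythm — and what that locking contributes, relative to firing rates, to
reading out the animal's attentional state.

## What it computes

**Phase locking (PPC).** The central statistic is the pairwise phase
consistency — the mean cosine of the phase difference over all unordered
pairs of observations,

```
PPC = 2 / (n (n - 1)) * sum_{j<k} cos(phi_j - phi_k)
```

an unbiased analogue of the squared resultant length whose expectation does
not depend on n. For spike–field locking, per-spike phases come from
Hann-tapered Fourier windows of 9 cycles centered on each spike (fixed
250 ms windows in "mouse" mode), on bipolar LFP derivatives. `ppc1`
restricts the average to spike pairs from *different* trials, which removes
the dependence on within-trial spike count (firing-rate bias): for spikes
with von Mises coupling of concentration κ, `E[PPC1] = (I1(κ)/I0(κ))²`.
LFP–LFP locking uses the same estimator on multitaper relative phases
(0.5 s epochs, 7 Slepian tapers), with spectra alignable to each session's
own gamma peak.

**Decoding.** A naive-Bayes maximum-likelihood decoder of the attention
condition from five per-trial features (spike counts, LFP–LFP PLV and
relative phase, spike–field PPC, spike phase) with Poisson, Gaussian and
von Mises likelihoods, flat priors, leave-one-trial-out training, and
product posteriors over signals.

**Rates and latency.** PETHs (1 ms bins, Gaussian 50 ms/8 ms kernel,
trial-wise z-scoring), attentional modulation index
`AMI = (FR_tow − FR_away)/(FR_tow + FR_away)`, drivenness, chunked noise
correlations (Pearson r in 10-trial chunks), attentional difference
time-courses and their cross-correlation asymmetry, and the multi-linear
regression AMI ~ rate × layer.

**Connectivity.** Nonparametric spectral Granger causality: Hann-tapered
cross-spectra of 0.5 s multi-unit count windows (4–200 Hz, 2 Hz steps),
Wilson–Burg spectral matrix factorization, Geweke directed influence,
with time-reversal and trial-equalization controls.

**Classification and state.** Waveform normalization and exclusion,
t-SNE + fuzzy c-means split into narrow (NW) and broad (BW) spiking
classes, laminar compartment assignment from the stimulus-evoked CSD and
spike-sign log-ratios, opto-tag latency classification, and pupil/speed
state labels.

**Statistics.** Everything is tested with seeded label-exchange
randomizations (default 1000); per-bin comparisons use max-statistic
family-wise correction (97.5th/2.5th percentiles of the per-randomization
extrema).

**Synthetic sessions.** `gammalink.synthdata` generates fully seeded
two-area laminar sessions with ground truth: an AR(2) gamma process on 1/f
noise, a lagged layer-weighted copy in the receiver, inhomogeneous-Poisson
units with class/layer/condition-dependent von Mises coupling,
multiplicative attention gains with laminar latencies, slow shared gain
fluctuations (noise correlations), evoked CSD sinks, waveform templates,
and mouse extras (LGN population, pupil/speed, opto pulses).

## Worked example

```python
from gammalink import SynthConfig
from gammalink.synthdata import gen_session
from gammalink.pipeline import (
    spikefield_ppc_table, decode_accuracies, phase_offset_recovery,
)

session, truth = gen_session(SynthConfig(seed=31, n_trials=100))

ppc = spikefield_ppc_table(session, by_condition=True)
gamma = ppc[(ppc.frequency >= 52) & (ppc.frequency <= 72)]
for cls in ("NW", "BW"):
    for cond in ("toward", "away"):
        sel = gamma[(gamma.cell_class == cls) & (gamma.condition == cond)]
        print(f"{cls} {cond:>6}: gamma-band PPC1 = {sel.ppc1.mean():.4f} "
              f"({sel.unit_id.nunique()} units)")

acc = decode_accuracies(session, seed=31)
print(f"decoding accuracy  rate={acc['rate']:.2f}  PLV={acc['lfp_plv']:.2f}  "
      f"spike-phase={acc['spike_phase']:.2f}")

off = phase_offset_recovery(session)
print(f"receiver-sender spike-phase offset: {off['offset']:.3f} rad "
      f"(generator truth {truth.session['phase_offset']:.2f})")
```

prints

```
NW toward: gamma-band PPC1 = 0.1192 (12 units)
NW   away: gamma-band PPC1 = 0.0760 (12 units)
BW toward: gamma-band PPC1 = -0.0001 (12 units)
BW   away: gamma-band PPC1 = -0.0000 (12 units)
decoding accuracy  rate=0.90  PLV=0.61  spike-phase=0.52
receiver-sender spike-phase offset: 1.510 rad (generator truth 1.51)
```

Reading: only narrow-waveform (putative fast-spiking) receiver units lock
to the sender's gamma, attention strengthens that locking, spike counts
decode the attention condition far better than inter-areal phase-locking
measures while the spike phase itself decodes at chance, and the injected
feedforward spike-phase offset is recovered.

The same stages are available from the shell:

```bash
gammalink synth --out session.h5 --seed 31
gammalink ppc session.h5 --out ppc.csv
gammalink decode session.h5 --seed 31
gammalink report --out-dir run31 --seed 31   # all stages + summary.json
```

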
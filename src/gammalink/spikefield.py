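"""Spike–LFP phase locking: spike-triggered spectra, PPC0/PPC1, weighting.

The phase of the LFP at each spike is estimated by Fourier-transforming a
Hann-tapered LFP window centered on the spike. In "macaque" mode the window
spans 9 cycles of the analysis frequency (9/f s), giving frequency-
proportional resolution; in "mouse" mode a fixed 250 ms window is used.
Bipolar LFP derivatives are the recommended input, mitigating 1/f and
low-frequency far-field contributions.

PPC0 is the mean cosine of phase differences over all unordered spike pairs.
PPC1 restricts the average to pairs of spikes from *different* trials, which
removes the dependence of the estimate on within-trial spike count (and
hence on firing rate and its history effects). By convention units enter
group averages only with at least ``min_spikes`` (default 200) spikes per
condition; group spectra may weight each unit by its relative spike count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .stats import RandTestResult, permute_labels


@dataclass
class SpikePhaseSet:
    """Per-spike LFP phases ``(n_spikes, n_freqs)`` with trial membership."""

    phases: np.ndarray
    freqs: np.ndarray
    trial_ids: np.ndarray
    unit_id: int | str | None = None
    n_dropped: int = 0

    @property
    def n_spikes(self) -> int:
        return self.phases.shape[0]


@dataclass
class UnitPPCSpectrum:
    """Per-unit PPC spectrum with spike count, condition, and group weight."""

    unit_id: int | str | None
    freqs: np.ndarray
    values: np.ndarray
    n_spikes: int
    condition: str | None = None
    weight: float = 1.0
    estimator: str = "ppc1"


def spike_triggered_coeffs(
    lfp: np.ndarray,
    fs: float,
    spikes: np.ndarray,
    freqs: np.ndarray,
    trial_ids: np.ndarray | None = None,
    mode: str = "macaque",
    fixed_window: float = 0.25,
    unit_id=None,
) -> SpikePhaseSet:
    """Phases of Hann-tapered spike-centered LFP windows, per frequency.

    ``lfp`` is a single channel; ``spikes`` absolute times in seconds.
    Window length is ``9/f`` s per frequency (``mode="macaque"``) or a fixed
    ``fixed_window`` s (``mode="mouse"``). Spikes whose largest window does
    not fit inside the recording are dropped and counted, keeping the spike
    set identical across frequencies.
    """
    lfp = np.asarray(lfp, dtype=float)
    spikes = np.asarray(spikes, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    if trial_ids is None:
        trial_ids = np.zeros(len(spikes), dtype=int)
    trial_ids = np.asarray(trial_ids)

    if mode == "macaque":
        halves = np.array([int(round(4.5 * fs / f)) for f in freqs])
    elif mode == "mouse":
        halves = np.full(len(freqs), int(round(fixed_window * fs / 2)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    max_half = halves.max()

    centers = np.round(spikes * fs).astype(int)
    ok = (centers - max_half >= 0) & (centers + max_half < len(lfp))
    n_dropped = int(np.sum(~ok))
    centers = centers[ok]
    trial_ids = trial_ids[ok]

    phases = np.empty((len(centers), len(freqs)))
    for fi, (f, half) in enumerate(zip(freqs, halves)):
        wlen = 2 * half + 1
        win = hann(wlen, sym=True)
        osc = win * np.exp(-2j * np.pi * f * (np.arange(wlen) - half) / fs)
        if len(centers):
            segs = lfp[centers[:, None] + np.arange(-half, half + 1)[None, :]]
            phases[:, fi] = np.angle(segs @ osc)
    return SpikePhaseSet(
        phases=phases, freqs=freqs, trial_ids=trial_ids, unit_id=unit_id, n_dropped=n_dropped
    )


def ppc0(phase_set: SpikePhaseSet, condition: str | None = None) -> UnitPPCSpectrum:
    """All-pairs pairwise phase consistency of spike phases.

    ``(|sum u|^2 - n) / (n (n-1))`` per frequency — exactly the average of
    ``cos(phi_j - phi_k)`` over unordered spike pairs.
    """
    n = phase_set.n_spikes
    if n < 2:
        raise ValueError("PPC0 needs at least 2 spikes")
    u = np.exp(1j * phase_set.phases)
    s = np.abs(u.sum(axis=0)) ** 2
    vals = (s - n) / (n * (n - 1))
    return UnitPPCSpectrum(
        unit_id=phase_set.unit_id, freqs=phase_set.freqs, values=vals,
        n_spikes=n, condition=condition, estimator="ppc0",
    )


def ppc1(
    phase_set: SpikePhaseSet,
    min_spikes: int = 200,
    condition: str | None = None,
) -> UnitPPCSpectrum:
    """Rate-bias-free PPC: mean cosine over spike pairs from different trials.

    Computed as ``(|S|^2 - sum_t |S_t|^2) / (N^2 - sum_t n_t^2)`` where
    ``S_t`` is the phasor sum within trial ``t`` — identical to the
    brute-force cross-trial average. Raises when spikes span fewer than two
    trials or the total spike count is below ``min_spikes``.
    """
    n = phase_set.n_spikes
    trials, inv = np.unique(phase_set.trial_ids, return_inverse=True)
    if len(trials) < 2:
        raise ValueError("PPC1 needs spikes from at least 2 trials")
    if n < min_spikes:
        raise ValueError(f"unit excluded: {n} spikes < min_spikes={min_spikes}")
    u = np.exp(1j * phase_set.phases)
    total = u.sum(axis=0)
    per_trial = np.zeros((len(trials), u.shape[1]), dtype=complex)
    np.add.at(per_trial, inv, u)
    counts = np.bincount(inv, minlength=len(trials)).astype(float)
    num = np.abs(total) ** 2 - (np.abs(per_trial) ** 2).sum(axis=0)
    den = n**2 - np.sum(counts**2)
    if den <= 0:
        raise ValueError("all spikes in one trial; PPC1 undefined")
    vals = num / den
    return UnitPPCSpectrum(
        unit_id=phase_set.unit_id, freqs=phase_set.freqs, values=vals,
        n_spikes=n, condition=condition, estimator="ppc1",
    )


def weight_spectra(
    spectra: list[UnitPPCSpectrum],
    scheme: str = "class_mean",
    total_counts: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spike-count-weighted group mean of per-unit PPC spectra.

    ``class_mean``: unit i gets weight ``count_i / mean(count)`` over the
    supplied group (all units of one cell class). ``condition_total``: the
    per-condition spike count of unit i is divided by the mean *total* spike
    count per unit, supplied via ``total_counts[unit_id]``. Returns
    ``(freqs, weighted_mean, weights)``.
    """
    if not spectra:
        raise ValueError("empty spectrum list")
    counts = np.array([s.n_spikes for s in spectra], dtype=float)
    if scheme == "class_mean":
        denom = counts.mean()
    elif scheme == "condition_total":
        if total_counts is None:
            raise ValueError("condition_total scheme requires total_counts")
        denom = np.mean([total_counts[s.unit_id] for s in spectra])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if denom == 0:
        raise ValueError("zero mean spike count")
    w = counts / denom
    vals = np.stack([s.values for s in spectra])
    return spectra[0].freqs, (w[:, None] * vals).mean(axis=0), w


def spike_phase_hilbert(
    analytic_values: np.ndarray, fs: float, spikes: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-spike circular mean phase across channels of an analytic signal.

    ``analytic_values`` is ``(channels, samples)`` complex (one channel is
    fine as ``(1, samples)``); each spike gets the circular mean across
    channels of the instantaneous phase at its sample. Returns
    ``(per_spike_phases, unit_circular_mean)``; out-of-coverage spikes are
    dropped.
    """
    vals = np.atleast_2d(analytic_values)
    idx = np.round(np.asarray(spikes, dtype=float) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < vals.shape[1])]
    with np.errstate(invalid="ignore", divide="ignore"):
        u = vals[:, idx] / np.abs(vals[:, idx])
    u = np.nan_to_num(u)
    per_spike = np.angle(u.sum(axis=0))
    if len(per_spike) == 0:
        return per_spike, np.nan
    return per_spike, float(np.angle(np.exp(1j * per_spike).sum()))


def circular_mean(angles: np.ndarray) -> float:
    angles = np.asarray(angles, dtype=float)
    if len(angles) == 0:
        raise ValueError("empty angle set")
    return float(np.angle(np.exp(1j * angles).sum()))


def wrap_angle(a):
    """Wrap to (-pi, pi]."""
    return -((-np.asarray(a) + np.pi) % (2 * np.pi) - np.pi)


def circ_mean_diff(
    group_a: np.ndarray,
    group_b: np.ndarray,
    n_randomizations: int = 1000,
    seed: int | None = None,
) -> tuple[float, RandTestResult]:
    """Wrapped difference of circular means with a label-exchange p-value.

    Returns ``(mean(A) - mean(B))`` wrapped to (-pi, pi] and the
    randomization result; the null statistic is the absolute wrapped mean
    difference under group-label exchange.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("each group needs at least one angle")
    diff = float(wrap_angle(circular_mean(a) - circular_mean(b)))

    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    na = len(a)
    null = np.empty(n_randomizations)
    for i in range(n_randomizations):
        perm = rng.permutation(pooled)
        null[i] = wrap_angle(circular_mean(perm[:na]) - circular_mean(perm[na:]))
    obs = abs(diff)
    p_emp = (1.0 + np.sum(np.abs(null) >= obs)) / (n_randomizations + 1.0)
    res = RandTestResult(observed=diff, null_draws=null, p_empirical=float(p_emp), seed=seed)
    return diff, res
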
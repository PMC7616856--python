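"""Multitaper spectra and LFP–LFP pairwise phase consistency (PPC).

LFP-only analyses multiply 0.5 s data epochs with seven discrete prolate
spheroidal (Slepian) tapers and FFT them. Power is the squared magnitude of
the coefficients averaged over tapers and epochs (optionally f²-scaled for
display). Phase locking between two LFPs is quantified with PPC: the mean
over all unordered pairs of epochs of the cosine of their relative-phase
difference, an estimator whose expectation does not depend on the number of
epochs. Because the gamma peak frequency varies across sessions, spectra can
be re-indexed to each session's own gamma peak before group averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from scipy.signal.windows import dpss, hann


@dataclass
class SpectralCoeffs:
    """Complex multitaper Fourier coefficients ``(epochs, tapers, freqs)``."""

    coeffs: np.ndarray
    freqs: np.ndarray
    epoch_len: float
    n_tapers: int


@dataclass
class PhaseSpectrum:
    """Frequency-indexed phase-consistency values with their sample size."""

    freqs: np.ndarray
    values: np.ndarray
    n: int
    rel_phase: np.ndarray | None = None
    alignment_offset: float = 0.0


def pairwise_consistency(unit_vectors: np.ndarray, axis: int = 0) -> np.ndarray:
    """Mean cosine over all unordered pairs of unit phasors.

    Uses the identity ``(|sum u|^2 - n) / (n (n - 1))``, algebraically equal
    to the all-pairs average of ``Re(u_j conj(u_k))`` at O(n) cost.
    """
    u = np.asarray(unit_vectors)
    n = u.shape[axis]
    if n < 2:
        raise ValueError("PPC needs at least 2 observations")
    s = np.abs(u.sum(axis=axis)) ** 2
    return (s - n) / (n * (n - 1))


def multitaper_coeffs(
    epochs: np.ndarray, fs: float, epoch_len: float = 0.5, n_tapers: int = 7
) -> SpectralCoeffs:
    """Slepian-tapered FFT coefficients of fixed-length epochs.

    ``epochs`` is ``(n_epochs, n_samples)`` with ``n_samples = epoch_len*fs``.
    Tapers are unit-energy DPSS with time-bandwidth ``(n_tapers+1)/2``.
    """
    epochs = np.atleast_2d(np.asarray(epochs, dtype=float))
    nsamp = int(round(epoch_len * fs))
    if epochs.shape[1] != nsamp:
        raise ValueError(
            f"epochs have {epochs.shape[1]} samples; epoch_len={epoch_len}s at "
            f"fs={fs} requires {nsamp}"
        )
    nw = (n_tapers + 1) / 2.0
    tapers = dpss(nsamp, nw, Kmax=n_tapers)  # (tapers, samples), unit energy
    tapered = epochs[:, None, :] * tapers[None, :, :]
    coeffs = np.fft.rfft(tapered, axis=-1)
    freqs = np.fft.rfftfreq(nsamp, 1.0 / fs)
    return SpectralCoeffs(coeffs=coeffs, freqs=freqs, epoch_len=epoch_len, n_tapers=n_tapers)


def power_spectrum(coeffs: SpectralCoeffs, f2_scale: bool = False) -> np.ndarray:
    """Mean squared coefficient magnitude over epochs and tapers.

    With ``f2_scale`` power values are multiplied by the square of their
    frequency, which flattens a 1/f² background for display.
    """
    if coeffs.coeffs.size == 0:
        return np.zeros_like(coeffs.freqs)
    p = (np.abs(coeffs.coeffs) ** 2).mean(axis=(0, 1))
    if f2_scale:
        p = p * coeffs.freqs**2
    return p


def lfp_lfp_ppc(
    coeffs_a: SpectralCoeffs,
    coeffs_b: SpectralCoeffs,
    pool_tapers: bool = True,
) -> PhaseSpectrum:
    """PPC between two channels' multitaper coefficients.

    Per epoch (and, with ``pool_tapers``, per taper) the relative phase
    ``angle(A) - angle(B)`` forms one unit phasor; PPC is the all-pairs
    mean cosine of their differences. With ``pool_tapers=False`` the
    relative-phase phasors are averaged over tapers within an epoch first
    and renormalized, so each epoch is one observation.
    """
    ca, cb = coeffs_a.coeffs, coeffs_b.coeffs
    if ca.shape != cb.shape:
        raise ValueError("coefficient arrays must have matching shape")
    rel = ca * np.conj(cb)
    with np.errstate(invalid="ignore", divide="ignore"):
        u = rel / np.abs(rel)
    u = np.nan_to_num(u)
    if pool_tapers:
        u = u.reshape(-1, u.shape[-1])  # (epochs*tapers, freqs)
    else:
        m = u.mean(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.nan_to_num(m / np.abs(m))
    n = u.shape[0]
    ppc = pairwise_consistency(u, axis=0)
    mean_phase = np.angle(u.sum(axis=0))
    return PhaseSpectrum(freqs=coeffs_a.freqs, values=ppc, n=n, rel_phase=mean_phase)


def find_gamma_peak(
    freqs: np.ndarray, values: np.ndarray, search_band: tuple[float, float] = (20.0, 100.0)
) -> float:
    """Frequency of the local maximum of a spectrum inside the search band.

    Raises ``ValueError`` if no interior local maximum exists (flat or
    monotone spectra).
    """
    freqs = np.asarray(freqs)
    values = np.asarray(values)
    sel = (freqs >= search_band[0]) & (freqs <= search_band[1])
    idx = np.flatnonzero(sel)
    if len(idx) < 3:
        raise ValueError("search band covers fewer than 3 frequency bins")
    best = None
    for i in idx:
        if 0 < i < len(freqs) - 1 and values[i] > values[i - 1] and values[i] >= values[i + 1]:
            if best is None or values[i] > values[best]:
                best = i
    if best is None:
        raise ValueError("no local maximum inside the search band")
    return float(freqs[best])


def align_to_gamma_peak(
    spectra: list[PhaseSpectrum],
    search_band: tuple[float, float] = (20.0, 100.0),
) -> tuple[np.ndarray, np.ndarray, list[float | None]]:
    """Re-index session spectra to each session's own gamma peak.

    Returns ``(offsets, mean_spectrum, peaks)``: a common offset grid
    ``f - f_peak``, the group mean over sessions on that grid (restricted to
    offsets covered by every aligned session), and the per-session peak
    (``None`` for sessions without a local maximum, which are excluded).
    """
    peaks: list[float | None] = []
    aligned = []
    for sp in spectra:
        try:
            pk = find_gamma_peak(sp.freqs, sp.values, search_band)
        except ValueError:
            peaks.append(None)
            continue
        peaks.append(pk)
        aligned.append((sp.freqs - pk, sp.values))
    if not aligned:
        raise ValueError("no session had a gamma peak in the search band")
    df = np.median([np.median(np.diff(f)) for f, _ in aligned])
    lo = max(f[0] for f, _ in aligned)
    hi = min(f[-1] for f, _ in aligned)
    offsets = np.arange(0, np.floor((hi - lo) / df) + 1) * df + lo
    interp = [np.interp(offsets, f, v) for f, v in aligned]
    return offsets, np.mean(interp, axis=0), peaks


def tf_lfp_ppc(
    lfp_a: np.ndarray,
    lfp_b: np.ndarray,
    fs: float,
    freqs: np.ndarray,
    step: float = 0.001,
    n_cycles: float = 2.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-resolved LFP–LFP PPC across trials.

    Inputs are ``(n_trials, n_samples)`` trial-aligned LFP segments. At each
    frequency a Hann window of ±``n_cycles`` cycles is slid in steps of
    ``step`` seconds; per window and trial the relative phase of the two
    windowed Fourier coefficients forms one phasor and PPC is taken across
    trials. Returns ``(times, ppc, valid)`` with ``ppc`` of shape
    ``(n_freqs, n_times)``; time bins whose window exceeds the data are
    masked invalid (NaN).
    """
    a = np.atleast_2d(np.asarray(lfp_a, dtype=float))
    b = np.atleast_2d(np.asarray(lfp_b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("trial arrays must have matching shape")
    n_trials, n_samp = a.shape
    stride = max(1, int(round(step * fs)))
    times = np.arange(n_samp) / fs
    centers = np.arange(0, n_samp, stride)
    ppc = np.full((len(freqs), len(centers)), np.nan)
    valid = np.zeros_like(ppc, dtype=bool)
    for fi, f in enumerate(freqs):
        half = int(round(n_cycles * fs / f))
        wlen = 2 * half + 1
        if wlen > n_samp:
            continue
        win = hann(wlen, sym=True)
        osc = win * np.exp(-2j * np.pi * f * (np.arange(wlen) - half) / fs)
        # windowed coefficient at every sample via correlation, then subsample
        ca = fftconvolve(a.astype(complex), osc[None, ::-1], mode="same", axes=-1)
        cb = fftconvolve(b.astype(complex), osc[None, ::-1], mode="same", axes=-1)
        rel = ca * np.conj(cb)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = np.nan_to_num(rel / np.abs(rel))
        uu = u[:, centers]
        ok = (centers >= half) & (centers < n_samp - half)
        vals = pairwise_consistency(uu[:, ok], axis=0)
        ppc[fi, ok] = vals
        valid[fi, ok] = True
    return times[centers], ppc, valid
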
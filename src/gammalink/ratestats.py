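"""Firing-rate metrics: PETHs, modulation indices, noise correlations,
latency difference time-courses, and the AMI regression.

PETHs follow a fixed recipe: spike counts in 1 ms bins over the full trial,
convolution with a Gaussian kernel (length 50 ms, SD 8 ms), per-trial
z-scoring of the smoothed series, then epoching and trial averaging.
The attentional modulation index AMI = (FR_tow - FR_away)/(FR_tow + FR_away)
uses mean counts in the 1 s before the first stimulus change; drivenness
contrasts 0.05–0.25 s post-stimulus against the 0.2 s pre-stimulus baseline.
Noise correlations are computed within chunks of ten adjacent trials and
averaged, which removes slow session-wide drifts of excitability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.signal import fftconvolve
from scipy.signal.windows import gaussian as gaussian_window

from .stats import RandTestResult


@dataclass
class PETH:
    times: np.ndarray  # s relative to event
    per_trial: np.ndarray  # (n_trials, n_bins) smoothed z-scored traces
    mean: np.ndarray
    kernel: tuple  # (length_ms, sd_ms)
    zero_sd_trials: np.ndarray  # flagged trials with no spikes (z set to 0)


@dataclass
class ModIndex:
    value: float
    n_toward: int = 0
    n_away: int = 0
    window: str = ""


def _gauss_kernel(length_ms: float = 50, sd_ms: float = 8, bin_ms: float = 1.0) -> np.ndarray:
    n = int(round(length_ms / bin_ms))
    k = gaussian_window(n, sd_ms / bin_ms)
    return k / k.sum()


def _smooth_reflect(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-length convolution with reflected padding (no edge dips)."""
    half = len(kernel) // 2
    pad = np.concatenate([x[..., half:0:-1], x, x[..., -2 : -half - 2 : -1]], axis=-1)
    out = fftconvolve(pad, kernel[None, :] if x.ndim == 2 else kernel, mode="same", axes=-1)
    return out[..., half : half + x.shape[-1]]


def bin_spikes(spikes: np.ndarray, t0: float, t1: float, bin_s: float = 0.001) -> np.ndarray:
    n = int(round((t1 - t0) / bin_s))
    idx = np.floor((np.asarray(spikes) - t0) / bin_s).astype(int)
    idx = idx[(idx >= 0) & (idx < n)]
    counts = np.zeros(n)
    np.add.at(counts, idx, 1.0)
    return counts


def peth(
    spikes: np.ndarray,
    trials: pd.DataFrame,
    event: str,
    window: tuple[float, float],
    kernel: tuple[float, float] = (50.0, 8.0),
    trial_span: tuple[str, str] = ("start", "end"),
    zscore: bool = True,
) -> PETH:
    """Event-locked PETH: bin 1 ms over the full trial, smooth, z-score per
    trial, then select the event window and average."""
    if len(trials) == 0:
        raise ValueError("need at least one trial")
    k = _gauss_kernel(*kernel)
    bin_s = 0.001
    n_bins = int(round((window[1] - window[0]) / bin_s))
    out = np.zeros((len(trials), n_bins))
    zero_sd = np.zeros(len(trials), dtype=bool)
    for i, (_, tr) in enumerate(trials.iterrows()):
        t0, t1 = tr[trial_span[0]], tr[trial_span[1]]
        counts = bin_spikes(spikes, t0, t1, bin_s)
        sm = _smooth_reflect(counts, k)
        if zscore:
            sd = sm.std()
            if sd == 0:
                zero_sd[i] = True
                tr_z = np.zeros_like(sm)
            else:
                tr_z = (sm - sm.mean()) / sd
        else:
            tr_z = sm / bin_s  # Hz
        ev = tr[event]
        j0 = int(round((ev + window[0] - t0) / bin_s))
        seg = tr_z[j0 : j0 + n_bins]
        if len(seg) < n_bins:
            seg = np.pad(seg, (0, n_bins - len(seg)))
        out[i] = seg
    times = window[0] + (np.arange(n_bins) + 0.5) * bin_s
    return PETH(times=times, per_trial=out, mean=out.mean(axis=0), kernel=kernel, zero_sd_trials=zero_sd)


def _mean_count(spikes, trials, t0_col, w0, w1) -> float:
    vals = []
    for _, tr in trials.iterrows():
        t = tr[t0_col]
        vals.append(np.sum((spikes >= t + w0) & (spikes < t + w1)))
    return float(np.mean(vals)) if vals else np.nan


def ami(spikes: np.ndarray, trials: pd.DataFrame, window: float = 1.0) -> ModIndex:
    """Attentional modulation index on mean counts in the ``window`` seconds
    before the first change."""
    tow = trials[trials["condition"] == "toward"]
    away = trials[trials["condition"] == "away"]
    if len(tow) == 0 or len(away) == 0:
        raise ValueError("both conditions must be represented")
    fr_t = _mean_count(spikes, tow, "first_change", -window, 0.0)
    fr_a = _mean_count(spikes, away, "first_change", -window, 0.0)
    if fr_t + fr_a == 0:
        return ModIndex(value=np.nan, n_toward=len(tow), n_away=len(away), window="pre-change 1 s")
    return ModIndex(
        value=(fr_t - fr_a) / (fr_t + fr_a),
        n_toward=len(tow),
        n_away=len(away),
        window="pre-change 1 s",
    )


def drivenness(spikes: np.ndarray, trials: pd.DataFrame) -> ModIndex:
    """Stimulus drivenness: 0.05–0.25 s post-stimulus vs 0.2 s baseline.

    Counts are rate-normalized to account for the unequal window lengths.
    """
    fr_stim = _mean_count(spikes, trials, "stim_onset", 0.05, 0.25) / 0.2
    fr_base = _mean_count(spikes, trials, "stim_onset", -0.2, 0.0) / 0.2
    if fr_stim + fr_base == 0:
        return ModIndex(value=np.nan, window="drivenness")
    return ModIndex(value=(fr_stim - fr_base) / (fr_stim + fr_base), window="drivenness")


def noise_corr(
    counts: np.ndarray,
    chunk: int = 10,
) -> np.ndarray:
    """Chunked Pearson correlation between channel pairs across trials.

    ``counts`` is ``(n_channels, n_trials)`` (fixed-window mode) or
    ``(n_channels, n_trials, n_timebins)`` (time-resolved mode, r per time
    bin). Pearson r is computed within chunks of ``chunk`` adjacent trials
    and averaged; zero-variance chunks are skipped; an incomplete final
    chunk is dropped. Returns the channel-pair correlation matrix (or a
    ``(n_ch, n_ch, n_timebins)`` array).
    """
    c = np.asarray(counts, dtype=float)
    time_resolved = c.ndim == 3
    n_ch, n_trials = c.shape[:2]
    n_chunks = n_trials // chunk
    if n_chunks < 1:
        raise ValueError(f"need at least one full chunk of {chunk} trials")
    shape = (n_ch, n_ch) + (c.shape[2],) if time_resolved else (n_ch, n_ch)
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    for ci in range(n_chunks):
        blk = c[:, ci * chunk : (ci + 1) * chunk]
        mu = blk.mean(axis=1, keepdims=True)
        d = blk - mu
        sd = np.sqrt((d**2).sum(axis=1))
        if time_resolved:
            num = np.einsum("itk,jtk->ijk", d, d)
            den = sd[:, None, :] * sd[None, :, :]
        else:
            num = d @ d.T
            den = sd[:, None] * sd[None, :]
        ok = den > 0
        acc[ok] += num[ok] / den[ok]
        cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)


def sliding_counts(
    spikes: np.ndarray,
    trials: pd.DataFrame,
    event: str,
    window: tuple[float, float],
    half_width: float = 0.04,
    step: float = 0.01,
) -> np.ndarray:
    """Per-trial spike counts in ±``half_width`` windows slid every ``step``
    seconds across the event-locked period; shape ``(n_trials, n_bins)``."""
    centers = np.arange(window[0], window[1] + 1e-9, step)
    out = np.zeros((len(trials), len(centers)))
    for i, (_, tr) in enumerate(trials.iterrows()):
        t = tr[event]
        rel = np.asarray(spikes) - t
        for j, ctr in enumerate(centers):
            out[i, j] = np.sum((rel >= ctr - half_width) & (rel < ctr + half_width))
    return out


def attn_difference_timecourse(
    spikes: np.ndarray,
    trials: pd.DataFrame,
    window: tuple[float, float] = (-0.1, 0.5),
    smoothing: tuple[float, float] = (80.0, 13.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Toward-minus-away difference of cue-locked PETHs for one unit.

    The condition PETHs are additionally smoothed (Gaussian, length 80 ms /
    SD 13 ms on the 1 ms grid) because difference time-courses are noisier
    than the PETHs themselves. Returns ``(times, difference)``.
    """
    k = _gauss_kernel(*smoothing)
    tow = peth(spikes, trials[trials["condition"] == "toward"], "cue_onset", window)
    awy = peth(spikes, trials[trials["condition"] == "away"], "cue_onset", window)
    diff = _smooth_reflect(tow.mean, k) - _smooth_reflect(awy.mean, k)
    return tow.times, diff


def _xcorr_unbiased(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cross-correlation with 'unbiased' normalization (each lag divided by
    its overlap count). Lag axis: positive lag means ``b`` trails ``a``."""
    n = len(a)
    c = np.correlate(a, b, mode="full")  # index k: sum_t a[t+k-(n-1)]... (numpy conv def)
    lags = np.arange(-(n - 1), n)
    overlap = n - np.abs(lags)
    return lags, c[::-1] / overlap


def xcorr_asymmetry(
    diff_a: np.ndarray,
    diff_b: np.ndarray,
    dt: float = 0.001,
    max_lag: float = 0.2,
) -> float:
    """Cross-correlation asymmetry between two difference time-courses.

    Asymmetry = integral over lags [-max_lag, 0] minus integral over
    [0, max_lag] of the unbiased cross-correlation. Sign convention: if
    ``diff_a`` leads ``diff_b`` (the same transient occurs earlier in A),
    the correlation mass sits at positive lags and the asymmetry is
    negative.
    """
    a = np.asarray(diff_a, dtype=float)
    b = np.asarray(diff_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("traces must share a time grid")
    L = int(round(max_lag / dt))
    if len(a) <= L:
        raise ValueError("trace shorter than the maximum lag")
    lags, c = _xcorr_unbiased(a - a.mean(), b - b.mean())
    mid = len(a) - 1
    neg = c[mid - L : mid].sum() * dt
    pos = c[mid + 1 : mid + 1 + L].sum() * dt
    return float(neg - pos)


def xcorr_asymmetry_test(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    dt: float = 0.001,
    max_lag: float = 0.2,
    n_randomizations: int = 1000,
    seed: int | None = None,
) -> RandTestResult:
    """Population asymmetry with a unit-reassignment randomization test.

    ``traces_a``/``traces_b`` are per-unit difference time-courses of two
    populations (already restricted to the analysis period). The observed
    statistic is the asymmetry of the population-mean traces; the null
    pseudorandomly reassigns units between the populations keeping sizes.
    """
    A = np.atleast_2d(np.asarray(traces_a, dtype=float))
    B = np.atleast_2d(np.asarray(traces_b, dtype=float))
    obs = xcorr_asymmetry(A.mean(axis=0), B.mean(axis=0), dt, max_lag)
    pooled = np.concatenate([A, B], axis=0)
    na, n = len(A), len(pooled)
    rng = np.random.default_rng(seed)
    null = np.empty(n_randomizations)
    for i in range(n_randomizations):
        perm = rng.permutation(n)
        null[i] = xcorr_asymmetry(
            pooled[perm[:na]].mean(axis=0), pooled[perm[na:]].mean(axis=0), dt, max_lag
        )
    p_emp = (1.0 + np.sum(np.abs(null) >= abs(obs))) / (n_randomizations + 1.0)
    return RandTestResult(observed=obs, null_draws=null, p_empirical=float(p_emp), seed=seed)


def ami_regression(df: pd.DataFrame):
    """Least-squares fit of AMI ~ baseline rate x laminar location.

    ``df`` needs columns ``ami`` (float), ``rate`` (baseline firing rate,
    Hz) and ``layer`` (categorical). Returns the fitted statsmodels OLS
    results (coefficients for rate, layer contrasts and their interaction,
    R², residuals). Raises on rank deficiency (e.g. a single layer).
    """
    if df["layer"].nunique() < 2:
        raise ValueError("need >= 2 layers represented (layer contrasts collinear)")
    model = smf.ols("ami ~ rate * C(layer)", data=df)
    res = model.fit()
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return res
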
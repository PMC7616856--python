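"""Waveform classification, laminar assignment, opto-tagging, state labels.

Mean spike waveforms are normalized (tail-median offset removed, unit L2
norm), contaminants discarded (triphasic shapes with a stronger early than
late positive peak; DC drift between the beginning and end segments), and
the remainder embedded with 2-D t-SNE and split by fuzzy c-means into two
clusters, labelled narrow (NW) and broad (BW) by mean trough-to-peak
duration. Laminar compartments are assigned from the stimulus-evoked CSD
(earliest/strongest sink anchors the granular input layer) together with
per-channel spike-sign log-ratios separating outside-brain, gray-matter and
white-matter contacts. Opto-tagged units are those with a significant
pulse-locked response peaking between 1 and 10 ms; arousal/locomotion state
labels follow fixed pupil and running-speed thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.manifold import TSNE

from .config import LAYERS
from .sigproc import CSDProfile


@dataclass
class ClassLabel:
    unit_id: int
    label: str  # "NW" | "BW" | "excluded"
    membership: float = np.nan  # degree of the assigned cluster, in [0, 1]
    reason: str = ""


def normalize_waveform(trace: np.ndarray) -> np.ndarray:
    """Remove the tail-median offset and scale to unit L2 norm."""
    w = np.asarray(trace, dtype=float)
    if len(w) < 20:
        raise ValueError("waveform needs >= 20 samples")
    offset = np.median(np.concatenate([w[:10], w[-10:]]))
    w = w - offset
    nrm = np.linalg.norm(w)
    if nrm == 0:
        raise ValueError("all-zero waveform")
    return w / nrm


def trough_to_peak(trace: np.ndarray, fs: float = 30000.0) -> float:
    """Trough-to-peak duration in ms (trough = global minimum, peak = the
    subsequent maximum)."""
    w = np.asarray(trace, dtype=float)
    ti = int(np.argmin(w))
    if ti >= len(w) - 1:
        return 0.0
    pi = ti + int(np.argmax(w[ti:]))
    return (pi - ti) / fs * 1000.0


def exclude_waveforms(
    traces: np.ndarray, dc_tol: float | None = None
) -> tuple[np.ndarray, list[str]]:
    """Flag contaminant waveforms for exclusion.

    Returns ``(keep_mask, reasons)``. Excluded: "triphasic" if the positive
    peak before the trough exceeds the one after it; "DC" if the absolute
    difference between the means of the first and last 10 samples exceeds
    ``dc_tol`` (default: 3x the population SD of those tail segments).
    """
    arr = np.atleast_2d(np.asarray(traces, dtype=float))
    tails = np.concatenate([arr[:, :10], arr[:, -10:]], axis=1)
    if dc_tol is None:
        dc_tol = 3.0 * tails.std()
    keep = np.ones(len(arr), dtype=bool)
    reasons = [""] * len(arr)
    for i, w in enumerate(arr):
        ti = int(np.argmin(w))
        pre = w[:ti].max(initial=0.0)
        post = w[ti + 1 :].max(initial=0.0)
        if pre > post:
            keep[i] = False
            reasons[i] = "triphasic"
            continue
        if abs(w[:10].mean() - w[-10:].mean()) > dc_tol:
            keep[i] = False
            reasons[i] = "DC"
    return keep, reasons


def _fuzzy_cmeans(
    x: np.ndarray,
    n_clusters: int = 2,
    fuzzifier: float = 2.0,
    tol: float = 1e-10,
    max_iter: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Fuzzy c-means (Euclidean metric). Returns (memberships, centers)."""
    rng = rng if rng is not None else np.random.default_rng()
    n = len(x)
    u = rng.random((n, n_clusters))
    u /= u.sum(axis=1, keepdims=True)
    m = fuzzifier
    centers = np.zeros((n_clusters, x.shape[1]))
    for _ in range(max_iter):
        um = u**m
        centers = (um.T @ x) / um.sum(axis=0)[:, None]
        d2 = ((x[:, None, :] - centers[None]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1))
        u_new = inv / inv.sum(axis=1, keepdims=True)
        if np.max(np.abs(u_new - u)) < tol:
            u = u_new
            break
        u = u_new
    return u, centers


def classify_bw_nw(
    traces: np.ndarray,
    fs: float = 30000.0,
    perplexity: float = 30.0,
    fuzzifier: float = 2.0,
    tol: float = 1e-10,
    seed: int = 0,
) -> list[ClassLabel]:
    """Two-cluster waveform classification: t-SNE embedding + fuzzy c-means.

    Traces are normalized first (classification is invariant to amplitude
    and DC offset); contaminants are excluded with reasons. Perplexity is
    auto-reduced for small banks. The cluster with the shorter mean
    trough-to-peak duration is named NW.
    """
    arr = np.atleast_2d(np.asarray(traces, dtype=float))
    norm = np.array([normalize_waveform(w) for w in arr])
    keep, reasons = exclude_waveforms(norm)
    labels: list[ClassLabel] = [
        ClassLabel(unit_id=i, label="excluded", reason=reasons[i])
        for i in range(len(arr))
    ]
    idx = np.flatnonzero(keep)
    if len(idx) < 4:
        raise ValueError("too few non-excluded waveforms to cluster")
    x = norm[idx]
    if np.allclose(x, x[0]):
        raise ValueError("degenerate embedding: all waveforms identical")
    perp = min(perplexity, (len(idx) - 1) / 3.0)
    emb = TSNE(
        n_components=2, perplexity=perp, random_state=seed, init="pca"
    ).fit_transform(x)
    u, centers = _fuzzy_cmeans(
        emb, 2, fuzzifier, tol, rng=np.random.default_rng(seed)
    )
    hard = u.argmax(axis=1)
    ttp = np.array([trough_to_peak(w, fs) for w in x])
    mean_ttp = [ttp[hard == c].mean() if np.any(hard == c) else np.inf for c in (0, 1)]
    name = {int(np.argmin(mean_ttp)): "NW", int(np.argmax(mean_ttp)): "BW"}
    for j, i in enumerate(idx):
        labels[i] = ClassLabel(
            unit_id=int(i), label=name[int(hard[j])], membership=float(u[j].max())
        )
    return labels


def spike_sign_logratio(sign_counts: np.ndarray) -> np.ndarray:
    """log(n_positive / n_negative) per channel (with +1 regularization)."""
    c = np.asarray(sign_counts, dtype=float)
    return np.log((c[:, 0] + 1.0) / (c[:, 1] + 1.0))


def assign_layers(
    csd: CSDProfile,
    sign_counts: np.ndarray,
    sink_window: slice | None = None,
    outside_tol: float = 0.3,
    granular_halfwidth: int = 1,
) -> tuple[list[str], dict]:
    """Per-channel laminar compartment from evoked CSD + spike-sign counts.

    Channels with spike-sign log-ratio within ``outside_tol`` of zero are
    "outside" the brain; positive log-ratios are "white_matter"; negative
    log-ratios are gray matter. Within gray matter the channel of the
    strongest evoked sink anchors the granular compartment
    (± ``granular_halfwidth`` channels); gray-matter channels above it are
    superficial, below it deep. ``csd`` holds the plain second spatial
    difference of the LFP, in which a sink (focal extracellular
    negativity, physical CSD = -sigma * d2V/dz2 < 0) appears as a positive
    deflection; the anchor is therefore the channel with the largest
    positive evoked value. Returns the labels and a dict of the
    anchor/thresholds for manual override.
    """
    lr = spike_sign_logratio(sign_counts)
    n_ch = len(lr)
    labels = ["unassigned"] * n_ch
    gray = []
    for ch in range(n_ch):
        if abs(lr[ch]) <= outside_tol:
            labels[ch] = "outside"
        elif lr[ch] > 0:
            labels[ch] = "white_matter"
        else:
            gray.append(ch)
    prof = csd.values if sink_window is None else csd.values[:, sink_window]
    sink_per_channel = prof.max(axis=1)  # sink = positive second difference
    interior = {int(c): i for i, c in enumerate(csd.channel_ids)}
    candidates = [ch for ch in gray if ch in interior]
    if not candidates:
        return labels, {"anchor": None, "log_ratio": lr, "note": "no sink found"}
    anchor = max(candidates, key=lambda ch: sink_per_channel[interior[ch]])
    for ch in gray:
        if abs(ch - anchor) <= granular_halfwidth:
            labels[ch] = "granular"
        elif ch < anchor:
            labels[ch] = "superficial"
        else:
            labels[ch] = "deep"
    info = {"anchor": int(anchor), "log_ratio": lr, "outside_tol": outside_tol}
    return labels, info


def default_pulse_response_test(
    spikes: np.ndarray, pulses: np.ndarray, window: float = 0.5, bin_width: float = 0.01
) -> float:
    """Pluggable default significance test for pulse-locked modulation.

    Tests for any time-locked rate modulation within the post-pulse window
    (the role the ZETA test plays): pulse-aligned spike counts are binned
    at ``bin_width``, the maximal bin count is compared against the uniform
    Poisson expectation, Bonferroni-corrected over bins. Returns a p-value.
    """
    from scipy.stats import poisson as poisson_dist

    spikes = np.asarray(spikes)
    rel = []
    for p in pulses:
        sel = spikes[(spikes >= p) & (spikes < p + window)]
        rel.append(sel - p)
    rel = np.concatenate(rel) if rel else np.array([])
    if len(rel) == 0:
        return 1.0
    n_bins = int(round(window / bin_width))
    hist, _ = np.histogram(rel, bins=np.linspace(0, window, n_bins + 1))
    expected = len(rel) / n_bins
    p_max = poisson_dist.sf(hist.max() - 1, expected)
    return float(min(1.0, n_bins * p_max))


def optotag(
    spikes: np.ndarray,
    pulses: np.ndarray,
    significance_test=default_pulse_response_test,
    alpha: float = 0.05,
    bin_ms: float = 0.5,
) -> tuple[bool, dict]:
    """Opto-tag decision: significant pulse-locked response with peak
    latency in (1 ms, 10 ms]. Peaks earlier than 1 ms are laser artifacts
    and the unit is discarded (not tagged)."""
    pulses = np.asarray(pulses, dtype=float)
    if len(pulses) == 0:
        raise ValueError("no optogenetic pulses")
    p = significance_test(spikes, pulses)
    rel = []
    for t in pulses:
        s = np.asarray(spikes)
        sel = s[(s >= t) & (s < t + 0.05)]
        rel.append(sel - t)
    rel = np.concatenate(rel) if rel else np.array([])
    info = {"p": p, "peak_latency_ms": np.nan}
    if p >= alpha or len(rel) == 0:
        return False, info
    edges = np.arange(0, 50 + bin_ms, bin_ms) / 1000.0
    hist, _ = np.histogram(rel, bins=edges)
    peak_ms = (np.argmax(hist) + 0.5) * bin_ms
    info["peak_latency_ms"] = float(peak_ms)
    if peak_ms <= 1.0:
        info["artifact"] = True
        return False, info
    return bool(peak_ms <= 10.0), info


def detect_state(
    pupil: np.ndarray,
    speed: np.ndarray,
    arousal_high: tuple[float, float] = (0.65, 0.95),
    arousal_low: tuple[float, float] = (0.30, 0.55),
    speed_high: float = 5.0,
    speed_low: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Arousal and locomotion labels per sample.

    The pupil trace is normalized by its per-session maximum, then labelled
    "high" inside [0.65, 0.95] and "low" inside [0.30, 0.55]; running
    speed > 5 cm/s is "high" locomotion, < 1 cm/s "low"; anything between
    the bands stays unlabeled ("").
    """
    pupil = np.asarray(pupil, dtype=float)
    speed = np.asarray(speed, dtype=float)
    mx = pupil.max()
    if mx <= 0:
        raise ValueError("non-positive pupil maximum")
    p = pupil / mx
    arousal = np.full(len(p), "", dtype=object)
    arousal[(p >= arousal_high[0]) & (p <= arousal_high[1])] = "high"
    arousal[(p >= arousal_low[0]) & (p <= arousal_low[1])] = "low"
    loco = np.full(len(speed), "", dtype=object)
    loco[speed > speed_high] = "high"
    loco[speed < speed_low] = "low"
    return arousal, loco
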
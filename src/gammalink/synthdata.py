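"""Seeded generator of two-area laminar sessions with known ground truth.

The generator emulates the statistical structure the analysis stages
assume, not biophysics:

* sender-area LFP carries a stimulus-induced narrowband gamma process — a
  damped stochastic oscillator (AR(2) with its spectral pole at the
  condition's peak frequency) riding on 1/f background noise;
* receiver-area LFP is a lagged, layer-weighted copy of the sender gamma
  (granular layer strongest) plus independent noise;
* single units fire as inhomogeneous Poisson processes with intensity
  proportional to ``exp(kappa * cos(phase - phi0))``, with von Mises
  concentration ``kappa`` depending on cell class (NW > BW), layer
  (granular strongest) and attention condition (NW-only increase);
  receiver units lock to the sender's gamma with a preferred-phase offset;
* attention multiplies firing rates (strongest superficially, earliest in
  the receiver's superficial layer; sigmoid onset ramp) and reduces the SD
  of a slow shared multiplicative gain that induces noise correlations;
* a stimulus-evoked LFP transient with a spatial profile centered on the
  granular channel produces a CSD sink there, and per-channel spike-sign
  counts encode outside-brain / gray-matter / white-matter positions;
* mouse mode adds an LGN unit population (for surrogate-LFP analyses),
  pupil and running-speed traces, and optogenetic pulse trains driving
  tagged units at short latency.

All randomness flows from a single seeded ``numpy`` generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import hilbert, lfilter

from .config import (
    AREAS,
    CELL_CLASSES,
    CONDITIONS,
    LAYERS,
    SynthConfig,
    paper_like,
)
from .session import GroundTruth, Session

__all__ = [
    "gen_lfp_oscillation",
    "gen_spikes_phase_locked",
    "gen_session",
    "make_waveform",
    "make_waveform_bank",
    "one_over_f_noise",
    "paper_like",
]

# laminar channel map for a 16-contact shank (depth index 0 = most
# superficial contact, above the pia)
def layer_of_channel(depth_index: int, n_channels: int = 16) -> str:
    frac_map = [
        (2, "outside"),
        (7, "superficial"),
        (10, "granular"),
        (14, "deep"),
        (99, "white_matter"),
    ]
    scaled = depth_index * 16 / n_channels
    for bound, name in frac_map:
        if scaled < bound:
            return name
    return "white_matter"


GRANULAR_ANCHOR = 8  # depth index of the granular-center contact


def one_over_f_noise(
    n: int, fs: float, exponent: float = 1.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Gaussian noise with power spectrum ~ 1/f**exponent, unit variance."""
    rng = rng if rng is not None else np.random.default_rng()
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1 / fs)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _ar2_oscillation(
    f_peak: float, bandwidth: float, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance damped stochastic oscillator (AR(2) pole at f_peak)."""
    r = np.exp(-np.pi * bandwidth / fs)
    theta = 2 * np.pi * f_peak / fs
    a = [1.0, -2 * r * np.cos(theta), r**2]
    burn = min(n, int(5 * fs / (np.pi * bandwidth)) + 1)
    eps = rng.standard_normal(n + burn)
    x = lfilter([1.0], a, eps)[burn:]
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_lfp_oscillation(
    f_peak: float,
    bandwidth: float,
    power: float,
    duration: float,
    fs: float,
    seed: int | np.random.Generator | None = None,
    background: float = 1.0,
    return_components: bool = False,
):
    """Narrowband stochastic gamma plus 1/f background.

    The narrowband component is an AR(2) process whose spectrum peaks at
    ``f_peak`` with half-width ~``bandwidth``; its variance is ``power``.
    The 1/f background has variance ``background``. With
    ``return_components`` also returns the bare oscillation and its
    analytic (Hilbert) phase.
    """
    if not (0 < f_peak < fs / 2):
        raise ValueError(f"f_peak={f_peak} must lie in (0, Nyquist={fs/2})")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    osc = np.zeros(n)
    if power > 0:
        osc = np.sqrt(power) * _ar2_oscillation(f_peak, bandwidth, n, fs, rng)
    bg = np.sqrt(background) * one_over_f_noise(n, fs, 1.0, rng) if background > 0 else 0.0
    sig = osc + bg
    if return_components:
        phase = np.angle(hilbert(osc)) if power > 0 else np.full(n, np.nan)
        return sig, osc, phase
    return sig


def _sample_inhomogeneous_poisson(
    intensity: np.ndarray, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Spike times from per-sample rates (Hz): Poisson counts per bin,
    uniform jitter within the bin."""
    lam = np.clip(intensity, 0, None) / fs
    counts = rng.poisson(lam)
    idx = np.repeat(np.arange(len(lam)), counts)
    return np.sort((idx + rng.random(len(idx))) / fs)


def gen_spikes_phase_locked(
    phase_series: np.ndarray,
    mean_rate: float,
    kappa: float,
    pref_phase: float,
    fs: float,
    seed: int | np.random.Generator | None = None,
    gain: np.ndarray | None = None,
) -> np.ndarray:
    """Inhomogeneous-Poisson spikes with von Mises phase coupling.

    Intensity is proportional to ``exp(kappa*cos(phase - pref_phase))``,
    normalized so the time-averaged rate equals ``mean_rate`` (before the
    optional multiplicative ``gain`` envelope). Samples where the phase is
    NaN couple with weight 1 (no modulation).
    """
    if mean_rate < 0 or kappa < 0:
        raise ValueError("mean_rate and kappa must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    phase = np.asarray(phase_series, dtype=float)
    w = np.ones_like(phase)
    ok = np.isfinite(phase)
    w[ok] = np.exp(kappa * np.cos(phase[ok] - pref_phase))
    if ok.any():
        w[ok] /= w[ok].mean()
    lam = mean_rate * w
    if gain is not None:
        lam = lam * gain
    return _sample_inhomogeneous_poisson(lam, fs, rng)


# ---------------------------------------------------------------------------
# waveform templates


def make_waveform(
    kind: str,
    fs: float = 30000.0,
    n_samples: int = 90,
    noise: float = 0.02,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Mean-waveform template of a given family.

    ``narrow``/``broad``: biphasic, trough-to-peak 0.2 vs 0.5 ms.
    ``triphasic``: contaminant with a stronger early than late positive peak.
    ``dc``: contaminant with a DC offset between beginning and end.
    """
    rng = rng if rng is not None else np.random.default_rng()
    t = np.arange(n_samples) / fs * 1000.0  # ms
    t_trough = 1.0
    ttp = {"narrow": 0.2, "broad": 0.5}.get(kind, 0.35)
    w = -np.exp(-((t - t_trough) ** 2) / (2 * 0.07**2))
    peak_sd = 0.10 if kind == "narrow" else 0.22
    w += 0.45 * np.exp(-((t - t_trough - ttp) ** 2) / (2 * peak_sd**2))
    if kind == "triphasic":
        w += 0.9 * np.exp(-((t - (t_trough - 0.35)) ** 2) / (2 * 0.08**2))
    elif kind == "dc":
        w += 0.35 * t / t[-1]
    elif kind not in ("narrow", "broad"):
        raise ValueError(f"unknown waveform kind {kind!r}")
    return w + noise * rng.standard_normal(n_samples)


def make_waveform_bank(
    n_narrow: int = 100,
    n_broad: int = 100,
    n_triphasic: int = 0,
    n_dc: int = 0,
    noise: float = 0.02,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Bank of noisy waveform templates with ground-truth labels."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    traces, labels = [], []
    for kind, n in (
        ("narrow", n_narrow),
        ("broad", n_broad),
        ("triphasic", n_triphasic),
        ("dc", n_dc),
    ):
        for _ in range(n):
            amp = rng.uniform(40.0, 160.0)  # µV-scale amplitude diversity
            traces.append(amp * make_waveform(kind, noise=noise, rng=rng))
            labels.append(kind)
    return np.array(traces), labels


# ---------------------------------------------------------------------------
# session generation


def _slow_gaussian(n: int, fs: float, tau: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance AR(1) series with autocorrelation time ``tau``."""
    a = np.exp(-1.0 / (tau * fs))
    x = lfilter([np.sqrt(1 - a**2)], [1.0, -a], rng.standard_normal(n))
    return x


def _sigmoid_ramp(t: np.ndarray, onset: float, width: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(t - onset) / (width / 4.0)))


def _make_trials(cfg: SynthConfig, rng: np.random.Generator) -> pd.DataFrame:
    tt = cfg.trial_timing
    rows = []
    t = 0.5  # lead-in
    conds = np.array([CONDITIONS[i % 2] for i in range(cfg.n_trials)])
    rng.shuffle(conds)
    for i in range(cfg.n_trials):
        pre = rng.uniform(*tt["pre_stim"])
        cue = rng.uniform(*tt["cue_delay"])
        chg = rng.uniform(*tt["change_delay"])
        stim_onset = t + pre
        cue_onset = stim_onset + cue
        first_change = cue_onset + chg
        n_extra = int(rng.random() < 0.3)
        extra = first_change + rng.uniform(0.792, 1.331) if n_extra else np.nan
        end = first_change + tt["tail"]
        rows.append(
            {
                "trial": i,
                "start": t,
                "stim_onset": stim_onset,
                "cue_onset": cue_onset,
                "first_change": first_change,
                "change_2": extra,
                "condition": conds[i],
                "valid": True,
                "end": end,
            }
        )
        t = end + 0.1
    return pd.DataFrame(rows)


def _make_geometry(cfg: SynthConfig) -> pd.DataFrame:
    rows = []
    ch = 0
    for area in AREAS:
        for d in range(cfg.n_channels_per_shank):
            rows.append(
                {
                    "channel": ch,
                    "area": area,
                    "shank": 0 if area == "sender" else 1,
                    "depth_index": d,
                    "depth_um": d * cfg.channel_spacing,
                    "layer": layer_of_channel(d, cfg.n_channels_per_shank),
                }
            )
            ch += 1
    return pd.DataFrame(rows)


def _laminar_profile(n_ch: int, center: float, sd: float, peak: float) -> np.ndarray:
    d = np.arange(n_ch)
    return peak * np.exp(-((d - center) ** 2) / (2 * sd**2))


def _plan_units(cfg: SynthConfig, geometry: pd.DataFrame, rng: np.random.Generator):
    layer_channels = {
        (area, layer): geometry.query("area == @area and layer == @layer")[
            "channel"
        ].to_numpy()
        for area in AREAS
        for layer in LAYERS
    }
    rows = []
    uid = 0
    for area in AREAS:
        n_per = cfg.units_per_class_layer[area]
        for layer in LAYERS:
            for cls in CELL_CLASSES:
                for _ in range(n_per):
                    rows.append(
                        {
                            "unit_id": uid,
                            "area": area,
                            "layer": layer,
                            "cell_class": cls,
                            "channel": int(rng.choice(layer_channels[(area, layer)])),
                            "base_rate": rng.uniform(*cfg.base_rate_range),
                            "opto_tagged": bool(cfg.mouse_mode and cls == "NW" and area == "receiver"),
                        }
                    )
                    uid += 1
    return pd.DataFrame(rows)


def gen_session(config: SynthConfig | None = None) -> tuple[Session, GroundTruth]:
    """Generate one seeded two-area laminar session plus its ground truth."""
    cfg = config if config is not None else paper_like()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs

    trials = _make_trials(cfg, rng)
    geometry = _make_geometry(cfg)
    n_ch = cfg.n_channels_per_shank
    duration = float(trials["end"].iloc[-1] + 0.5)
    n_samp = int(round(duration * fs))
    times = np.arange(n_samp) / fs

    # --- sender gamma process: per-trial segments with condition-specific
    # peak frequency and power, Hilbert phase tracked for spike coupling
    gamma = np.zeros(n_samp, dtype=np.float32)
    phase = np.full(n_samp, np.nan, dtype=np.float32)
    for _, tr in trials.iterrows():
        i0 = int(round(tr["stim_onset"] * fs))
        i1 = min(int(round((tr["first_change"] + 0.1) * fs)), n_samp)
        seg_n = i1 - i0
        cond = tr["condition"]
        osc = _ar2_oscillation(cfg.gamma_peak[cond], cfg.gamma_bandwidth, seg_n, fs, rng)
        osc = np.sqrt(cfg.gamma_power[cond]) * osc
        taper = np.ones(seg_n)
        edge = int(0.05 * fs)
        taper[:edge] = np.sin(np.linspace(0, np.pi / 2, edge)) ** 2
        taper[-edge:] = np.sin(np.linspace(np.pi / 2, 0, edge)) ** 2
        gamma[i0:i1] = (osc * taper).astype(np.float32)
        phase[i0:i1] = np.angle(hilbert(osc)).astype(np.float32)

    lag_samp = int(round(cfg.feedforward_lag / 1000.0 * fs))
    gamma_lagged = np.zeros_like(gamma)
    if lag_samp > 0:
        gamma_lagged[lag_samp:] = gamma[:-lag_samp]
    else:
        gamma_lagged[:] = gamma

    # --- laminar LFP assembly
    lfp = np.zeros((2 * n_ch, n_samp), dtype=np.float32)
    send_profile = _laminar_profile(n_ch, GRANULAR_ANCHOR * n_ch / 16, 3.0, 1.0)
    recv_profile = _laminar_profile(n_ch, GRANULAR_ANCHOR * n_ch / 16, 2.0, 0.8)
    gray = np.array(
        [layer_of_channel(d, n_ch) in LAYERS for d in range(n_ch)]
    )
    noise_scale = np.where(gray, cfg.noise_sd, 0.25 * cfg.noise_sd)

    # stimulus-evoked transient -> CSD sink at the granular anchor
    evoked_t = np.zeros(n_samp, dtype=np.float32)
    kern_len = int(0.12 * fs)
    kt = np.arange(kern_len) / fs
    kernel = -np.exp(-((kt - 0.05) ** 2) / (2 * 0.012**2))
    for i0 in (trials["stim_onset"] * fs).round().astype(int):
        stop = min(kern_len, n_samp - i0)
        evoked_t[i0 : i0 + stop] += kernel[:stop]
    evoked_profile = _laminar_profile(n_ch, GRANULAR_ANCHOR * n_ch / 16, 1.2, 3.0)

    for area_i, (g, prof) in enumerate(
        ((gamma, send_profile), (gamma_lagged, recv_profile))
    ):
        base = area_i * n_ch
        for d in range(n_ch):
            w = prof[d] if gray[d] else 0.0
            ev = evoked_profile[d] if gray[d] else 0.0
            lfp[base + d] = (
                w * g
                + ev * evoked_t
                + noise_scale[d] * one_over_f_noise(n_samp, fs, 1.0, rng).astype(np.float32)
            )

    # per-channel spike-sign counts: gray matter negative-dominated,
    # outside balanced, white matter positive-dominated
    sign_counts = np.zeros((2 * n_ch, 2))  # columns: positive, negative
    for i, row in geometry.iterrows():
        layer = row["layer"]
        if layer in LAYERS:
            pos, neg = 200, 4000
        elif layer == "outside":
            pos, neg = 300, 300
        else:
            pos, neg = 900, 300
        sign_counts[row["channel"]] = rng.poisson([pos, neg])

    # --- shared slow gain (noise correlations), one series per area
    sd_series = np.full(n_samp, cfg.shared_gain_sd["away"], dtype=np.float32)
    for _, tr in trials.iterrows():
        i0 = int(round(tr["start"] * fs))
        i1 = min(int(round(tr["end"] * fs)), n_samp)
        sd_series[i0:i1] = cfg.shared_gain_sd[tr["condition"]]
    shared = {
        area: np.exp(
            sd_series * _slow_gaussian(n_samp, fs, cfg.shared_gain_tau, rng)
            - sd_series**2 / 2.0
        )
        for area in AREAS
    }

    # --- attention gain envelopes per (area, layer): sigmoid onset at
    # cue + latency in attend-toward trials only
    gain_env = {}
    for area in AREAS:
        for layer in LAYERS:
            env = np.ones(n_samp, dtype=np.float32)
            lat = cfg.attention_latency[(area, layer)]
            for _, tr in trials.iterrows():
                if tr["condition"] != "toward":
                    continue
                i0 = int(round(tr["cue_onset"] * fs))
                i1 = min(int(round(tr["end"] * fs)), n_samp)
                tloc = np.arange(i1 - i0) / fs
                g = cfg.attention_gain[(layer, "toward")]
                env[i0:i1] = 1.0 + (g - 1.0) * _sigmoid_ramp(tloc, lat, cfg.attention_ramp)
            gain_env[(area, layer)] = env

    # --- units
    units = _plan_units(cfg, geometry, rng)
    pref = cfg.preferred_phase
    spikes = []
    waveforms = []
    truth_rows = []
    # per-trial condition mask at sample resolution for kappa switching
    cond_is_toward = np.zeros(n_samp, dtype=bool)
    for _, tr in trials.iterrows():
        if tr["condition"] == "toward":
            i0 = int(round(tr["start"] * fs))
            i1 = min(int(round(tr["end"] * fs)), n_samp)
            cond_is_toward[i0:i1] = True

    for _, u in units.iterrows():
        area, layer, cls = u["area"], u["layer"], u["cell_class"]
        phi0 = pref["sender"] if area == "sender" else pref["sender"] + pref["receiver"]
        k_tow = cfg.coupling_kappa[(cls, layer, "toward")]
        k_away = cfg.coupling_kappa[(cls, layer, "away")]
        # von Mises modulation, normalized per gamma segment so the mean
        # rate within each stimulus period stays calibrated
        w = np.ones(n_samp, dtype=np.float32)
        for _, tr in trials.iterrows():
            i0 = int(round(tr["stim_onset"] * fs))
            i1 = min(int(round((tr["first_change"] + 0.1) * fs)), n_samp)
            k = k_tow if tr["condition"] == "toward" else k_away
            if k > 0:
                seg = np.exp(k * np.cos(phase[i0:i1] - phi0))
                w[i0:i1] = seg / seg.mean()
        lam = u["base_rate"] * w * gain_env[(area, layer)] * shared[area]
        st = _sample_inhomogeneous_poisson(lam.astype(float), fs, rng)
        spikes.append(st)
        waveforms.append(
            rng.uniform(40, 160) * make_waveform("narrow" if cls == "NW" else "broad", rng=rng)
        )
        truth_rows.append(
            {
                "unit_id": u["unit_id"],
                "area": area,
                "layer": layer,
                "cell_class": cls,
                "kappa_toward": k_tow,
                "kappa_away": k_away,
                "pref_phase": phi0,
                "rate_toward": u["base_rate"] * cfg.attention_gain[(layer, "toward")],
                "rate_away": u["base_rate"],
                "opto_tagged": u["opto_tagged"],
            }
        )

    extras: dict = {"spike_sign_counts": sign_counts}

    if cfg.mouse_mode:
        lgn = []
        for _ in range(cfg.n_lgn_units):
            lgn.append(
                gen_spikes_phase_locked(
                    phase, 15.0, 1.0, pref["sender"], fs, rng
                )
            )
        extras["lgn_spikes"] = lgn
        pupil_raw = _slow_gaussian(n_samp, fs, 5.0, rng)
        pupil = (pupil_raw - pupil_raw.min()) / (pupil_raw.max() - pupil_raw.min())
        extras["pupil"] = (0.2 + 0.8 * pupil).astype(np.float32)
        speed = np.clip(5.0 + 4.0 * _slow_gaussian(n_samp, fs, 3.0, rng), 0, None)
        extras["speed"] = speed.astype(np.float32)
        pulse_t0 = duration - 0.5 - 0.25 * cfg.n_opto_pulses
        pulses = pulse_t0 + 0.25 * np.arange(cfg.n_opto_pulses)
        extras["opto_pulses"] = pulses
        for i, u in units.iterrows():
            if u["opto_tagged"]:
                hit = pulses[rng.random(len(pulses)) < 0.9]
                resp = hit + np.clip(rng.normal(0.004, 0.001, size=len(hit)), 0.0015, 0.009)
                spikes[i] = np.sort(np.concatenate([spikes[i], resp]))

    sess = Session(
        lfp=lfp,
        fs=fs,
        geometry=geometry,
        spikes=spikes,
        units=units.drop(columns=["base_rate"]),
        trials=trials,
        waveforms=np.array(waveforms),
        extras=extras,
    )
    truth = GroundTruth(
        units=pd.DataFrame(truth_rows),
        session={
            "gamma_peak_toward": cfg.gamma_peak["toward"],
            "gamma_peak_away": cfg.gamma_peak["away"],
            "feedforward_lag_ms": cfg.feedforward_lag,
            "granular_channel_sender": GRANULAR_ANCHOR,
            "granular_channel_receiver": n_ch + GRANULAR_ANCHOR,
            "phase_offset": pref["receiver"],
            "seed": cfg.seed,
        },
        sender_phase=phase,
    )
    sess.validate()
    return sess, truth
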
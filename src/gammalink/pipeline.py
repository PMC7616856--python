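"""End-to-end orchestration of the analysis stages on one session.

Each helper runs one stage of the standard workflow on a
:class:`~gammalink.session.Session` (synthetic or user-supplied);
:func:`run_pipeline` chains them and writes tidy CSV tables, a JSON summary
and a run log. The qualitative pattern expected on the default generator
preset: NW (narrow-waveform) units in the receiver area phase-lock to the
sender's gamma while BW units do not; attention raises NW locking, firing
rates (superficial layers first) and sender gamma power, and lowers noise
correlations; spike rates decode the attention condition better than
LFP–LFP phase-locking measures; directed influence runs sender -> receiver.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import CONDITIONS, SynthConfig
from .connectivity import nonparametric_gc, time_reversal_control
from .decode import (
    FAMILY_BY_MODALITY,
    loo_accuracy,
    trial_plv,
    trial_relphase,
    trial_spikefield_ppc,
)
from .ratestats import ami, attn_difference_timecourse, noise_corr, xcorr_asymmetry_test
from .session import Session, load_session
from .sigproc import bandpass_hilbert, bipolar_derive, select_epoch_spikes
from .spectral import find_gamma_peak, lfp_lfp_ppc, multitaper_coeffs
from .spikefield import (
    circular_mean,
    ppc1,
    spike_phase_hilbert,
    spike_triggered_coeffs,
    wrap_angle,
)
from .stats import compare_spectra
from .synthdata import GRANULAR_ANCHOR, gen_session


DEFAULT_FREQS = np.arange(20.0, 102.0, 2.0)


def _granular_channel(session: Session, area: str) -> int:
    g = session.geometry
    sel = g[(g["area"] == area) & (g["layer"] == "granular")]
    mid = sel.iloc[len(sel) // 2]
    return int(mid["channel"])


def _stim_epochs(trials: pd.DataFrame, epoch_len: float = 0.5) -> list[tuple[float, float, str]]:
    """Non-overlapping epochs tiled between stimulus onset and first change."""
    out = []
    for _, tr in trials.iterrows():
        t = tr["stim_onset"]
        while t + epoch_len <= tr["first_change"]:
            out.append((t, t + epoch_len, tr["condition"]))
            t += epoch_len
    return out


def lfp_ppc_spectrum(session: Session, condition: str | None = None, epoch_len: float = 0.5):
    """Sender–receiver LFP–LFP PPC from tiled multitaper epochs."""
    trials = session.trials
    if condition is not None:
        trials = trials[trials["condition"] == condition]
    epochs = _stim_epochs(trials, epoch_len)
    ch_a = _granular_channel(session, "sender")
    ch_b = _granular_channel(session, "receiver")
    nsamp = int(round(epoch_len * session.fs))
    seg_a, seg_b = [], []
    for t0, _, _ in epochs:
        i0 = int(round(t0 * session.fs))
        seg_a.append(session.lfp[ch_a, i0 : i0 + nsamp])
        seg_b.append(session.lfp[ch_b, i0 : i0 + nsamp])
    ca = multitaper_coeffs(np.array(seg_a), session.fs, epoch_len)
    cb = multitaper_coeffs(np.array(seg_b), session.fs, epoch_len)
    return lfp_lfp_ppc(ca, cb)


def spikefield_ppc_table(
    session: Session,
    freqs: np.ndarray = DEFAULT_FREQS,
    min_spikes: int = 200,
    by_condition: bool = False,
    target_area: str = "receiver",
    lfp_area: str = "sender",
) -> pd.DataFrame:
    """PPC1 spectra of ``target_area`` units against a bipolar LFP of
    ``lfp_area`` (channel nearest the granular anchor), tidy per unit
    (and optionally per condition).

    Spikes are taken from the stimulus-onset-to-first-change period of each
    trial; units below ``min_spikes`` (per condition when split) are
    excluded, mirroring the standard inclusion rule.
    """
    bip, bip_geo = bipolar_derive(session.lfp, session.geometry)
    cand = bip_geo[bip_geo["area"] == lfp_area]
    # pick the bipolar derivative with the strongest gamma band (best SNR
    # for phase estimation; the granular-peak derivative is near zero)
    an = bandpass_hilbert(bip[cand["channel"].to_numpy()], session.fs, (40.0, 90.0))
    ch = int(cand.iloc[int(np.argmax((an.amplitude**2).mean(axis=1)))]["channel"])
    lfp = bip[ch]

    conds = CONDITIONS if by_condition else (None,)
    rows = []
    for ui in range(session.n_units):
        u = session.units.iloc[ui]
        if u["area"] != target_area:
            continue
        for cond in conds:
            trials = session.trials if cond is None else session.trials[
                session.trials["condition"] == cond
            ]
            sp, tid = [], []
            for _, tr in trials.iterrows():
                s = session.spikes[ui]
                sel = s[(s >= tr["stim_onset"]) & (s < tr["first_change"])]
                sp.append(sel)
                tid.append(np.full(len(sel), tr["trial"]))
            spikes = np.concatenate(sp)
            tids = np.concatenate(tid)
            if len(spikes) < max(min_spikes, 2):
                continue
            ps = spike_triggered_coeffs(
                lfp, session.fs, spikes, freqs, trial_ids=tids, unit_id=int(u["unit_id"])
            )
            try:
                spec = ppc1(ps, min_spikes=min_spikes, condition=cond)
            except ValueError:
                continue
            for f, v in zip(freqs, spec.values):
                rows.append(
                    {
                        "unit_id": int(u["unit_id"]),
                        "cell_class": u["cell_class"],
                        "layer": u["layer"],
                        "condition": cond if cond else "both",
                        "frequency": f,
                        "ppc1": v,
                        "n_spikes": spec.n_spikes,
                    }
                )
    return pd.DataFrame(rows)


def rate_table(session: Session) -> pd.DataFrame:
    """Per-unit condition rates (1 s pre-change window) and AMI."""
    rows = []
    for ui in range(session.n_units):
        u = session.units.iloc[ui]
        s = session.spikes[ui]
        rates = {}
        for cond in CONDITIONS:
            trials = session.trials[session.trials["condition"] == cond]
            counts = [
                np.sum((s >= tr["first_change"] - 1.0) & (s < tr["first_change"]))
                for _, tr in trials.iterrows()
            ]
            rates[cond] = float(np.mean(counts))
        idx = ami(s, session.trials)
        rows.append(
            {
                "unit_id": int(u["unit_id"]),
                "area": u["area"],
                "cell_class": u["cell_class"],
                "layer": u["layer"],
                "rate_toward": rates["toward"],
                "rate_away": rates["away"],
                "ami": idx.value,
            }
        )
    return pd.DataFrame(rows)


def decode_features(session: Session, band: tuple[float, float] = (40.0, 90.0)) -> pd.DataFrame:
    """Per-trial features for the five decoding modalities.

    The decoding epoch is the 1 s before the first luminance change. LFP
    features use the gamma-band analytic signals of the granular sender and
    receiver channels; spike features pool the receiver units' spikes.
    """
    fs = session.fs
    ch_a = _granular_channel(session, "sender")
    ch_b = _granular_channel(session, "receiver")
    an = bandpass_hilbert(session.lfp[[ch_a, ch_b]], fs, band)
    va, vb = an.values[0], an.values[1]
    recv_units = session.area_units("receiver")

    rows = []
    for _, tr in session.trials.iterrows():
        t1 = tr["first_change"]
        i0, i1 = int(round((t1 - 1.0) * fs)), int(round(t1 * fs))
        ea, eb = va[i0:i1], vb[i0:i1]
        pooled = np.concatenate(
            [select_epoch_spikes(session.spikes[ui], t1, (-1.0, 0.0)) + t1 for ui in recv_units]
        )
        sp_idx = np.round(pooled * fs).astype(int)
        sp_idx = sp_idx[(sp_idx >= 0) & (sp_idx < len(va))]
        phases = np.angle(va[sp_idx])
        row = {
            "trial": int(tr["trial"]),
            "condition": tr["condition"],
            "lfp_plv": trial_plv(ea, eb),
            "lfp_relphase": trial_relphase(ea, eb),
            "spike_ppc": trial_spikefield_ppc(phases) if len(phases) >= 2 else np.nan,
            "spike_phase": circular_mean(phases) if len(phases) else np.nan,
        }
        for k, ui in enumerate(recv_units):
            s = session.spikes[ui]
            row[f"rate_{k}"] = float(np.sum((s >= t1 - 1.0) & (s < t1)))
        rows.append(row)
    return pd.DataFrame(rows)


def decode_accuracies(session: Session, seed: int = 0) -> dict:
    """Leave-one-out decoding accuracy per modality.

    Rates use the population of receiver units (product posterior); the
    LFP–LFP and pooled spike-PPC modalities are one signal per trial. The
    spike-phase modality follows the per-SU-LFP-pair treatment: each unit's
    per-trial mean phase of spiking is decoded on its own and the mean
    single-unit accuracy is reported.
    """
    feats = decode_features(session)
    labels = feats["condition"].to_numpy()
    rate_cols = [c for c in feats.columns if c.startswith("rate_")]
    out = {
        "rate": loo_accuracy(feats[rate_cols].to_numpy(), labels, "poisson", seed=seed)
    }
    for mod in ("lfp_plv", "lfp_relphase", "spike_ppc"):
        vals = feats[mod].to_numpy()
        ok = np.isfinite(vals)
        out[mod] = loo_accuracy(vals[ok], labels[ok], FAMILY_BY_MODALITY[mod], seed=seed)
    out["spike_phase"] = float(
        np.mean(_per_unit_spike_phase_accuracies(session, seed=seed))
    )
    out["n_trials"] = int(len(labels))
    return out


def _per_unit_spike_phase_accuracies(
    session: Session, band: tuple[float, float] = (40.0, 90.0), seed: int = 0
) -> list[float]:
    fs = session.fs
    ch_a = _granular_channel(session, "sender")
    va = bandpass_hilbert(session.lfp[[ch_a]], fs, band).values[0]
    labels = session.trials["condition"].to_numpy()
    accs = []
    for ui in session.area_units("receiver"):
        s = session.spikes[ui]
        phases = np.full(len(labels), np.nan)
        for i, (_, tr) in enumerate(session.trials.iterrows()):
            t1 = tr["first_change"]
            sel = s[(s >= t1 - 1.0) & (s < t1)]
            idx = np.round(sel * fs).astype(int)
            if len(idx):
                phases[i] = circular_mean(np.angle(va[idx]))
        ok = np.isfinite(phases)
        try:
            accs.append(loo_accuracy(phases[ok], labels[ok], "vonmises", seed=seed))
        except ValueError:
            continue
    return accs


def phase_offset_recovery(session: Session, band: tuple[float, float] = (40.0, 90.0)) -> dict:
    """Sender–receiver spike-phase offset (feedforward analogue).

    Computes each gamma-locked (NW) unit's circular mean phase of spiking
    in the sender area's gamma (mean analytic phase across sender
    gray-matter channels), then the wrapped difference of the circular
    means of receiver vs sender unit phases.
    """
    g = session.geometry
    sender_gray = g[(g["area"] == "sender") & (g["layer"].isin(["superficial", "granular", "deep"]))][
        "channel"
    ].to_numpy()
    an = bandpass_hilbert(session.lfp[sender_gray], session.fs, band)
    unit_phase = {}
    for ui in range(session.n_units):
        u = session.units.iloc[ui]
        if u["cell_class"] != "NW":
            continue
        # spikes in stimulus periods only (phase is defined there)
        sp = []
        for _, tr in session.trials.iterrows():
            s = session.spikes[ui]
            sp.append(s[(s >= tr["stim_onset"]) & (s < tr["first_change"])])
        spikes = np.concatenate(sp)
        _, mean_ph = spike_phase_hilbert(an.values, session.fs, spikes)
        unit_phase[ui] = (u["area"], mean_ph)
    send = [p for a, p in unit_phase.values() if a == "sender"]
    recv = [p for a, p in unit_phase.values() if a == "receiver"]
    diff = wrap_angle(circular_mean(np.array(recv)) - circular_mean(np.array(send)))
    return {
        "offset": float(diff),
        "n_sender_units": len(send),
        "n_receiver_units": len(recv),
    }


def gc_between_areas(session: Session, window: float = 0.5) -> dict:
    """Nonparametric GC between pooled-area MU count series, with the
    time-reversal control."""
    fs = 1000.0
    segs = {0: [], 1: []}
    nwin = int(round(window * fs))
    for _, tr in session.trials.iterrows():
        t = tr["stim_onset"] + 0.1
        while t + window <= tr["first_change"]:
            for k, area in enumerate(("sender", "receiver")):
                counts = np.zeros(nwin)
                for ui in session.area_units(area):
                    s = session.spikes[ui]
                    sel = s[(s >= t) & (s < t + window)]
                    idx = np.floor((sel - t) * fs).astype(int)
                    np.add.at(counts, np.clip(idx, 0, nwin - 1), 1.0)
                segs[k].append(counts)
            t += window
    series = np.stack([np.stack(segs[0]), np.stack(segs[1])])  # (2, nseg, nwin)
    gc = nonparametric_gc(series, fs, window)
    rev = time_reversal_control(series, fs, window)
    band = (gc.freqs >= 30) & (gc.freqs <= 90)
    return {
        "freqs": gc.freqs,
        "gc_fwd": gc.gc[(0, 1)],
        "gc_bwd": gc.gc[(1, 0)],
        "band_fwd": float(gc.gc[(0, 1)][band].mean()),
        "band_bwd": float(gc.gc[(1, 0)][band].mean()),
        "band_fwd_rev": float(rev.gc[(0, 1)][band].mean()),
        "band_bwd_rev": float(rev.gc[(1, 0)][band].mean()),
        "diagnostics": gc.diagnostics,
    }


def latency_contrast(
    session: Session, pop_a: str = "superficial", pop_b: str = "granular", seed: int = 0
):
    """Attentional-latency contrast between two receiver-unit populations
    via cross-correlation asymmetry of cue-locked difference time-courses.

    Only positively attention-modulated units enter (standard exclusion).
    A negative asymmetry means population A leads.
    """
    traces = {pop_a: [], pop_b: []}
    rt = rate_table(session)
    for ui in range(session.n_units):
        u = session.units.iloc[ui]
        if u["area"] != "receiver" or u["layer"] not in traces:
            continue
        if rt.loc[rt["unit_id"] == u["unit_id"], "ami"].iloc[0] <= 0:
            continue
        t, d = attn_difference_timecourse(session.spikes[ui], session.trials)
        sel = (t >= 0.05) & (t <= 0.5)
        traces[u["layer"]].append(d[sel])
    return xcorr_asymmetry_test(
        np.array(traces[pop_a]), np.array(traces[pop_b]), seed=seed
    )


def noise_correlation_by_condition(session: Session, area: str = "receiver") -> dict:
    """Mean pairwise chunked noise correlation of unit counts (0.5 s
    pre-change window) per condition."""
    out = {}
    units = session.area_units(area)
    for cond in CONDITIONS:
        trials = session.trials[session.trials["condition"] == cond]
        counts = np.zeros((len(units), len(trials)))
        for k, ui in enumerate(units):
            s = session.spikes[ui]
            counts[k] = [
                np.sum((s >= tr["first_change"] - 0.5) & (s < tr["first_change"]))
                for _, tr in trials.iterrows()
            ]
        r = noise_corr(counts)
        iu = np.triu_indices(len(units), k=1)
        out[cond] = float(np.nanmean(r[iu]))
    return out


@dataclass
class PipelineConfig:
    stages: list = field(
        default_factory=lambda: [
            "rates",
            "spikefield",
            "lfp_ppc",
            "decode",
            "gc",
            "latency",
            "noisecorr",
            "phase_offset",
        ]
    )
    input_path: str | None = None  # session HDF5; None -> generate synthetic
    out_dir: str = "pipeline_out"
    seed: int = 0
    synth: dict = field(default_factory=dict)  # SynthConfig overrides


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages, write CSV/JSON outputs, return the summary."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cfg.input_path:
        session, _ = load_session(cfg.input_path)
    else:
        session, _ = gen_session(SynthConfig(seed=cfg.seed, **cfg.synth))

    summary: dict = {"seed": cfg.seed, "stages": list(cfg.stages)}
    log = {
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": cfg.seed,
        "stages_run": [],
        "skipped": {},
    }
    for stage in cfg.stages:
        try:
            if stage == "rates":
                rt = rate_table(session)
                rt.to_csv(out_dir / "rates.csv", index=False)
                grp = rt[rt["area"] == "receiver"].groupby(["cell_class", "layer"])["ami"].mean()
                summary["ami_by_class_layer"] = {
                    "|".join(k): float(v) for k, v in grp.items()
                }
            elif stage == "spikefield":
                sf = spikefield_ppc_table(session, by_condition=True)
                sf.to_csv(out_dir / "spikefield_ppc.csv", index=False)
                peak = {}
                for cls in ("NW", "BW"):
                    sel = sf[sf["cell_class"] == cls]
                    if len(sel):
                        peak[cls] = float(
                            sel.groupby("frequency")["ppc1"].mean().max()
                        )
                summary["spikefield_peak_ppc"] = peak
            elif stage == "lfp_ppc":
                sp = lfp_ppc_spectrum(session)
                pd.DataFrame(
                    {"frequency": sp.freqs, "ppc": sp.values, "n": sp.n}
                ).to_csv(out_dir / "lfp_ppc.csv", index=False)
                summary["lfp_gamma_peak"] = find_gamma_peak(sp.freqs, sp.values)
            elif stage == "decode":
                acc = decode_accuracies(session, seed=cfg.seed)
                summary["decode_accuracy"] = acc
                pd.DataFrame([acc]).to_csv(out_dir / "decode_accuracy.csv", index=False)
            elif stage == "gc":
                gc = gc_between_areas(session)
                pd.DataFrame(
                    {"frequency": gc["freqs"], "gc_fwd": gc["gc_fwd"], "gc_bwd": gc["gc_bwd"]}
                ).to_csv(out_dir / "granger.csv", index=False)
                summary["gc_band"] = {
                    k: gc[k] for k in ("band_fwd", "band_bwd", "band_fwd_rev", "band_bwd_rev")
                }
            elif stage == "latency":
                res = latency_contrast(session, seed=cfg.seed)
                summary["latency_asymmetry"] = {
                    "asymmetry": float(res.observed),
                    "p_empirical": res.p_empirical,
                }
            elif stage == "noisecorr":
                summary["noise_correlation"] = noise_correlation_by_condition(session)
            elif stage == "phase_offset":
                summary["phase_offset"] = phase_offset_recovery(session)
            log["stages_run"].append(stage)
        except (ValueError, KeyError) as exc:  # missing inputs -> skip, log
            log["skipped"][stage] = str(exc)

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))
    return summary
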
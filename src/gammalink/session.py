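"""Session containers and HDF5 serialization.

A :class:`Session` bundles everything the analysis stages consume: the LFP
matrix with its channel geometry, per-unit spike trains with metadata and
mean waveforms, and the trial table. :class:`GroundTruth` carries the
generator's drawn parameters (coupling, preferred phases, rates, layers,
lags) for parameter-recovery tests; it is absent for real recordings.

On disk a session is a single HDF5 file with groups ``/lfp``, ``/geometry``,
``/units``, ``/trials``, ``/extras`` and (optionally) ``/groundtruth``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


@dataclass
class Session:
    lfp: np.ndarray  # (channels, samples)
    fs: float
    geometry: pd.DataFrame  # channel, area, shank, depth_index, depth_um
    spikes: list  # list of np.ndarray spike times (s), index = unit row
    units: pd.DataFrame  # unit_id, area, channel, cell_class, layer, opto_tagged
    trials: pd.DataFrame  # stim_onset, cue_onset, first_change, condition, valid
    waveforms: np.ndarray | None = None  # (n_units, n_samples) mean waveforms
    waveform_fs: float = 30000.0
    extras: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return self.lfp.shape[1] / self.fs

    @property
    def n_units(self) -> int:
        return len(self.spikes)

    def validate(self) -> None:
        if not np.all(np.isfinite(self.lfp)):
            raise ValueError("LFP contains non-finite samples")
        chans = set(self.geometry["channel"])
        for ch in self.units["channel"]:
            if ch not in chans:
                raise ValueError(f"unit channel {ch} missing from geometry")
        for st in self.spikes:
            if len(st) and (st.min() < 0 or st.max() > self.duration):
                raise ValueError("spike times outside recording span")
        t = self.trials
        if not np.all((t["stim_onset"] < t["cue_onset"]) & (t["cue_onset"] < t["first_change"])):
            raise ValueError("trial events must be ordered stim < cue < first change")

    def area_channels(self, area: str) -> np.ndarray:
        return self.geometry.loc[self.geometry["area"] == area, "channel"].to_numpy()

    def area_units(self, area: str) -> np.ndarray:
        return np.flatnonzero((self.units["area"] == area).to_numpy())


@dataclass
class GroundTruth:
    units: pd.DataFrame  # kappa/rate per condition, pref_phase, layer, class
    session: dict  # gamma peaks, lag, granular channels, phase offset, ...
    sender_phase: np.ndarray | None = None  # per-sample phase (NaN off-stimulus)


def _write_df(grp: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        vals = df[col].to_numpy()
        if vals.dtype == object or vals.dtype.kind in "US":
            grp.create_dataset(col, data=np.asarray(vals, dtype="S"))
        else:
            grp.create_dataset(col, data=vals)
    grp.attrs["columns"] = list(df.columns)


def _read_df(grp: h5py.Group) -> pd.DataFrame:
    cols = list(grp.attrs["columns"])
    data = {}
    for col in cols:
        vals = grp[col][()]
        if vals.dtype.kind == "S":
            vals = vals.astype(str)
        data[col] = vals
    return pd.DataFrame(data)


def save_session(path: str | Path, session: Session, truth: GroundTruth | None = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("lfp")
        g.create_dataset("data", data=session.lfp.astype(np.float32), compression="gzip")
        g.attrs["fs"] = session.fs
        _write_df(f.create_group("geometry"), session.geometry)
        ug = f.create_group("units")
        _write_df(ug.create_group("meta"), session.units)
        sg = ug.create_group("spikes")
        for i, st in enumerate(session.spikes):
            sg.create_dataset(str(i), data=np.asarray(st, dtype=float))
        if session.waveforms is not None:
            ug.create_dataset("waveforms", data=session.waveforms)
            ug.attrs["waveform_fs"] = session.waveform_fs
        _write_df(f.create_group("trials"), session.trials)
        eg = f.create_group("extras")
        for k, v in session.extras.items():
            if isinstance(v, list):
                sub = eg.create_group(k)
                for i, arr in enumerate(v):
                    sub.create_dataset(str(i), data=np.asarray(arr, dtype=float))
            else:
                eg.create_dataset(k, data=np.asarray(v))
        if truth is not None:
            tg = f.create_group("groundtruth")
            _write_df(tg.create_group("units"), truth.units)
            meta = tg.create_group("session")
            for k, v in truth.session.items():
                meta.attrs[k] = v
            if truth.sender_phase is not None:
                tg.create_dataset("sender_phase", data=truth.sender_phase.astype(np.float32))


def load_session(path: str | Path) -> tuple[Session, GroundTruth | None]:
    with h5py.File(path, "r") as f:
        lfp = f["lfp/data"][()]
        fs = float(f["lfp"].attrs["fs"])
        geometry = _read_df(f["geometry"])
        units = _read_df(f["units/meta"])
        sg = f["units/spikes"]
        spikes = [sg[str(i)][()] for i in range(len(sg))]
        waveforms = f["units/waveforms"][()] if "waveforms" in f["units"] else None
        wf_fs = float(f["units"].attrs.get("waveform_fs", 30000.0))
        trials = _read_df(f["trials"])
        extras = {}
        for k, v in f["extras"].items():
            if isinstance(v, h5py.Group):
                extras[k] = [v[str(i)][()] for i in range(len(v))]
            else:
                extras[k] = v[()]
        truth = None
        if "groundtruth" in f:
            tg = f["groundtruth"]
            truth = GroundTruth(
                units=_read_df(tg["units"]),
                session=dict(tg["session"].attrs),
                sender_phase=tg["sender_phase"][()] if "sender_phase" in tg else None,
            )
    sess = Session(
        lfp=lfp, fs=fs, geometry=geometry, spikes=spikes, units=units,
        trials=trials, waveforms=waveforms, waveform_fs=wf_fs, extras=extras,
    )
    return sess, truth


def export_trials_csv(session: Session, path: str | Path) -> None:
    session.trials.to_csv(path, index=False)
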
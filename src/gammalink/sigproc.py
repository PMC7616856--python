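"""Continuous-signal preprocessing for laminar LFP recordings.

Shank re-referencing, bipolar derivation, zero-phase band-pass filtering with
analytic-signal (Hilbert) phase, current-source-density profiles, surrogate
LFP from population spiking, and event-locked epoch selection.

Conventions: times in seconds; epochs are half-open ``[event+w0, event+w1)``;
bipolar derivatives are deeper minus shallower contact and inherit the
midpoint depth; LFP matrices are ``(channels, samples)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal


@dataclass
class AnalyticSignal:
    """Complex band-limited analytic signal per channel.

    ``values`` is ``(channels, samples)`` complex; ``band`` the pass band in
    Hz; ``order`` the Butterworth design order (two-way applied).
    """

    values: np.ndarray
    band: tuple[float, float]
    order: int
    fs: float

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)


@dataclass
class CSDProfile:
    """Current source density (second spatial derivative of the LFP).

    ``values`` is ``(channels-2, time)`` per shank in µV/µm² up to sign
    convention (sinks negative); ``channel_ids`` the interior channels the
    rows correspond to; ``interpolated`` marks channels replaced by linear
    interpolation before differencing.
    """

    values: np.ndarray
    channel_ids: np.ndarray
    spacing: float
    interpolated: np.ndarray


def _shank_groups(geometry: pd.DataFrame):
    for (_, _), grp in geometry.groupby(["area", "shank"], sort=False):
        yield grp


def shank_rereference(lfp: np.ndarray, geometry: pd.DataFrame) -> np.ndarray:
    """Subtract the per-shank average LFP from each channel of the shank.

    Removes common-mode reference/headstage noise. Geometry rows index into
    ``lfp`` via their ``channel`` column.
    """
    out = np.array(lfp, dtype=float, copy=True)
    for grp in _shank_groups(geometry):
        ch = grp["channel"].to_numpy()
        if len(ch) < 2:
            raise ValueError("shank with a single channel cannot be re-referenced")
        out[ch] -= out[ch].mean(axis=0, keepdims=True)
    return out


def bipolar_derive(
    lfp: np.ndarray, geometry: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Adjacent-contact bipolar derivatives per shank (deep minus superficial).

    Suppresses the common reference and 1/f far-field components when
    estimating local gamma phase. Returns the derived ``(channels', samples)``
    matrix and a geometry table with midpoint depths; channel count per
    shank drops by one.
    """
    rows = []
    chunks = []
    new_ch = 0
    for grp in _shank_groups(geometry):
        grp = grp.sort_values("depth_index")
        d = grp["depth_index"].to_numpy()
        if np.any(np.diff(d) <= 0):
            raise ValueError("geometry depth_index must be strictly ordered within shank")
        ch = grp["channel"].to_numpy()
        deep = lfp[ch[1:]]
        shallow = lfp[ch[:-1]]
        chunks.append(deep - shallow)
        for i in range(len(ch) - 1):
            rows.append(
                {
                    "channel": new_ch,
                    "area": grp["area"].iloc[0],
                    "shank": grp["shank"].iloc[0],
                    "depth_index": (d[i] + d[i + 1]) / 2.0,
                    "src_deep": ch[i + 1],
                    "src_shallow": ch[i],
                }
            )
            new_ch += 1
    return np.concatenate(chunks, axis=0), pd.DataFrame(rows)


def bandpass_hilbert(
    lfp: np.ndarray, fs: float, band: tuple[float, float], order: int = 12
) -> AnalyticSignal:
    """Two-way Butterworth band-pass followed by the Hilbert transform.

    The filter is designed at the given order per band edge (an order-12
    design yields a 24th-order band-pass, applied forward and backward for
    zero phase) and realized as second-order sections for stability. Apply
    to complete trials/recordings, then select epochs.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} outside (0, Nyquist={fs/2})")
    arr = np.atleast_2d(np.asarray(lfp, dtype=float))
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, arr, axis=-1)
    analytic = signal.hilbert(filt, axis=-1)
    values = analytic if lfp.ndim > 1 else analytic[0]
    return AnalyticSignal(values=values, band=(lo, hi), order=order, fs=fs)


def compute_csd(
    evoked_lfp: np.ndarray,
    spacing: float,
    bad_channels: list[int] | None = None,
) -> CSDProfile:
    """CSD as the second discrete spatial depth derivative of the LFP.

    ``evoked_lfp`` is ``(channels, time)`` for one shank ordered by depth.
    Low-SNR channels listed in ``bad_channels`` (row indices) are replaced by
    linear interpolation of their neighbors before differencing; they may
    not sit at the shank edges. ``CSD(i) = (V(i-1) - 2 V(i) + V(i+1)) / h^2``.
    """
    v = np.array(evoked_lfp, dtype=float, copy=True)
    n_ch = v.shape[0]
    if n_ch < 3:
        raise ValueError("need >= 3 channels for a CSD")
    interp = np.zeros(n_ch, dtype=bool)
    for b in sorted(bad_channels or []):
        if b <= 0 or b >= n_ch - 1:
            raise ValueError(f"bad channel {b} at shank edge cannot be interpolated")
        v[b] = 0.5 * (v[b - 1] + v[b + 1])
        interp[b] = True
    csd = (v[:-2] - 2 * v[1:-1] + v[2:]) / spacing**2
    return CSDProfile(
        values=csd,
        channel_ids=np.arange(1, n_ch - 1),
        spacing=spacing,
        interpolated=interp,
    )


def surrogate_lfp(
    spike_trains: list[np.ndarray],
    duration: float,
    fs: float = 1000.0,
    band: tuple[float, float] = (1.0, 100.0),
    min_units: int = 10,
    override_min_units: bool = False,
) -> np.ndarray:
    """Surrogate LFP from summed population spiking (e.g. LGN).

    Nuclei without columnar structure produce no usable LFP; the summed
    spike-count series of all isolated units, binned at 1 ms and band-passed
    1–100 Hz, serves as the population oscillation reference. Sessions with
    fewer than ``min_units`` units are rejected unless overridden.
    """
    if len(spike_trains) < min_units and not override_min_units:
        raise ValueError(
            f"only {len(spike_trains)} units; >= {min_units} required for a surrogate LFP"
        )
    n = int(round(duration * fs))
    counts = np.zeros(n)
    for st in spike_trains:
        idx = np.floor(np.asarray(st) * fs).astype(int)
        idx = idx[(idx >= 0) & (idx < n)]
        np.add.at(counts, idx, 1.0)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, counts)


def select_epoch_series(
    series: np.ndarray, fs: float, event: float, window: tuple[float, float]
) -> np.ndarray:
    """Half-open sample slice ``[event+w0, event+w1)`` of a continuous series."""
    i0 = int(round((event + window[0]) * fs))
    i1 = int(round((event + window[1]) * fs))
    n = series.shape[-1]
    if i0 < 0 or i1 > n:
        raise ValueError("epoch window exceeds recording bounds")
    return series[..., i0:i1]


def select_epoch_spikes(
    spikes: np.ndarray, event: float, window: tuple[float, float]
) -> np.ndarray:
    """Event-relative spike times within the half-open window."""
    spikes = np.asarray(spikes, dtype=float)
    t0, t1 = event + window[0], event + window[1]
    sel = spikes[(spikes >= t0) & (spikes < t1)]
    return sel - event
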
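"""Configuration for the synthetic two-area laminar session generator.

The defaults constitute the "paper-like" preset: a macaque-style attention
session with a gamma-generating sender area ("V1"), a receiver area ("V4")
whose LFP carries a lagged, layer-weighted copy of the sender gamma, and
single units whose gamma phase locking depends on cell class (NW > BW) and
layer (granular strongest). Attention (attend-toward vs attend-away)
multiplies firing rates (strongest superficially, earliest in the receiver's
superficial layer), raises NW phase-locking only, increases sender gamma
power and peak frequency, and reduces slow shared rate co-fluctuations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

CONDITIONS = ("toward", "away")
CELL_CLASSES = ("NW", "BW")
LAYERS = ("superficial", "granular", "deep")
COMPARTMENTS = LAYERS + ("outside", "white_matter")
AREAS = ("sender", "receiver")


def _default_gamma_peak() -> dict:
    return {"toward": 63.0, "away": 60.0}


def _default_gamma_power() -> dict:
    return {"toward": 1.2, "away": 1.0}


def _default_kappa() -> dict:
    # kappa[(cell_class, layer, condition)]; NW locks (granular strongest),
    # BW does not; attention raises NW coupling only (factor 1.4, a free
    # parameter of the generator).
    away = {"superficial": 0.8, "granular": 1.2, "deep": 0.6}
    table = {}
    for layer in LAYERS:
        table[("NW", layer, "away")] = away[layer]
        table[("NW", layer, "toward")] = 1.4 * away[layer]
        table[("BW", layer, "away")] = 0.0
        table[("BW", layer, "toward")] = 0.0
    return table


def _default_attention_gain() -> dict:
    gain = {"superficial": 1.35, "granular": 1.2, "deep": 1.15}
    table = {}
    for layer in LAYERS:
        table[(layer, "toward")] = gain[layer]
        table[(layer, "away")] = 1.0
    return table


def _default_attention_latency() -> dict:
    # seconds after cue onset; attention arrives first in the receiver's
    # superficial compartment
    return {
        ("receiver", "superficial"): 0.15,
        ("receiver", "granular"): 0.35,
        ("receiver", "deep"): 0.35,
        ("sender", "superficial"): 0.35,
        ("sender", "granular"): 0.35,
        ("sender", "deep"): 0.35,
    }


def _default_shared_gain_sd() -> dict:
    return {"toward": 0.10, "away": 0.22}


def _default_trial_timing() -> dict:
    # seconds: fixed pre-stimulus delay, then uniform stimulus->cue and
    # cue->first-change delays (macaque-T-style task timing)
    return {
        "pre_stim": (0.614, 0.614),
        "cue_delay": (0.618, 1.131),
        "change_delay": (1.162, 2.133),
        "tail": 0.4,
    }


def _default_units_per_cell() -> int:
    return 4


@dataclass
class SynthConfig:
    """Parameters of the synthetic two-area laminar session generator."""

    n_trials: int = 100
    fs: float = 1000.0
    n_channels_per_shank: int = 16
    channel_spacing: float = 150.0  # µm
    gamma_peak: dict = field(default_factory=_default_gamma_peak)  # Hz per condition
    gamma_bandwidth: float = 4.0  # Hz half-width of the sender gamma peak
    gamma_power: dict = field(default_factory=_default_gamma_power)
    feedforward_lag: float = 4.0  # ms, sender->receiver LFP propagation
    coupling_kappa: dict = field(default_factory=_default_kappa)
    preferred_phase: dict = field(
        default_factory=lambda: {"sender": 0.0, "receiver": 1.51}
    )  # radians; receiver offset mirrors the feedforward spike-phase shift
    base_rate_range: tuple = (8.0, 15.0)  # Hz, per-unit uniform draw
    attention_gain: dict = field(default_factory=_default_attention_gain)
    attention_latency: dict = field(default_factory=_default_attention_latency)
    attention_ramp: float = 0.05  # s, sigmoid width of the gain onset
    shared_gain_sd: dict = field(default_factory=_default_shared_gain_sd)
    shared_gain_tau: float = 0.2  # s, autocorrelation time of the shared gain
    trial_timing: dict = field(default_factory=_default_trial_timing)
    units_per_class_layer: dict = field(
        default_factory=lambda: {"receiver": 4, "sender": 2}
    )
    noise_sd: float = 0.5  # 1/f background SD relative to unit-variance gamma
    mouse_mode: bool = False
    n_lgn_units: int = 12
    n_opto_pulses: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for (cls, layer, cond), k in self.coupling_kappa.items():
            if cls not in CELL_CLASSES:
                raise ValueError(f"unknown cell class in coupling_kappa key: {cls!r}")
            if layer not in LAYERS:
                raise ValueError(f"unknown layer in coupling_kappa key: {layer!r}")
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition in coupling_kappa key: {cond!r}")
            if k < 0:
                raise ValueError(f"kappa must be >= 0, got {k} for {(cls, layer, cond)}")
        for (layer, cond), g in self.attention_gain.items():
            if layer not in LAYERS:
                raise ValueError(f"unknown layer in attention_gain key: {layer!r}")
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition in attention_gain key: {cond!r}")
            if g <= 0:
                raise ValueError("attention gains must be > 0")
        for (area, layer) in self.attention_latency:
            if area not in AREAS or layer not in LAYERS:
                raise ValueError(f"unknown attention_latency key: {(area, layer)!r}")
        t = self.trial_timing
        for key in ("pre_stim", "cue_delay", "change_delay"):
            lo, hi = t[key]
            if lo <= 0 or hi < lo:
                raise ValueError(f"trial_timing[{key!r}] must be positive and ordered")
        if not (0 < min(self.gamma_peak.values()) and max(self.gamma_peak.values()) < self.fs / 2):
            raise ValueError("gamma peaks must lie within (0, Nyquist)")
        if min(self.base_rate_range) < 0:
            raise ValueError("rates must be >= 0")

    # ---- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupling_kappa"] = {"|".join(k): v for k, v in self.coupling_kappa.items()}
        d["attention_gain"] = {"|".join(k): v for k, v in self.attention_gain.items()}
        d["attention_latency"] = {"|".join(k): v for k, v in self.attention_latency.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        d = dict(d)
        for key in ("coupling_kappa", "attention_gain", "attention_latency"):
            if key in d:
                d[key] = {tuple(k.split("|")): v for k, v in d[key].items()}
        for key in ("base_rate_range",):
            if key in d:
                d[key] = tuple(d[key])
        if "trial_timing" in d:
            d["trial_timing"] = {
                k: (tuple(v) if isinstance(v, (list, tuple)) else v)
                for k, v in d["trial_timing"].items()
            }
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SynthConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def paper_like(seed: int = 0, n_trials: int = 100, mouse_mode: bool = False) -> SynthConfig:
    """The default study-condition preset."""
    return SynthConfig(seed=seed, n_trials=n_trials, mouse_mode=mouse_mode)
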
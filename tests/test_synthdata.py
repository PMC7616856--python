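import numpy as np
import pytest
from scipy import signal
from scipy.special import i0, i1

from gammalink.config import SynthConfig
from gammalink.spikefield import wrap_angle
from gammalink.synthdata import (
    gen_lfp_oscillation,
    gen_session,
    gen_spikes_phase_locked,
    layer_of_channel,
    make_waveform_bank,
)

FS = 1000.0


class TestOscillation:
    def test_spectral_peak_location(self):
        sig = gen_lfp_oscillation(60, 10, 1.0, 20.0, FS, seed=0)
        f, p = signal.welch(sig, fs=FS, nperseg=1024)
        sel = (f > 30) & (f < 100)
        assert abs(f[sel][np.argmax(p[sel])] - 60) <= 5

    def test_zero_power_no_bump(self):
        bg = gen_lfp_oscillation(60, 10, 0.0, 20.0, FS, seed=0)
        f, p = signal.welch(bg, fs=FS, nperseg=1024)
        band = p[(f > 55) & (f < 65)].mean()
        flank = p[(f > 85) & (f < 95)].mean()
        assert band < 3 * flank  # 1/f decay only, no gamma bump

    def test_determinism(self):
        a = gen_lfp_oscillation(60, 5, 1.0, 2.0, FS, seed=42)
        b = gen_lfp_oscillation(60, 5, 1.0, 2.0, FS, seed=42)
        assert np.array_equal(a, b)

    def test_nyquist_rejected(self):
        with pytest.raises(ValueError):
            gen_lfp_oscillation(600, 5, 1.0, 1.0, FS, seed=0)


class TestPhaseLockedSpikes:
    def test_uncoupled_uniform_phases(self):
        _, _, phase = gen_lfp_oscillation(
            60, 2, 1.0, 60.0, FS, seed=1, background=0.0, return_components=True
        )
        st = gen_spikes_phase_locked(phase, 20.0, 0.0, 0.0, FS, seed=2)
        ph = phase[np.clip((st * FS).astype(int), 0, len(phase) - 1)]
        r = np.abs(np.exp(1j * ph).mean())
        assert r < 0.05

    def test_strong_coupling_concentrates(self):
        _, _, phase = gen_lfp_oscillation(
            60, 2, 1.0, 30.0, FS, seed=1, background=0.0, return_components=True
        )
        st = gen_spikes_phase_locked(phase, 20.0, 50.0, 1.0, FS, seed=2)
        ph = phase[np.clip((st * FS).astype(int), 0, len(phase) - 1)]
        assert np.abs(np.exp(1j * ph).mean()) > 0.95
        assert abs(wrap_angle(np.angle(np.exp(1j * ph).sum()) - 1.0)) < 0.1

    def test_mean_resultant_matches_bessel(self):
        # kappa=1: spike-phase resultant length -> I1(1)/I0(1)
        _, _, phase = gen_lfp_oscillation(
            60, 2, 1.0, 120.0, FS, seed=3, background=0.0, return_components=True
        )
        st = gen_spikes_phase_locked(phase, 25.0, 1.0, 0.0, FS, seed=4)
        ph = phase[np.clip((st * FS).astype(int), 0, len(phase) - 1)]
        r = np.abs(np.exp(1j * ph).mean())
        assert r == pytest.approx(i1(1) / i0(1), abs=0.03)

    def test_rate_normalization(self):
        _, _, phase = gen_lfp_oscillation(
            60, 2, 1.0, 100.0, FS, seed=5, background=0.0, return_components=True
        )
        st = gen_spikes_phase_locked(phase, 15.0, 2.0, 0.0, FS, seed=6)
        assert len(st) / 100.0 == pytest.approx(15.0, abs=3 * np.sqrt(15 * 100) / 100)

    def test_determinism(self):
        phase = np.linspace(0, 200 * np.pi, 5000) % (2 * np.pi) - np.pi
        a = gen_spikes_phase_locked(phase, 10.0, 1.0, 0.0, FS, seed=9)
        b = gen_spikes_phase_locked(phase, 10.0, 1.0, 0.0, FS, seed=9)
        assert np.array_equal(a, b)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            gen_spikes_phase_locked(np.zeros(10), -1.0, 0.0, 0.0, FS, seed=0)


class TestConfigValidation:
    def test_unknown_layer_key_rejected(self):
        cfg = SynthConfig()
        cfg.coupling_kappa[("NW", "layer5", "toward")] = 1.0
        with pytest.raises(ValueError, match="layer5"):
            cfg.validate()

    def test_negative_kappa_rejected(self):
        cfg = SynthConfig()
        cfg.coupling_kappa[("NW", "granular", "toward")] = -0.5
        with pytest.raises(ValueError):
            cfg.validate()

    def test_bad_timing_rejected(self):
        cfg = SynthConfig()
        cfg.trial_timing["cue_delay"] = (0.5, 0.2)
        with pytest.raises(ValueError):
            cfg.validate()

    def test_roundtrip_yaml(self, tmp_path):
        cfg = SynthConfig(seed=3, n_trials=12)
        path = tmp_path / "cfg.yaml"
        cfg.save(path)
        back = SynthConfig.load(path)
        assert back.seed == 3 and back.n_trials == 12
        assert back.coupling_kappa == cfg.coupling_kappa


class TestSession:
    def test_determinism(self):
        cfg = dict(seed=5, n_trials=6)
        s1, t1 = gen_session(SynthConfig(**cfg))
        s2, t2 = gen_session(SynthConfig(**cfg))
        assert np.array_equal(s1.lfp, s2.lfp)
        assert all(np.array_equal(a, b) for a, b in zip(s1.spikes, s2.spikes))
        assert t1.units.equals(t2.units)

    def test_trial_ordering_invariant(self, small_session):
        sess, _ = small_session
        t = sess.trials
        assert (t["stim_onset"] < t["cue_onset"]).all()
        assert (t["cue_onset"] < t["first_change"]).all()
        assert set(t["condition"]) == {"toward", "away"}

    def test_rate_calibration_within_three_se(self, small_session):
        sess, truth = small_session
        away = sess.trials[sess.trials["condition"] == "away"]
        for ui in range(sess.n_units):
            s = sess.spikes[ui]
            counts = np.array(
                [
                    np.sum((s >= tr["first_change"] - 1.0) & (s < tr["first_change"]))
                    for _, tr in away.iterrows()
                ]
            )
            se = counts.std(ddof=1) / np.sqrt(len(counts))
            assert abs(counts.mean() - truth.units.iloc[ui]["rate_away"]) < 3 * se + 0.5

    def test_lag_calibration(self, small_session):
        # sender/receiver gamma envelopes peak at the configured lag
        sess, truth = small_session
        lag_ms = truth.session["feedforward_lag_ms"]
        fs = sess.fs
        band = (50, 75)
        sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
        ch_s = sess.geometry.query("area=='sender' and depth_index==8")["channel"].iloc[0]
        ch_r = sess.geometry.query("area=='receiver' and depth_index==8")["channel"].iloc[0]
        tr = sess.trials.iloc[0]
        i0, i1 = int(tr["stim_onset"] * fs) + 100, int(tr["first_change"] * fs)
        a = signal.sosfiltfilt(sos, sess.lfp[ch_s, i0:i1].astype(float))
        b = signal.sosfiltfilt(sos, sess.lfp[ch_r, i0:i1].astype(float))
        xc = signal.correlate(b, a, mode="full")
        lag = np.argmax(xc) - (len(a) - 1)
        assert abs(lag - lag_ms * fs / 1000.0) <= 1

    def test_no_attention_gain_gives_zero_ami(self):
        from gammalink.config import CONDITIONS, LAYERS
        from gammalink.ratestats import ami

        cfg = SynthConfig(seed=8, n_trials=40)
        for layer in LAYERS:
            for cond in CONDITIONS:
                cfg.attention_gain[(layer, cond)] = 1.0
        sess, _ = gen_session(cfg)
        amis = []
        for ui in range(sess.n_units):
            idx = ami(sess.spikes[ui], sess.trials)
            if np.isfinite(idx.value):
                amis.append(idx.value)
        assert abs(np.mean(amis)) < 0.05

    def test_layer_map_covers_shank(self):
        layers = [layer_of_channel(d) for d in range(16)]
        assert layers[0] == "outside" and layers[15] == "white_matter"
        assert layers[8] == "granular"
        assert "superficial" in layers and "deep" in layers


@pytest.fixture(scope="module")
def mouse_session():
    return gen_session(SynthConfig(seed=21, n_trials=10, mouse_mode=True))


class TestMouseMode:
    def test_lgn_population_present(self, mouse_session):
        sess, _ = mouse_session
        assert len(sess.extras["lgn_spikes"]) == 12

    def test_pupil_speed_traces(self, mouse_session):
        sess, _ = mouse_session
        assert len(sess.extras["pupil"]) == sess.lfp.shape[1]
        assert sess.extras["pupil"].max() <= 1.0
        assert (sess.extras["speed"] >= 0).all()

    def test_tagged_units_respond_within_10ms(self, mouse_session):
        sess, truth = mouse_session
        pulses = sess.extras["opto_pulses"]
        for ui in range(sess.n_units):
            if not truth.units.iloc[ui]["opto_tagged"]:
                continue
            s = sess.spikes[ui]
            lat = []
            for p in pulses:
                nxt = s[(s > p) & (s < p + 0.05)]
                if len(nxt):
                    lat.append(nxt[0] - p)
            assert np.median(lat) < 0.010


def test_waveform_bank_families():
    traces, labels = make_waveform_bank(5, 5, 2, 2, seed=0)
    assert len(traces) == 14
    assert labels.count("narrow") == 5 and labels.count("dc") == 2
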
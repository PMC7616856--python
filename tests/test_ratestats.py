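import numpy as np
import pandas as pd
import pytest

from gammalink.ratestats import (
    ami,
    ami_regression,
    attn_difference_timecourse,
    drivenness,
    noise_corr,
    peth,
    xcorr_asymmetry,
    xcorr_asymmetry_test,
)


def make_trials(n=20, conditions=None, length=4.0):
    rows = []
    t = 0.0
    for i in range(n):
        cond = conditions[i] if conditions is not None else ("toward" if i % 2 else "away")
        rows.append(
            {
                "trial": i,
                "start": t,
                "stim_onset": t + 0.6,
                "cue_onset": t + 1.4,
                "first_change": t + 3.0,
                "condition": cond,
                "valid": True,
                "end": t + length,
            }
        )
        t += length
    return pd.DataFrame(rows)


def poisson_spikes(rate, duration, rng):
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0, duration, n))


class TestPETH:
    def test_constant_rate_z_near_zero(self, rng):
        trials = make_trials(30)
        spikes = poisson_spikes(20.0, 30 * 4.0, rng)
        p = peth(spikes, trials, "cue_onset", (-0.5, 0.5))
        # averaged z-trace fluctuates at ~1/sqrt(n_trials) with no structure
        assert abs(p.mean.mean()) < 0.2
        assert np.abs(p.mean).max() < 1.0

    def test_single_spike_kernel_shape(self):
        trials = make_trials(10)
        spikes = trials["cue_onset"].to_numpy() + 0.1
        p = peth(spikes, trials, "cue_onset", (-0.2, 0.4), zscore=False)
        peak_t = p.times[np.argmax(p.mean)]
        assert peak_t == pytest.approx(0.1, abs=0.005)
        # Gaussian kernel: symmetric decay around the impulse
        assert p.mean[np.argmax(p.mean)] > 0

    def test_rate_step_rises_at_onset(self, rng):
        trials = make_trials(60)
        spikes = []
        for _, tr in trials.iterrows():
            # 10 Hz before the cue, 20 Hz after
            pre = tr["cue_onset"] - tr["start"]
            post = tr["end"] - tr["cue_onset"]
            spikes.append(tr["start"] + np.sort(rng.uniform(0, pre, rng.poisson(10 * pre))))
            spikes.append(tr["cue_onset"] + np.sort(rng.uniform(0, post, rng.poisson(20 * post))))
        spikes = np.sort(np.concatenate(spikes))
        p = peth(spikes, trials, "cue_onset", (-0.3, 0.3))
        assert p.mean[p.times > 0.1].mean() > p.mean[p.times < -0.1].mean() + 0.2

    def test_empty_train_flagged(self):
        trials = make_trials(3)
        p = peth(np.array([]), trials, "cue_onset", (-0.1, 0.1))
        assert p.zero_sd_trials.all()
        assert np.allclose(p.mean, 0)

    def test_no_trials_rejected(self):
        with pytest.raises(ValueError):
            peth(np.array([1.0]), make_trials(0), "cue_onset", (-0.1, 0.1))


class TestModulationIndices:
    def test_ami_arithmetic(self, rng):
        trials = make_trials(40)
        spikes = []
        for _, tr in trials.iterrows():
            rate = 6.0 if tr["condition"] == "toward" else 2.0
            n = int(rate)  # deterministic counts in the 1 s pre-change window
            spikes.append(np.linspace(tr["first_change"] - 0.9, tr["first_change"] - 0.1, n))
        idx = ami(np.sort(np.concatenate(spikes)), trials)
        assert idx.value == pytest.approx(0.5)

    def test_ami_antisymmetry(self, rng):
        trials = make_trials(40)
        spikes = poisson_spikes(10.0, 160.0, rng)
        flipped = trials.copy()
        flipped["condition"] = flipped["condition"].map(
            {"toward": "away", "away": "toward"}
        )
        assert ami(spikes, trials).value == pytest.approx(-ami(spikes, flipped).value)

    def test_ami_requires_both_conditions(self):
        trials = make_trials(10, conditions=["toward"] * 10)
        with pytest.raises(ValueError):
            ami(np.array([1.0]), trials)

    def test_drivenness_examples(self):
        trials = make_trials(50)
        # silent baseline, active stimulus period -> dr = 1
        spikes = np.concatenate(
            [tr["stim_onset"] + np.linspace(0.06, 0.24, 5) for _, tr in trials.iterrows()]
        )
        assert drivenness(np.sort(spikes), trials).value == pytest.approx(1.0)

    def test_drivenness_rate_ratio(self, rng):
        # 10 Hz baseline -> 15 Hz stimulus: dr = (15-10)/25 = 0.2
        trials = make_trials(400)
        spikes = []
        for _, tr in trials.iterrows():
            s0 = tr["stim_onset"]
            spikes.append(s0 - 0.2 + np.sort(rng.uniform(0, 0.2, rng.poisson(10 * 0.2))))
            spikes.append(s0 + 0.05 + np.sort(rng.uniform(0, 0.2, rng.poisson(15 * 0.2))))
        d = drivenness(np.sort(np.concatenate(spikes)), trials)
        assert d.value == pytest.approx(0.2, abs=0.05)


class TestNoiseCorr:
    def test_identical_series(self, rng):
        c = rng.poisson(10, (1, 40)).astype(float)
        counts = np.vstack([c, c])
        r = noise_corr(counts)
        assert r[0, 1] == pytest.approx(1.0)

    def test_anti_varying_series(self):
        a = np.tile([4.0, 6.0], 20)
        counts = np.vstack([a, -a + 10])
        assert noise_corr(counts)[0, 1] == pytest.approx(-1.0)

    def test_independent_near_zero(self, rng):
        counts = rng.poisson(10, (2, 100)).astype(float)
        assert abs(noise_corr(counts)[0, 1]) < 0.3

    def test_chunking_removes_common_drift(self, rng):
        # a shared monotone drift inflates whole-session r but not chunked r
        n = 100
        drift = np.linspace(0, 20, n)
        a = rng.poisson(10, n) + drift
        b = rng.poisson(10, n) + drift
        counts = np.vstack([a, b])
        whole = np.corrcoef(a, b)[0, 1]
        chunked = noise_corr(counts)[0, 1]
        assert whole - chunked > 0.1

    def test_incomplete_chunk_dropped(self, rng):
        counts = rng.poisson(5, (2, 19)).astype(float)
        r = noise_corr(counts, chunk=10)  # only one full chunk used
        assert np.isfinite(r[0, 1])

    def test_too_few_trials_rejected(self, rng):
        with pytest.raises(ValueError):
            noise_corr(rng.poisson(5, (2, 5)).astype(float), chunk=10)


class TestXcorrAsymmetry:
    def test_identical_traces_zero(self, rng):
        x = rng.standard_normal(600)
        assert xcorr_asymmetry(x, x) == pytest.approx(0.0, abs=1e-10)

    def test_delayed_copy_sign(self):
        # B = A delayed by 50 ms -> A leads -> negative asymmetry
        t = np.arange(600) / 1000.0
        a = np.exp(-((t - 0.15) ** 2) / (2 * 0.04**2))
        b = np.exp(-((t - 0.20) ** 2) / (2 * 0.04**2))
        assert xcorr_asymmetry(a, b) < 0
        assert xcorr_asymmetry(b, a) > 0

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            xcorr_asymmetry(np.zeros(100), np.zeros(100), max_lag=0.2)

    def test_population_randomization_detects_lead(self, rng):
        t = np.arange(450) / 1000.0
        bump = lambda mu: np.exp(-((t - mu) ** 2) / (2 * 0.05**2))
        A = bump(0.15) + 0.3 * rng.standard_normal((25, 450))
        B = bump(0.20) + 0.3 * rng.standard_normal((25, 450))
        res = xcorr_asymmetry_test(A, B, n_randomizations=300, seed=0)
        assert res.observed < 0
        assert res.p_empirical < 0.05


class TestAttnDifference:
    def test_identical_conditions_flat(self, rng):
        trials = make_trials(60)
        spikes = poisson_spikes(15.0, 240.0, rng)
        _, diff = attn_difference_timecourse(spikes, trials)
        assert np.abs(diff).max() < 1.0

    def test_gain_after_cue_positive(self, rng):
        trials = make_trials(120)
        spikes = []
        for _, tr in trials.iterrows():
            dur = tr["end"] - tr["start"]
            rate = 12.0
            base = tr["start"] + np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
            spikes.append(base)
            if tr["condition"] == "toward":
                post = tr["end"] - tr["cue_onset"]
                extra = tr["cue_onset"] + np.sort(
                    rng.uniform(0, post, rng.poisson(0.5 * rate * post))
                )
                spikes.append(extra)
        spikes = np.sort(np.concatenate(spikes))
        t, diff = attn_difference_timecourse(spikes, trials)
        assert diff[t > 0.15].mean() > diff[t < 0.0].mean()


class TestAmiRegression:
    def test_exact_linear_fit(self, rng):
        rate = rng.uniform(1, 20, 60)
        layer = np.repeat(["superficial", "granular", "deep"], 20)
        df = pd.DataFrame({"ami": 0.1 * rate, "rate": rate, "layer": layer})
        res = ami_regression(df)
        assert res.rsquared == pytest.approx(1.0)
        assert res.params["rate"] == pytest.approx(0.1)

    def test_constant_ami(self, rng):
        df = pd.DataFrame(
            {
                "ami": 0.3,
                "rate": rng.uniform(1, 20, 40),
                "layer": np.repeat(["superficial", "deep"], 20),
            }
        )
        res = ami_regression(df)
        assert res.params["Intercept"] == pytest.approx(0.3)
        assert abs(res.params["rate"]) < 1e-10

    def test_layer_offsets_recovered(self, rng):
        offsets = {"superficial": 0.2, "granular": 0.05, "deep": -0.1}
        layer = np.repeat(list(offsets), 40)
        rate = rng.uniform(1, 20, 120)
        amiv = np.array([offsets[l] for l in layer]) + 0.01 * rng.standard_normal(120)
        df = pd.DataFrame({"ami": amiv, "rate": rate, "layer": layer})
        res = ami_regression(df)
        pred = res.predict(pd.DataFrame({"rate": [10.0] * 3, "layer": list(offsets)}))
        for p, (_, off) in zip(pred, offsets.items()):
            assert p == pytest.approx(off, abs=0.02)

    def test_single_layer_rejected(self):
        df = pd.DataFrame({"ami": [0.1, 0.2], "rate": [1.0, 2.0], "layer": ["deep", "deep"]})
        with pytest.raises(ValueError):
            ami_regression(df)
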
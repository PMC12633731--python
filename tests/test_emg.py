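"""EMG conditioning, burst detection and burst metrics against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finstroke import emg as E
from finstroke.kinematics import StrokeCycle

FS = 10_000.0


def make_channel(samples, quiet=(0.0, 0.1), muscle="Add"):
    return E.EMGChannel("f1", muscle, FS, np.asarray(samples, dtype=float),
                        quiet_window=quiet)


class TestCenterSignal:
    def test_constant_becomes_zero(self):
        ch = make_channel(np.full(5000, 3.7))
        assert np.allclose(E.center_signal(ch), 0.0)

    def test_baseline_offset_removed(self, rng):
        x = rng.normal(size=5000)
        x[:1000] = 0.0
        a = E.center_signal(make_channel(x))
        b = E.center_signal(make_channel(x + 0.3))
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_quiet_window_mean_near_zero(self, rng):
        x = rng.normal(2.0, 1.0, size=20_000)
        out = E.center_signal(make_channel(x, quiet=(0.0, 0.5)))
        assert abs(out[:5000].mean()) < 1e-12 * np.abs(x).max()

    def test_short_quiet_window_rejected(self):
        ch = make_channel(np.zeros(5000), quiet=(0.0, 0.03))
        with pytest.raises(ValueError, match="quiet window"):
            E.center_signal(ch)


class TestBandpass:
    t = np.arange(0, 2, 1 / FS)

    def _amp(self, f):
        y = E.bandpass(np.sin(2 * np.pi * f * self.t), FS)
        return np.sqrt(2) * np.std(y[5000:-5000])

    def test_dc_removed(self):
        assert np.abs(E.bandpass(np.ones(20_000), FS)).max() < 1e-6

    def test_passband_tone_preserved(self):
        assert 0.89 <= self._amp(500.0) <= 1.0

    def test_stopband_tones_attenuated(self):
        assert self._amp(10.0) <= 0.1
        assert self._amp(4500.0) <= 0.1  # >= 20 dB

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            E.bandpass(np.zeros(1000), fs=6000.0)


class TestDenoise:
    def test_zero_input_zero_output(self):
        assert np.allclose(E.denoise(np.zeros(1024)), 0.0)

    def test_white_noise_variance_reduced(self, rng):
        x = rng.standard_normal(2**16)
        assert E.denoise(x).std() < 0.5

    def test_burst_energy_retained(self, rng):
        x = rng.standard_normal(2**16) * 0.1
        burst = slice(20_000, 26_000)
        carrier = E.bandpass(rng.standard_normal(6000), FS)
        carrier /= carrier.std()
        x[burst] += carrier
        d = E.denoise(x)
        ratio = np.sum(d[burst] ** 2) / np.sum(x[burst] ** 2)
        assert ratio >= 0.9

    def test_length_preserved_and_nonfinite_rejected(self, rng):
        for n in (1000, 2**14 + 17):
            assert E.denoise(rng.standard_normal(n)).size == n
        with pytest.raises(ValueError):
            E.denoise(np.r_[np.zeros(100), np.nan, np.zeros(100)])


class TestRmsEnvelope:
    def test_constant_signal(self):
        env = E.rms_envelope(np.full(2000, 2.0), 400)
        np.testing.assert_allclose(env, 2.0)

    def test_sine_gives_rms_amplitude(self):
        t = np.arange(0, 1, 1 / FS)
        env = E.rms_envelope(3.0 * np.sin(2 * np.pi * 500 * t), 400)
        np.testing.assert_allclose(env[500:-500], 3.0 / np.sqrt(2), rtol=0.01)

    def test_matches_brute_force_windowed_rms(self, rng):
        x = rng.normal(size=300)
        w = 40
        env = E.rms_envelope(x, w)
        for i in (0, 5, 150, 299):
            lo, hi = max(i - w // 2, 0), min(i + w - w // 2, x.size)
            assert env[i] == pytest.approx(
                np.sqrt(np.mean(x[lo:hi] ** 2)), rel=1e-10)


class TestDetectBursts:
    def test_plateau_recovered(self):
        env = np.zeros(10_000)
        env[1000:2000] = 1.0
        bursts = E.detect_bursts(env, FS)
        assert len(bursts) == 1
        assert bursts[0].onset_s == pytest.approx(0.10, abs=1e-9)
        assert bursts[0].offset_s == pytest.approx(0.20, abs=1e-9)

    def test_constant_envelope_single_full_burst(self):
        bursts = E.detect_bursts(np.full(5000, 0.8), FS)
        assert len(bursts) == 1
        assert bursts[0].onset_s == 0.0
        assert bursts[0].offset_s == pytest.approx(0.5)

    def test_zero_envelope_empty(self):
        assert E.detect_bursts(np.zeros(1000), FS) == []


class TestRateFilter:
    def test_close_bursts_merged(self):
        b = [E.Burst(0.0, 0.1), E.Burst(0.105, 0.2)]
        out = E.rate_filter(b)
        assert len(out) == 1
        assert (out[0].onset_s, out[0].offset_s) == (0.0, 0.2)

    def test_short_isolated_burst_removed(self):
        assert E.rate_filter([E.Burst(0.0, 0.004)]) == []

    def test_matches_brute_force_merge_then_drop(self, rng):
        # random burst trains vs an independently coded merge/drop pass
        for _ in range(20):
            edges = np.sort(rng.uniform(0, 1, size=16))
            bursts = [E.Burst(a, b) for a, b in zip(edges[::2], edges[1::2])]
            oracle = []
            for b in bursts:
                if oracle and b.onset_s - oracle[-1][1] < 0.010:
                    oracle[-1][1] = max(oracle[-1][1], b.offset_s)
                else:
                    oracle.append([b.onset_s, b.offset_s])
            oracle = [tuple(o) for o in oracle if o[1] - o[0] >= 0.010]
            got = [(b.onset_s, b.offset_s) for b in E.rate_filter(bursts)]
            assert got == oracle

    @given(st.lists(st.tuples(st.floats(0, 1), st.floats(0.0001, 0.05)),
                    min_size=0, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_idempotent(self, spec):
        bursts = sorted((E.Burst(on, on + d) for on, d in spec),
                        key=lambda b: b.onset_s)
        once = E.rate_filter(bursts)
        twice = E.rate_filter(once)
        assert [(b.onset_s, b.offset_s) for b in once] == \
            [(b.onset_s, b.offset_s) for b in twice]


class TestBurstMetrics:
    cycle = StrokeCycle(1.0, 1.4, 2.0)

    def test_constant_amplitude_burst_at_channel_max(self):
        # one burst of constant rectified amplitude == max_amp over 10% of
        # the cycle: duty 10%, RIA% = 100, amp% = 100
        n = int(3.0 * FS)
        centered = np.zeros(n)
        i0, i1 = int(1.1 * FS), int(1.2 * FS)
        centered[i0:i1 + 1] = 0.5
        bursts = [E.Burst(1.1, 1.2)]
        norm = E.ChannelNormalization("f1", "Add", 0.5)
        out = E.burst_metrics(centered, FS, 0.0, bursts, self.cycle, norm)
        full = out["full_cycle"]
        assert full.duty_factor_pct == pytest.approx(10.0)
        assert full.ria_pct == pytest.approx(100.0)
        assert full.amp_pct == pytest.approx(100.0)
        assert full.n_bursts == 1

    def test_burst_spanning_propulsion_only(self):
        n = int(3.0 * FS)
        centered = np.ones(n) * 0.2
        bursts = [E.Burst(1.0, 1.4)]
        norm = E.ChannelNormalization("f1", "Add", 1.0)
        out = E.burst_metrics(centered, FS, 0.0, bursts, self.cycle, norm)
        assert out["propulsion"].duty_factor_pct == pytest.approx(100.0)
        assert out["recovery"].duty_factor_pct == 0.0
        assert out["recovery"].n_bursts == 0
        assert np.isnan(out["recovery"].amp_pct)

    def test_metrics_match_trapezoid_oracle(self, rng):
        n = int(3.0 * FS)
        centered = rng.normal(size=n)
        bursts = [E.Burst(1.05, 1.20), E.Burst(1.30, 1.55), E.Burst(1.7, 1.9)]
        norm = E.ChannelNormalization("f1", "Add", np.abs(centered).max())
        out = E.burst_metrics(centered, FS, 0.0, bursts, self.cycle, norm)
        t = np.arange(n) / FS
        # full-cycle oracle by direct trapezoid integration per burst
        ria = theo = 0.0
        pooled = []
        for b in bursts:
            m = (t >= b.onset_s - 1e-12) & (t <= b.offset_s + 1e-12)
            ria += np.trapezoid(np.abs(centered[m]), t[m])
            theo += norm.max_amp * (b.offset_s - b.onset_s)
            pooled.append(np.abs(centered[m]))
        pooled = np.sort(np.concatenate(pooled))
        k = max(1, int(np.ceil(0.05 * pooled.size)))
        amp = pooled[-k:].mean()
        full = out["full_cycle"]
        assert full.ria_pct == pytest.approx(100 * ria / theo, rel=1e-8)
        assert full.amp_pct == pytest.approx(100 * amp / norm.max_amp,
                                             rel=1e-8)
        assert full.activation_duration_s == pytest.approx(0.6, rel=1e-12)

    def test_phase_durations_sum_to_full_cycle(self, rng):
        n = int(3.0 * FS)
        centered = rng.normal(size=n)
        bursts = [E.Burst(1.1, 1.5), E.Burst(1.6, 1.95)]  # one straddles t_mid
        norm = E.ChannelNormalization("f1", "Add", 1.0)
        out = E.burst_metrics(centered, FS, 0.0, bursts, self.cycle, norm)
        assert (out["propulsion"].activation_duration_s
                + out["recovery"].activation_duration_s) == pytest.approx(
            out["full_cycle"].activation_duration_s, abs=1e-12)
        # duty factor x duration identity
        assert out["full_cycle"].duty_factor_pct / 100 * self.cycle.duration \
            == pytest.approx(out["full_cycle"].activation_duration_s)
        # straddling burst counts once in each phase it intersects
        assert out["propulsion"].n_bursts == 1
        assert out["recovery"].n_bursts == 2

    def test_polar_timings_in_range(self, rng):
        n = int(3.0 * FS)
        centered = rng.normal(size=n)
        bursts = [E.Burst(1.1, 1.99)]
        norm = E.ChannelNormalization("f1", "Add", 1.0)
        out = E.burst_metrics(centered, FS, 0.0, bursts, self.cycle, norm)
        for s in out.values():
            for a in s.onsets_deg + s.offsets_deg:
                assert 0 <= a < 360


class TestChannelNormalization:
    def test_max_over_bursts(self):
        bursts = [E.Burst(0, 1, amp_top5=1.0), E.Burst(2, 3, amp_top5=3.0),
                  E.Burst(4, 5, amp_top5=2.0)]
        assert E.channel_normalization("f1", "Add", bursts).max_amp == 3.0

    def test_no_bursts_rejected(self):
        with pytest.raises(ValueError, match="no bursts"):
            E.channel_normalization("f1", "Add", [])

    def test_exactly_one_cycle_reaches_100pct(self, rng):
        # by construction the largest-amplitude burst attains amp_pct == 100
        n = int(5.0 * FS)
        centered = rng.normal(size=n) * 0.1
        spans = [(0.5, 0.8), (1.5, 1.9), (2.5, 3.0), (4.0, 4.4)]
        for k, (a, b) in enumerate(spans):
            i0, i1 = int(a * FS), int(b * FS)
            centered[i0:i1] += (k + 1) * 0.5 * np.sin(
                2 * np.pi * 300 * np.arange(i1 - i0) / FS)
        bursts = E.annotate_bursts(centered, FS, 0.0,
                                   [E.Burst(a, b) for a, b in spans])
        norm = E.channel_normalization("f1", "Add", bursts)
        pcts = [100 * b.amp_top5 / norm.max_amp for b in bursts]
        assert all(p <= 100 + 1e-12 for p in pcts)
        assert sum(abs(p - 100.0) < 1e-9 for p in pcts) == 1
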
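"""Circular descriptive statistics and the four-test decision tree."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from finstroke import circstats as cs


class TestCircSummary:
    def test_two_point_symmetric_sample(self):
        s = cs.circ_summary([0.0, 90.0])
        assert s.mean_deg == pytest.approx(45.0)
        assert s.R_bar == pytest.approx(np.cos(np.deg2rad(45.0)))
        assert s.ang_var == pytest.approx(1 - np.cos(np.deg2rad(45.0)))

    def test_antipodal_sample_has_undefined_mean(self):
        with pytest.warns(UserWarning, match="undefined"):
            s = cs.circ_summary([0.0, 180.0])
        assert s.R_bar == pytest.approx(0.0, abs=1e-12)
        assert not s.mean_defined
        assert np.isnan(s.mean_deg)

    def test_von_mises_sample_recovers_mean_direction(self, rng):
        ang = np.rad2deg(sps.vonmises.rvs(4.0, loc=np.deg2rad(120),
                                          size=500, random_state=rng)) % 360
        s = cs.circ_summary(ang)
        diff = (s.mean_deg - 120 + 180) % 360 - 180
        assert abs(diff) < 5

    def test_agrees_with_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        ang = rng.uniform(0, 360, 50)
        s = cs.circ_summary(ang)
        assert s.mean_deg % 360 == pytest.approx(
            np.rad2deg(pingouin.circ_mean(np.deg2rad(ang))) % 360)
        assert s.R_bar == pytest.approx(pingouin.circ_r(np.deg2rad(ang)))

    @given(st.integers(0, 2**32 - 1), st.floats(1.0, 359.0))
    @settings(max_examples=25, deadline=None)
    def test_rotation_shifts_mean_and_preserves_spread(self, seed, rot):
        rng = np.random.default_rng(seed)
        ang = rng.uniform(0, 360, 20)
        a = cs.circ_summary(ang)
        b = cs.circ_summary((ang + rot) % 360)
        assert b.R_bar == pytest.approx(a.R_bar, abs=1e-9)
        diff = (b.mean_deg - a.mean_deg - rot + 180) % 360 - 180
        assert abs(diff) < 1e-6


class TestRayleigh:
    def test_identical_angles_strongly_rejected(self):
        r = cs.rayleigh(np.full(10, 42.0))
        assert r.statistic == pytest.approx(10.0)
        assert r.p < 0.001

    def test_statistic_matches_brute_force_resultant(self, rng):
        ang = rng.uniform(0, 360, 37)
        rad = np.deg2rad(ang)
        rbar = np.hypot(np.cos(rad).sum(), np.sin(rad).sum()) / ang.size
        assert cs.rayleigh(ang).statistic == pytest.approx(
            ang.size * rbar**2, rel=1e-12)

    def test_p_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        ang = rng.uniform(0, 360, 60)
        z, p = pingouin.circ_rayleigh(np.deg2rad(ang))
        r = cs.rayleigh(ang)
        assert r.statistic == pytest.approx(z, rel=1e-9)
        assert r.p == pytest.approx(p, rel=1e-6)


class TestHermansRasson:
    def test_statistic_invariant_to_sample_order(self, rng):
        ang = rng.uniform(0, 360, 30)
        t1 = cs.hermans_rasson_statistic(np.deg2rad(ang))
        t2 = cs.hermans_rasson_statistic(np.deg2rad(rng.permutation(ang)))
        assert t1 == pytest.approx(t2, rel=1e-12)

    def test_more_powerful_than_rayleigh_on_axial_sample(self, rng):
        # axially bimodal data defeat Rayleigh (resultant cancels) but not HR
        n, sims = 50, 60
        null = cs.hermans_rasson_null(n, 2000, np.random.default_rng(1))
        crit = np.quantile(null, 0.95)
        hr_rej = ray_rej = 0
        for _ in range(sims):
            half = sps.vonmises.rvs(5.0, loc=0.0, size=n // 2, random_state=rng)
            other = sps.vonmises.rvs(5.0, loc=np.pi, size=n - n // 2,
                                     random_state=rng)
            rad = np.concatenate([half, other])
            if cs.hermans_rasson_statistic(rad) > crit:
                hr_rej += 1
            if cs.rayleigh(np.rad2deg(rad) % 360).p < 0.05:
                ray_rej += 1
        assert hr_rej > ray_rej
        assert hr_rej / sims > 0.9

    def test_concentrated_sample_rejected(self, rng):
        ang = np.rad2deg(sps.vonmises.rvs(8.0, size=40, random_state=rng)) % 360
        r = cs.hermans_rasson(ang, n_boot=500, seed=0)
        assert r.p < 0.01


class TestKuiperVonMises:
    def test_von_mises_sample_retained(self, rng):
        ang = np.rad2deg(sps.vonmises.rvs(3.0, loc=1.0, size=100,
                                          random_state=rng)) % 360
        r = cs.kuiper_vonmises(ang, n_boot=200, seed=0)
        assert r.p > 0.05

    def test_antipodal_bimodal_sample_rejected(self, rng):
        a = sps.vonmises.rvs(10.0, loc=0.0, size=50, random_state=rng)
        b = sps.vonmises.rvs(10.0, loc=np.pi, size=50, random_state=rng)
        ang = np.rad2deg(np.concatenate([a, b])) % 360
        r = cs.kuiper_vonmises(ang, n_boot=200, seed=0)
        assert r.p < 0.05

    def test_degenerate_sample_flagged(self):
        r = cs.kuiper_vonmises(np.full(20, 90.0), n_boot=50, seed=0)
        assert r.p == 0.0
        assert "degenerate" in r.selection_trace

    def test_requires_minimum_sample(self):
        with pytest.raises(ValueError):
            cs.kuiper_vonmises([0.0, 10.0, 20.0])


class TestWatsonWilliams:
    def test_identical_samples_give_zero_F(self, rng):
        ang = np.rad2deg(sps.vonmises.rvs(8.0, size=30, random_state=rng)) % 360
        r = cs.watson_williams(ang, ang.copy())
        assert r.statistic == pytest.approx(0.0, abs=1e-9)
        assert r.df == (1, 58)

    def test_matches_brute_force_circular_anova(self, rng):
        # independent re-derivation from the resultant-length decomposition
        a = np.rad2deg(sps.vonmises.rvs(6.0, loc=0.5, size=12,
                                        random_state=rng)) % 360
        b = np.rad2deg(sps.vonmises.rvs(6.0, loc=1.0, size=15,
                                        random_state=rng)) % 360
        ra, rb = np.deg2rad(a), np.deg2rad(b)

        def res_len(r):
            return np.hypot(np.cos(r).sum(), np.sin(r).sum())

        R1, R2 = res_len(ra), res_len(rb)
        R = res_len(np.concatenate([ra, rb]))
        N = a.size + b.size
        rw = (R1 + R2) / N
        kappa = cs._a1inv(rw)
        F_oracle = (1 + 3 / (8 * kappa)) * (N - 2) * (R1 + R2 - R) / (N - R1 - R2)
        assert cs.watson_williams(a, b).statistic == pytest.approx(
            F_oracle, rel=1e-10)

    def test_power_on_separated_means(self, rng):
        hits = 0
        for _ in range(40):
            a = np.rad2deg(sps.vonmises.rvs(8.0, loc=0.0, size=50,
                                            random_state=rng)) % 360
            b = np.rad2deg(sps.vonmises.rvs(8.0, loc=np.pi / 2, size=50,
                                            random_state=rng)) % 360
            if cs.watson_williams(a, b).p < 0.01:
                hits += 1
        assert hits >= 38


class TestWatsonU2:
    def test_identical_samples_give_high_p(self):
        ang = np.linspace(0, 350, 8)
        r = cs.watson_u2(ang, ang.copy())
        assert r.p > 0.9

    def test_disjoint_clusters_rejected(self, rng):
        a = np.rad2deg(sps.vonmises.rvs(20.0, loc=0.0, size=30,
                                        random_state=rng)) % 360
        b = np.rad2deg(sps.vonmises.rvs(20.0, loc=np.pi, size=30,
                                        random_state=rng)) % 360
        assert cs.watson_u2(a, b).p < 0.01

    @given(st.integers(0, 2**32 - 1), st.floats(1.0, 359.0))
    @settings(max_examples=20, deadline=None)
    def test_rotation_invariance(self, seed, rot):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 360, 15)
        b = rng.uniform(0, 360, 12)
        u1 = cs.watson_u2(a, b).statistic
        u2 = cs.watson_u2((a + rot) % 360, (b + rot) % 360).statistic
        assert u1 == pytest.approx(u2, abs=1e-9)


class TestDecisionTree:
    def test_von_mises_concentrated_routes_to_watson_williams(self, rng):
        a = np.rad2deg(sps.vonmises.rvs(8.0, loc=0.0, size=60,
                                        random_state=rng)) % 360
        b = np.rad2deg(sps.vonmises.rvs(8.0, loc=1.0, size=60,
                                        random_state=rng)) % 360
        res = cs.timing_decision_tree(a, b, kuiper_boot=100, hr_boot=500,
                                      seed=0)
        assert res[-1].test == "watson_williams"

    def test_uniform_samples_suppress_two_sample_test(self, rng):
        a = rng.uniform(0, 360, 80)
        b = rng.uniform(0, 360, 80)
        res = cs.timing_decision_tree(a, b, kuiper_boot=100, hr_boot=500,
                                      seed=0)
        assert res[-1].test == "none"
        assert "uniform" in res[-1].selection_trace

    def test_non_von_mises_routes_to_hr_and_watson_u2(self, rng):
        def bimodal(loc):
            x = sps.vonmises.rvs(12.0, loc=loc, size=40, random_state=rng)
            y = sps.vonmises.rvs(12.0, loc=loc + np.pi, size=40,
                                 random_state=rng)
            return np.rad2deg(np.concatenate([x, y])) % 360

        res = cs.timing_decision_tree(bimodal(0.0), bimodal(0.4),
                                      kuiper_boot=150, hr_boot=1000, seed=3)
        tests = [r.test for r in res]
        assert "hermans_rasson" in tests
        assert res[-1].test == "watson_u2"
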
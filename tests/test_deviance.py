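"""Deviance statistic, FDR mask, window mapping, dMMN decomposition,
deviance maps, photostimulation comparison and effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmmn import deviance as D
from conftest import make_aligned


class TestSelectControlTrials:
    def test_worked_example(self):
        durs = [100, 50, 100, 225, 100, 25, 100]
        md = pd.DataFrame({
            "duration_ms": np.array(durs, dtype=float),
            "prev_duration_ms": [np.nan] + [float(d) for d in durs[:-1]],
        })
        idx = D.select_control_trials(md)
        # 1-based positions {3, 7}: position 1 has no predecessor,
        # position 5 is preceded by a 225-ms tone
        assert list(idx + 1) == [3, 7]

    def test_permissive_mode_takes_all_non_first(self):
        durs = [100.0, 100.0, 100.0, 50.0, 100.0]
        md = pd.DataFrame({
            "duration_ms": durs,
            "prev_duration_ms": [np.nan] + durs[:-1],
        })
        idx = D.select_control_trials(md, allowed_prev_ms=None)
        assert list(idx) == [1, 2, 4]

    def test_matches_brute_force_scan(self, rng):
        durset = [10, 25, 50, 75, 100, 125, 150, 175, 200, 225]
        durs = rng.choice(durset, 500).astype(float)
        md = pd.DataFrame({
            "duration_ms": durs,
            "prev_duration_ms": np.concatenate([[np.nan], durs[:-1]]),
        })
        got = set(D.select_control_trials(md))
        expected = {i for i in range(1, 500)
                    if durs[i] == 100.0 and durs[i - 1] in (10, 25, 50)}
        assert got == expected
        # the filter never selects a trial whose predecessor exceeded 50 ms
        assert all(durs[i - 1] <= 50.0 for i in got)


class TestTimecourse:
    def test_identical_sets_empty_mask(self, rng):
        v = rng.normal(0, 0.01, (10, 20))
        res = D.timecourse_comparison(v, v.copy(), np.arange(20) * 33.3)
        assert np.allclose(res.difference, 0.0)
        assert not res.mask.any()

    def test_planted_window_detected(self, rng):
        n_frames = 20
        dev = rng.normal(0, 0.01, (30, n_frames))
        ctl = rng.normal(0, 0.01, (8, n_frames))
        dev[:, 8:14] += 0.1
        times = (np.arange(n_frames) - 5) * 1000 / 30
        res = D.timecourse_comparison(dev, ctl, times)
        assert res.mask[8:14].all()
        assert not res.mask[:6].any()
        est = res.difference[8:14].mean()
        assert est == pytest.approx(0.1, abs=0.01)

    def test_degenerate_frames_get_p_one(self):
        dev = np.zeros((5, 4))
        ctl = np.zeros((5, 4))
        res = D.timecourse_comparison(dev, ctl, np.arange(4.0))
        assert (res.p_values == 1.0).all()

    def test_fdr_controls_null_mask_rate(self):
        rng = np.random.default_rng(11)
        fracs = []
        times = np.arange(-5, 15) * 1000 / 30
        for _ in range(200):
            dev = rng.normal(0, 0.02, (30, 20))
            ctl = rng.normal(0, 0.02, (8, 20))
            fracs.append(D.timecourse_comparison(dev, ctl, times).mask.mean())
        assert np.mean(fracs) <= 0.05

    def test_mask_subset_of_unadjusted(self, rng):
        dev = rng.normal(0, 0.02, (12, 20)) + 0.01
        ctl = rng.normal(0, 0.02, (12, 20))
        res = D.timecourse_comparison(dev, ctl, np.arange(20.0))
        assert not (res.mask_two_sided & (res.p_values >= 0.05)).any()

    def test_min_trials_enforced(self, rng):
        with pytest.raises(ValueError):
            D.timecourse_comparison(rng.random((3, 5)), rng.random((8, 5)),
                                    np.arange(5.0))


class TestWindowAmplitude:
    def test_constant_series(self):
        times = np.arange(-5, 15) * 1000 / 30
        v = np.full(20, 0.7)
        assert D.window_amplitude(v, times, (0, 200)) == pytest.approx(0.7)

    def test_frame_selection_200_400ms(self):
        # frames 6..12 at 30 Hz fall in the 200-400 ms window
        times = np.arange(0, 20) * 1000 / 30
        idx = D.window_frames(times, (200.0, 400.0))
        assert list(idx) == [6, 7, 8, 9, 10, 11, 12]

    def test_tone_end_reference_shifts(self):
        times = np.arange(0, 30) * 1000 / 30
        series = np.arange(30.0)
        a = D.window_amplitude(series, times, (100, 300),
                               reference="tone_end", duration_ms=100.0)
        b = D.window_amplitude(series, times, (200, 400))
        assert a == b

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            D.window_amplitude(np.ones(5), np.arange(5.0), (100, 200))


class TestDecomposition:
    def test_worked_scalar_example(self):
        c = D.dmmn_decomposition([0.10], [0.02], [0.06], [0.03])
        assert c.dmmn[0] == pytest.approx(0.08)
        assert c.deviance_detection[0] == pytest.approx(0.04)
        assert c.tone_difference[0] == pytest.approx(0.03)
        assert c.adaptation[0] == pytest.approx(0.01)

    def test_adaptation_zero_when_contexts_match(self, rng):
        x = rng.random(20)
        c = D.dmmn_decomposition(rng.random(20), x, rng.random(20), x)
        assert np.allclose(c.adaptation, 0.0)

    @given(st.integers(0, 2**31 - 1))
    def test_identity_exact(self, seed):
        r = np.random.default_rng(seed)
        dev, std, c100, c50 = r.normal(size=(4, 15))
        c = D.dmmn_decomposition(dev, std, c100, c50)
        resid = c.dmmn - (c.deviance_detection + c.tone_difference
                          + c.adaptation)
        assert np.abs(resid).max() < 1e-15

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            D.dmmn_decomposition(np.ones(5), np.ones(5), np.ones(5),
                                 np.ones(6))


class TestAmplitudeEstimator:
    def test_recovers_planted_injection(self, rng):
        from dmmn.synthetic import CalciumKernel
        k = CalciumKernel().sample(30.0)
        n_frames, base = 20, 5
        d = 0.08
        rel = 3  # 100-ms tone end at 30 Hz
        resp = np.array([d * k[f - rel] if f >= rel else 0.0
                         for f in np.arange(-base, n_frames - base)])
        dev = rng.normal(0, 0.004, (30, n_frames)) + resp
        ctl = rng.normal(0, 0.004, (10, n_frames))
        # integer-frame onsets so every trial has rel = 3
        dv = make_aligned(dev, roles=["deviant"] * 30,
                          durations=[100.0] * 30, soa=1.0)
        cv = make_aligned(ctl, roles=["control"] * 10,
                          durations=[100.0] * 10, soa=1.0)
        est = D.estimate_deviance_amplitude(dv, cv, k)
        assert est == pytest.approx(d, rel=0.1)


class TestDevianceMap:
    def _stacks(self, rng, amp=0.12):
        n_frames = 20
        dev = rng.normal(0, 0.01, (20, n_frames, 4, 4))
        ctl = rng.normal(0, 0.01, (8, n_frames, 4, 4))
        # responsive + deviant quadrant: top-left
        dev[:, 6:14, :2, :2] += amp
        times = (np.arange(n_frames) - 5) * 1000 / 30
        return dev, ctl, times

    def test_planted_quadrant_localized(self, rng):
        dev, ctl, times = self._stacks(rng)
        m = D.deviance_map(dev, ctl, times)
        assert m.responsive[:2, :2].all()
        assert not m.responsive[2:, 2:].any()
        assert np.isfinite(m.amplitude[:2, :2]).all()

    def test_noise_movie_mostly_empty(self, rng):
        dev = rng.normal(0, 0.01, (20, 20, 4, 4))
        ctl = rng.normal(0, 0.01, (8, 20, 4, 4))
        times = (np.arange(20) - 5) * 1000 / 30
        with pytest.warns(UserWarning):
            m = D.deviance_map(dev, ctl, times)
        assert m.responsive.mean() <= 0.05 or m.status == "empty"

    def test_display_floor_preserves_data(self, rng):
        dev, ctl, times = self._stacks(rng)
        # second weaker patch to fall under the half-max floor
        dev[:, 6:14, 3, 3] += 0.03
        m = D.deviance_map(dev, ctl, times)
        vmax = np.nanmax(m.amplitude)
        weak = m.amplitude[3, 3]
        assert weak < vmax / 2
        assert m.display[3, 3] == pytest.approx(vmax / 2)
        assert m.amplitude[3, 3] == weak  # data untouched


class TestPhotostim:
    def _stack(self, rng, resp_region=None, amp=0.1, n=20, frames=25):
        v = rng.normal(0, 0.01, (n, frames, 4, 4))
        if resp_region is not None:
            v[:, 8:20, resp_region[0], resp_region[1]] += amp
        return v

    def test_stim_only_region_excluded(self, rng):
        times = (np.arange(25) - 5) * 1000 / 30
        tone_stim = self._stack(rng, (slice(0, 4), slice(0, 4)))
        tone_only = self._stack(rng, (slice(0, 4), slice(0, 4)))
        stim_only = self._stack(rng, (slice(0, 2), slice(0, 2)))
        rep = D.photostim_comparison(tone_stim, tone_only, stim_only, times)
        assert not rep.included_mask[:2, :2].any()
        assert rep.included_mask[2:, 2:].all()

    def test_supra_additive_enhancement_detected(self, rng):
        times = (np.arange(25) - 5) * 1000 / 30
        region = (slice(0, 4), slice(0, 4))
        tone_stim = self._stack(rng, region, amp=0.2, n=40)
        tone_only = self._stack(rng, region, amp=0.1, n=40)
        stim_only = self._stack(rng, None, n=40)
        rep = D.photostim_comparison(tone_stim, tone_only, stim_only, times)
        assert rep.p_value < 0.05
        assert rep.effect_size > 0

    def test_null_case_no_difference(self, rng):
        times = (np.arange(25) - 5) * 1000 / 30
        region = (slice(0, 4), slice(0, 4))
        tone_stim = self._stack(rng, region, amp=0.1, n=30)
        tone_only = self._stack(rng, region, amp=0.1, n=30)
        stim_only = self._stack(rng, None, n=30)
        rep = D.photostim_comparison(tone_stim, tone_only, stim_only, times)
        assert rep.p_value >= 0.05


class TestCohensD:
    def test_identical_samples_zero(self):
        assert D.cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_constant_shift(self, rng):
        a = rng.normal(0, 1, 500)
        b = a + 2.0
        d = D.cohens_d(b, a)
        assert d == pytest.approx(2.0 / a.std(ddof=1), rel=1e-9)

    def test_matches_textbook_formula(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(0.5, 2, 40)
        d = D.cohens_d(a, b)
        sp = np.sqrt((29 * a.var(ddof=1) + 39 * b.var(ddof=1)) / 68)
        assert d == pytest.approx((a.mean() - b.mean()) / sp, abs=1e-12)

    def test_paired_mode(self, rng):
        a = rng.normal(0, 1, 50)
        b = a + rng.normal(0.3, 0.1, 50)
        d = D.cohens_d(b, a, paired=True)
        diff = b - a
        assert d == pytest.approx(diff.mean() / diff.std(ddof=1))

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError):
            D.cohens_d([1.0, 1.0], [2.0, 2.0])
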
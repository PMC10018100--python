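"""Scrubbing, confound regression, band-pass filtering, correlation."""

import numpy as np
import pandas as pd
import pytest

from fcendo.connectivity import (TB_BAND, TR_BAND, DegenerateDesignError,
                                 FlaggedRegionError, TimeSeriesMatrix,
                                 bandpass, boxcar_regressors,
                                 build_confound_matrix, correlation_matrix,
                                 detect_outlier_scans, double_gamma_hrf,
                                 regress_confounds, subject_fc)


def make_ts(values, tr=1.0):
    return TimeSeriesMatrix(values=np.asarray(values, float), tr_seconds=tr)


class TestOutlierDetection:
    def test_clean_data_unflagged(self):
        mask = detect_outlier_scans(np.zeros((200, 6)), np.ones(200))
        assert not mask.any()

    def test_single_translation_jump_flagged(self):
        motion = np.zeros((300, 6))
        motion[100:, 0] = 5.0  # 5 mm step at t=100
        mask = detect_outlier_scans(motion, np.ones(300), fd_threshold=0.9)
        assert mask[100] and mask.sum() == 1

    def test_rotation_converted_on_sphere(self):
        motion = np.zeros((10, 6))
        motion[5:, 3] = 0.02   # 0.02 rad * 50 mm = 1 mm displacement
        mask = detect_outlier_scans(motion, np.ones(10), fd_threshold=0.9)
        assert mask[5] and mask.sum() == 1

    def test_white_noise_global_signal_rarely_flags(self):
        rng = np.random.default_rng(0)
        for s in range(5):
            gs = rng.standard_normal(300)
            mask = detect_outlier_scans(np.zeros((300, 6)), gs, z_threshold=5.0)
            assert mask.sum() == 0  # 2*Phi(-5) ~ 6e-7 per scan

    def test_wrong_column_count(self):
        with pytest.raises(ValueError):
            detect_outlier_scans(np.zeros((50, 5)), np.ones(50))


class TestConfoundMatrix:
    def test_rest_only_column_count(self):
        design = build_confound_matrix(np.zeros((100, 6)),
                                       np.zeros(100, dtype=bool))
        assert design.shape[1] == 13  # intercept + 6 motion + 6 diffs

    def test_spike_columns(self):
        mask = np.zeros(100, dtype=bool)
        mask[[10, 50]] = True
        design = build_confound_matrix(np.zeros((100, 6)), mask)
        assert design.shape[1] == 15
        assert design["spike_10"].sum() == 1.0

    def test_tr_mode_adds_task_regressor_and_derivative(self):
        events = pd.DataFrame({"onset": [20.0], "duration": [20.0],
                               "trial_type": ["task"]})
        tb = build_confound_matrix(np.zeros((100, 6)), np.zeros(100, bool),
                                   events=events, mode="tb")
        tr = build_confound_matrix(np.zeros((100, 6)), np.zeros(100, bool),
                                   events=events, mode="tr")
        assert tr.shape[1] == tb.shape[1] + 2

    def test_all_flagged_degenerate(self):
        with pytest.raises(DegenerateDesignError):
            build_confound_matrix(np.zeros((20, 6)), np.ones(20, bool))


class TestRegression:
    def test_intercept_only_demeans(self):
        rng = np.random.default_rng(1)
        ts = make_ts(rng.standard_normal((80, 3)) + 5.0)
        out = regress_confounds(ts, np.ones((80, 1)))
        assert np.allclose(out.values, ts.values - ts.values.mean(0))

    def test_confound_column_fully_removed(self):
        rng = np.random.default_rng(2)
        conf = rng.standard_normal((100, 1))
        ts = make_ts(np.hstack([conf, rng.standard_normal((100, 1))]))
        out = regress_confounds(ts, np.hstack([np.ones((100, 1)), conf]))
        assert np.abs(out.values[:, 0]).max() < 1e-10

    def test_residuals_orthogonal_to_motion(self):
        rng = np.random.default_rng(3)
        motion = rng.standard_normal((200, 6))
        signal = 2 * motion[:, [0]] + 0.5 * rng.standard_normal((200, 1))
        ts = make_ts(np.hstack([signal, rng.standard_normal((200, 1))]))
        design = build_confound_matrix(motion, np.zeros(200, bool))
        out = regress_confounds(ts, design)
        r = np.corrcoef(out.values[:, 0], motion[:, 0])[0, 1]
        assert abs(r) < 1e-8


class TestBandpass:
    def test_passband_tone_retained(self):
        t = np.arange(600)
        tone = np.sin(2 * np.pi * 0.03 * t)
        ts = make_ts(np.column_stack([tone, tone]))
        out = bandpass(ts, *TR_BAND)
        core = slice(100, 500)  # ignore filter edges
        assert np.abs(out.values[core, 0]).max() >= 0.9

    def test_stopband_tone_attenuated(self):
        t = np.arange(600)
        tone = np.sin(2 * np.pi * 0.2 * t)
        ts = make_ts(np.column_stack([tone, tone]))
        out = bandpass(ts, *TR_BAND)
        core = slice(100, 500)  # steady state, away from filter edges
        assert np.abs(out.values[core, 0]).max() <= 0.1

    def test_dc_removed(self):
        ts = make_ts(np.full((300, 2), 7.0))
        out = bandpass(ts, *TB_BAND)
        assert np.abs(out.values).max() < 1e-6

    def test_invalid_band(self):
        ts = make_ts(np.random.default_rng(0).standard_normal((100, 2)))
        with pytest.raises(ValueError):
            bandpass(ts, 0.1, 0.6)   # above Nyquist at TR=1
        with pytest.raises(ValueError):
            bandpass(ts, 0.2, 0.1)


class TestCorrelation:
    def test_duplicate_and_negated_regions(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(120)
        ts = make_ts(np.column_stack([x, x, -x]))
        c = correlation_matrix(ts)
        assert c.values[0, 1] == pytest.approx(1.0)
        assert c.values[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(c.values), 1.0)

    def test_independent_noise_small_r(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            ts = make_ts(rng.standard_normal((300, 2)))
            c = correlation_matrix(ts)
            assert abs(c.values[0, 1]) < 0.2   # null sd ~ 1/sqrt(300)

    def test_zero_variance_region_flagged(self):
        vals = np.random.default_rng(6).standard_normal((100, 3))
        vals[:, 1] = 0.0
        with pytest.raises(FlaggedRegionError):
            correlation_matrix(make_ts(vals))


class TestHRF:
    def test_double_gamma_shape(self):
        h = double_gamma_hrf(1.0)
        assert h.max() == pytest.approx(1.0)
        peak = int(np.argmax(h))
        assert 4 <= peak <= 7
        assert h[12:25].min() < 0   # undershoot present

    def test_boxcar_regressors(self):
        events = pd.DataFrame({"onset": [10.0, 50.0], "duration": [10.0, 10.0],
                               "trial_type": ["task", "task"]})
        box = boxcar_regressors(events, 100, 1.0)
        assert box["block_task"].sum() == 20


class TestSubjectFC:
    def _task_cohort_ts(self, seed, amp=3.0):
        rng = np.random.default_rng(seed)
        t = np.arange(300)
        box = ((t // 30) % 2 == 1).astype(float)
        hrf = double_gamma_hrf(1.0)
        evoked = np.convolve(box, hrf)[:300]
        weights = rng.uniform(0.5, 1.5, size=12)
        vals = amp * np.outer(evoked, weights) + rng.standard_normal((300, 12))
        events = pd.DataFrame({"onset": [30.0 + 60 * k for k in range(5)],
                               "duration": [30.0] * 5,
                               "trial_type": ["task"] * 5})
        return make_ts(vals), events

    def test_tr_mode_attenuates_task_driven_correlations(self):
        deltas = []
        for seed in range(5):
            ts, events = self._task_cohort_ts(seed)
            motion = np.zeros((300, 6))
            tb = subject_fc(ts, events, motion, mode="tb")
            tr = subject_fc(ts, events, motion, mode="tr")
            off = ~np.eye(12, dtype=bool)
            deltas.append(np.abs(tb.values[off]).mean()
                          - np.abs(tr.values[off]).mean())
        assert np.mean(deltas) > 0
        assert min(deltas) > 0

    def test_deterministic(self):
        ts, events = self._task_cohort_ts(1)
        motion = np.zeros((300, 6))
        a = subject_fc(ts, events, motion, mode="tb")
        b = subject_fc(ts, events, motion, mode="tb")
        assert np.array_equal(a.values, b.values)

    def test_modes_agree_without_events_and_same_band(self):
        rng = np.random.default_rng(9)
        ts = make_ts(rng.standard_normal((200, 8)))
        motion = np.zeros((200, 6))
        a = subject_fc(ts, None, motion, mode="tb", band=(0.009, 0.09))
        b = subject_fc(ts, None, motion, mode="tr", band=(0.009, 0.09))
        assert np.allclose(a.values, b.values)

    def test_provenance_recorded(self):
        ts, events = self._task_cohort_ts(2)
        fc = subject_fc(ts, events, np.zeros((300, 6)), mode="tr",
                        subject_id="sub-001")
        assert fc.provenance["mode"] == "tr"
        assert fc.provenance["band_hz"] == list(TR_BAND)
        assert fc.subject_id == "sub-001"
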
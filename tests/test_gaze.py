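"""Gaze preprocessing: smoothing, filtering, QC, I-DT fixation detection
(against a brute-force oracle), pre-bounce selection and discretization."""

import numpy as np
import pytest

from pupilhgf.gaze import (
    Fixation,
    GazeTrace,
    butter_lowpass,
    detect_fixations,
    discretize_pitch,
    median_smooth3,
    participant_gaze_qc,
    select_prebounce_fixation,
    trial_gaze_qc,
)


def _trace(pitch, yaw=None, rate=120.0, valid=None, bounce=None):
    n = len(pitch)
    t = np.arange(n) / rate
    yaw = np.zeros(n) if yaw is None else yaw
    valid = np.ones(n, dtype=bool) if valid is None else valid
    bounce = t[-1] if bounce is None else bounce
    return GazeTrace(t=t, pitch=np.asarray(pitch, dtype=float), yaw=yaw,
                     valid=valid, rate=rate, bounce_time=bounce,
                     contact_time=bounce + 0.5)


class TestMedianSmooth:
    @pytest.mark.parametrize("series,expected", [
        ([5, 5, 5, 5], [5, 5, 5, 5]),
        ([1, 100, 2, 3], [1, 2, 3, 3]),
        ([7], [7]),
    ])
    def test_hand_evaluated_windows(self, series, expected):
        assert median_smooth3(series).tolist() == expected


class TestButterworth:
    def test_constant_series_unchanged(self):
        x = np.full(500, 4.2)
        assert np.allclose(butter_lowpass(x, 120.0, 15.0), x, atol=1e-9)

    def test_cutoff_sinusoid_halved(self):
        # dual pass: two -3 dB attenuations = amplitude ratio 0.5
        t = np.arange(0, 8, 1 / 120)
        x = np.sin(2 * np.pi * 15.0 * t)
        out = butter_lowpass(x, 120.0, 15.0)
        mid = out[240:-240]
        assert np.abs(mid).max() == pytest.approx(0.5, abs=0.02)

    def test_low_frequency_preserved(self):
        t = np.arange(0, 8, 1 / 120)
        x = np.sin(2 * np.pi * 1.5 * t)  # 0.1 x cutoff
        out = butter_lowpass(x, 120.0, 15.0)
        mid = out[240:-240]
        assert np.abs(mid).max() == pytest.approx(1.0, abs=0.01)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butter_lowpass(np.zeros(100), 120.0, 60.0)


class TestTrialQC:
    def test_missing_fraction_rule(self):
        valid = np.ones(200, dtype=bool)
        valid[::4] = False  # 25 % invalid, max run 1 sample
        keep, reason = trial_gaze_qc(_trace(np.zeros(200), valid=valid))
        assert not keep and reason == "missing_fraction"

    def test_tracking_gap_rule(self):
        valid = np.ones(300, dtype=bool)
        valid[100:115] = False  # 15 samples at 120 Hz = 125 ms, 5 % of trial
        keep, reason = trial_gaze_qc(_trace(np.zeros(300), valid=valid))
        assert not keep and reason == "tracking_gap"

    def test_clean_trace_kept(self):
        keep, reason = trial_gaze_qc(_trace(np.zeros(300)))
        assert keep and reason is None


def _brute_force_idt(trace, dispersion_deg=3.0, min_dur_s=0.100):
    """Exhaustive re-implementation: for each window start, scan every
    candidate window and recompute dispersion from scratch."""
    out = []
    valid_idx = np.flatnonzero(trace.valid)
    runs = []
    if len(valid_idx):
        split = np.flatnonzero(np.diff(valid_idx) > 1)
        runs = np.split(valid_idx, split + 1)
    for idx in runs:
        i = 0
        while i < len(idx):
            j_best = i
            for j in range(i, len(idx)):
                w = idx[i:j + 1]
                disp = (trace.pitch[w].max() - trace.pitch[w].min()) + \
                       (trace.yaw[w].max() - trace.yaw[w].min())
                if disp <= dispersion_deg:
                    j_best = j
                else:
                    break
            if trace.t[idx[j_best]] - trace.t[idx[i]] >= min_dur_s:
                w = idx[i:j_best + 1]
                out.append((trace.t[idx[i]], trace.t[idx[j_best]],
                            trace.pitch[w].mean(), trace.yaw[w].mean()))
                i = j_best + 1
            else:
                i += 1
    return out


class TestFixationDetection:
    def test_single_stationary_cluster(self):
        rng = np.random.default_rng(0)
        fast = np.tile([0.0, -35.0], 30)      # saccadic back-and-forth motion
        pitch = np.concatenate([
            fast,
            -15 + rng.normal(0, 0.1, 18),     # ~150 ms stationary cluster
            fast + 20.0,
        ])
        fixations = detect_fixations(_trace(pitch))
        assert len(fixations) == 1
        assert fixations[0].centroid_pitch == pytest.approx(-15, abs=0.1)
        assert fixations[0].duration >= 0.100

    def test_short_cluster_rejected(self):
        fast = np.tile([0.0, -35.0], 30)
        pitch = np.concatenate([fast, np.full(10, -15.0), fast + 20.0])
        # 10 samples span 75 ms at 120 Hz: below the 100 ms minimum
        assert detect_fixations(_trace(pitch)) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_noise(self, seed):
        rng = np.random.default_rng(seed)
        n = 400
        pitch = np.cumsum(rng.normal(0, 0.8, n))
        yaw = np.cumsum(rng.normal(0, 0.8, n))
        valid = rng.random(n) > 0.05
        trace = _trace(pitch, yaw=yaw, valid=valid)
        got = detect_fixations(trace)
        expected = _brute_force_idt(trace)
        assert len(got) == len(expected)
        for f, (on, off, cp, cy) in zip(got, expected):
            assert f.onset == pytest.approx(on)
            assert f.offset == pytest.approx(off)
            assert f.centroid_pitch == pytest.approx(cp)
            assert f.centroid_yaw == pytest.approx(cy)

    def test_fixations_ordered_and_disjoint(self):
        rng = np.random.default_rng(99)
        pitch = np.cumsum(rng.normal(0, 0.5, 500))
        fixations = detect_fixations(_trace(pitch))
        for a, b in zip(fixations, fixations[1:]):
            assert a.offset < b.onset


class TestPrebounceSelection:
    def _fix(self, offset):
        return Fixation(onset=offset - 0.15, offset=offset, centroid_pitch=-15,
                        centroid_yaw=0, n_samples=18)

    def test_within_window_selected(self):
        f = self._fix(1.0)
        assert select_prebounce_fixation([f], bounce_time=1.2) is f

    def test_outside_window_missing(self):
        assert select_prebounce_fixation([self._fix(0.6)], bounce_time=1.2) is None

    def test_latest_qualifying_wins(self):
        early, late = self._fix(0.9), self._fix(1.1)
        assert select_prebounce_fixation([early, late], bounce_time=1.2) is late


class TestDiscretization:
    def test_threshold_crossings(self):
        # large jumps cross the 1 SD(change) threshold; small ones do not
        pitch = np.array([-15.0, -27.0, -15.0, -27.0, -16.0, -15.0, -15.5])
        y, sigma = discretize_pitch(pitch)
        assert np.isnan(y[0])
        assert y[1] == 1.0  # downward shift -> expecting normal bounce
        assert y[2] == 0.0
        assert y[3] == 1.0
        assert y[4] == 0.0
        assert y[5] == 0.0 and y[6] == 0.0  # sub-threshold carries

    def test_subthreshold_carries_previous(self):
        pitch = np.array([-15.0, -25.0, -25.2, -25.1, -15.0])
        y, sigma = discretize_pitch(pitch)
        assert y[1] == 1.0
        assert y[2] == 1.0 and y[3] == 1.0  # carried
        assert y[4] == 0.0

    def test_subthreshold_missing_without_carry(self):
        pitch = np.array([-15.0, -25.0, -25.2, -25.1, -24.9, -25.0, -15.0])
        y, _ = discretize_pitch(pitch, carry=False)
        assert y[1] == 1.0
        assert np.isnan(y[2]) and np.isnan(y[3])
        assert y[6] == 0.0

    def test_missing_pitch_propagates(self):
        pitch = np.array([-15.0, np.nan, -25.0, -25.1, -15.0])
        y, _ = discretize_pitch(pitch)
        assert np.isnan(y[1])
        assert np.isnan(y[2])  # predecessor missing, carry source missing
        assert y[4] == 0.0

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        pitch = np.cumsum(rng.normal(0, 2.0, 60)) - 15
        y0, s0 = discretize_pitch(pitch)
        y1, s1 = discretize_pitch(pitch + 7.5)
        y2, s2 = discretize_pitch(pitch * 3.0)
        np.testing.assert_array_equal(y0, y1)
        np.testing.assert_array_equal(y0, y2)
        assert s2 == pytest.approx(3.0 * s0)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            discretize_pitch(np.array([np.nan, -15.0]))


class TestParticipantQC:
    def test_excessive_missing_excludes(self):
        pitch = np.full(100, -15.0)
        pitch[:20] = np.nan
        include, _, fractions = participant_gaze_qc(pitch)
        assert not include
        assert fractions["missing"] == pytest.approx(0.20)

    def test_clean_included(self):
        rng = np.random.default_rng(0)
        include, cleaned, fractions = participant_gaze_qc(rng.normal(-15, 2, 100))
        assert include and fractions["total"] == 0.0

    def test_extreme_value_flagged_as_outlier(self, rng):
        pitch = rng.normal(0.0, 1.0, 200)
        pitch[50] = 5.0  # z = 5 on unit-normal pitches
        include, cleaned, fractions = participant_gaze_qc(pitch)
        assert np.isnan(cleaned[50])
        assert fractions["outliers"] == pytest.approx(1 / 200)
        assert include
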
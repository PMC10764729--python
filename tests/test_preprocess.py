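"""Cleaning-chain unit tests: blink interpolation, smoothing,
z-transform and the missingness / gaze rejection rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pupilbayes.preprocess import (
    GazeWindow,
    PreprocessParams,
    fit_gaze_window,
    interpolate_blinks,
    preprocess_session,
    reject_gaze,
    reject_missing,
    smooth_sliding_mean,
    zscore_session,
)

from _oracles import brute_force_window_mean, linear_interp_oracle
from conftest import make_series


def simple_events(fs=250.0, n_trials=1, fixation_s=1.0, anticipation_s=6.0):
    rows = []
    t = 0.5
    for k in range(n_trials):
        rows.append(
            {
                "participant_id": "P001",
                "trial_index": k + 1,
                "condition": ["reward", "neutral", "control"][k % 3],
                "fixation_onset_s": t,
                "cue_onset_s": t + fixation_s,
                "cue_offset_s": t + fixation_s + anticipation_s,
                "feedback_onset_s": np.nan,
                "feedback_success": np.nan,
            }
        )
        t += fixation_s + anticipation_s + 1.0
    return pd.DataFrame(rows)


class TestInterpolateBlinks:
    def test_zero_pad_linear_bridge(self):
        s = make_series([1.0, 2.0, 0.0, 0.0, 5.0], valid=[1, 1, 0, 0, 1])
        out = interpolate_blinks(s, pad_ms=0.0)
        np.testing.assert_allclose(out.pupil, [1, 2, 3, 4, 5])
        assert list(out.interpolated) == [False, False, True, True, False]
        # raw validity is never rewritten
        assert list(out.valid) == [True, True, False, False, True]

    def test_no_invalid_is_identity(self):
        s = make_series(np.sin(np.arange(100)))
        out = interpolate_blinks(s)
        np.testing.assert_array_equal(out.pupil, s.pupil)
        assert not out.interpolated.any()

    def test_padded_anchors_and_line_oracle(self):
        # 50-sample blink at 250 Hz with 100 ms pad: anchors sit exactly
        # 25 samples outside the gap and the bridged span lies on the
        # two-point line between them
        rng = np.random.default_rng(0)
        pupil = rng.normal(5.0, 1.0, 1000)
        valid = np.ones(1000, dtype=bool)
        valid[400:450] = False
        s = make_series(pupil, valid)
        out = interpolate_blinks(s, pad_ms=100.0)
        left, right = 375, 474  # 400 - 25, 449 + 25
        assert not out.interpolated[left] and not out.interpolated[right]
        assert out.interpolated[left + 1 : right].all()
        expected = linear_interp_oracle(
            s.time_s[left], pupil[left], s.time_s[right], pupil[right],
            s.time_s[left + 1 : right],
        )
        np.testing.assert_allclose(out.pupil[left + 1 : right], expected, atol=1e-12)
        # anchors keep their own values
        assert out.pupil[left] == pupil[left] and out.pupil[right] == pupil[right]

    def test_boundary_gap_left_missing(self):
        s = make_series([0.0, 0.0, 3.0, 4.0], valid=[0, 0, 1, 1])
        out = interpolate_blinks(s, pad_ms=0.0)
        assert np.isnan(out.pupil[0]) and np.isnan(out.pupil[1])
        assert not out.interpolated[:2].any()

    def test_all_invalid_errors(self):
        s = make_series([0.0, 0.0, 0.0], valid=[0, 0, 0])
        with pytest.raises(ValueError, match="entire series"):
            interpolate_blinks(s)


class TestSmoothing:
    def test_constant_unchanged(self):
        s = make_series(np.full(500, 3.25))
        np.testing.assert_allclose(smooth_sliding_mean(s).pupil, 3.25)

    def test_impulse_interior_mean(self):
        pupil = np.zeros(500)
        pupil[250] = 1.0
        out = smooth_sliding_mean(make_series(pupil), window_ms=200.0)
        assert out.pupil[250] == pytest.approx(1.0 / 51.0)

    def test_subsample_window_is_identity(self):
        s = make_series(np.random.default_rng(1).normal(size=100))
        out = smooth_sliding_mean(s, window_ms=2.0)  # < one 250 Hz period
        np.testing.assert_array_equal(out.pupil, s.pupil)

    @pytest.mark.parametrize("i", [0, 3, 24, 250, 475, 499])
    def test_truncated_window_oracle(self, i):
        rng = np.random.default_rng(2)
        pupil = rng.normal(size=500)
        out = smooth_sliding_mean(make_series(pupil), window_ms=200.0)
        assert out.pupil[i] == pytest.approx(brute_force_window_mean(pupil, i, 25))

    def test_length_and_flags_preserved(self):
        valid = np.ones(300, dtype=bool)
        valid[100:120] = False
        s = make_series(np.random.default_rng(3).normal(size=300), valid)
        out = smooth_sliding_mean(s)
        assert out.pupil.size == 300
        np.testing.assert_array_equal(out.valid, valid)


class TestZscore:
    def test_two_point_symmetry(self):
        out = zscore_session(make_series([0.0, 2.0]))
        np.testing.assert_allclose(out.pupil, [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_idempotent(self):
        s = make_series(np.random.default_rng(4).normal(size=400))
        once = zscore_session(s)
        twice = zscore_session(once)
        np.testing.assert_allclose(twice.pupil, once.pupil, atol=1e-12)

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mean_zero_sd_one(self, seed):
        vals = np.random.default_rng(seed).normal(2.0, 3.0, 200)
        out = zscore_session(make_series(vals))
        assert abs(np.mean(out.pupil)) < 1e-10
        assert abs(np.std(out.pupil, ddof=1) - 1.0) < 1e-10

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            zscore_session(make_series(np.ones(50)))


class TestRejectMissing:
    def _series_with_missing(self, frac, fs=250.0):
        n = int(9.0 * fs)
        valid = np.ones(n, dtype=bool)
        ev = simple_events(fs)
        i0 = int(ev.cue_onset_s[0] * fs)
        n_win = int(6.0 * fs)
        n_miss = int(round(frac * n_win))
        valid[i0 : i0 + n_miss] = False
        pupil = np.random.default_rng(0).normal(size=n)
        pupil[~valid] = np.nan
        return make_series(pupil, valid), ev

    def test_strict_trial_threshold(self):
        s, ev = self._series_with_missing(0.5)
        qc = reject_missing(s, ev, params=PreprocessParams(count_interpolated_as_missing=False))
        assert not qc.trials["dropped"].iloc[0]  # exactly 50%: kept
        s, ev = self._series_with_missing(0.51)
        qc = reject_missing(s, ev, params=PreprocessParams(count_interpolated_as_missing=False))
        assert qc.trials["dropped"].iloc[0]
        assert qc.trials["drop_reason"].iloc[0] == "missing"

    def test_strict_session_threshold(self):
        n = 1000
        for n_missing, dropped in [(150, False), (151, True)]:
            valid = np.ones(n, dtype=bool)
            valid[:n_missing] = False
            s = make_series(np.random.default_rng(1).normal(size=n), valid)
            ev = simple_events(fs=250.0, fixation_s=0.1, anticipation_s=1.0).iloc[:0]
            qc = reject_missing(
                s, ev, params=PreprocessParams(count_interpolated_as_missing=False)
            )
            assert qc.session_missing_fraction == pytest.approx(n_missing / n)
            assert qc.session_dropped is dropped

    def test_event_outside_series_errors(self):
        s = make_series(np.zeros(100) + np.arange(100))
        ev = simple_events()  # extends past 0.4 s of data
        with pytest.raises(ValueError, match="outside"):
            reject_missing(s, ev)


class TestGazeWindow:
    def _sessions(self, sds, n_trials=1, fs=250.0, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for i, sd in enumerate(sds):
            ev = simple_events(fs, n_trials=n_trials)
            ev["participant_id"] = f"P{i:03d}"
            n = int((ev["cue_offset_s"].max() + 1) * fs)
            gx = 512.0 + (rng.normal(0, sd, n) if sd else np.zeros(n))
            gy = 384.0 + (rng.normal(0, sd, n) if sd else np.zeros(n))
            s = make_series(rng.normal(size=n), fs=fs, participant_id=f"P{i:03d}",
                            gaze_x=gx, gaze_y=gy)
            out[f"P{i:03d}"] = (s, ev)
        return out

    def test_halfwidth_arithmetic(self):
        # SDs of 10 and 20 px across two participants -> 3.3 * 15 = 49.5
        sessions = self._sessions([10.0, 20.0])
        # replace gaze with exact-SD sequences for deterministic arithmetic
        for k, sd in zip(sessions, (10.0, 20.0)):
            s, ev = sessions[k]
            i0 = int(ev.cue_onset_s[0] * 250)
            i1 = int(ev.cue_offset_s[0] * 250)
            n_win = i1 - i0
            pattern = np.resize([sd, -sd], n_win)
            scale = sd / np.std(pattern, ddof=1)
            s.gaze_x_px[:] = 512.0
            s.gaze_y_px[:] = 384.0
            s.gaze_x_px[i0:i1] = 512.0 + pattern * scale
            s.gaze_y_px[i0:i1] = 384.0 + pattern * scale
        windows = fit_gaze_window(sessions)
        for w in windows.values():
            assert w.half_width_x_px == pytest.approx(3.3 * 15.0)

    def test_monte_carlo_halfwidth(self):
        # Gaussian gaze noise sd 15 px, many participants: 3.3 * 15 = 49.5
        sessions = self._sessions([15.0] * 50, seed=5)
        windows = fit_gaze_window(sessions)
        w = next(iter(windows.values()))
        assert w.half_width_x_px == pytest.approx(49.5, rel=0.03)

    def test_degenerate_window_flagged_downstream(self):
        sessions = self._sessions([0.0, 0.0])
        windows = fit_gaze_window(sessions)
        s, ev = sessions["P000"]
        qc = reject_missing(s, ev)
        with pytest.raises(ValueError, match="half-width"):
            reject_gaze(s, ev, windows["P000"], qc)

    def test_single_participant_errors(self):
        sessions = self._sessions([10.0])
        with pytest.raises(ValueError, match="2 participants"):
            fit_gaze_window(sessions)

    @pytest.mark.parametrize("dur_s,dropped", [(0.8, False), (1.2, True)])
    def test_one_second_rule(self, dur_s, dropped):
        sessions = self._sessions([15.0, 15.0], seed=6)
        s, ev = sessions["P000"]
        i0 = int(ev.cue_onset_s[0] * 250) + 50
        s.gaze_x_px[i0 : i0 + int(dur_s * 250)] += 1000.0
        windows = fit_gaze_window(sessions)
        qc = reject_missing(s, ev)
        qc = reject_gaze(s, ev, windows["P000"], qc)
        assert bool(qc.trials["dropped"].iloc[0]) is dropped
        if dropped:
            assert qc.trials["drop_reason"].iloc[0] == "gaze"

    def test_centered_gaze_keeps_all(self):
        sessions = self._sessions([15.0, 15.0], seed=7)
        windows = fit_gaze_window(sessions)
        for pid, (s, ev) in sessions.items():
            qc = reject_gaze(s, ev, windows[pid], reject_missing(s, ev))
            assert not qc.trials["dropped"].any()


class TestPlantedArtifacts:
    def test_dropped_set_equals_planted_set(self, artifact_study, artifact_pipeline):
        _, reports, _ = artifact_pipeline
        expected = artifact_study.truth.expected_dropped()
        got = {pid: set(rep.dropped_trials) for pid, rep in reports.items()}
        assert got == expected
        assert sum(len(v) for v in expected.values()) > 0  # fixture planted something

    def test_partition_invariant(self, artifact_study, artifact_pipeline):
        _, reports, _ = artifact_pipeline
        for pid, rep in reports.items():
            kept, dropped = set(rep.kept_trials), set(rep.dropped_trials)
            assert kept | dropped == set(range(1, 31))
            assert not kept & dropped

    def test_rerun_bit_identical(self, artifact_study):
        from pupilbayes.preprocess import preprocess_study

        pairs = artifact_study.session_pairs()
        clean_a, _, _ = preprocess_study(pairs)
        clean_b, _, _ = preprocess_study(pairs)
        for pid in clean_a:
            np.testing.assert_array_equal(clean_a[pid].pupil, clean_b[pid].pupil)

    def test_interpolation_preserves_untouched_samples(self, artifact_study):
        pid, (series, events) = next(iter(artifact_study.session_pairs().items()))
        out = interpolate_blinks(series)
        untouched = series.valid & ~out.interpolated
        np.testing.assert_array_equal(out.pupil[untouched], series.pupil[untouched])
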
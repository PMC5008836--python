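"""Scoring chain: tachometer, EMG envelope, trial scores, artifacts, summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import loudtone as lt
from loudtone.io import Channel, Recording
from loudtone.scoring import (IbiSeries, PRE_WINDOW, POST_WINDOWS,
                              summarize_subject_condition)


# ---------------------------------------------------------------------------
# tachometer
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("ibi,expected", [(1.0, 60.0), (0.5, 120.0)])
def test_constant_ibi_gives_constant_hr(ibi, expected):
    beats = np.arange(0, 20 * ibi + ibi / 2, ibi)
    trace = lt.ibi_to_hr_trace(IbiSeries(beats), sampling_rate=100.0)
    assert np.allclose(trace.samples, expected, atol=1e-9)


def test_hr_trace_shows_preceding_interval():
    """IBIs [1.0, 0.8, 1.0]: on (1.8, 2.8] the trace reads 60/0.8 = 75 BPM."""
    trace = lt.ibi_to_hr_trace(IbiSeries([0.0, 1.0, 1.8, 2.8]), sampling_rate=10.0)
    t = trace.times
    inside = (t > 1.8) & (t <= 2.8)
    assert np.allclose(trace.samples[inside], 75.0)
    # back-fill before the first defined value
    assert np.allclose(trace.samples[t <= 1.0], 60.0)


def _brute_force_tachometer(beats, t):
    """Per-sample lookup of the interval preceding the last beat before t."""
    out = np.empty_like(t)
    ibis = np.diff(beats)
    for i, ti in enumerate(t):
        done = [k for k in range(1, len(beats)) if beats[k] < ti]
        k = done[-1] if done else 1
        out[i] = 60.0 / ibis[k - 1]
    return out


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=0.4, max_value=1.5), min_size=3, max_size=30),
       st.floats(min_value=10, max_value=100))
def test_hr_trace_matches_brute_force_oracle(ibis, fs):
    beats = np.concatenate([[0.0], np.cumsum(ibis)])
    trace = lt.ibi_to_hr_trace(IbiSeries(beats), sampling_rate=fs)
    oracle = _brute_force_tachometer(beats, trace.times)
    assert np.allclose(trace.samples, oracle, atol=1e-9)


def test_non_increasing_beats_rejected():
    with pytest.raises(lt.DataError):
        IbiSeries([0.0, 1.0, 1.0])


# ---------------------------------------------------------------------------
# EMG envelope
# ---------------------------------------------------------------------------

def _emg(samples, fs=1000.0):
    return Channel("EMG", fs, "uV", np.asarray(samples, dtype=float))


def test_envelope_of_zero_is_zero():
    env = lt.rectify_integrate_emg(_emg(np.zeros(100)))
    assert np.all(env.samples == 0)


def test_envelope_converges_to_constant_amplitude():
    """Alternating-sign input of amplitude c: steady state c within 5 tau."""
    c = 3.7
    x = c * (-1.0) ** np.arange(2000)
    env = lt.rectify_integrate_emg(_emg(x), time_constant=0.010)
    n5tau = int(5 * 0.010 * 1000)
    assert abs(env.samples[n5tau] - c) / c < 0.01
    assert np.all(np.abs(env.samples[n5tau:] - c) / c < 0.01)


def test_envelope_impulse_response_matches_recursion():
    x = np.zeros(200)
    x[0] = 1.0
    tau, fs = 0.010, 1000.0
    env = lt.rectify_integrate_emg(_emg(x, fs), time_constant=tau)
    alpha = 1 - np.exp(-1.0 / (fs * tau))
    # direct recursion with y[0] = |x[0]|
    y = np.empty_like(x)
    y[0] = 1.0
    for n in range(1, len(x)):
        y[n] = y[n - 1] + alpha * (abs(x[n]) - y[n - 1])
    assert np.allclose(env.samples, y, atol=1e-12)
    assert np.allclose(env.samples, (1 - alpha) ** np.arange(200), atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=2, max_size=300))
def test_envelope_nonnegative_and_bounded_by_running_max(xs):
    env = lt.rectify_integrate_emg(_emg(xs)).samples
    running_max = np.maximum.accumulate(np.abs(xs))
    assert np.all(env >= 0)
    assert np.all(env <= running_max + 1e-12)


def test_envelope_requires_dt_below_time_constant():
    with pytest.raises(lt.ConfigurationError):
        lt.rectify_integrate_emg(_emg(np.zeros(10), fs=50.0), time_constant=0.010)


# ---------------------------------------------------------------------------
# trial scores
# ---------------------------------------------------------------------------

def _single_channel_recording(name, samples, fs, onset=10.0):
    ch = Channel(name, fs, {"HR": "BPM", "SC": "uS", "EMG": "uV"}[name], samples)
    events = pd.DataFrame({"onset": [onset], "duration": [0.5], "label": ["tone"]})
    return Recording(subject_id="s1", condition={"bandwidth": "pure_tone",
                                                 "posture": "sitting"},
                     channels={name: ch}, events=events)


def test_constant_trace_scores_zero():
    rec = _single_channel_recording("HR", np.full(2000, 70.0), 100.0)
    s = lt.score_trial(rec, 10.0, "HR")
    assert s.raw_response == 0.0 and s.transformed_response == 0.0
    assert s.pre_level == 70.0


def test_baseline_to_peak_arithmetic():
    """Pre-mean 60, post-max 66: raw 6 BPM, transformed sqrt(6)."""
    fs = 100.0
    x = np.full(2000, 60.0)
    onset = 10.0
    x[int((onset + 2.0) * fs)] = 66.0  # single peak inside [1, 4]
    rec = _single_channel_recording("HR", x, fs)
    s = lt.score_trial(rec, onset, "HR")
    assert np.isclose(s.raw_response, 6.0)
    assert np.isclose(s.transformed_response, np.sqrt(6.0))


def test_sc_peak_found_by_grid_search_oracle():
    """Tonic + unit bi-exponential SCR: score equals the window grid maximum."""
    fs, onset, tonic = 100.0, 12.0, 10.0
    t = np.arange(int(30 * fs)) / fs
    u = np.clip(t - onset, 0, None)
    kernel = np.where(t >= onset, np.exp(-u / 2.0) - np.exp(-u / 0.75), 0.0)
    rec = _single_channel_recording("SC", tonic + kernel, fs, onset=onset)
    s = lt.score_trial(rec, onset, "SC")
    # independent dense search over every sample in [onset+1, onset+4]
    mask = (t >= onset + 1.0) & (t <= onset + 4.0)
    oracle = np.max(kernel[mask])
    assert np.isclose(s.raw_response, oracle, atol=1e-12)


@settings(max_examples=20, deadline=None)
@given(st.floats(min_value=-30, max_value=30),
       st.floats(min_value=0.1, max_value=7.0),
       st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_shift_invariance_and_scale_equivariance(shift, k, seed):
    rng = np.random.default_rng(seed)
    fs, onset = 100.0, 10.0
    x = 70 + rng.normal(0, 2, 2000)
    base = lt.score_trial(_single_channel_recording("HR", x, fs), onset, "HR")
    shifted = lt.score_trial(_single_channel_recording("HR", x + shift, fs),
                             onset, "HR")
    scaled = lt.score_trial(_single_channel_recording("HR", k * x, fs), onset, "HR")
    assert np.isclose(shifted.raw_response, base.raw_response, atol=1e-9)
    assert np.isclose(scaled.raw_response, k * base.raw_response, atol=1e-9)
    assert np.isclose(abs(scaled.transformed_response),
                      np.sqrt(k) * abs(base.transformed_response), atol=1e-9)


@given(st.floats(min_value=-1e6, max_value=1e6))
def test_signed_sqrt_is_odd_and_square_recovers(x):
    s = lt.signed_sqrt(x)
    assert np.isclose(lt.signed_sqrt(-x), -s)
    assert np.isclose(s * s, abs(x), rtol=1e-12, atol=1e-12)


def test_epoch_beyond_recording_marks_truncated():
    rec = _single_channel_recording("HR", np.full(1050, 70.0), 100.0)
    s = lt.score_trial(rec, 10.0, "HR")  # post window ends at 14 s > 10.5 s
    assert s.artifact and s.artifact_reason == "truncated"
    assert np.isnan(s.raw_response)


# ---------------------------------------------------------------------------
# artifact heuristics
# ---------------------------------------------------------------------------

def test_injected_hr_jump_is_flagged():
    fs, onset = 100.0, 10.0
    x = np.full(2000, 70.0)
    x += np.sin(np.arange(2000) / 7.0) * 0.5  # avoid flatline
    rec = _single_channel_recording("HR", x, fs)
    clean = lt.score_recording(rec, detect=True)
    assert not clean["artifact"].any()
    x2 = x.copy()
    x2[int((onset + 2.0) * fs):] += 30.0  # single 30-BPM step inside the epoch
    flagged = lt.score_recording(_single_channel_recording("HR", x2, fs),
                                 detect=True)
    assert flagged["artifact"].all()
    assert "HR jump" in flagged["artifact_reason"].iloc[0]


def test_flatline_window_is_flagged():
    rec = _single_channel_recording("SC", np.full(2000, 10.0), 100.0)
    flagged = lt.score_recording(rec, detect=True)
    assert flagged["artifact"].all()
    assert "flatline" in flagged["artifact_reason"].iloc[0]


def test_sustained_sc_drift_is_flagged():
    fs, onset = 100.0, 10.0
    t = np.arange(2000) / fs
    x = 10.0 + np.sin(t * 3) * 0.01
    x = np.where(t > onset + 1.0, x + 8.0 * np.clip(t - onset - 1.0, 0, 1.0), x)
    flagged = lt.score_recording(_single_channel_recording("SC", x, fs), detect=True)
    assert flagged["artifact"].all()
    assert "SC slope" in flagged["artifact_reason"].iloc[0]


def test_false_flag_rate_on_clean_generator_trials():
    """Default-noise cohorts should almost never trip the artifact rules."""
    cfg = lt.GeneratorConfig(n_subjects=6)
    cohort = lt.SyntheticCohort(cfg, seed=77)
    scores = pd.concat([lt.score_recording(r, detect=True)
                        for r in cohort.iter_recordings()], ignore_index=True)
    assert len(scores) == 6 * 4 * 15 * 3
    assert scores["artifact"].mean() < 0.01


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def _score_rows(values, artifact=None):
    artifact = artifact or [False] * len(values)
    return pd.DataFrame({
        "subject_id": "s1", "bandwidth": "pure_tone", "posture": "sitting",
        "channel": "HR", "trial_index": np.arange(1, len(values) + 1),
        "onset_s": 0.0, "pre_level": 70.0, "raw_response": values,
        "transformed_response": values, "artifact": artifact,
        "artifact_reason": "",
    })


def test_summary_of_identical_scores():
    out = summarize_subject_condition(_score_rows([2.5] * 15))
    assert out["mean_transformed_response"].item() == 2.5
    assert out["n_valid_trials"].item() == 15


def test_summary_excludes_artifact_trials():
    vals = [1.0] * 14 + [100.0]
    art = [False] * 14 + [True]
    out = summarize_subject_condition(_score_rows(vals, art))
    assert out["mean_transformed_response"].item() == 1.0
    assert out["n_valid_trials"].item() == 14


def test_summary_with_no_valid_trials_is_missing():
    out = summarize_subject_condition(_score_rows([1.0] * 15, [True] * 15))
    assert out["n_valid_trials"].item() == 0
    assert np.isnan(out["mean_transformed_response"].item())
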
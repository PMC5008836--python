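"""Stimulus-locked response scoring.

Implements the conventional loud-tone scoring chain: the cardiotachometer
transform (piecewise-constant HR from interbeat intervals), rectification and
leaky integration of raw EMG with a 10-ms time constant, baseline-to-peak
response scores (HR/SC peak within 1-4 s post onset, EMG peak within
40-200 ms, each minus the mean level over the 1 s preceding onset), a signed
square-root transform, automated artifact heuristics, and per
subject-condition averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exceptions import ConfigurationError, DataError
from .io import Channel, Recording, TRIAL_SCORE_COLUMNS

#: post-stimulus peak-search windows in seconds relative to onset (closed)
POST_WINDOWS = {"HR": (1.0, 4.0), "SC": (1.0, 4.0), "EMG": (0.040, 0.200)}
#: pre-stimulus baseline window, half-open [-1, 0): the onset sample is excluded
PRE_WINDOW = (-1.0, 0.0)

#: default automated artifact thresholds (the original screening was visual)
HR_JUMP_BPM = 20.0
SC_SLOPE_MAX = 5.0       # uS/s
SC_SLOPE_MIN_DURATION = 0.5  # s


@dataclass(frozen=True)
class IbiSeries:
    """Strictly increasing heartbeat times; IBIs are their differences."""

    beat_times: np.ndarray

    def __post_init__(self):
        bt = np.asarray(self.beat_times, dtype=float)
        if bt.ndim != 1 or len(bt) < 2:
            raise DataError("an IBI series needs at least two beats")
        if np.any(np.diff(bt) <= 0):
            raise DataError("beat times must be strictly increasing")
        object.__setattr__(self, "beat_times", bt)

    @property
    def ibis(self) -> np.ndarray:
        return np.diff(self.beat_times)


def ibi_to_hr_trace(ibi: IbiSeries, sampling_rate: float,
                    duration: float | None = None) -> Channel:
    """Cardiotachometer transform: sample-and-hold HR of the preceding IBI.

    At any time ``t`` the trace shows ``60 / ibi`` BPM for the most recently
    *completed* interbeat interval, i.e. the value updates at each beat to
    reflect the interval that just ended.  Samples before the second beat are
    back-filled with the first defined value; samples after the last beat hold
    the last defined value.

    Parameters
    ----------
    ibi : IbiSeries
    sampling_rate : float
        Output grid rate in Hz.
    duration : float, optional
        Trace duration in seconds; defaults to the last beat time.
    """
    beats = ibi.beat_times
    hr_values = 60.0 / ibi.ibis  # value k valid on (beats[k+1], beats[k+2]]
    if duration is None:
        duration = beats[-1]
    n = int(round(duration * sampling_rate)) + 1
    t = np.arange(n) / sampling_rate
    # value k is held on (beats[k+1], beats[k+2]]: the update lands just
    # after the beat, so a sample landing exactly on a beat still shows the
    # interval completed at the *previous* beat
    idx = np.searchsorted(beats, t, side="left") - 2
    idx = np.clip(idx, 0, len(hr_values) - 1)
    return Channel(name="HR", sampling_rate=sampling_rate, units="BPM",
                   samples=hr_values[idx])


def rectify_integrate_emg(raw: Channel, time_constant: float = 0.010) -> Channel:
    """Full-wave rectify then leaky-integrate an EMG channel.

    First-order low-pass of the rectified signal,
    ``y[n] = y[n-1] + alpha * (|x[n]| - y[n-1])`` with
    ``alpha = 1 - exp(-dt / tau)`` and ``y[0] = |x[0]|``, so the envelope is
    non-negative and bounded by the running maximum of ``|x|``.
    """
    dt = 1.0 / raw.sampling_rate
    if dt >= time_constant:
        raise ConfigurationError(
            f"sampling interval {dt:g} s must be smaller than the "
            f"integration time constant {time_constant:g} s")
    alpha = 1.0 - np.exp(-dt / time_constant)
    rect = np.abs(raw.samples)
    # zi chosen so that y[0] = |x[0]| exactly
    env, _ = lfilter([alpha], [1.0, alpha - 1.0], rect,
                     zi=np.array([(1.0 - alpha) * rect[0]]) if len(rect) else np.zeros(1))
    return Channel(name=raw.name, sampling_rate=raw.sampling_rate,
                   units=raw.units, samples=env)


def signed_sqrt(x):
    """Odd, monotone square-root transform: ``sign(x) * sqrt(|x|)``."""
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.sqrt(np.abs(x))


@dataclass
class TrialScore:
    subject_id: str
    bandwidth: str
    posture: str
    channel: str
    trial_index: int
    onset_s: float
    pre_level: float
    raw_response: float
    transformed_response: float
    artifact: bool = False
    artifact_reason: str = ""


def _window_indices(onset, lo, hi, fs, n_samples):
    """Closed window [onset+lo, onset+hi] resolved to nearest-sample indices."""
    i0 = int(round((onset + lo) * fs))
    i1 = int(round((onset + hi) * fs))
    if i0 < 0 or i1 >= n_samples:
        return None
    return i0, i1


def score_trial(recording: Recording, onset: float, channel_name: str,
                trial_index: int = 0, post_windows=None) -> TrialScore:
    """Score one stimulus presentation on one channel.

    ``raw_response`` is the maximum level within the post-stimulus window
    minus the mean level over the 1 s preceding onset; the transformed score
    is its signed square root.  The EMG channel is assumed to be
    envelope-transformed already (see :func:`rectify_integrate_emg`).
    Epochs extending beyond the recording are flagged ``truncated``.
    """
    ch = recording.channels[channel_name]
    fs = ch.sampling_rate
    n = len(ch.samples)
    windows = post_windows or POST_WINDOWS
    w0, w1 = windows[channel_name]
    base = dict(subject_id=recording.subject_id,
                bandwidth=recording.condition.get("bandwidth", ""),
                posture=recording.condition.get("posture", ""),
                channel=channel_name, trial_index=trial_index, onset_s=onset)
    i_on = int(round(onset * fs))
    i_pre0 = int(round((onset + PRE_WINDOW[0]) * fs))
    post = _window_indices(onset, w0, w1, fs, n)
    if i_pre0 < 0 or i_on > n or post is None:
        return TrialScore(**base, pre_level=np.nan, raw_response=np.nan,
                          transformed_response=np.nan, artifact=True,
                          artifact_reason="truncated")
    pre = ch.samples[i_pre0:i_on]  # [-1, 0): onset sample excluded
    pre_level = float(np.mean(pre))
    peak = float(np.max(ch.samples[post[0]:post[1] + 1]))  # earliest tie wins
    raw = peak - pre_level
    return TrialScore(**base, pre_level=pre_level, raw_response=raw,
                      transformed_response=float(signed_sqrt(raw)))


def score_recording(recording: Recording, emg_time_constant: float = 0.010,
                    detect: bool = True, post_windows=None,
                    artifact_options=None) -> pd.DataFrame:
    """Score every stimulus event on every channel of a recording.

    The raw EMG channel is envelope-transformed before scoring; HR and SC are
    scored as stored.  Returns a trial-level table with one row per
    trial x channel.
    """
    rec = recording
    if "EMG" in rec.channels:
        env = rectify_integrate_emg(rec.channels["EMG"], emg_time_constant)
        rec = Recording(subject_id=recording.subject_id,
                        condition=recording.condition,
                        channels={**recording.channels, "EMG": env},
                        events=recording.events, meta=recording.meta)
    rows = []
    for trial_index, ev in enumerate(rec.events.itertuples(index=False), start=1):
        for name in rec.channels:
            rows.append(score_trial(rec, ev.onset, name, trial_index=trial_index,
                                    post_windows=post_windows))
    scores = pd.DataFrame([vars(s) for s in rows], columns=TRIAL_SCORE_COLUMNS)
    if detect:
        scores = detect_artifacts(rec, scores, post_windows=post_windows,
                                  **(artifact_options or {}))
    return scores


def detect_artifacts(recording: Recording, scores: pd.DataFrame,
                     hr_jump_bpm: float = HR_JUMP_BPM,
                     sc_slope_max: float = SC_SLOPE_MAX,
                     sc_slope_min_duration: float = SC_SLOPE_MIN_DURATION,
                     post_windows=None) -> pd.DataFrame:
    """Flag implausible trials; flags never alter the stored score values.

    Rules (thresholds configurable; the defaults are conventional
    physiological plausibility bounds replacing visual inspection):

    * HR: any step between adjacent tachometer values inside the epoch
      exceeding ``hr_jump_bpm`` ("HR jump").
    * SC: slope magnitude above ``sc_slope_max`` uS/s sustained for at least
      ``sc_slope_min_duration`` s inside the epoch ("SC slope").
    * any channel: zero variance in a scored (pre or post) window ("flatline").

    Note the EMG channel passed here must be the envelope if the scores were
    computed on the envelope (``score_recording`` arranges this).
    """
    scores = scores.copy()
    windows = post_windows or POST_WINDOWS
    for i in scores.index:
        row = scores.loc[i]
        if row["artifact"]:
            continue
        ch = recording.channels[row["channel"]]
        fs = ch.sampling_rate
        onset = row["onset_s"]
        reasons = []
        epoch_idx = _window_indices(onset, PRE_WINDOW[0], windows[row["channel"]][1],
                                    fs, len(ch.samples))
        if epoch_idx is not None:
            epoch = ch.samples[epoch_idx[0]:epoch_idx[1] + 1]
            if row["channel"] == "HR":
                if np.any(np.abs(np.diff(epoch)) > hr_jump_bpm):
                    reasons.append("HR jump")
            if row["channel"] == "SC":
                slope = np.diff(epoch) * fs
                run_len = int(round(sc_slope_min_duration * fs))
                exceed = np.abs(slope) > sc_slope_max
                if run_len > 0 and len(exceed) >= run_len:
                    sustained = np.convolve(exceed.astype(int),
                                            np.ones(run_len, dtype=int),
                                            mode="valid") >= run_len
                    if np.any(sustained):
                        reasons.append("SC slope")
        w0, w1 = windows[row["channel"]]
        pre_idx = _window_indices(onset, PRE_WINDOW[0], PRE_WINDOW[1], fs, len(ch.samples))
        post_idx = _window_indices(onset, w0, w1, fs, len(ch.samples))
        if pre_idx is not None and post_idx is not None:
            pre = ch.samples[pre_idx[0]:pre_idx[1]]  # excludes onset sample
            post = ch.samples[post_idx[0]:post_idx[1] + 1]
            if (len(pre) > 1 and np.var(pre) == 0) or (len(post) > 1 and np.var(post) == 0):
                reasons.append("flatline")
        if reasons:
            scores.loc[i, "artifact"] = True
            scores.loc[i, "artifact_reason"] = "; ".join(reasons)
    return scores


def summarize_subject_condition(scores: pd.DataFrame) -> pd.DataFrame:
    """Average transformed responses over valid (non-artifact) trials.

    Returns one row per subject x condition x channel with the mean pre-level,
    mean transformed response and the number of valid trials.  Groups with no
    valid trial are kept with NaN means so the missingness propagates visibly
    to the statistics layer.
    """
    rows = []
    keys = ["subject_id", "bandwidth", "posture", "channel"]
    for key, grp in scores.groupby(keys, sort=True):
        valid = grp[~grp["artifact"]]
        rows.append(dict(zip(keys, key)) | {
            "mean_pre_level": float(valid["pre_level"].mean()) if len(valid) else np.nan,
            "mean_transformed_response": (float(valid["transformed_response"].mean())
                                          if len(valid) else np.nan),
            "n_valid_trials": int(len(valid)),
        })
    return pd.DataFrame(rows)
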
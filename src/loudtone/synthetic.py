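"""Seeded synthetic loud-tone cohorts: schedules, raw recordings, ratings.

The generator is two-level by design:

* a **score-level statistical model** — per-trial transformed response
  amplitudes ``s_t = cell_mean + subject_effect + slope * (log10 t - mean)
  + noise`` with equicorrelated between-subject effects across the four
  condition cells — which is the calibrated "truth" that Monte-Carlo tests
  (parameter recovery, type-I error, power) sample from directly via
  :meth:`SyntheticCohort.score_table`; and
* a **raw-signal forward model** that embeds exactly the same per-trial
  amplitudes into physiologically shaped waveforms (tachometer-style HR from
  solved beat times, tonic + bi-exponential phasic skin conductance,
  broadband EMG with enveloped startle bursts), so that scoring a noise-free
  raw recording returns the configured amplitudes exactly and scoring a
  noisy one returns the *same draws* up to small waveform-level
  perturbations.

All randomness flows from one integer seed through ``numpy`` seed
sequences; identical seeds give identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm as norm_dist

from . import scoring
from .calibration import (BANDWIDTHS, CELLS, CHANNELS, POSTURES,
                          DEFAULT_RATING_PARAMS, default_cell_targets)
from .exceptions import ConfigurationError
from .io import Channel, Recording, TRIAL_SCORE_COLUMNS
from .scoring import IbiSeries, ibi_to_hr_trace, rectify_integrate_emg

# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StimulusSchedule:
    """Onsets of the 15 loud stimuli after the resting baseline."""

    baseline_duration: float
    onsets: tuple
    stimulus_duration: float = 0.5
    bandwidth_label: str = "pure_tone"
    posture_label: str = "sitting"

    def __post_init__(self):
        onsets = tuple(float(o) for o in self.onsets)
        object.__setattr__(self, "onsets", onsets)
        if len(onsets) == 0:
            raise ConfigurationError("schedule needs at least one onset")
        if any(nxt <= prev for prev, nxt in zip(onsets[:-1], onsets[1:])):
            raise ConfigurationError("onsets must be strictly increasing")
        if onsets[0] < self.baseline_duration - 1e-9:
            raise ConfigurationError(
                f"first onset {onsets[0]:g} precedes the {self.baseline_duration:g} s baseline")

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    @property
    def gaps(self) -> np.ndarray:
        return np.diff(self.onsets)


@dataclass(frozen=True)
class ResponseKernelParams:
    """Shapes of the evoked-response kernels (generator assumptions).

    The HR kernel is a trapezoid: the plateau (default 1.1-3.9 s post onset,
    centred ~2.5 s) is long enough that at least one full interbeat interval
    sits at the peak rate, so the tachometer trace attains the configured
    peak exactly.  The SCR kernel is the bi-exponential (Bateman) form with
    rise tau 0.75 s and decay tau 2.0 s, peaking ~1.2 s post onset, inside
    the 1-4 s scoring window.  The EMG burst is broadband noise under a
    Gaussian envelope at 60 ms onset latency, 80 ms duration, inside the
    40-200 ms scoring window.
    """

    hr_rise_start: float = 0.4
    hr_plateau_start: float = 1.1
    hr_plateau_end: float = 3.9
    hr_fall_end: float = 6.5
    scr_rise_tau: float = 0.75
    scr_decay_tau: float = 2.0
    scr_support: float = 20.0
    emg_burst_onset: float = 0.060
    emg_burst_duration: float = 0.080

    def __post_init__(self):
        for name in ("scr_rise_tau", "scr_decay_tau", "emg_burst_duration"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (0.0 < self.hr_rise_start < self.hr_plateau_start
                < self.hr_plateau_end < self.hr_fall_end):
            raise ConfigurationError("HR kernel breakpoints must be increasing")
        if not 0.040 <= self.emg_burst_onset <= 0.200:
            raise ConfigurationError(
                "emg_burst_onset must lie within the scored 40-200 ms window")
        if self.emg_burst_onset + self.emg_burst_duration > 0.200 + 1e-9:
            raise ConfigurationError("EMG burst must end inside the scored window")
        if self.scr_rise_tau >= self.scr_decay_tau:
            raise ConfigurationError("SCR rise tau must be below the decay tau")

    @property
    def max_duration(self) -> float:
        return max(self.hr_fall_end, self.scr_support,
                   self.emg_burst_onset + self.emg_burst_duration)

    def hr_trapezoid(self, u):
        """Unit-peak trapezoid evaluated at post-onset time(s) ``u``."""
        u = np.asarray(u, dtype=float)
        r0, p0, p1, f1 = (self.hr_rise_start, self.hr_plateau_start,
                          self.hr_plateau_end, self.hr_fall_end)
        rise = np.clip((u - r0) / (p0 - r0), 0.0, 1.0)
        fall = np.clip((f1 - u) / (f1 - p1), 0.0, 1.0)
        return np.minimum(rise, fall)


@dataclass
class GeneratorConfig:
    """Synthetic-cohort configuration.

    Defaults are the paradigm's study conditions: 24 subjects x 4 conditions
    (bandwidth x posture) x 15 trials, 5-min baseline, 27-52 s inter-trial
    intervals, with cell means/SDs calibrated to the published descriptive
    table (see :mod:`loudtone.calibration`).  ``noise_sd`` is the
    trial-to-trial SD of the transformed response; its default (0.05) is the
    value consistent with the published slope SDs given the OLS sampling
    variance of a 14-trial log-trial regression.  ``within_subject_corr``
    is the correlation of a subject's effects across the four condition
    cells (not published; 0.6 is a typical session-to-session consistency
    for autonomic measures).
    """

    n_subjects: int = 24
    n_trials: int = 15
    baseline_duration: float = 300.0
    stimulus_duration: float = 0.5
    iti_min: float = 27.0
    iti_max: float = 52.0
    sampling_rate: float = 100.0       # HR and SC channels
    emg_sampling_rate: float = 1000.0
    tail_duration: float = 10.0
    cell_targets: dict = None
    within_subject_corr: float = 0.6
    noise_sd: dict = None              # per-channel trial noise, transformed scale
    between_subject_scale: float = 1.0
    sc_meas_noise_sd: float = 0.01     # uS, white measurement noise on SC
    ibi_jitter_sd: float = 0.001       # s, beat-timing jitter on HR
    emg_background_scale: float = 1.0  # scales the broadband EMG background
    seed: int = 0

    def __post_init__(self):
        if self.cell_targets is None:
            self.cell_targets = default_cell_targets()
        if self.noise_sd is None:
            self.noise_sd = {ch: 0.05 for ch in CHANNELS}
        elif np.isscalar(self.noise_sd):
            self.noise_sd = {ch: float(self.noise_sd) for ch in CHANNELS}
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if not (0 < self.iti_min <= self.iti_max):
            raise ConfigurationError(
                f"invalid ITI bounds [{self.iti_min}, {self.iti_max}]")
        if self.sampling_rate < 50 or self.emg_sampling_rate < 1000:
            raise ConfigurationError(
                "sampling_rate must be >= 50 Hz (HR/SC) and >= 1000 Hz (EMG)")
        if not 0.0 <= self.within_subject_corr <= 1.0:
            raise ConfigurationError("within_subject_corr must be in [0, 1]")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ConfigurationError("noise SDs must be >= 0")

    def noise_free(self) -> "GeneratorConfig":
        """Copy with every source of variability switched off.

        Scoring such a cohort returns the configured cell means exactly.
        """
        return replace(self, noise_sd={ch: 0.0 for ch in CHANNELS},
                       between_subject_scale=0.0, sc_meas_noise_sd=0.0,
                       ibi_jitter_sd=0.0, emg_background_scale=0.0)


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

def generate_schedule(config: GeneratorConfig, bandwidth: str = "pure_tone",
                      posture: str = "sitting", rng=None) -> StimulusSchedule:
    """Draw one stimulus schedule: gaps uniform on [iti_min, iti_max].

    Onsets are snapped to the HR/SC sample grid (which is a subgrid of the
    EMG grid), so evoked kernels are sampled identically on every trial.
    """
    rng = np.random.default_rng(rng)
    gaps = rng.uniform(config.iti_min, config.iti_max, size=config.n_trials - 1)
    grid = config.sampling_rate
    gaps = np.round(gaps * grid) / grid
    gaps = np.clip(gaps, config.iti_min, config.iti_max)
    onsets = config.baseline_duration + np.concatenate([[0.0], np.cumsum(gaps)])
    return StimulusSchedule(baseline_duration=config.baseline_duration,
                            onsets=tuple(onsets),
                            stimulus_duration=config.stimulus_duration,
                            bandwidth_label=bandwidth, posture_label=posture)


# ---------------------------------------------------------------------------
# score-level statistical model
# ---------------------------------------------------------------------------

#: trial index support helpers
def _log10_trials(n_trials):
    lt = np.log10(np.arange(1, n_trials + 1, dtype=float))
    return lt, lt.mean()


def _slope_sxx(n_trials, trial_range=(2, 15)):
    t = np.arange(trial_range[0], min(trial_range[1], n_trials) + 1)
    x = np.log10(t)
    return float(np.sum((x - x.mean()) ** 2))


def _equicorrelated_normal(rng, n, k, rho):
    """n x k standard normals with pairwise correlation rho >= 0."""
    shared = rng.standard_normal((n, 1))
    indiv = rng.standard_normal((n, k))
    return np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * indiv


@dataclass
class CohortEffects:
    """True per-subject generator parameters (the recovery-test ground truth).

    Arrays are indexed ``[subject, cell, channel]`` (cell order
    :data:`loudtone.calibration.CELLS`); ``amplitudes`` adds a trial axis and
    holds the per-trial transformed response scores the raw waveforms embed.
    """

    tonic: np.ndarray        # (n, 4, 3) channel units
    mean_response: np.ndarray  # (n, 4, 3) transformed scale, trial-mean target
    slope: np.ndarray        # (n, 4, 3) transformed units per log10 trial
    amplitudes: np.ndarray   # (n, 4, 3, n_trials) transformed scale

    def to_frame(self) -> pd.DataFrame:
        rows = []
        n = self.tonic.shape[0]
        for s in range(n):
            for c, (bw, po) in enumerate(CELLS):
                for k, ch in enumerate(CHANNELS):
                    rows.append({
                        "subject_id": subject_label(s), "bandwidth": bw,
                        "posture": po, "channel": ch,
                        "true_tonic": self.tonic[s, c, k],
                        "true_mean_response": self.mean_response[s, c, k],
                        "true_slope": self.slope[s, c, k],
                    })
        return pd.DataFrame(rows)


def subject_label(i: int) -> str:
    return f"sub-{i + 1:02d}"


def _draw_tonic(rng, means, sds, n, rho, channel):
    """Between-subject tonic levels, equicorrelated across the 4 cells.

    HR uses a (floored) normal; SC and EMG use gamma marginals through a
    Gaussian copula so levels stay positive with the target mean and SD.
    """
    z = _equicorrelated_normal(rng, n, len(means), rho)
    if np.all(sds == 0):
        return np.tile(means, (n, 1))
    if channel == "HR":
        return np.maximum(means + sds * z, 45.0)
    out = np.empty((n, len(means)))
    for c, (m, sd) in enumerate(zip(means, sds)):
        if sd == 0:
            out[:, c] = m
            continue
        shape = (m / sd) ** 2
        u = norm_dist.cdf(z[:, c])
        out[:, c] = gamma_dist.ppf(u, shape, scale=sd ** 2 / m)
    return out


def draw_cohort_effects(config: GeneratorConfig, rng) -> CohortEffects:
    """Sample all subject-level effects and per-trial amplitudes.

    Between-subject SDs are deflated by the share of the published cell SDs
    that trial noise already accounts for (``noise_sd^2 / n_trials`` for the
    response mean, ``noise_sd^2 / Sxx`` for the slope), so the *observed*
    cell SDs of scored cohorts match the calibration targets.
    """
    n = config.n_subjects
    rho = config.within_subject_corr
    bscale = config.between_subject_scale
    lt, lbar = _log10_trials(config.n_trials)
    sxx = _slope_sxx(config.n_trials)
    tonic = np.empty((n, 4, 3))
    mean_resp = np.empty((n, 4, 3))
    slope = np.empty((n, 4, 3))
    amps = np.empty((n, 4, 3, config.n_trials))
    for k, ch in enumerate(CHANNELS):
        targets = config.cell_targets[ch]
        noise = config.noise_sd[ch]

        pre_m = np.array([targets["pre_level"][c][0] for c in CELLS])
        pre_sd = np.array([targets["pre_level"][c][1] for c in CELLS]) * bscale
        tonic[:, :, k] = _draw_tonic(rng, pre_m, pre_sd, n, rho, ch)

        r_m = np.array([targets["response"][c][0] for c in CELLS])
        r_sd = np.array([targets["response"][c][1] for c in CELLS])
        vu = np.clip(r_sd ** 2 - noise ** 2 / config.n_trials, 0.0, None) * bscale ** 2
        z = _equicorrelated_normal(rng, n, 4, rho)
        mean_resp[:, :, k] = r_m + np.sqrt(vu) * z

        s_m = np.array([targets["slope"][c][0] for c in CELLS])
        s_sd = np.array([targets["slope"][c][1] for c in CELLS])
        vs = np.clip(s_sd ** 2 - noise ** 2 / sxx, 0.0, None) * bscale ** 2
        z = _equicorrelated_normal(rng, n, 4, rho)
        slope[:, :, k] = s_m + np.sqrt(vs) * z

        eps = (rng.standard_normal((n, 4, config.n_trials)) * noise
               if noise > 0 else np.zeros((n, 4, config.n_trials)))
        amps[:, :, k, :] = (mean_resp[:, :, k][:, :, None]
                            + slope[:, :, k][:, :, None] * (lt - lbar)[None, None, :]
                            + eps)
    return CohortEffects(tonic=tonic, mean_response=mean_resp, slope=slope,
                         amplitudes=amps)


# ---------------------------------------------------------------------------
# raw-signal forward model
# ---------------------------------------------------------------------------

def _solve_beats(knot_t, knot_v, duration):
    """Beat times for a piecewise-linear heart-rate function (BPM).

    A beat occurs whenever the integrated instantaneous rate accumulates one
    full beat (60 BPM-seconds).  The integral is evaluated exactly per linear
    segment, so an interbeat interval lying entirely within a constant
    segment equals 60/rate to float precision.
    """
    beats = [0.0]
    nseg = len(knot_t) - 1
    seg = 0
    while beats[-1] <= duration + 2.0:
        t = beats[-1]
        while seg + 1 < nseg and knot_t[seg + 1] <= t:
            seg += 1
        s = seg
        remaining = 60.0
        while True:
            if s >= nseg:  # beyond the last knot: hold the final rate
                beats.append(t + remaining / knot_v[-1])
                break
            t0, t1 = knot_t[s], knot_t[s + 1]
            v0, v1 = knot_v[s], knot_v[s + 1]
            m = (v1 - v0) / (t1 - t0)
            f_t = v0 + m * (t - t0)
            area = 0.5 * (f_t + v1) * (t1 - t)
            if area >= remaining:
                if m == 0.0:
                    beats.append(t + remaining / f_t)
                else:
                    beats.append(t + 2.0 * remaining
                                 / (f_t + np.sqrt(f_t * f_t + 2.0 * m * remaining)))
                break
            remaining -= area
            t = t1
            s += 1
    return np.asarray(beats)


def _signed_square(s):
    s = np.asarray(s, dtype=float)
    return np.sign(s) * s ** 2


def _make_hr_channel(onsets, amps_transformed, tonic, config, kernels, rng):
    fs = config.sampling_rate
    duration = onsets[-1] + config.tail_duration
    raw = _signed_square(amps_transformed)
    # inversion factor so that negative (decelerative) responses score back
    # approximately: the window max of a dip is set by the smallest kernel
    # value inside the scoring window
    w0, w1 = scoring.POST_WINDOWS["HR"]
    k_min = float(min(kernels.hr_trapezoid(w0), kernels.hr_trapezoid(w1)))
    knot_t = [0.0]
    knot_v = [tonic]
    for o, a in zip(onsets, raw):
        e = a if a >= 0 else a / k_min
        e = max(e, -(tonic - 30.0))  # keep the rate physiological
        knot_t += [o + kernels.hr_rise_start, o + kernels.hr_plateau_start,
                   o + kernels.hr_plateau_end, o + kernels.hr_fall_end]
        knot_v += [tonic, tonic + e, tonic + e, tonic]
    knot_t.append(duration + 30.0)
    knot_v.append(tonic)
    beats = _solve_beats(knot_t, knot_v, duration)
    if config.ibi_jitter_sd > 0:
        beats = beats + np.concatenate(
            [[0.0], rng.normal(0.0, config.ibi_jitter_sd, len(beats) - 1)])
        beats = np.sort(beats)
    return ibi_to_hr_trace(IbiSeries(beats), fs, duration=duration)


def _scr_kernel(config, kernels):
    """Bateman kernel on the SC sample grid, unit peak within the scoring window."""
    fs = config.sampling_rate
    u = np.arange(int(round(kernels.scr_support * fs)) + 1) / fs
    k = np.exp(-u / kernels.scr_decay_tau) - np.exp(-u / kernels.scr_rise_tau)
    w0, w1 = scoring.POST_WINDOWS["SC"]
    lo, hi = int(round(w0 * fs)), int(round(w1 * fs))
    window = k[lo:hi + 1]
    k = k / np.max(window)
    k_min_win = float(np.min(k[lo:hi + 1]))
    return k, k_min_win


def _make_sc_channel(onsets, amps_transformed, tonic, config, kernels, rng):
    fs = config.sampling_rate
    duration = onsets[-1] + config.tail_duration
    n = int(round(duration * fs)) + 1
    sc = np.full(n, tonic)
    kern, k_min_win = _scr_kernel(config, kernels)
    raw = _signed_square(amps_transformed)
    for o, a in zip(onsets, raw):
        e = a if a >= 0 else a / k_min_win
        i0 = int(round(o * fs))
        seg = kern[:max(0, n - i0)]
        sc[i0:i0 + len(seg)] += e * seg
    if config.sc_meas_noise_sd > 0:
        sc = sc + rng.normal(0.0, config.sc_meas_noise_sd, n)
    return Channel(name="SC", sampling_rate=fs, units="uS", samples=sc)


def _make_emg_channel(onsets, amps_transformed, tonic, config, kernels, rng,
                      emg_time_constant=0.010):
    fs = config.emg_sampling_rate
    duration = onsets[-1] + config.tail_duration
    n = int(round(duration * fs)) + 1
    background_mean = tonic * config.emg_background_scale
    sigma = background_mean * np.sqrt(np.pi / 2.0)  # envelope mean -> noise SD
    x = rng.normal(0.0, sigma, n) if sigma > 0 else np.zeros(n)
    # burst template support
    j0 = int(round(kernels.emg_burst_onset * fs))
    j1 = int(round((kernels.emg_burst_onset + kernels.emg_burst_duration) * fs))
    u = np.arange(j0, j1 + 1) / fs
    center = kernels.emg_burst_onset + kernels.emg_burst_duration / 2.0
    env = np.exp(-0.5 * ((u - center) / (kernels.emg_burst_duration / 6.0)) ** 2)
    w0, w1 = scoring.POST_WINDOWS["EMG"]
    seg_len = int(round(0.25 * fs)) + 1
    raw = _signed_square(amps_transformed)
    for o, a in zip(onsets, raw):
        if a <= 0:
            continue  # an integrated-EMG envelope cannot dip below a zero floor
        carrier = rng.standard_normal(len(env))
        burst = env * carrier
        # measure the integrator's response to this burst in isolation and
        # precompensate, so the scored envelope peak equals the amplitude
        seg = np.zeros(seg_len)
        seg[j0:j0 + len(burst)] = burst
        env_resp = rectify_integrate_emg(
            Channel("EMG", fs, "uV", seg), emg_time_constant).samples
        peak = np.max(env_resp[int(round(w0 * fs)):int(round(w1 * fs)) + 1])
        if background_mean > 0:
            # bursts add to the background roughly in quadrature
            a_eff = np.sqrt(a * (a + 2.0 * background_mean))
        else:
            a_eff = a
        i0 = int(round(o * fs)) + j0  # burst begins at its onset latency
        put = burst[:max(0, n - i0)]
        x[i0:i0 + len(put)] += (a_eff / peak) * put
    return Channel(name="EMG", sampling_rate=fs, units="uV", samples=x)


def generate_recording(schedule: StimulusSchedule, config: GeneratorConfig,
                       kernels: ResponseKernelParams | None = None,
                       subject_effects: dict | None = None,
                       rng=None) -> Recording:
    """Forward-model one multichannel recording from per-trial amplitudes.

    Parameters
    ----------
    subject_effects : dict, optional
        ``{"tonic": {channel: level}, "transformed_amplitudes":
        {channel: array of n_trials}}``.  Defaults to the configured cell
        targets for the schedule's condition with a noise-free amplitude
        law (cell mean + slope * centred log10 trial).
    """
    kernels = kernels or ResponseKernelParams()
    if kernels.max_duration >= config.iti_min:
        raise ConfigurationError(
            f"kernel durations ({kernels.max_duration:g} s) must not exceed "
            f"the minimum inter-trial interval ({config.iti_min:g} s)")
    rng = np.random.default_rng(rng)
    cell = (schedule.bandwidth_label, schedule.posture_label)
    if subject_effects is None:
        lt, lbar = _log10_trials(schedule.n_trials)
        subject_effects = {"tonic": {}, "transformed_amplitudes": {}}
        for ch in CHANNELS:
            tg = config.cell_targets[ch]
            subject_effects["tonic"][ch] = tg["pre_level"][cell][0]
            subject_effects["transformed_amplitudes"][ch] = (
                tg["response"][cell][0] + tg["slope"][cell][0] * (lt - lbar))
    onsets = np.asarray(schedule.onsets)
    tonic = subject_effects["tonic"]
    amps = subject_effects["transformed_amplitudes"]
    channels = {
        "HR": _make_hr_channel(onsets, amps["HR"], tonic["HR"], config, kernels, rng),
        "SC": _make_sc_channel(onsets, amps["SC"], tonic["SC"], config, kernels, rng),
        "EMG": _make_emg_channel(onsets, amps["EMG"], tonic["EMG"], config,
                                 kernels, rng),
    }
    events = pd.DataFrame({"onset": onsets,
                           "duration": schedule.stimulus_duration,
                           "label": "tone"})
    return Recording(
        subject_id=subject_effects.get("subject_id", "sub-01"),
        condition={"bandwidth": schedule.bandwidth_label,
                   "posture": schedule.posture_label},
        channels=channels, events=events,
        meta={"generator": "loudtone.synthetic"})


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: balanced (Williams) Latin square over the four conditions
_WILLIAMS_4 = ((0, 1, 3, 2), (1, 2, 0, 3), (2, 3, 1, 0), (3, 0, 2, 1))


class SyntheticCohort:
    """A seeded cohort: manifest, ground truth, score table, raw recordings.

    Construction draws all subject effects and schedules up front;
    :meth:`iter_recordings` synthesizes the (large) raw waveforms lazily, one
    recording at a time, from per-recording child seeds, so iterating twice
    yields identical data.
    """

    def __init__(self, config: GeneratorConfig,
                 kernels: ResponseKernelParams | None = None, seed=None):
        self.config = config
        self.kernels = kernels or ResponseKernelParams()
        self.seed = int(config.seed if seed is None else seed)
        ss = np.random.SeedSequence(self.seed)
        eff_ss, sched_ss, wave_ss = ss.spawn(3)
        self.effects = draw_cohort_effects(config, np.random.default_rng(eff_ss))
        entries = []
        sched_rng = np.random.default_rng(sched_ss)
        for s in range(config.n_subjects):
            # subject s runs the conditions in the order of their Latin-square
            # row; entries stay in canonical cell order with the session noted
            order = _WILLIAMS_4[s % 4]
            for c, cell in enumerate(CELLS):
                entries.append({"subject_id": subject_label(s),
                                "subject_index": s, "cell_index": c,
                                "bandwidth": cell[0], "posture": cell[1],
                                "session_index": int(order.index(c)) + 1})
        # schedules drawn in manifest order so they are seed-reproducible
        self.schedules = []
        for e in entries:
            self.schedules.append(generate_schedule(
                config, bandwidth=e["bandwidth"], posture=e["posture"],
                rng=sched_rng))
        self.entries = entries
        self._wave_seeds = wave_ss.spawn(len(entries))

    # -- metadata -----------------------------------------------------------

    def manifest(self) -> dict:
        cfg = {k: v for k, v in vars(self.config).items() if k != "cell_targets"}
        cfg["noise_sd"] = dict(self.config.noise_sd)
        return {
            "seed": self.seed,
            "config": cfg,
            "cell_targets": {
                ch: {m: {f"{b}/{p}": list(v) for (b, p), v in cells.items()}
                     for m, cells in tgt.items()}
                for ch, tgt in self.config.cell_targets.items()},
            "recordings": [
                {"subject_id": e["subject_id"], "bandwidth": e["bandwidth"],
                 "posture": e["posture"], "session_index": e["session_index"],
                 "n_trials": self.schedules[i].n_trials}
                for i, e in enumerate(self.entries)],
        }

    def truth(self) -> pd.DataFrame:
        return self.effects.to_frame()

    # -- score-level route --------------------------------------------------

    def score_table(self) -> pd.DataFrame:
        """Trial-level scores drawn directly from the statistical model.

        These are the exact amplitudes the raw waveforms embed; the raw route
        (generate, then score) returns the same values up to waveform-level
        measurement noise, and exactly so in a noise-free configuration.
        """
        rows = []
        for i, e in enumerate(self.entries):
            s, c = e["subject_index"], e["cell_index"]
            onsets = self.schedules[i].onsets
            for k, ch in enumerate(CHANNELS):
                amps = self.effects.amplitudes[s, c, k]
                for t in range(self.config.n_trials):
                    rows.append((e["subject_id"], e["bandwidth"], e["posture"],
                                 ch, t + 1, onsets[t],
                                 self.effects.tonic[s, c, k],
                                 float(_signed_square(amps[t])), float(amps[t]),
                                 False, ""))
        return pd.DataFrame(rows, columns=TRIAL_SCORE_COLUMNS)

    # -- raw-signal route ---------------------------------------------------

    def recording(self, index: int) -> Recording:
        e = self.entries[index]
        s, c = e["subject_index"], e["cell_index"]
        effects = {
            "subject_id": e["subject_id"],
            "tonic": {ch: self.effects.tonic[s, c, k]
                      for k, ch in enumerate(CHANNELS)},
            "transformed_amplitudes": {ch: self.effects.amplitudes[s, c, k]
                                       for k, ch in enumerate(CHANNELS)},
        }
        return generate_recording(self.schedules[index], self.config,
                                  self.kernels, effects,
                                  rng=np.random.default_rng(self._wave_seeds[index]))

    def iter_recordings(self):
        for i in range(len(self.entries)):
            yield self.recording(i)

    def __len__(self):
        return len(self.entries)


def generate_cohort(config: GeneratorConfig,
                    kernels: ResponseKernelParams | None = None,
                    seed=None) -> SyntheticCohort:
    """Build a seeded cohort of ``n_subjects x 4 conditions`` recordings."""
    return SyntheticCohort(config, kernels=kernels, seed=seed)


# ---------------------------------------------------------------------------
# magnitude-estimation ratings
# ---------------------------------------------------------------------------

def generate_magnitude_ratings(n_subjects: int = None,
                               power_law_slope_per_db=None,
                               type_offset: float = None,
                               noise_sd_log: float = None,
                               rng_seed=None,
                               subject_intercept_sd: float = None,
                               subject_slope_sd: float = None,
                               interaction_per_db: float = None,
                               spls=None, n_presentations: int = None,
                               dimensions=("loudness", "valence")) -> pd.DataFrame:
    """Simulate magnitude-estimation ratings relative to a 65 dB reference.

    ``log10(rating) = subject_intercept + slope * (spl - 65)
    + type_offset * [white_noise] + interaction * (spl - 65) * [white_noise]
    + Normal(0, noise_sd_log)``, with optional subject-specific slope
    deviations.  Each sound type x SPL cell is presented
    ``n_presentations`` times per dimension.
    """
    d = DEFAULT_RATING_PARAMS
    n_subjects = d["n_subjects"] if n_subjects is None else n_subjects
    if n_subjects < 2:
        raise ConfigurationError("rating generator needs n_subjects >= 2")
    slope = (d["slope_per_db"] if power_law_slope_per_db is None
             else power_law_slope_per_db)
    if np.isscalar(slope):
        slope = {dim: float(slope) for dim in dimensions}
    type_offset = d["type_offset"] if type_offset is None else type_offset
    noise_sd_log = d["noise_sd_log"] if noise_sd_log is None else noise_sd_log
    subject_intercept_sd = (d["subject_intercept_sd"] if subject_intercept_sd is None
                            else subject_intercept_sd)
    subject_slope_sd = (d["subject_slope_sd"] if subject_slope_sd is None
                        else subject_slope_sd)
    interaction_per_db = (d["interaction_per_db"] if interaction_per_db is None
                          else interaction_per_db)
    spls = d["spls"] if spls is None else spls
    n_presentations = (d["n_presentations"] if n_presentations is None
                       else n_presentations)
    rng = np.random.default_rng(rng_seed)
    rows = []
    for dim in dimensions:
        icepts = rng.normal(0.0, subject_intercept_sd, n_subjects)
        slopes = slope[dim] + rng.normal(0.0, subject_slope_sd, n_subjects)
        for s in range(n_subjects):
            for sound_type in ("pure_tone", "white_noise"):
                wn = 1.0 if sound_type == "white_noise" else 0.0
                for spl in spls:
                    for pres in range(1, n_presentations + 1):
                        log_r = (icepts[s] + slopes[s] * (spl - 65.0)
                                 + type_offset * wn
                                 + interaction_per_db * (spl - 65.0) * wn)
                        if noise_sd_log > 0:
                            log_r += rng.normal(0.0, noise_sd_log)
                        rows.append((subject_label(s), sound_type, spl, pres,
                                     dim, 10.0 ** log_r))
    return pd.DataFrame(rows, columns=["subject_id", "sound_type", "spl",
                                       "presentation_index", "dimension",
                                       "rating"])
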
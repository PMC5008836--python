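# Methods

## The paradigm and the scoring model

The loud-tone procedure presents 15 sudden, brief (500 ms), loud (95 dB
SPL) auditory stimuli — pure tones (1000 Hz) or white noise — after a
5-minute resting baseline, with inter-trial intervals drawn uniformly from
27–52 s.  Each subject completes the four bandwidth × posture conditions
(pure tone / white noise × sitting / supine) in counterbalanced sessions.
Three peripheral channels are scored:

| channel | signal | response window | units |
|---|---|---|---|
| HR | cardiotachometer trace: piecewise-constant 60/IBI, updated at each beat with the interval that just ended | peak in [1, 4] s − mean of [−1, 0) s | BPM |
| SC | skin conductance | peak in [1, 4] s − mean of [−1, 0) s | μS |
| EMG | rectified, leaky-integrated (τ = 10 ms) orbicularis-oculi EMG | envelope peak in [40, 200] ms − 1-s pre-stimulus envelope mean | μV |

Scores are transformed with the signed square root `sign(x)·√|x|`.  The
square-root transform for positive responses is the field's convention for
variance stabilisation; the signed extension keeps the transform defined
for the negative raw scores that arise on weak-response trials (it is odd,
monotone, and its square recovers the magnitude).  Habituation is the OLS
slope of transformed score on log₁₀(trial) over trials 2–15 (trial 1 is
excluded from the slope, but included in the 15-trial response means and
the LOESS curves).  "Log trial number" is read as log₁₀; natural log would
rescale slopes by ln 10 ≈ 2.303, and the log base is an argument of
`habituation_slope` for anyone preferring it.

Window endpoints resolve to nearest-sample indices; peak searches run over
the discrete samples of the closed window, earliest sample winning ties.
The pre-stimulus window is half-open, [−1, 0), so the onset sample never
contaminates the baseline.

## Statistics

**2×2 fully within-subject ANOVA.**  For factors A (bandwidth) and B
(posture) on n subjects, the classical decomposition

SS_total = SS_subject + SS_A + SS_B + SS_AB + SS_{A×s} + SS_{B×s} + SS_{AB×s}

is computed from cell and marginal means; each effect is tested against
its own effect×subject error term on (1, n−1) df.  Two-level factors need
no sphericity correction.  Effect size is generalized eta squared in the
Olejnik–Algina sense — for a fully within design all subject-linked
variance enters the denominator:

η²G(effect) = SS_effect / (SS_effect + SS_subject + SS_{A×s} + SS_{B×s} + SS_{AB×s}).

Incomplete subjects are dropped listwise (with a logged count); fewer than
two complete subjects is an error.

**Magnitude estimation.**  Ratings (numbers assigned relative to a 65 dB
SPL pure-tone reference) are averaged over the three presentations per
subject × sound-type × SPL cell, log₁₀-transformed, and fitted by REML
(statsmodels `MixedLM`) with fixed effects SPL (dB, centred at 65), sound
type, and their interaction, plus a per-subject random intercept.  t
statistics use df = N_obs − n_subjects (135 for the standard 15-subject
design); a "residual" df option subtracts the slope parameters as well.
The choice of log base does not affect t statistics, only the scale of the
coefficients.  If the REML fit degenerates (e.g. zero residual variance on
noise-free data) the fixed effects fall back to OLS, which coincides with
GLS in this balanced design.

**LOESS.**  Local polynomial regression with tricube weights, span 0.75,
degree 2, no robustness iterations — conventional defaults.  For spans
above 1 the bandwidth is the data range times the span, so large spans
converge to a global polynomial fit.  A span giving fewer than degree + 2
points is widened with a logged warning.

## The synthetic cohort

The generator is two-level by construction.

**Score level (the calibrated statistical model).**  Per subject s, cell c
(the four bandwidth × posture conditions) and channel, the transformed
trial score is

s_t = μ_c + u_{s,c} + (b_c + v_{s,c}) · (log₁₀ t − mean log₁₀ t) + ε_t,

with μ_c / b_c the target cell mean and slope, u and v between-subject
effects that are equicorrelated across the four cells (correlation
`within_subject_corr`, default 0.6), and ε trial noise (`noise_sd`,
default 0.05 transformed units).  Between-subject SDs are deflated by the
share of the target cell SDs that trial noise already explains
(noise²/15 for means, noise²/S_xx for slopes), so *observed* cell SDs of
scored cohorts match the targets.  Tonic (pre-stimulus) levels are drawn
per cell from a normal (HR, floored at 45 BPM) or a gamma with matching
mean/SD through a Gaussian copula (SC, EMG — conductance and envelope
levels must stay positive).  Cell targets default to the paradigm's
published descriptive table: pre-tone levels keep the four printed cell
values (sitting above supine for HR and SC), while response means and
slopes are collapsed across posture within bandwidth — posture is modelled
as a tonic shift with no effect on response magnitude, the structure the
paradigm's null posture finding implies.  This also makes the posture main
effect an exact null, used for the type-I-error check.

Defaults chosen where the design was open: `within_subject_corr = 0.6` is
a typical session-to-session consistency for autonomic measures (the
cross-condition correlation is not published, so it is an explicit
parameter); `noise_sd = 0.05` is the trial noise consistent with the
published slope SDs, given that an OLS slope over trials 2–15 inherits
sampling variance noise²/S_xx ≈ (0.054)² from trial noise alone.  The
rating generator uses a loudness slope of 0.030 log₁₀/dB (doubling per
10 dB), valence 0.019, per-presentation log₁₀ noise 0.35 and
between-subject slope SD 0.02 — magnitude estimates are notoriously
variable, and these values put the SPL t statistic in the low teens, the
order the paradigm reports.

**Raw-signal level.**  The same per-trial amplitudes are embedded in
waveforms:

- **HR** — a piecewise-linear instantaneous-rate function (baseline h BPM
  plus, per trial, a trapezoidal acceleration: rise from 0.4 s, plateau
  1.1–3.9 s, back to baseline by 6.5 s) is integrated exactly segment by
  segment to produce beat times; the tachometer transform of those beats
  is the HR channel.  The plateau, rather than a sharp peak, is
  deliberate: a tachometer holds one value per interbeat interval, so only
  a peak that lasts at least one full IBI can be represented — and scored —
  exactly.  Optional beat-time jitter (default SD 1 ms) keeps the trace
  from being degenerate-flat.
- **SC** — tonic level plus a per-trial bi-exponential (Bateman) kernel,
  rise τ 0.75 s, decay τ 2.0 s (peak ≈ 1.2 s, inside the scoring window),
  truncated at 20 s, normalised to unit peak on the sample grid of the
  scoring window; plus white measurement noise (default 0.01 μS).
- **EMG** — zero-mean broadband background whose rectified-integrated
  envelope mean equals the tonic target (σ = tonic·√(π/2)), plus per-trial
  bursts: broadband carrier under a Gaussian envelope at 60 ms latency,
  80 ms duration.  Each burst is scaled by the numerically measured
  integrator response so the scored envelope peak equals the target
  amplitude (with a quadrature correction for the background when it is
  present).

With all noise sources off (`GeneratorConfig.noise_free()`), scoring a raw
cohort returns the configured amplitudes and slopes *exactly* (float
precision); the round trip is asserted in the tests.  Negative amplitudes
(weak-response trials) are embedded as inverted kernels rescaled by the
window minimum of the kernel so SC round-trips them exactly too; through
the tachometer the HR inversion is approximate, and EMG clamps negative
amplitudes at zero (an envelope cannot dip below a zero baseline) — with
the background present, raw-route EMG scores sit slightly above the model
values because the window peak rides on envelope ripple.

**What the generator does and does not emulate.**  It reproduces the
between-subject, between-condition and trial-wise statistical structure of
scored loud-tone data and physiologically plausible waveform shapes.  It
does not model respiration, motion, electrode artifacts, spontaneous SC
fluctuations, heart-rate variability beyond small beat jitter, or
condition-order effects — so passing tests certify the scoring and
inference chain, not robustness to every contingency of real recordings.
Artifact screening in real studies was visual; here three automated
heuristics replace it (adjacent tachometer steps > 20 BPM, SC drift
> 5 μS/s sustained ≥ 0.5 s, zero-variance windows), with configurable
thresholds chosen as conventional plausibility bounds.  Artifact trials
are excluded before averaging and before slope fits, and `n_valid_trials`
is reported.

**Monte-Carlo problem sizes.**  The statistical checks (parameter
recovery, type-I error, power) sample the score-level model directly —
200, 500 and 100 replicate 24-subject cohorts respectively — because the
raw route embeds the identical draws; the equality of the two routes is
itself verified, exactly in the noise-free configuration and within small
waveform-noise tolerances at the defaults.  Single full raw-signal runs
(24 subjects, ≈ 900-s recordings at 100 Hz for HR/SC and 1000 Hz for EMG)
exercise the end-to-end pipeline.  The reduced HR/SC rate relative to a
1-kHz acquisition system is a configurable economy; the scored windows
contain hundreds of samples either way.

## Numerical notes and limitations

- Stimulus onsets are snapped to the HR/SC sample grid so evoked kernels
  are sampled identically on every trial; schedule gaps remain within
  their bounds after snapping.
- Beat solving inverts the integrated rate exactly per linear segment
  (quadratic formula in its numerically stable form), so constant-rate
  IBIs equal 60/rate to float precision.
- The tachometer value for interval k is held on (beat_{k+1}, beat_{k+2}]:
  a sample landing exactly on a beat shows the interval completed at the
  previous beat.  Samples before the second beat are back-filled; samples
  after the last beat hold the final value.
- Degenerate slope t-tests (zero-variance slopes, nonzero mean) report
  infinite |t| with p = 0 and a `degenerate` flag rather than failing.
- The ANOVA is restricted to the 2×2 fully-within design; there is no
  general factorial machinery, no between-subject factors, and no
  sphericity machinery (unneeded at two levels).
- SCR decomposition/deconvolution, ECG R-peak detection and proprietary
  acquisition formats are out of scope; recordings enter as IBI series or
  continuous channels in the package's plain-text format.
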
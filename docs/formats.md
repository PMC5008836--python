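# File formats

All files are plain text, UTF-8, '.' decimal point.  Floats are written
with 17 significant digits, so write/read cycles are lossless.  Time is
seconds from recording start; event onsets mark stimulus onset.

## Recording (per subject × condition)

Written by `write_recording(recording, prefix)`; mirrors the BIDS
physiological-recording convention without claiming compliance.

- `<prefix>_channel-<NAME>.csv` — one per channel (`HR`, `SC`, `EMG`),
  columns `time_s,value`.  Units: HR in BPM, SC in uS, EMG in uV
  (Unicode μS/μV accepted on input).
- `<prefix>_events.tsv` — tab-separated `onset  duration  label`; onsets
  non-negative and strictly increasing (violations are rejected with the
  offending line number).
- `<prefix>.json` — sidecar with `subject_id`, `condition`
  (`bandwidth` ∈ {pure_tone, white_noise}, `posture` ∈ {sitting, supine}),
  and per-channel `sampling_rate`, `units`, `n_samples`.

## Trial-level score table (`trial_scores.csv`)

One row per trial × channel:

| column | meaning |
|---|---|
| subject_id | e.g. `sub-01` |
| bandwidth, posture | condition labels |
| channel | HR / SC / EMG |
| trial_index | 1–15 |
| onset_s | stimulus onset in seconds |
| pre_level | mean level over [−1, 0) s, channel units |
| raw_response | post-window peak − pre_level |
| transformed_response | sign(raw)·√|raw| |
| artifact | boolean flag |
| artifact_reason | e.g. `HR jump`, `SC slope`, `flatline`, `truncated` |

`read_scores_table(path, kind="trial")` requires subject_id, bandwidth,
posture, channel, trial_index, transformed_response; unknown columns are
preserved.

## Subject-level summary (`subject_summaries.csv`)

One row per subject × condition × channel: `mean_pre_level`,
`mean_transformed_response`, `n_valid_trials`, `habituation_slope`,
`intercept`, `n_trials_used`.  Means are over non-artifact trials only.

## Other bundle tables

- `habituation_slopes.csv` — slope fits (trials 2–15, log₁₀ trial).
- `slope_ttests.csv` — one-sample t of slopes vs 0 per channel × cell.
- `anova_table.csv` — channel × measure × effect rows with SS, SS_error,
  df, F, p, eta2_g.
- `mixed_model.csv` — magnitude-estimation fixed effects per dimension.
- `descriptives.csv` — mean (SD) per condition cell, per channel ×
  measure.
- `loess_curves.csv` — fitted LOESS values per condition × trial.
- `ratings.csv` — `subject_id, sound_type, spl, presentation_index,
  dimension, rating` (ratings strictly positive).
- `results.json` — all statistics, machine-readable; `provenance.json` —
  package version, seed, config digest; `manifest.json` — cohort recipe
  (config, cell targets, per-recording condition/session).

Deposited subject-level study data can be analysed by placing tables with
the `subject_summaries.csv` column convention (plus `habituation_slope`)
under `data/deposited/psychophysiology.csv` and a rating table under
`data/deposited/magnitude_estimation.csv`.
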
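"""Default calibration targets for the synthetic cohort.

The generator emulates a 24-subject, 4-condition (bandwidth x posture),
15-trial loud-tone study.  Cell targets below are the published descriptive
statistics of that paradigm: pre-stimulus tonic levels differ by posture
(sitting > supine for HR and SC), while response magnitudes and habituation
slopes are calibrated with posture collapsed within bandwidth — posture is
modelled as a tonic-level shift only, with no effect on response magnitude,
which is the structure the paradigm's null posture finding implies.  Response
and slope values are on the transformed (signed square root) scale.
"""

from __future__ import annotations

import copy

CHANNELS = ("HR", "SC", "EMG")
BANDWIDTHS = ("pure_tone", "white_noise")
POSTURES = ("sitting", "supine")
#: fixed cell order used throughout the generator
CELLS = tuple((b, p) for b in BANDWIDTHS for p in POSTURES)

# cell -> (mean, sd); cell order: (PT, sit), (PT, sup), (WN, sit), (WN, sup)


def _cells(*pairs):
    return {cell: pair for cell, pair in zip(CELLS, pairs)}


#: descriptive targets per channel and measure
DEFAULT_CELL_TARGETS = {
    "HR": {
        # tonic level in BPM: sitting ~5.6 BPM above supine
        "pre_level": _cells((73.73, 12.19), (68.08, 9.59), (70.95, 11.19), (65.41, 9.58)),
        # mean transformed response in sqrt(BPM); posture collapsed
        "response": _cells((1.38, 0.59), (1.38, 0.56), (1.71, 0.62), (1.71, 0.64)),
        # habituation slope (transformed response per log10 trial)
        "slope": _cells((-0.01, 0.10), (-0.01, 0.08), (-0.055, 0.12), (-0.055, 0.09)),
    },
    "SC": {
        # tonic skin conductance level in uS
        "pre_level": _cells((14.19, 7.92), (10.20, 9.27), (14.96, 8.99), (12.69, 7.31)),
        "response": _cells((0.695, 0.67), (0.695, 0.71), (1.09, 0.59), (1.09, 0.83)),
        "slope": _cells((-0.08, 0.07), (-0.08, 0.06), (-0.085, 0.05), (-0.085, 0.07)),
    },
    "EMG": {
        # tonic integrated-EMG level in uV
        "pre_level": _cells((0.67, 0.05), (0.77, 0.36), (0.70, 0.09), (0.68, 0.07)),
        "response": _cells((2.19, 1.14), (2.19, 1.35), (3.00, 1.72), (3.00, 1.63)),
        "slope": _cells((-0.065, 0.09), (-0.065, 0.06), (-0.07, 0.10), (-0.07, 0.05)),
    },
}


def default_cell_targets() -> dict:
    """A deep copy of the default calibration table (safe to mutate)."""
    return copy.deepcopy(DEFAULT_CELL_TARGETS)


#: magnitude-estimation defaults: power-law slope per dB on the log10 scale
#: (~doubling of perceived loudness per 10 dB), a shallower aversiveness
#: slope, and rating variability typical of magnitude estimation
DEFAULT_RATING_PARAMS = {
    "slope_per_db": {"loudness": 0.030, "valence": 0.019},
    "type_offset": 0.0,
    "interaction_per_db": 0.0,
    "noise_sd_log": 0.35,
    "subject_intercept_sd": 0.15,
    "subject_slope_sd": 0.02,
    "n_subjects": 15,
    "spls": (35, 50, 65, 80, 95),
    "n_presentations": 3,
}
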
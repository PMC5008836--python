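"""Within-session habituation: slope regression and LOESS response curves.

Relative habituation is the slope ``b`` of the ordinary least-squares fit
``Y = a + b * X`` over trials 2-15, where ``Y`` is the transformed (square
root) response score and ``X`` the log trial number (log10 by default; the
base is configurable and only rescales ``b``).  Group-level habituation is
assessed with a one-sample t-test of the subject slopes against zero.
LOESS curves (local polynomial regression with tricube weights) describe the
trial-by-trial response time course including trial 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import DataError

log = logging.getLogger(__name__)

TRIAL_RANGE = (2, 15)


@dataclass
class HabituationSlope:
    subject_id: str
    bandwidth: str
    posture: str
    channel: str
    intercept: float
    slope: float
    n_trials_used: int
    trial_range: tuple = TRIAL_RANGE
    missing: bool = False


def habituation_slope(trial_indices, responses, log_base: float = 10.0,
                      trial_range=TRIAL_RANGE, min_trials: int = 3,
                      **labels) -> HabituationSlope:
    """OLS slope of transformed response on log(trial) over trials 2-15.

    Artifact trials are expected to be excluded by the caller; fits with
    fewer than ``min_trials`` usable trials are marked missing.
    """
    t = np.asarray(trial_indices, dtype=float)
    y = np.asarray(responses, dtype=float)
    keep = (t >= trial_range[0]) & (t <= trial_range[1]) & np.isfinite(y)
    t, y = t[keep], y[keep]
    meta = {k: labels.get(k, "") for k in ("subject_id", "bandwidth", "posture", "channel")}
    if len(t) < min_trials:
        return HabituationSlope(**meta, intercept=np.nan, slope=np.nan,
                                n_trials_used=len(t), trial_range=trial_range,
                                missing=True)
    x = np.log(t) / np.log(log_base)
    slope, intercept = np.polyfit(x, y, 1)
    return HabituationSlope(**meta, intercept=float(intercept), slope=float(slope),
                            n_trials_used=len(t), trial_range=trial_range)


def fit_all_slopes(scores: pd.DataFrame, log_base: float = 10.0,
                   trial_range=TRIAL_RANGE) -> pd.DataFrame:
    """Fit one habituation slope per subject x condition x channel.

    Artifact trials are dropped before fitting.
    """
    rows = []
    keys = ["subject_id", "bandwidth", "posture", "channel"]
    for key, grp in scores.groupby(keys, sort=True):
        valid = grp[~grp["artifact"]]
        fit = habituation_slope(valid["trial_index"], valid["transformed_response"],
                                log_base=log_base, trial_range=trial_range,
                                **dict(zip(keys, key)))
        rows.append({**{k: getattr(fit, k) for k in keys},
                     "intercept": fit.intercept, "slope": fit.slope,
                     "n_trials_used": fit.n_trials_used, "missing": fit.missing})
    return pd.DataFrame(rows)


@dataclass
class SlopeTTest:
    t: float
    df: int
    p: float
    mean: float
    sd: float
    n: int
    degenerate: bool = False  # zero-variance slopes: |t| reported as inf


def slope_t_test(slopes) -> SlopeTTest:
    """One-sample t-test of subject habituation slopes against zero."""
    b = np.asarray(slopes, dtype=float)
    b = b[np.isfinite(b)]
    n = len(b)
    if n < 2:
        raise DataError("slope t-test needs at least 2 non-missing slopes")
    mean = float(np.mean(b))
    sd = float(np.std(b, ddof=1))
    df = n - 1
    if sd == 0.0:
        if mean == 0.0:
            return SlopeTTest(t=0.0, df=df, p=1.0, mean=mean, sd=sd, n=n)
        return SlopeTTest(t=float(np.sign(mean)) * np.inf, df=df, p=0.0,
                          mean=mean, sd=sd, n=n, degenerate=True)
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return SlopeTTest(t=float(t), df=df, p=float(p), mean=mean, sd=sd, n=n)


def slope_t_test_table(slopes: pd.DataFrame) -> pd.DataFrame:
    """Group-level slope t-tests per channel x condition cell."""
    rows = []
    for (ch, bw, po), grp in slopes.groupby(["channel", "bandwidth", "posture"],
                                            sort=True):
        res = slope_t_test(grp["slope"])
        rows.append({"channel": ch, "bandwidth": bw, "posture": po,
                     "mean_slope": res.mean, "sd_slope": res.sd, "n": res.n,
                     "t": res.t, "df": res.df, "p": res.p,
                     "degenerate": res.degenerate})
    return pd.DataFrame(rows)


@dataclass
class LoessCurve:
    channel: str
    bandwidth: str
    posture: str
    grid: np.ndarray
    fitted: np.ndarray
    span: float
    degree: int


def _loess_fit_at(x, y, x0, span, degree):
    n = len(x)
    d = np.abs(x - x0)
    q = int(np.ceil(span * n))
    min_pts = degree + 2
    if q < min_pts:
        log.warning("LOESS span %.3g gives %d points; widened to %d", span, q, min_pts)
        q = min_pts
    if q >= n:
        # span > 1: bandwidth extends beyond the data range so all points keep
        # positive weight; as span -> inf this converges to a global fit
        h = np.max(d) * max(span, 1.0)
    else:
        h = np.sort(d)[q - 1]
    if h <= 0:
        h = np.finfo(float).tiny
    w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
    if np.count_nonzero(w) < degree + 1:
        w = np.ones_like(w)
    coeffs = np.polyfit(x - x0, y, degree, w=np.sqrt(w))
    return coeffs[-1]  # value at x0


def loess_response_curve(trial_indices, responses, grid=None, span: float = 0.75,
                         degree: int = 2, **labels) -> LoessCurve:
    """Local polynomial regression (tricube weights) of response vs trial.

    Defaults: span 0.75, locally quadratic.  Deterministic for fixed inputs;
    exactly reproduces data lying on a polynomial of degree <= ``degree``.
    """
    x = np.asarray(trial_indices, dtype=float)
    y = np.asarray(responses, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 5:
        raise DataError("LOESS needs at least 5 points")
    if grid is None:
        grid = np.arange(1, 16, dtype=float)
    grid = np.asarray(grid, dtype=float)
    fitted = np.array([_loess_fit_at(x, y, g, span, degree) for g in grid])
    return LoessCurve(channel=labels.get("channel", ""),
                      bandwidth=labels.get("bandwidth", ""),
                      posture=labels.get("posture", ""),
                      grid=grid, fitted=fitted, span=span, degree=degree)


def loess_curves_by_condition(scores: pd.DataFrame, span: float = 0.75,
                              degree: int = 2, channels=("HR", "SC")) -> pd.DataFrame:
    """Pooled per-condition LOESS response curves (long format for plotting)."""
    rows = []
    for (ch, bw, po), grp in scores.groupby(["channel", "bandwidth", "posture"],
                                            sort=True):
        if ch not in channels:
            continue
        valid = grp[~grp["artifact"]]
        curve = loess_response_curve(valid["trial_index"],
                                     valid["transformed_response"],
                                     span=span, degree=degree,
                                     channel=ch, bandwidth=bw, posture=po)
        for g, f in zip(curve.grid, curve.fitted):
            rows.append({"channel": ch, "bandwidth": bw, "posture": po,
                         "trial": g, "fitted": f, "span": span, "degree": degree})
    return pd.DataFrame(rows)
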
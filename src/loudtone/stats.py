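"""Inferential layer: 2x2 within-subject ANOVA with generalized eta squared,
and the magnitude-estimation mixed model.

The ANOVA is the classical fully-within decomposition for two two-level
factors A (stimulus bandwidth) and B (posture) measured on every subject:

    SS_total = SS_subject + SS_A + SS_B + SS_AB
               + SS_{A x s} + SS_{B x s} + SS_{AB x s}

with ``F_A = MS_A / MS_{A x s}`` etc. on (1, n-1) degrees of freedom (no
sphericity correction is needed with two-level factors).  Effect sizes are
generalized eta squared in the Olejnik-Algina sense: for a fully
within-subject design every non-manipulated variance source enters the
denominator,

    eta2_G(effect) = SS_effect /
        (SS_effect + SS_subject + SS_{A x s} + SS_{B x s} + SS_{AB x s}).

Magnitude-estimation ratings are analyzed on the log10 scale after averaging
the three presentations per cell, with sound pressure level (centered at the
65 dB reference), sound type and their interaction as fixed effects and a
random intercept per subject (REML, via statsmodels MixedLM).  t statistics
use ``df = N_obs - n_subjects`` by default, which yields t(135) for the
standard 15-subject, 150-cell-mean design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import ConfigurationError, DataError

log = logging.getLogger(__name__)

BANDWIDTHS = ("pure_tone", "white_noise")
POSTURES = ("sitting", "supine")
EFFECTS = ("bandwidth", "posture", "bandwidth:posture")


def _cell_array(table: pd.DataFrame, dv: str, subject: str = "subject_id"):
    """Pivot a long CellTable into a complete (n, 2, 2) array.

    Incomplete subjects are dropped listwise (with a logged count).
    """
    required = {subject, "bandwidth", "posture", dv}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"cell table missing columns {sorted(missing)}")
    t = table[[subject, "bandwidth", "posture", dv]].dropna(subset=[dv])
    wide = t.pivot_table(index=subject, columns=["bandwidth", "posture"],
                         values=dv, aggfunc="mean")
    needed = [(b, p) for b in BANDWIDTHS for p in POSTURES]
    for cell in needed:
        if cell not in wide.columns:
            raise DataError(f"cell {cell} absent from the table")
    wide = wide[needed]
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        log.info("rm-ANOVA: dropped %d incomplete subject(s) listwise", n_dropped)
    if len(complete) < 2:
        raise DataError(
            f"rm-ANOVA needs at least 2 complete subjects, have {len(complete)}")
    y = complete.to_numpy().reshape(len(complete), 2, 2)
    return y, list(complete.index)


def ss_decomposition(y: np.ndarray) -> dict:
    """All eight sums of squares of the 2x2 fully within design.

    ``y`` has shape (n_subjects, 2, 2) indexed [subject, A level, B level].
    """
    n = y.shape[0]
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))          # subject means
    m_a = y.mean(axis=(0, 2))          # A (bandwidth) level means
    m_b = y.mean(axis=(0, 1))          # B (posture) level means
    m_ab = y.mean(axis=0)              # cell means (2, 2)
    m_as = y.mean(axis=2)              # (n, 2)
    m_bs = y.mean(axis=1)              # (n, 2)

    ss = {
        "subject": 4.0 * np.sum((m_s - grand) ** 2),
        "A": 2.0 * n * np.sum((m_a - grand) ** 2),
        "B": 2.0 * n * np.sum((m_b - grand) ** 2),
        "AB": n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2),
        "As": 2.0 * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2),
        "Bs": 2.0 * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2),
        "total": np.sum((y - grand) ** 2),
    }
    ss["ABs"] = (ss["total"] - ss["subject"] - ss["A"] - ss["B"] - ss["AB"]
                 - ss["As"] - ss["Bs"])
    return ss


def generalized_eta_squared(ss: dict) -> dict:
    """Olejnik-Algina generalized eta squared for each manipulated effect.

    With every factor manipulated within subjects the denominator is the
    effect SS plus all subject-linked variance (subject and the three
    effect-by-subject error terms).  A zero denominator yields NaN.
    """
    denom_base = ss["subject"] + ss["As"] + ss["Bs"] + ss["ABs"]
    out = {}
    for eff, key in zip(EFFECTS, ("A", "B", "AB")):
        denom = ss[key] + denom_base
        out[eff] = float(ss[key] / denom) if denom > 0 else np.nan
    return out


@dataclass
class WithinAnova2x2Results:
    """Fitted 2x2 within-subject ANOVA: effect table and SS decomposition."""

    anova_table: pd.DataFrame
    ss: dict
    n_subjects: int
    dv: str = ""

    @property
    def eta2_g(self) -> dict:
        return dict(zip(self.anova_table["effect"], self.anova_table["eta2_g"]))

    def summary(self) -> str:
        lines = [f"2x2 within-subject ANOVA on {self.dv or 'response'} "
                 f"(n = {self.n_subjects} subjects)",
                 f"{'effect':<22}{'df':>8}{'F':>10}{'p':>8}{'eta2_G':>9}"]
        for row in self.anova_table.itertuples(index=False):
            lines.append(f"{row.effect:<22}{f'({row.df1:.0f}, {row.df2:.0f})':>8}"
                         f"{row.F:>10.2f}{row.p:>8.3f}{row.eta2_g:>9.3f}")
        return "\n".join(lines)


class WithinAnova2x2:
    """Repeated-measures ANOVA model for the bandwidth x posture design.

    Parameters
    ----------
    table : DataFrame
        Long format with columns ``subject_id``, ``bandwidth``
        (pure_tone/white_noise), ``posture`` (sitting/supine) and the
        dependent variable.
    dv : str
        Name of the dependent-variable column.
    """

    def __init__(self, table: pd.DataFrame, dv: str, subject: str = "subject_id"):
        self.dv = dv
        self.y, self.subjects = _cell_array(table, dv, subject=subject)

    @classmethod
    def from_dataframe(cls, table, dv, subject="subject_id"):
        return cls(table, dv, subject=subject)

    def fit(self) -> WithinAnova2x2Results:
        y = self.y
        n = y.shape[0]
        ss = ss_decomposition(y)
        eta = generalized_eta_squared(ss)
        rows = []
        for eff, key, err in zip(EFFECTS, ("A", "B", "AB"), ("As", "Bs", "ABs")):
            df1, df2 = 1, n - 1
            ms_eff = ss[key] / df1
            ms_err = ss[err] / df2
            F = ms_eff / ms_err if ms_err > 0 else (0.0 if ms_eff == 0 else np.inf)
            p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
            rows.append({"effect": eff, "SS": ss[key], "SS_error": ss[err],
                         "df1": df1, "df2": df2, "F": float(F), "p": p,
                         "eta2_g": eta[eff]})
        return WithinAnova2x2Results(anova_table=pd.DataFrame(rows), ss=ss,
                                     n_subjects=n, dv=self.dv)


def rm_anova_2x2(table: pd.DataFrame, dv: str,
                 subject: str = "subject_id") -> WithinAnova2x2Results:
    """Convenience wrapper: build and fit :class:`WithinAnova2x2`."""
    return WithinAnova2x2(table, dv, subject=subject).fit()


# ---------------------------------------------------------------------------
# magnitude-estimation mixed model
# ---------------------------------------------------------------------------

@dataclass
class MagnitudeEstimationResults:
    """Fixed effects (log10 scale), variance components and fit metadata."""

    params: pd.DataFrame       # index: term; columns: estimate, se, t, df, p
    random_intercept_var: float
    residual_var: float
    dimension: str
    n_obs: int
    n_subjects: int
    converged: bool = True
    method: str = "MixedLM-REML"

    @property
    def fixed_effects(self) -> dict:
        return dict(zip(self.params.index, self.params["estimate"]))

    def summary(self) -> str:
        lines = [f"Magnitude estimation ({self.dimension}): random-intercept "
                 f"model on log10 cell-mean ratings",
                 f"n_obs = {self.n_obs}, n_subjects = {self.n_subjects}, "
                 f"method = {self.method}",
                 f"{'term':<28}{'estimate':>12}{'SE':>10}{'t':>8}{'df':>6}{'p':>8}"]
        for term, row in self.params.iterrows():
            lines.append(f"{term:<28}{row['estimate']:>12.5f}{row['se']:>10.5f}"
                         f"{row['t']:>8.2f}{row['df']:>6.0f}{row['p']:>8.3f}")
        lines.append(f"random intercept var = {self.random_intercept_var:.5g}, "
                     f"residual var = {self.residual_var:.5g}")
        return "\n".join(lines)


class MagnitudeEstimationModel:
    """Mixed model for loudness/valence magnitude estimates.

    Ratings are averaged over the three presentations per subject x sound
    type x SPL cell, log10-transformed, and modelled with fixed effects for
    SPL (dB, centered at the 65 dB reference), sound type (white noise vs
    pure tone) and their interaction, plus a random intercept per subject.

    Parameters
    ----------
    ratings : DataFrame
        Long rating table (columns ``subject_id, sound_type, spl,
        presentation_index, dimension, rating``).
    dimension : str
        ``"loudness"`` or ``"valence"``.
    df_method : str
        ``"obs_minus_subjects"`` (default): t degrees of freedom are
        ``N_obs - n_subjects``; ``"residual"``: ``N_obs - n_subjects -
        n_fixed + 1``.
    """

    TERMS = ["intercept", "spl", "sound_type[white_noise]", "spl:sound_type"]

    def __init__(self, ratings: pd.DataFrame, dimension: str = "loudness",
                 df_method: str = "obs_minus_subjects", log_base: float = 10.0):
        if df_method not in ("obs_minus_subjects", "residual"):
            raise ConfigurationError(f"unknown df_method {df_method!r}")
        if "dimension" in ratings.columns:
            ratings = ratings[ratings["dimension"] == dimension]
        if not len(ratings):
            raise DataError(f"no ratings for dimension {dimension!r}")
        cells = (ratings.groupby(["subject_id", "sound_type", "spl"], sort=True)
                 ["rating"].mean().reset_index())
        if cells["subject_id"].nunique() < 2:
            raise DataError("mixed model needs at least 2 subjects")
        if cells["spl"].nunique() < 2:
            raise DataError("mixed model needs at least 2 SPL levels")
        cells["log_rating"] = np.log(cells["rating"]) / np.log(log_base)
        cells["spl_c"] = cells["spl"] - 65.0
        cells["is_wn"] = (cells["sound_type"] == "white_noise").astype(float)
        self.cells = cells
        self.dimension = dimension
        self.df_method = df_method

    def _df(self) -> int:
        n_obs, n_subj = len(self.cells), self.cells["subject_id"].nunique()
        if self.df_method == "obs_minus_subjects":
            return n_obs - n_subj
        return n_obs - n_subj - len(self.TERMS) + 1

    def fit(self) -> MagnitudeEstimationResults:
        import statsmodels.formula.api as smf

        c = self.cells
        X = pd.DataFrame({
            "log_rating": c["log_rating"], "spl_c": c["spl_c"],
            "is_wn": c["is_wn"], "subject_id": c["subject_id"],
        })
        converged = True
        try:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                md = smf.mixedlm("log_rating ~ spl_c + is_wn + spl_c:is_wn", X,
                                 groups=X["subject_id"])
                mf = md.fit(reml=True)
            params = np.asarray(mf.fe_params)
            bse = np.asarray(mf.bse_fe)
            re_var = float(np.asarray(mf.cov_re).ravel()[0])
            resid_var = float(mf.scale)
            converged = bool(mf.converged)
            if not np.all(np.isfinite(bse)):
                raise np.linalg.LinAlgError("non-finite mixed-model SEs")
        except (np.linalg.LinAlgError, ValueError):
            # degenerate data (e.g. zero residual variance): the balanced
            # design makes the GLS fixed effects coincide with OLS
            import statsmodels.api as sm

            Xd = sm.add_constant(np.column_stack([
                c["spl_c"], c["is_wn"], c["spl_c"] * c["is_wn"]]))
            ols = sm.OLS(c["log_rating"].to_numpy(), Xd).fit()
            params, bse = np.asarray(ols.params), np.asarray(ols.bse)
            re_var, resid_var = 0.0, float(ols.mse_resid)
            converged = False
        df = self._df()
        with np.errstate(divide="ignore", invalid="ignore"):
            t = params / bse
        t = np.where(np.isnan(t), 0.0, t)  # 0/0: no effect, no evidence
        p = 2.0 * sps.t.sf(np.abs(t), df)
        table = pd.DataFrame({"estimate": params, "se": bse, "t": t,
                              "df": float(df), "p": p}, index=self.TERMS)
        return MagnitudeEstimationResults(
            params=table, random_intercept_var=re_var, residual_var=resid_var,
            dimension=self.dimension, n_obs=len(c),
            n_subjects=c["subject_id"].nunique(), converged=converged)


def lmm_fixed_effect(ratings: pd.DataFrame, dimension: str = "loudness",
                     df_method: str = "obs_minus_subjects") -> MagnitudeEstimationResults:
    """Convenience wrapper: build and fit :class:`MagnitudeEstimationModel`."""
    return MagnitudeEstimationModel(ratings, dimension, df_method=df_method).fit()


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def condition_descriptives(summaries: pd.DataFrame,
                           slopes: pd.DataFrame | None = None) -> pd.DataFrame:
    """Descriptive block: mean and SD per condition cell, per channel.

    Rows are channel x measure (pre-tone level, mean transformed response
    and, when a slope table is supplied, the habituation slope); columns the
    four bandwidth x posture cells.  Single-subject cells report SD as NaN.
    """
    frames = [("pre_level", summaries, "mean_pre_level"),
              ("mean_response", summaries, "mean_transformed_response")]
    if slopes is not None:
        frames.append(("response_slope", slopes, "slope"))
    rows = []
    for measure, df, col in frames:
        for ch, chgrp in df.groupby("channel", sort=True):
            row = {"channel": ch, "measure": measure}
            for b in BANDWIDTHS:
                for p in POSTURES:
                    vals = chgrp[(chgrp["bandwidth"] == b)
                                 & (chgrp["posture"] == p)][col].dropna()
                    row[f"{b}/{p}/mean"] = float(vals.mean()) if len(vals) else np.nan
                    row[f"{b}/{p}/sd"] = (float(vals.std(ddof=1))
                                          if len(vals) > 1 else np.nan)
            rows.append(row)
    return pd.DataFrame(rows)
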
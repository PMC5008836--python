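"""Within-subject ANOVA, generalized eta squared, mixed model, descriptives."""

import numpy as np
import pandas as pd
import pytest

import loudtone as lt
from loudtone.stats import ss_decomposition, generalized_eta_squared

from conftest import random_cell_table

CELLS = [("pure_tone", "sitting"), ("pure_tone", "supine"),
         ("white_noise", "sitting"), ("white_noise", "supine")]


def _table_from_array(y):
    rows = []
    for s in range(y.shape[0]):
        for a, b_lab in enumerate(("pure_tone", "white_noise")):
            for b, p_lab in enumerate(("sitting", "supine")):
                rows.append({"subject_id": f"s{s:02d}", "bandwidth": b_lab,
                             "posture": p_lab, "value": y[s, a, b]})
    return pd.DataFrame(rows)


def brute_force_ss(y):
    """Every SS term by explicit summation over cells and marginals."""
    n = y.shape[0]
    grand = y.mean()
    ss = {k: 0.0 for k in ("subject", "A", "B", "AB", "As", "Bs", "ABs", "total")}
    for s in range(n):
        m_s = y[s].mean()
        ss["subject"] += 4 * (m_s - grand) ** 2
    for a in range(2):
        ss["A"] += 2 * n * (y[:, a, :].mean() - grand) ** 2
    for b in range(2):
        ss["B"] += 2 * n * (y[:, :, b].mean() - grand) ** 2
    for a in range(2):
        for b in range(2):
            ss["AB"] += n * (y[:, a, b].mean() - y[:, a, :].mean()
                             - y[:, :, b].mean() + grand) ** 2
    for s in range(n):
        for a in range(2):
            ss["As"] += 2 * (y[s, a, :].mean() - y[:, a, :].mean()
                             - y[s].mean() + grand) ** 2
        for b in range(2):
            ss["Bs"] += 2 * (y[s, :, b].mean() - y[:, :, b].mean()
                             - y[s].mean() + grand) ** 2
    for s in range(n):
        for a in range(2):
            for b in range(2):
                ss["total"] += (y[s, a, b] - grand) ** 2
                resid = (y[s, a, b] - y[:, a, b].mean() - y[s, a, :].mean()
                         - y[s, :, b].mean() + y[:, a, :].mean()
                         + y[:, :, b].mean() + y[s].mean() - grand)
                ss["ABs"] += resid ** 2
    return ss


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def test_subject_offsets_only_give_zero_effects(rng):
    y = np.repeat(rng.normal(0, 3, 8)[:, None, None], 4).reshape(8, 2, 2)
    res = lt.rm_anova_2x2(_table_from_array(y), "value")
    assert np.allclose(res.anova_table["SS"], 0.0, atol=1e-18)
    assert np.allclose(res.anova_table["F"], 0.0, atol=1e-12)


def test_f_invariant_under_affine_transform(rng):
    df = random_cell_table(rng)
    res0 = lt.rm_anova_2x2(df, "value")
    df2 = df.assign(value=3.0 * df["value"] + 7.0)
    res1 = lt.rm_anova_2x2(df2, "value")
    assert np.allclose(res0.anova_table["F"], res1.anova_table["F"], rtol=1e-10)
    assert np.allclose(res0.anova_table["p"], res1.anova_table["p"], rtol=1e-10)


def test_ss_match_brute_force_oracle(rng):
    for _ in range(50):
        y = rng.normal(0, 1, (6, 2, 2)) + rng.normal(0, 2, (6, 1, 1))
        mine = ss_decomposition(y)
        oracle = brute_force_ss(y)
        for key in oracle:
            assert np.isclose(mine[key], oracle[key], atol=1e-10), key
        res = lt.rm_anova_2x2(_table_from_array(y), "value")
        for eff, key, err in zip(("bandwidth", "posture", "bandwidth:posture"),
                                 ("A", "B", "AB"), ("As", "Bs", "ABs")):
            f_oracle = (oracle[key] / 1.0) / (oracle[err] / 5.0)
            row = res.anova_table[res.anova_table.effect == eff].iloc[0]
            assert np.isclose(row["F"], f_oracle, atol=1e-10)


def test_ss_conservation(rng):
    y = rng.normal(0, 1, (10, 2, 2))
    ss = ss_decomposition(y)
    parts = (ss["subject"] + ss["A"] + ss["B"] + ss["AB"]
             + ss["As"] + ss["Bs"] + ss["ABs"])
    assert np.isclose(parts, ss["total"], atol=1e-9)


def test_anova_agrees_with_pingouin(rng):
    pg = pytest.importorskip("pingouin")
    df = random_cell_table(rng, n_subjects=12)
    res = lt.rm_anova_2x2(df, "value")
    ref = pg.rm_anova(data=df, dv="value", within=["bandwidth", "posture"],
                      subject="subject_id", detailed=True, effsize="ng2")
    for eff, src in (("bandwidth", "bandwidth"), ("posture", "posture"),
                     ("bandwidth:posture", "bandwidth * posture")):
        mine = res.anova_table[res.anova_table.effect == eff].iloc[0]
        theirs = ref[ref.Source == src].iloc[0]
        assert np.isclose(mine["F"], theirs["F"], rtol=1e-9)
        assert np.isclose(mine["p"], theirs["p_unc"], rtol=1e-9)
        assert np.isclose(mine["eta2_g"], theirs["ng2"], rtol=1e-9)


def test_single_subject_refused():
    y = np.zeros((1, 2, 2))
    with pytest.raises(lt.DataError):
        lt.rm_anova_2x2(_table_from_array(y), "value")


def test_incomplete_subject_dropped_listwise(rng):
    df = random_cell_table(rng, n_subjects=5)
    df = df.drop(df[(df.subject_id == "s00")
                    & (df.posture == "supine")
                    & (df.bandwidth == "pure_tone")].index)
    res = lt.rm_anova_2x2(df, "value")
    assert res.n_subjects == 4


# ---------------------------------------------------------------------------
# generalized eta squared
# ---------------------------------------------------------------------------

def test_eta2g_zero_for_null_effect():
    ss = {"A": 0.0, "B": 1.0, "AB": 0.5, "subject": 4.0,
          "As": 1.0, "Bs": 1.0, "ABs": 1.0}
    eta = generalized_eta_squared(ss)
    assert eta["bandwidth"] == 0.0


def test_eta2g_on_constructed_bandwidth_only_dataset():
    """Only bandwidth effect + subject offsets: eta2G = SS_A/(SS_A + SS_s)."""
    n = 6
    offsets = np.arange(n, dtype=float)
    y = np.empty((n, 2, 2))
    for s in range(n):
        y[s, 0, :] = offsets[s]        # pure tone
        y[s, 1, :] = offsets[s] + 2.0  # white noise: +2 everywhere
    ss = ss_decomposition(y)
    # by hand: SS_A = n_obs_per_level*2*(delta/2)^2 summed = 4n; SS_subject known
    ss_a_hand = 2 * n * 2 * 1.0 ** 2
    ss_subj_hand = 4 * np.sum((offsets - offsets.mean()) ** 2)
    assert np.isclose(ss["A"], ss_a_hand)
    assert np.isclose(ss["subject"], ss_subj_hand)
    eta = generalized_eta_squared(ss)
    assert np.isclose(eta["bandwidth"], ss_a_hand / (ss_a_hand + ss_subj_hand),
                      atol=1e-12)
    assert eta["posture"] == 0.0


def test_eta2g_bounded(rng):
    for _ in range(20):
        y = rng.normal(0, 1, (5, 2, 2))
        eta = generalized_eta_squared(ss_decomposition(y))
        for v in eta.values():
            assert 0.0 <= v <= 1.0


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------

def test_lmm_exact_recovery_on_noise_free_ratings():
    r = lt.generate_magnitude_ratings(n_subjects=15, power_law_slope_per_db=0.03,
                                      type_offset=0.0, noise_sd_log=0.0,
                                      subject_slope_sd=0.0, rng_seed=0)
    res = lt.lmm_fixed_effect(r, "loudness")
    assert abs(res.params.loc["spl", "estimate"] - 0.03) < 1e-8
    assert abs(res.params.loc["spl:sound_type", "estimate"]) < 1e-8


def test_lmm_df_convention_yields_135():
    r = lt.generate_magnitude_ratings(n_subjects=15, rng_seed=2)
    res = lt.lmm_fixed_effect(r, "loudness")
    assert res.n_obs == 150 and res.n_subjects == 15
    assert res.params["df"].iloc[0] == 135.0


def test_lmm_refuses_degenerate_designs():
    r = lt.generate_magnitude_ratings(n_subjects=2, rng_seed=1)
    with pytest.raises(lt.DataError):
        lt.lmm_fixed_effect(r[r.subject_id == "sub-01"], "loudness")
    with pytest.raises(lt.DataError):
        lt.lmm_fixed_effect(r[r.spl == 65], "loudness")


def test_lmm_type_offset_null_is_centered():
    """With no true sound-type effect its t statistic hovers around zero."""
    ts = []
    for rep in range(25):
        r = lt.generate_magnitude_ratings(n_subjects=15, type_offset=0.0,
                                          rng_seed=3000 + rep,
                                          dimensions=("loudness",))
        ts.append(lt.lmm_fixed_effect(r, "loudness")
                  .params.loc["sound_type[white_noise]", "t"])
    ts = np.asarray(ts)
    assert abs(ts.mean()) < 2.5 * ts.std(ddof=1) / np.sqrt(len(ts))


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def test_single_subject_descriptives_have_missing_sd():
    df = pd.DataFrame([{"subject_id": "s1", "bandwidth": b, "posture": p,
                        "channel": "HR", "mean_pre_level": 70.0,
                        "mean_transformed_response": 1.0, "n_valid_trials": 15}
                       for b, p in CELLS])
    out = lt.condition_descriptives(df)
    assert np.isnan(out["pure_tone/sitting/sd"]).all()
    assert (out["pure_tone/sitting/mean"] == [70.0, 1.0]).all()


def test_noise_free_cohort_descriptives_equal_targets(noise_free_cohort):
    """Calibrated noise-free cohort: cell means come back exactly."""
    cohort = noise_free_cohort
    scores = cohort.score_table()
    summaries = lt.summarize_subject_condition(scores)
    slopes = lt.fit_all_slopes(scores)
    desc = lt.condition_descriptives(summaries, slopes)
    tg = cohort.config.cell_targets
    for ch in ("HR", "SC", "EMG"):
        for measure, key in (("pre_level", "pre_level"),
                             ("mean_response", "response"),
                             ("response_slope", "slope")):
            row = desc[(desc.channel == ch) & (desc.measure == measure)].iloc[0]
            for b, p in CELLS:
                assert np.isclose(row[f"{b}/{p}/mean"], tg[ch][key][(b, p)][0],
                                  atol=1e-9), (ch, measure, b, p)
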
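"""Pipeline orchestration: simulate -> score -> summarize -> analyze -> report.

A run produces a results bundle directory containing the trial-level score
table, subject-condition summaries, habituation slopes and group t-tests,
the 2x2 within-subject ANOVA table for every channel x measure, the
magnitude-estimation mixed-model table, a Table-style descriptive block,
LOESS response curves, a machine-readable ``results.json`` and a provenance
record.  Output files carry no timestamps, so a bundle is byte-identical
for a fixed seed and configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from . import habituation, io, scoring, stats
from .calibration import CHANNELS
from .exceptions import ConfigurationError, DataError
from .synthetic import (GeneratorConfig, ResponseKernelParams, SyntheticCohort,
                        generate_magnitude_ratings)

log = logging.getLogger("loudtone.pipeline")

MEASURES = {
    "pre_level": "mean_pre_level",
    "mean_response": "mean_transformed_response",
    "slope": "slope",
}


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    ``mode`` is ``simulate`` (generate + score, no statistics), ``analyze``
    (statistics on an existing score table) or ``full``.
    """

    mode: str = "full"
    out_dir: str = "loudtone_out"
    seed: int = 0
    generator: dict = field(default_factory=dict)   # GeneratorConfig overrides
    kernels: dict = field(default_factory=dict)     # ResponseKernelParams overrides
    scores_path: str | None = None                  # analyze mode input
    ratings_path: str | None = None
    simulate_level: str = "raw"                     # "raw" | "scores"
    emg_time_constant: float = 0.010
    artifact_options: dict = field(default_factory=dict)
    detect_artifacts: bool = True
    log_base: float = 10.0
    df_method: str = "obs_minus_subjects"
    write_raw: bool = False
    verbose: bool = False

    def __post_init__(self):
        if self.mode not in ("simulate", "analyze", "full"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze" and not self.scores_path:
            raise ConfigurationError("analyze mode requires scores_path")
        if self.simulate_level not in ("raw", "scores"):
            raise ConfigurationError(f"unknown simulate_level {self.simulate_level!r}")

    @classmethod
    def from_yaml(cls, path, **overrides):
        import yaml

        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def generator_config(self) -> GeneratorConfig:
        try:
            return GeneratorConfig(seed=self.seed, **self.generator)
        except TypeError as exc:
            raise ConfigurationError(f"bad generator options: {exc}") from exc

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)   # where a bundle lives must not change its content
        d.pop("verbose", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _setup_log(out_dir: Path, verbose: bool):
    logger = logging.getLogger("loudtone")
    logger.setLevel(logging.DEBUG if verbose else logging.INFO)
    for h in list(logger.handlers):
        logger.removeHandler(h)
    fh = logging.FileHandler(out_dir / "pipeline.log", mode="w", encoding="utf-8")
    # stage-tagged, untimestamped: bundles must be byte-identical per seed
    fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(fh)
    return logger, fh


def score_cohort(cohort: SyntheticCohort, config: PipelineConfig,
                 out_dir: Path | None = None) -> pd.DataFrame:
    """Score every recording of a cohort (raw-signal route)."""
    frames = []
    for i in range(len(cohort)):
        rec = cohort.recording(i)
        if config.write_raw and out_dir is not None:
            prefix = out_dir / "raw" / (
                f"{rec.subject_id}_{rec.condition['bandwidth']}"
                f"_{rec.condition['posture']}")
            io.write_recording(rec, prefix)
        frames.append(scoring.score_recording(
            rec, emg_time_constant=config.emg_time_constant,
            detect=config.detect_artifacts,
            artifact_options=config.artifact_options))
        if config.verbose:
            n_art = int(frames[-1]["artifact"].sum())
            log.debug("scored %s %s/%s: %d artifact trial-scores",
                      rec.subject_id, rec.condition["bandwidth"],
                      rec.condition["posture"], n_art)
    return pd.concat(frames, ignore_index=True)


def analyze_scores(scores: pd.DataFrame, ratings: pd.DataFrame | None = None,
                   log_base: float = 10.0,
                   df_method: str = "obs_minus_subjects") -> dict:
    """Run the full inferential layer on a trial-level score table.

    Returns a dict of DataFrames/objects: summaries, slopes, slope t-tests,
    ANOVA table, descriptives, LOESS curves and (if ratings are given)
    mixed-model tables per dimension.
    """
    summaries = scoring.summarize_subject_condition(scores)
    slopes = habituation.fit_all_slopes(scores, log_base=log_base)
    summaries = summaries.merge(
        slopes[["subject_id", "bandwidth", "posture", "channel", "slope",
                "intercept", "n_trials_used"]],
        on=["subject_id", "bandwidth", "posture", "channel"], how="left")
    summaries = summaries.rename(columns={"slope": "habituation_slope"})
    ttests = habituation.slope_t_test_table(slopes)
    loess = habituation.loess_curves_by_condition(scores)
    anova_rows = []
    anova_results = {}
    for ch in sorted(scores["channel"].unique()):
        for measure, col in MEASURES.items():
            df = (slopes if measure == "slope" else summaries)
            sub = df[df["channel"] == ch].rename(columns={col: "value"})
            try:
                res = stats.rm_anova_2x2(sub, "value")
            except DataError as exc:
                log.warning("ANOVA skipped for %s/%s: %s", ch, measure, exc)
                continue
            anova_results[(ch, measure)] = res
            for row in res.anova_table.itertuples(index=False):
                anova_rows.append({"channel": ch, "measure": measure,
                                   "effect": row.effect, "SS": row.SS,
                                   "SS_error": row.SS_error, "df1": row.df1,
                                   "df2": row.df2, "F": row.F, "p": row.p,
                                   "eta2_g": row.eta2_g})
    out = {
        "summaries": summaries,
        "slopes": slopes,
        "slope_ttests": ttests,
        "anova_table": pd.DataFrame(anova_rows),
        "anova_results": anova_results,
        "descriptives": stats.condition_descriptives(summaries, slopes),
        "loess_curves": loess,
    }
    if ratings is not None:
        mixed = {}
        for dim in sorted(ratings["dimension"].unique()):
            mixed[dim] = stats.lmm_fixed_effect(ratings, dim, df_method=df_method)
        out["mixed_models"] = mixed
    return out


def _results_json(analysis: dict, seed: int) -> dict:
    res = {"seed": seed, "anova": {}, "slope_ttests": {}, "mixed_models": {}}
    for row in analysis["anova_table"].itertuples(index=False):
        res["anova"].setdefault(row.channel, {}).setdefault(row.measure, {})[
            row.effect] = {"F": row.F, "p": round(row.p, 3), "eta2_g": row.eta2_g,
                           "df": [row.df1, row.df2]}
    for row in analysis["slope_ttests"].itertuples(index=False):
        res["slope_ttests"].setdefault(row.channel, {})[
            f"{row.bandwidth}/{row.posture}"] = {
                "t": row.t if np.isfinite(row.t) else None,
                "df": row.df, "p": round(row.p, 3), "mean_slope": row.mean_slope}
    for dim, mm in analysis.get("mixed_models", {}).items():
        res["mixed_models"][dim] = {
            term: {"estimate": r["estimate"], "se": r["se"], "t": r["t"],
                   "df": r["df"], "p": round(r["p"], 3)}
            for term, r in mm.params.iterrows()}
        res["mixed_models"][dim]["variance"] = {
            "random_intercept": mm.random_intercept_var,
            "residual": mm.residual_var}
    return res


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the configured pipeline; returns the bundle directory."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logger, handler = _setup_log(out_dir, config.verbose)
    stage = "setup"
    try:
        ratings = None
        if config.mode == "analyze":
            stage = "load"
            log.info("[load] reading scores from %s", config.scores_path)
            scores = io.read_scores_table(config.scores_path, kind="trial")
            if config.ratings_path:
                ratings = io.read_ratings_table(config.ratings_path)
        else:
            stage = "simulate"
            gen = config.generator_config()
            try:
                kernels = ResponseKernelParams(**config.kernels)
            except TypeError as exc:
                raise ConfigurationError(f"bad kernel options: {exc}") from exc
            cohort = SyntheticCohort(gen, kernels=kernels, seed=config.seed)
            io.write_manifest(cohort.manifest(), out_dir / "manifest.json")
            log.info("[simulate] cohort: %d subjects, %d recordings, seed %d",
                     gen.n_subjects, len(cohort), config.seed)
            stage = "score"
            if config.simulate_level == "scores":
                scores = cohort.score_table()
            else:
                scores = score_cohort(cohort, config, out_dir)
            io.write_table(cohort.truth(), out_dir / "generator_truth.csv")
            rating_seed = np.random.SeedSequence(config.seed).spawn(4)[3]
            ratings = generate_magnitude_ratings(
                rng_seed=np.random.default_rng(rating_seed))
            io.write_table(ratings, out_dir / "ratings.csv")
        io.write_table(scores, out_dir / "trial_scores.csv")
        n_art = int(scores["artifact"].sum())
        log.info("[score] %d trial-scores, %d flagged artifact", len(scores), n_art)

        if config.mode == "simulate":
            handler.close()
            logger.removeHandler(handler)
            return out_dir

        stage = "analyze"
        analysis = analyze_scores(scores, ratings, log_base=config.log_base,
                                  df_method=config.df_method)
        io.write_table(analysis["summaries"], out_dir / "subject_summaries.csv")
        io.write_table(analysis["slopes"], out_dir / "habituation_slopes.csv")
        io.write_table(analysis["slope_ttests"], out_dir / "slope_ttests.csv")
        io.write_table(analysis["anova_table"], out_dir / "anova_table.csv")
        io.write_table(analysis["descriptives"], out_dir / "descriptives.csv")
        io.write_table(analysis["loess_curves"], out_dir / "loess_curves.csv")
        if "mixed_models" in analysis:
            rows = []
            for dim, mm in analysis["mixed_models"].items():
                for term, r in mm.params.iterrows():
                    rows.append({"dimension": dim, "term": term, **r.to_dict()})
            io.write_table(pd.DataFrame(rows), out_dir / "mixed_model.csv")
        stage = "report"
        results = _results_json(analysis, config.seed)
        with open(out_dir / "results.json", "w", encoding="utf-8") as fh:
            json.dump(results, fh, indent=2, sort_keys=True)
            fh.write("\n")
        provenance = {"package": "loudtone", "version": _pkg_version,
                      "seed": config.seed, "mode": config.mode,
                      "config_digest": config.digest()}
        with open(out_dir / "provenance.json", "w", encoding="utf-8") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
            fh.write("\n")
        log.info("[report] bundle complete")
        handler.close()
        logger.removeHandler(handler)
        return out_dir
    except Exception as exc:
        log.error("[%s] failed: %s", stage, exc)
        (out_dir / "INCOMPLETE").write_text(f"stage {stage} failed: {exc}\n")
        handler.close()
        logger.removeHandler(handler)
        raise


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def render_report(bundle_dir, figures: bool = True) -> Path:
    """Render a human-readable report (plus LOESS figures) from a bundle.

    Regenerates identically from the same bundle.  Missing channels or
    tables are flagged explicitly rather than failing the whole report.
    """
    bundle = Path(bundle_dir)
    desc_path = bundle / "descriptives.csv"
    if not desc_path.exists():
        raise DataError(f"no descriptives.csv in {bundle}; not a results bundle")
    desc = pd.read_csv(desc_path)
    anova = pd.read_csv(bundle / "anova_table.csv") if (bundle / "anova_table.csv").exists() else None
    lines = ["# Loud-tone pipeline report", ""]
    gaps = []
    lines.append("## Responses by stimulus bandwidth and posture")
    lines.append("")
    header = ("| channel | measure | PT/sitting | PT/supine | WN/sitting | "
              "WN/supine | F(bandwidth) | p | eta2_G | F(posture) | p | eta2_G "
              "| F(interaction) | p | eta2_G |")
    lines += [header, "|" + "---|" * 15]
    for ch in CHANNELS:
        chd = desc[desc["channel"] == ch]
        if chd.empty:
            gaps.append(f"channel {ch} absent from descriptives")
            continue
        for measure in ("pre_level", "mean_response", "response_slope"):
            row = chd[chd["measure"] == measure]
            if row.empty:
                continue
            row = row.iloc[0]
            cells = []
            for b in ("pure_tone", "white_noise"):
                for p in ("sitting", "supine"):
                    m, sd = row[f"{b}/{p}/mean"], row[f"{b}/{p}/sd"]
                    cells.append(f"{m:.2f} ({sd:.2f})" if np.isfinite(sd)
                                 else f"{m:.2f}")
            stats_cells = []
            akey = {"pre_level": "pre_level", "mean_response": "mean_response",
                    "response_slope": "slope"}[measure]
            for eff in ("bandwidth", "posture", "bandwidth:posture"):
                arow = None
                if anova is not None:
                    sel = anova[(anova["channel"] == ch)
                                & (anova["measure"] == akey)
                                & (anova["effect"] == eff)]
                    arow = sel.iloc[0] if len(sel) else None
                if arow is None:
                    stats_cells += ["-", "-", "-"]
                else:
                    stats_cells += [f"{arow['F']:.2f}", f"{arow['p']:.3f}",
                                    f"{arow['eta2_g']:.3f}"]
            lines.append("| " + " | ".join([ch, measure] + cells + stats_cells) + " |")
    for name, title in (("slope_ttests.csv", "Habituation t-tests (slopes vs 0)"),
                        ("mixed_model.csv", "Magnitude estimation (mixed model)")):
        path = bundle / name
        if not path.exists():
            gaps.append(f"{name} missing")
            continue
        df = pd.read_csv(path)
        lines += ["", f"## {title}", "", "```",
                  df.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
                  "```"]
    if figures:
        fig_paths = _render_figures(bundle)
        if fig_paths:
            lines += ["", "## Figures", ""]
            lines += [f"![{p.stem}]({p.name})" for p in fig_paths]
        else:
            gaps.append("no LOESS curves available for figures")
    if gaps:
        lines += ["", "## Gaps", ""] + [f"- {g}" for g in gaps]
    report = bundle / "report.md"
    report.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return report


def _render_figures(bundle: Path):
    path = bundle / "loess_curves.csv"
    if not path.exists():
        return []
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = pd.read_csv(path)
    out = []
    for ch, chc in curves.groupby("channel"):
        fig, ax = plt.subplots(figsize=(6, 4))
        for (bw, po), grp in chc.groupby(["bandwidth", "posture"]):
            ax.plot(grp["trial"], grp["fitted"], marker="o", ms=3,
                    label=f"{bw}/{po}")
        ax.set_xlabel("trial")
        ax.set_ylabel("transformed response")
        ax.set_title(f"{ch}: LOESS response time course")
        ax.legend(fontsize=8)
        fig.tight_layout()
        p = bundle / f"loess_{ch}.png"
        fig.savefig(p, dpi=100, metadata={"Date": None})  # reproducible bytes
        plt.close(fig)
        out.append(p)
    return out
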
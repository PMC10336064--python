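"""End-to-end reproduction pipeline.

Chains the stages in study order: synthetic cohort generation, adaptive
staircase runs for the rise-time discrimination (RTD) task, psychometric
fits with quality control for the phoneme-identification task, the
normative deviance analysis, and the group/brain-behavior statistics,
writing CSV/JSON outputs plus a human-readable summary. Identical
(config, seed) inputs give identical outputs; every artifact records the
config hash and seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import cohort_table as ct
from .deviance import DevianceConfig, deviance_report
from .observers import Cohort, CohortConfig, cohort_to_frames, generate_cohort
from .psychometric import PriorSpec, fit_psychometric, qc_exclude
from .staircase import StaircaseConfig, build_ladder, run_staircase
from .stats import compare_groups, fdr_adjust, fit_group_model, predict_phonology


class PipelineConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    staircase: StaircaseConfig = Field(default_factory=StaircaseConfig)
    priors: PriorSpec = Field(default_factory=PriorSpec)
    deviance: DevianceConfig = Field(default_factory=DevianceConfig)
    smooth_hearing_for_id: bool = True

    def digest(self) -> str:
        payload = self.model_dump_json().encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_tasks(cohort: Cohort, config: PipelineConfig) -> pd.DataFrame:
    """Simulate both tasks for every observer and score them.

    Returns one row per participant with log RTD threshold (NaN when the
    staircase was not completed or produced too few reversals) and the
    identification slope (NaN when the task was not completed or the fit
    failed quality control).
    """
    ladder = build_ladder()
    seeds = np.random.SeedSequence(config.seed).spawn(len(cohort.observers))
    rows = []
    for obs, ss in zip(cohort.observers, seeds):
        rng = np.random.default_rng(ss)
        log_thr = np.nan
        if obs.rtd_completed:
            res = run_staircase(obs, config.staircase, ladder, rng)
            if res.valid:
                log_thr = math.log(res.threshold_ms)
        slope = np.nan
        qc = False
        if obs.id_completed:
            fit = fit_psychometric(cohort.identification[obs.participant_id],
                                   config.priors)
            qc = qc_exclude(fit)
            if not qc and fit.slope50 is not None:
                slope = fit.slope50
        rows.append(
            {
                "participant_id": obs.participant_id,
                "group": obs.group,
                "log_rtd_threshold": log_thr,
                "id_slope": slope,
                "id_qc_excluded": qc,
                "hearing": obs.hearing_fletcher_db,
                "cognition": obs.cognition_z,
                "phonology_screeling": obs.phonology_screeling,
                "fluency": obs.fluency_count,
            }
        )
    return pd.DataFrame(rows)


def _scores_long(analysis: pd.DataFrame) -> pd.DataFrame:
    parts = []
    for task, col in (("rtd_log_threshold", "log_rtd_threshold"),
                      ("id_slope", "id_slope")):
        parts.append(pd.DataFrame({
            "participant_id": analysis["participant_id"],
            "group": analysis["group"],
            "task": task,
            "score": analysis[col],
            "valid": analysis[col].notna(),
        }))
    return pd.concat(parts, ignore_index=True)


def run_statistics(analysis: pd.DataFrame, config: PipelineConfig) -> dict:
    """Group comparisons, covariate-adjusted group models, and the
    within-patient phonology regressions with FDR correction (n = 2
    phonology outcomes per task)."""
    out: dict = {}
    rtd = analysis.dropna(subset=["log_rtd_threshold"])
    ids = analysis.dropna(subset=["id_slope"])

    for label, sub, col in (("rtd", rtd, "log_rtd_threshold"),
                            ("id_slope", ids, "id_slope")):
        a = sub.loc[sub.group == "aphasia", col]
        c = sub.loc[sub.group == "control", col]
        tr = compare_groups(a, c)
        out[f"{label}_group_comparison"] = {
            "method": tr.method, "statistic": tr.statistic,
            "df": tr.df, "p": tr.p_two_sided,
            "n_aphasia": int(len(a)), "n_control": int(len(c)),
        }

    def modelfit_dict(mf):
        return {
            "formula": mf.formula, "kind": mf.model_kind,
            "n": mf.n_obs, "n_dropped": mf.n_dropped,
            "adjusted_r2": mf.adjusted_r2,
            "coefficients": {k: [float(mf.params[k]), float(mf.bse[k])]
                             for k in mf.params.index},
            "terms": {t: {"F": mf.term_f[t], "df": mf.term_df[t],
                          "p": mf.term_p[t]} for t in mf.term_f},
        }

    out["rtd_adjusted_model"] = modelfit_dict(
        fit_group_model(rtd, "log_rtd_threshold"))
    out["id_adjusted_model"] = modelfit_dict(
        fit_group_model(ids, "id_slope",
                        smooth_hearing=config.smooth_hearing_for_id))

    # within-aphasia phonology predictions; FDR over the two phonology
    # outcomes per task score
    for task_label, task_col in (("rtd", "log_rtd_threshold"),
                                 ("id_slope", "id_slope")):
        fits = {}
        for outcome in ("phonology_screeling", "fluency"):
            mf = predict_phonology(analysis, outcome, task_col)
            fits[outcome] = mf
        raw_p = [fits[o].term_p[task_col] for o in fits]
        adj = fdr_adjust(raw_p)
        out[f"phonology_models_{task_label}"] = {
            o: dict(modelfit_dict(fits[o]),
                    task_p_fdr=float(adj[i]))
            for i, o in enumerate(fits)
        }
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": config.digest(), "seed": config.seed}

    cohort = generate_cohort(config.cohort, config.seed)
    participants, trials = cohort_to_frames(cohort)
    participants.to_csv(outdir / "participants.csv", index=False)
    trials.to_csv(outdir / "identification_trials.csv", index=False)

    analysis = run_tasks(cohort, config)
    analysis.to_csv(outdir / "task_scores.csv", index=False)

    report = deviance_report(_scores_long(analysis), config.deviance)
    dev = dict(meta, **report.summary())
    (outdir / "deviance.json").write_text(json.dumps(dev, indent=2))

    stats = dict(meta, **run_statistics(analysis, config))
    (outdir / "stats.json").write_text(json.dumps(stats, indent=2, default=str))

    summary = _human_summary(analysis, dev, stats)
    (outdir / "summary.txt").write_text(summary)
    (outdir / "config.json").write_text(
        json.dumps(dict(meta, config=json.loads(config.model_dump_json())), indent=2))
    return {"meta": meta, "analysis": analysis, "deviance": dev, "stats": stats}


def _human_summary(analysis: pd.DataFrame, dev: dict, stats: dict) -> str:
    lines = ["Auditory-phonemic assessment pipeline - summary", ""]
    for g, sub in analysis.groupby("group"):
        thr = np.exp(sub["log_rtd_threshold"].dropna())
        lines.append(
            f"{g}: n={len(sub)}, RTD threshold geometric mean "
            f"{np.exp(np.log(thr).mean()):.1f} ms (n valid {len(thr)}), "
            f"identification slope mean "
            f"{sub['id_slope'].mean():.3f} (n valid {sub['id_slope'].notna().sum()})"
        )
    lines.append("")
    for key in ("rtd_group_comparison", "id_slope_group_comparison"):
        s = stats[key]
        lines.append(f"{key}: {s['method']} statistic={s['statistic']:.3f} "
                     f"p={s['p']:.4g}")
    u = dev["union"]
    lines.append("")
    lines.append(
        f"Deviance: {u['deviant']}/{u['n']} patients "
        f"({100 * u['proportion']:.1f}%) deviant on at least one task"
    )
    return "\n".join(lines) + "\n"


def reproduce_cohort_table(path=None) -> dict:
    """Recompute the printed descriptive statistics, cut-off counts and
    vessel proportions from the packaged cohort table."""
    table = ct.load_cohort_table(path)
    age = ct.descriptives(table["age"])
    tss = ct.descriptives(table["time_since_stroke_months"])
    cut = ct.cutoff_counts(table)
    return {
        "n": int(len(table)),
        "age_mean": age["mean"], "age_sd": age["sd"],
        "time_since_stroke_mean": tss["mean"], "time_since_stroke_sd": tss["sd"],
        "time_since_stroke_median": tss["median"],
        "percent_female": 100.0 * float((table["sex"] == "f").mean()),
        "percent_mca_known_vessel": 100.0 * ct.vessel_proportions(table),
        "below_either_cutoff": cut["below_either"],
        "below_nbt_cutoff": cut["below_nbt"],
        "below_screeling_cutoff": cut["below_screeling"],
    }
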
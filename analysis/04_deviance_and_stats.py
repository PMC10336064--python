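#!/usr/bin/env python
"""Run the inferential stage on the simulated task scores: the
trimmed-norm individual deviance analysis, the covariate-adjusted group
comparisons, and the within-aphasia phonology regressions with FDR
correction.

Reads results/cohort/task_scores.csv (from 03_run_tasks.py); writes
results/deviance.json and results/stats.json.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from audphon.deviance import DevianceConfig, deviance_report
from audphon.pipeline import PipelineConfig, _scores_long, run_statistics

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--scores", type=Path,
                    default=ROOT / "results" / "cohort" / "task_scores.csv")
    args = ap.parse_args()

    analysis = pd.read_csv(args.scores)
    config = PipelineConfig()

    report = deviance_report(_scores_long(analysis), DevianceConfig())
    summary = report.summary()
    (ROOT / "results" / "deviance.json").write_text(json.dumps(summary, indent=2))
    for task, d in summary["per_task"].items():
        print(f"{task}: {d['n_patients_deviant']}/{d['n_patients']} patients "
              f"deviant ({100 * d['proportion_deviant']:.1f}%).")
    u = summary["union"]
    print(f"Union: {u['deviant']}/{u['n']} patients "
          f"({100 * u['proportion']:.1f}%) deviant on at least one task.")

    stats = run_statistics(analysis, config)
    (ROOT / "results" / "stats.json").write_text(
        json.dumps(stats, indent=2, default=str))
    for key in ("rtd_group_comparison", "id_slope_group_comparison"):
        s = stats[key]
        print(f"{key}: {s['method']}, statistic {s['statistic']:.3f}, "
              f"p = {s['p']:.4g}")
    rtd_model = stats["phonology_models_rtd"]["phonology_screeling"]
    beta, se = rtd_model["coefficients"]["log_rtd_threshold"]
    print(f"Phonology ~ log RTD threshold (within aphasia): beta "
          f"{beta:.2f} (SE {se:.2f}), FDR-adjusted p "
          f"{rtd_model['task_p_fdr']:.3f}.")


if __name__ == "__main__":
    main()
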
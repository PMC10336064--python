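#!/usr/bin/env python
"""Recompute the published descriptives of the 29-participant aphasia
cohort from the packaged table: age and time-since-stroke summaries, sex
ratio, lesion-vessel proportions and the diagnostic cut-off counts.

Writes results/cohort_table_summary.json.
"""

import json
from pathlib import Path

from audphon import reproduce_cohort_table

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summary = reproduce_cohort_table()
    OUT.mkdir(exist_ok=True)
    (OUT / "cohort_table_summary.json").write_text(json.dumps(summary, indent=2))
    print(
        f"Cohort n={summary['n']}: age {summary['age_mean']:.2f} "
        f"(SD {summary['age_sd']:.2f}), time since stroke "
        f"{summary['time_since_stroke_mean']:.1f} months "
        f"(SD {summary['time_since_stroke_sd']:.1f}, median "
        f"{summary['time_since_stroke_median']:.1f}), "
        f"{summary['percent_female']:.1f}% female."
    )
    print(
        f"{summary['percent_mca_known_vessel']:.1f}% of known-vessel lesions "
        f"involve the MCA; {summary['below_either_cutoff']} participants score "
        f"below at least one language cut-off ({summary['below_nbt_cutoff']} "
        f"below the naming cut-off, {summary['below_screeling_cutoff']} below "
        "the ScreeLing cut-off)."
    )


if __name__ == "__main__":
    main()
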
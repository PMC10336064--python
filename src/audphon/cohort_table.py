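"""Packaged aphasia cohort table and covariate composites.

Ships the 29-row demographics/lesion/language-score table of the
aphasia group as a plain-CSV fixture, with typed loading, descriptive
statistics, the published diagnostic cut-offs (picture-naming NBT < 255,
ScreeLing total < 68, both strict), lesion-vessel proportions, and the
two covariate composites used by the statistical models: the Fletcher
hearing index (mean pure-tone threshold at 1, 2 and 4 kHz, averaged over
ears) and a cognition composite (mean of z-scored attention, executive
and memory subscales).
"""

from __future__ import annotations

from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

NBT_MAX, NBT_CUTOFF = 276, 255
SCREELING_MAX, SCREELING_CUTOFF = 72, 68

VALID_VESSELS = {"VA", "MCA", "PCA", "ACA", "LLA", "PICA"}
_SCHEMA = [
    "participant_id", "age", "sex", "time_since_stroke_months", "stroke_type",
    "vessels", "hemisphere", "slt", "nbt", "screeling_total",
]


class TableSchemaError(ValueError):
    pass


def default_table_path():
    return resources.files("audphon.data") / "aphasia_cohort_table.csv"


def load_cohort_table(path=None) -> pd.DataFrame:
    """Load and validate the cohort table.

    Multi-vessel entries such as "MCA/PCA" are parsed into frozensets in
    the ``vessel_set`` column; missing entries (the table's dashes)
    become NaN / empty sets with a ``vessel_known`` flag.
    """
    path = path if path is not None else default_table_path()
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise TableSchemaError(f"empty cohort table at {path}") from e
    missing = [c for c in _SCHEMA if c not in df.columns]
    if missing:
        raise TableSchemaError(f"cohort table missing columns {missing}")
    for i, row in df.iterrows():
        if row["sex"] not in ("m", "f"):
            raise TableSchemaError(f"row {i}: bad sex {row['sex']!r}")
        if pd.notna(row["stroke_type"]) and row["stroke_type"] not in (
            "ischemia", "hemorrhage"
        ):
            raise TableSchemaError(f"row {i}: bad stroke_type {row['stroke_type']!r}")
        if pd.notna(row["hemisphere"]) and row["hemisphere"] not in (
            "left", "bilateral"
        ):
            raise TableSchemaError(f"row {i}: bad hemisphere {row['hemisphere']!r}")
        if pd.notna(row["nbt"]) and not (0 <= row["nbt"] <= NBT_MAX):
            raise TableSchemaError(f"row {i}: NBT score {row['nbt']} out of range")
        if pd.notna(row["screeling_total"]) and not (
            0 <= row["screeling_total"] <= SCREELING_MAX
        ):
            raise TableSchemaError(
                f"row {i}: ScreeLing score {row['screeling_total']} out of range"
            )

    def parse_vessels(v):
        if pd.isna(v) or v == "":
            return frozenset()
        parts = frozenset(str(v).split("/"))
        bad = parts - VALID_VESSELS
        if bad:
            raise TableSchemaError(f"unknown vessel codes {sorted(bad)}")
        return parts

    df = df.copy()
    df["vessel_set"] = df["vessels"].map(parse_vessels)
    df["vessel_known"] = df["vessel_set"].map(bool)
    return df


def descriptives(
    column: pd.Series,
    statistics: Sequence[str] = ("mean", "sd", "median", "min", "max"),
) -> dict:
    """Descriptive summary of a numeric column; missing values dropped
    (count reported), sample SD with n-1."""
    x = pd.to_numeric(column, errors="raise").dropna()
    if x.empty:
        raise ValueError("column has no non-missing values")
    fns = {
        "mean": lambda v: float(v.mean()),
        "sd": lambda v: float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
        "median": lambda v: float(v.median()),
        "min": lambda v: float(v.min()),
        "max": lambda v: float(v.max()),
    }
    out = {s: fns[s](x) for s in statistics}
    out["n"] = int(len(x))
    out["n_missing"] = int(column.isna().sum())
    return out


def cutoff_counts(
    table: pd.DataFrame,
    nbt_cutoff: float = NBT_CUTOFF,
    screeling_cutoff: float = SCREELING_CUTOFF,
) -> dict:
    """Counts of participants strictly below the diagnostic cut-offs
    (a score equal to the cut-off does not count as below)."""
    below_nbt = table["nbt"] < nbt_cutoff
    below_scr = table["screeling_total"] < screeling_cutoff
    return {
        "below_nbt": int(below_nbt.sum()),
        "below_screeling": int(below_scr.sum()),
        "below_either": int((below_nbt | below_scr).sum()),
    }


def vessel_proportions(table: pd.DataFrame, vessel: str = "MCA") -> float:
    """Proportion of participants whose lesion involves the given vessel,
    among those with known vessel information (multi-vessel rows count
    once)."""
    known = table[table["vessel_known"]]
    if known.empty:
        raise ValueError("no rows with vessel information")
    has = known["vessel_set"].map(lambda s: vessel in s)
    return float(has.sum() / len(known))


FLETCHER_FREQS_KHZ = (1.0, 2.0, 4.0)


def fletcher_index(audiogram: Mapping[str, Mapping[float, float]]) -> float:
    """Fletcher index: per-ear mean threshold (dB HL) at 1, 2 and 4 kHz,
    then averaged across the two ears.

    ``audiogram`` maps ear ("left"/"right") to {frequency_khz: dB HL}.
    """
    if set(audiogram) != {"left", "right"}:
        raise ValueError("audiogram must have exactly ears 'left' and 'right'")
    ear_means = []
    for ear, thresholds in audiogram.items():
        missing = [f for f in FLETCHER_FREQS_KHZ if f not in thresholds]
        if missing:
            raise ValueError(f"{ear} ear missing thresholds at {missing} kHz")
        ear_means.append(np.mean([thresholds[f] for f in FLETCHER_FREQS_KHZ]))
    return float(np.mean(ear_means))


def cognition_composite(
    subscales: pd.DataFrame,
    reference: Optional[pd.DataFrame] = None,
) -> pd.Series:
    """Cognition composite: mean of the z-scored attention, executive and
    memory subscales, standardized against a reference sample (the input
    sample itself when none is given). Missing subscales are an error —
    no imputation."""
    cols = ["attention", "executive", "memory"]
    missing_cols = [c for c in cols if c not in subscales.columns]
    if missing_cols:
        raise ValueError(f"missing subscales: {missing_cols}")
    if subscales[cols].isna().any().any():
        raise ValueError("missing subscale values; composite requires all three")
    ref = reference if reference is not None else subscales
    z = pd.DataFrame(index=subscales.index)
    for c in cols:
        mu = ref[c].mean()
        sd = ref[c].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"reference SD for {c!r} is zero")
        z[c] = (subscales[c] - mu) / sd
    return z.mean(axis=1)
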
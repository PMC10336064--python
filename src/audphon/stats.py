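"""Group comparisons and covariate-adjusted models.

Implements the inferential toolkit used on the task scores:

* ``compare_groups`` — two-sided unpaired comparison with a normality
  gate: Welch's t-test when a Shapiro-Wilk check passes in both groups,
  otherwise the Wilcoxon rank-sum (Mann-Whitney U) test, exact for small
  untied samples and mid-rank/normal-approximation otherwise.
* ``fit_group_model`` — task score ~ group + hearing + cognition, as an
  ordinary linear model or, with ``smooth_hearing``, a penalised
  B-spline smooth for hearing (generalized additive model). Main effects
  only; per-term marginal (Type-II) F tests.
* ``predict_phonology`` — within-patient-group linear model
  phonology ~ task score + hearing + cognition (RTD thresholds enter on
  the natural-log scale), with a per-predictor ANOVA.
* ``fdr_adjust`` — Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

Method = Literal["auto", "t_welch", "wilcoxon_ranksum"]


class CollinearityError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    method: Literal["t_welch", "wilcoxon_ranksum", "chi_square"]
    statistic: float
    df: Optional[float | tuple]
    p_two_sided: float
    normality_ok: Optional[tuple[bool, bool]] = None


def shapiro_normal(x: Sequence[float], alpha: float = 0.05) -> bool:
    """Shapiro-Wilk normality gate for one sample."""
    x = np.asarray(x, dtype=float)
    if x.size < 3 or np.ptp(x) == 0:
        return False
    return bool(sps.shapiro(x).pvalue > alpha)


def compare_groups(
    x: Sequence[float],
    y: Sequence[float],
    force_method: Method = "auto",
    alpha_normality: float = 0.05,
) -> TestResult:
    """Two-sided unpaired group comparison, normality-gated.

    The rank-sum statistic follows the first-sample convention (U for
    ``x``); for two samples of 2 with no overlap it is 0 with exact
    two-sided p = 1/3.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    norm = (shapiro_normal(x, alpha_normality), shapiro_normal(y, alpha_normality))
    method = force_method
    if method == "auto":
        method = "t_welch" if all(norm) else "wilcoxon_ranksum"
    if method == "t_welch":
        res = sps.ttest_ind(x, y, equal_var=False)
        return TestResult("t_welch", float(res.statistic), float(res.df),
                          float(res.pvalue), norm)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult("wilcoxon_ranksum", float(res.statistic), None,
                      float(res.pvalue), norm)


def chi_square(table, correction: bool = True) -> TestResult:
    """Chi-square test of independence on a contingency table (Yates
    continuity correction on 2x2 by default, matching common practice)."""
    chi2, p, dof, _ = sps.chi2_contingency(np.asarray(table), correction=correction)
    return TestResult("chi_square", float(chi2), float(dof), float(p))


@dataclass
class ModelFit:
    formula: str
    model_kind: Literal["linear", "smooth"]
    n_obs: int
    n_dropped: int
    params: pd.Series
    bse: pd.Series
    term_f: dict[str, float]
    term_df: dict[str, float | tuple]
    term_p: dict[str, float]
    adjusted_r2: float
    smooth_edf: Optional[float] = None


def _complete_cases(df: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    sub = df[cols].dropna()
    return sub, len(df) - len(sub)


def _check_rank(design: pd.DataFrame) -> None:
    X = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a culprit: column whose removal restores full rank
        for j, name in enumerate(design.columns):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank:
                raise CollinearityError(
                    f"design matrix rank deficient; column {name!r} is "
                    "collinear with the others"
                )
        raise CollinearityError("design matrix rank deficient")


def fit_group_model(
    df: pd.DataFrame,
    score_col: str,
    group_col: str = "group",
    hearing_col: str = "hearing",
    cognition_col: str = "cognition",
    smooth_hearing: bool = False,
    anova_type: int = 2,
) -> ModelFit:
    """Covariate-adjusted group model (main effects only).

    Listwise deletion on the model columns; per-term F tests are
    marginal (Type-II) by default. With ``smooth_hearing`` the hearing
    covariate enters as a penalised B-spline smooth and its test is a
    joint Wald F over the spline coefficients.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    cols = [score_col, group_col, hearing_col, cognition_col]
    data, n_dropped = _complete_cases(df, cols)
    data = data.copy()
    data["_group"] = (data[group_col] != "control").astype(float)
    design = pd.DataFrame(
        {
            "intercept": 1.0,
            "group": data["_group"],
            hearing_col: data[hearing_col],
            cognition_col: data[cognition_col],
        }
    )
    _check_rank(design)

    if not smooth_hearing:
        formula = f"{score_col} ~ _group + {hearing_col} + {cognition_col}"
        res = smf.ols(formula, data=data).fit()
        an = anova_lm(res, typ=anova_type)
        term_f, term_df, term_p = {}, {}, {}
        rename = {"_group": "group", hearing_col: "hearing",
                  cognition_col: "cognition"}
        for row in an.index:
            if row == "Residual":
                continue
            name = rename.get(row, row)
            term_f[name] = float(an.loc[row, "F"])
            term_df[name] = (float(an.loc[row, "df"]),
                             float(an.loc["Residual", "df"]))
            term_p[name] = float(an.loc[row, "PR(>F)"])
        return ModelFit(
            formula=f"{score_col} ~ group + {hearing_col} + {cognition_col}",
            model_kind="linear",
            n_obs=int(res.nobs), n_dropped=n_dropped,
            params=res.params.rename(index=rename),
            bse=res.bse.rename(index=rename),
            term_f=term_f, term_df=term_df, term_p=term_p,
            adjusted_r2=float(res.rsquared_adj),
        )

    from statsmodels.gam.api import BSplines, GLMGam

    bs = BSplines(data[[hearing_col]], df=[6], degree=[3],
                  variable_names=[hearing_col])
    formula = f"{score_col} ~ _group + {cognition_col}"
    gam = GLMGam.from_formula(formula, data=data, smoother=bs)
    try:
        alpha_opt = gam.select_penweight()[0]
        gam = GLMGam.from_formula(formula, data=data, smoother=bs, alpha=alpha_opt)
    except Exception:
        gam = GLMGam.from_formula(formula, data=data, smoother=bs, alpha=[1.0])
    res = gam.fit()

    smooth_names = [n for n in res.params.index if n.startswith(f"{hearing_col}_s")]
    term_f, term_df, term_p = {}, {}, {}
    rename = {"_group": "group", cognition_col: "cognition"}
    for raw in ("_group", cognition_col):
        name = rename[raw]
        wt = res.wald_test(f"{raw} = 0", use_f=True, scalar=True)
        term_f[name] = float(wt.statistic)
        term_df[name] = (float(wt.df_num), float(wt.df_denom))
        term_p[name] = float(wt.pvalue)
    constraint = ", ".join(f"{n} = 0" for n in smooth_names)
    wt = res.wald_test(constraint, use_f=True, scalar=True)
    edf = None
    try:
        edf = float(np.sum(res.edf[[res.params.index.get_loc(n)
                                    for n in smooth_names]]))
    except Exception:
        pass
    term_f["hearing"] = float(wt.statistic)
    term_df["hearing"] = ((edf if edf is not None else float(wt.df_num)),
                          float(wt.df_denom))
    term_p["hearing"] = float(wt.pvalue)

    fitted = np.asarray(res.fittedvalues, dtype=float)
    y = data[score_col].to_numpy(dtype=float)
    rss = float(np.sum((y - fitted) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    n = len(y)
    p_eff = float(np.sum(res.edf)) if hasattr(res, "edf") else len(res.params)
    adj_r2 = 1.0 - (rss / max(n - p_eff, 1)) / (tss / (n - 1))
    return ModelFit(
        formula=f"{score_col} ~ group + s({hearing_col}) + {cognition_col}",
        model_kind="smooth",
        n_obs=n, n_dropped=n_dropped,
        params=res.params.rename(index=rename),
        bse=res.bse.rename(index=rename),
        term_f=term_f, term_df=term_df, term_p=term_p,
        adjusted_r2=adj_r2, smooth_edf=edf,
    )


def predict_phonology(
    df: pd.DataFrame,
    outcome_col: str,
    task_col: str,
    hearing_col: str = "hearing",
    cognition_col: str = "cognition",
    group_col: Optional[str] = "group",
    patient_group: str = "aphasia",
    anova_type: int = 2,
) -> ModelFit:
    """Within-patient-group prediction of a phonological outcome from an
    acoustic-phonemic task score, adjusting for hearing and cognition.

    The caller supplies the task score on the analysis scale (log ms for
    RTD thresholds).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    if group_col is not None and group_col in df.columns:
        df = df[df[group_col] == patient_group]
    cols = [outcome_col, task_col, hearing_col, cognition_col]
    data, n_dropped = _complete_cases(df, cols)
    design = data[[task_col, hearing_col, cognition_col]].assign(intercept=1.0)
    _check_rank(design)

    formula = f"{outcome_col} ~ {task_col} + {hearing_col} + {cognition_col}"
    res = smf.ols(formula, data=data).fit()
    an = anova_lm(res, typ=anova_type)
    term_f, term_df, term_p = {}, {}, {}
    for row in an.index:
        if row == "Residual":
            continue
        term_f[row] = float(an.loc[row, "F"])
        term_df[row] = (float(an.loc[row, "df"]),
                        float(an.loc["Residual", "df"]))
        term_p[row] = float(an.loc[row, "PR(>F)"])
    return ModelFit(
        formula=formula, model_kind="linear",
        n_obs=int(res.nobs), n_dropped=n_dropped,
        params=res.params, bse=res.bse,
        term_f=term_f, term_df=term_df, term_p=term_p,
        adjusted_r2=float(res.rsquared_adj),
    )


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
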
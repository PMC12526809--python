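"""Cohort stratification, posture-effect testing and eta-squared effect sizes.

Subjects are stratified into 10-year age decades (AGE10) by sex. The
posture effect on each index is tested with a repeated-measures ANOVA with
posture as the single within-subject factor and, optionally, one
between-subject grouping factor (split-plot layout, complete cases only).
Effect sizes are population eta squared, SS_effect / SS_total.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import LYING_POSTURES


def age10(age: float) -> int:
    """Decade bin: floor(age / 10) * 10, capped at 90."""
    if age < 0:
        raise ValueError("age must be non-negative")
    return min(int(age // 10) * 10, 90)


@dataclass
class EffectSize:
    factor: str
    ss_effect: float
    ss_total: float
    eta_sq: float
    p: float


def eta_squared(values, groups, factor: str = "group") -> EffectSize:
    """One-way between-group eta squared with its F-test p-value.

    eta^2 = SS_between / SS_total; when SS_total is zero the effect is
    defined as zero.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if len(y) != len(g):
        raise ValueError("values and groups must have equal length")
    ok = ~np.isnan(y)
    y, g = y[ok], g[ok]
    levels = np.unique(g)
    if len(levels) < 2 or len(y) < 2:
        raise ValueError("need >= 2 groups and >= 2 values")
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    ss_effect = float(sum(np.sum(g == lv) * (y[g == lv].mean() - grand) ** 2 for lv in levels))
    if ss_total == 0:
        return EffectSize(factor, 0.0, 0.0, 0.0, 1.0)
    df_b = len(levels) - 1
    df_w = len(y) - len(levels)
    ss_within = ss_total - ss_effect
    if df_w <= 0 or ss_within <= 0:
        p = float("nan") if df_w <= 0 else 0.0
    else:
        f = (ss_effect / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return EffectSize(factor, ss_effect, ss_total, ss_effect / ss_total, p)


def stratified_table(summaries: list[dict],
                     columns: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Cell mean, SD (n-1) and n per (sex, AGE10, posture) for every index.

    ``summaries`` are the per-subject dicts from ``summarize_subject``
    augmented with 'age' and 'sex'; ineligible subjects are skipped.
    """
    rows = []
    for s in summaries:
        if not s.get("eligible", False):
            continue
        per = s["per_posture"].set_index("posture")
        for posture in LYING_POSTURES:
            row = {"subject_id": s["subject_id"], "sex": s["sex"],
                   "age10": age10(s["age"]), "posture": posture,
                   "posture_pct": s["posture_pct"][posture]}
            for c in per.columns:
                if c != "n_epochs":
                    row[c] = per.loc[posture, c]
            rows.append(row)
    if not rows:
        raise ValueError("no eligible subjects")
    long = pd.DataFrame(rows)
    value_cols = columns or [c for c in long.columns
                             if c not in ("subject_id", "sex", "age10", "posture")]
    out = (long.groupby(["sex", "age10", "posture"])[list(value_cols)]
           .agg(["mean", lambda v: v.std(ddof=1), "count"]))
    out.columns = [f"{c}_{'sd' if fn == '<lambda_0>' else fn}" for c, fn in out.columns]
    return out.reset_index()


def posture_rm_anova(matrix: pd.DataFrame, groups: np.ndarray | None = None) -> dict:
    """Repeated-measures ANOVA: posture within subjects, optional between factor.

    ``matrix`` has one row per subject and one column per posture; rows
    with any missing value are dropped (complete-case). Returns F and p for
    the posture main effect and, when ``groups`` is given, the posture x
    group interaction (split-plot decomposition, error term = posture x
    subject within groups).
    """
    data = matrix.to_numpy(dtype=float)
    keep = ~np.isnan(data).any(axis=1)
    data = data[keep]
    n, k = data.shape
    if n < 2:
        return {"F_posture": np.nan, "p_posture": np.nan,
                "F_interaction": np.nan, "p_interaction": np.nan, "n": n}
    g = (np.asarray(groups)[keep] if groups is not None
         else np.zeros(n, dtype=int))
    levels = np.unique(g)
    G = len(levels)

    grand = data.mean()
    subj_means = data.mean(axis=1)
    post_means = data.mean(axis=0)
    ss_total = float(np.sum((data - grand) ** 2))
    ss_between = k * float(np.sum((subj_means - grand) ** 2))
    ss_group = k * float(sum(np.sum(g == lv) * (subj_means[g == lv].mean() - grand) ** 2
                             for lv in levels))
    ss_subj_within = ss_between - ss_group
    ss_posture = n * float(np.sum((post_means - grand) ** 2))
    ss_inter = 0.0
    for lv in levels:
        sub = data[g == lv]
        cell = sub.mean(axis=0)
        ss_inter += len(sub) * float(np.sum(
            (cell - sub.mean() - post_means + grand) ** 2))
    ss_error = ss_total - ss_group - ss_subj_within - ss_posture - ss_inter

    df_post = k - 1
    df_err = (n - G) * (k - 1)
    out = {"n": int(n), "ss_posture": ss_posture, "ss_error": ss_error}
    if df_err <= 0 or ss_error <= 0:
        f_post = np.inf if ss_posture > 0 else 0.0
        out.update(F_posture=f_post, p_posture=np.nan)
    else:
        f_post = (ss_posture / df_post) / (ss_error / df_err)
        out.update(F_posture=float(f_post),
                   p_posture=float(stats.f.sf(f_post, df_post, df_err)))
    if G > 1:
        df_int = (G - 1) * (k - 1)
        if df_err > 0 and ss_error > 0:
            f_int = (ss_inter / df_int) / (ss_error / df_err)
            out.update(F_interaction=float(f_int),
                       p_interaction=float(stats.f.sf(f_int, df_int, df_err)))
        else:
            out.update(F_interaction=np.nan, p_interaction=np.nan)
    else:
        out.update(F_interaction=np.nan, p_interaction=np.nan)
    return out
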
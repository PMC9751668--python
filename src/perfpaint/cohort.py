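"""Cohort aggregation and between-plan comparison statistics.

Per-subject plan metrics are collected in a long-format table and summarized
as mean ± SD (sample, n-1) per (plan, structure, metric). Between-plan
changes are reported as increment percentages computed on the plan means —
100 x (comparator - reference) / reference — and plans are compared with a
one-way ANOVA followed by least-significant-difference (LSD) pairwise
t tests on the pooled within-group variance. (The ANOVA treats plans as
independent groups even when they are paired by subject, matching common
clinical reporting; the pairing caveat is documented.)
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["increment_percent", "anova_lsd", "summarize", "CohortSummary"]


def increment_percent(reference: float, comparator: float) -> float:
    """Percent change from reference to comparator: 100 (c - r) / r.

    Full precision; round only at report time.
    """
    if reference == 0:
        raise ValueError("increment is undefined for a zero reference value")
    return 100.0 * (comparator - reference) / reference


def anova_lsd(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA with LSD pairwise comparisons.

    Returns F, the overall p, degrees of freedom, and for every group pair
    the LSD t statistic and two-sided p computed from the pooled
    within-group mean square. Degenerate input (all groups constant with
    equal means, hence no variance at all) takes the F = 0, p = 1 branch.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("ANOVA needs at least two groups")
    arrays = {k: np.asarray(v, dtype=np.float64).ravel() for k, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least two values")

    n_total = sum(a.size for a in arrays.values())
    grand = sum(a.sum() for a in arrays.values()) / n_total
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(names) - 1
    df_within = n_total - len(names)

    if ss_within == 0 and ss_between == 0:
        f_stat, p_value = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p_value = float("inf"), 0.0
    else:
        ms_between = ss_between / df_between
        ms_within = ss_within / df_within
        f_stat = ms_between / ms_within
        p_value = float(stats.f.sf(f_stat, df_between, df_within))

    mse = ss_within / df_within if df_within > 0 else float("nan")
    pairwise = {}
    for a_name, b_name in combinations(names, 2):
        a, b = arrays[a_name], arrays[b_name]
        if mse == 0:
            p_pair = 1.0 if a.mean() == b.mean() else 0.0
            t_stat = 0.0 if a.mean() == b.mean() else float("inf")
        else:
            se = np.sqrt(mse * (1.0 / a.size + 1.0 / b.size))
            t_stat = float((a.mean() - b.mean()) / se)
            p_pair = float(2.0 * stats.t.sf(abs(t_stat), df_within))
        pairwise[(a_name, b_name)] = {
            "t": t_stat,
            "p": p_pair,
            "significant": bool(p_pair < 0.05),
        }
    return {
        "F": float(f_stat),
        "p": float(p_value),
        "df": (df_between, df_within),
        "pairwise": pairwise,
    }


@dataclass
class CohortSummary:
    """Cohort-level result tables.

    ``stats`` is a DataFrame indexed by (structure, metric) with per-plan
    mean/SD columns, ANOVA F and p, pairwise LSD p values, and increment
    percentages between plan means. Increments use the first plan of each
    pair as the reference; swapping arguments changes the value (the ratio
    is not antisymmetric), which is why each pair is reported once in a
    fixed order.
    """

    stats: pd.DataFrame
    plan_ids: list[str]

    def rounded(self, decimals: int = 2) -> pd.DataFrame:
        return self.stats.round(decimals)


REQUIRED_COLUMNS = ("subject", "plan", "structure", "metric", "value")


def summarize(
    table: pd.DataFrame,
    per_subject_increments: bool = False,
) -> CohortSummary:
    """Aggregate a long-format metric table into the cohort summary.

    ``table`` needs columns (subject, plan, structure, metric, value) with
    each key combination appearing at most once. Increments are computed on
    plan means by default (matching how published increment percentages are
    derived from summary tables); ``per_subject_increments`` switches to the
    mean of per-subject increments.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"metric table is missing columns {missing}")
    keys = ["subject", "plan", "structure", "metric"]
    if table.duplicated(subset=keys).any():
        raise ValueError("metric table has duplicate (subject, plan, structure, metric) rows")

    plan_ids = sorted(table["plan"].unique())
    rows = []
    for (structure, metric), block in table.groupby(["structure", "metric"], sort=True):
        row: dict = {"structure": structure, "metric": metric}
        groups: dict[str, np.ndarray] = {}
        means: dict[str, float] = {}
        for plan in plan_ids:
            vals = block.loc[block["plan"] == plan, "value"].to_numpy(dtype=np.float64)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                row[f"{plan}_mean"] = np.nan
                row[f"{plan}_sd"] = np.nan
                continue
            groups[plan] = vals
            means[plan] = float(vals.mean())
            row[f"{plan}_mean"] = means[plan]
            row[f"{plan}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else np.nan

        for a, b in combinations(plan_ids, 2):
            key = f"pct_{a}_{b}"
            if a in means and b in means and means[a] != 0:
                if per_subject_increments:
                    merged = pd.merge(
                        block.loc[block["plan"] == a, ["subject", "value"]],
                        block.loc[block["plan"] == b, ["subject", "value"]],
                        on="subject",
                        suffixes=("_a", "_b"),
                    )
                    ref = merged["value_a"].to_numpy()
                    cmp_ = merged["value_b"].to_numpy()
                    ok = ref != 0
                    row[key] = (
                        float(np.mean(100.0 * (cmp_[ok] - ref[ok]) / ref[ok]))
                        if ok.any()
                        else np.nan
                    )
                else:
                    row[key] = increment_percent(means[a], means[b])
            else:
                row[key] = np.nan

        eligible = {k: v for k, v in groups.items() if v.size >= 2}
        if len(eligible) >= 2:
            res = anova_lsd(eligible)
            row["F"] = res["F"]
            row["p"] = res["p"]
            for (a, b), pair in res["pairwise"].items():
                row[f"p_{a}_{b}"] = pair["p"]
        else:
            row["F"] = np.nan
            row["p"] = np.nan
        rows.append(row)

    frame = pd.DataFrame(rows).set_index(["structure", "metric"]).sort_index()
    return CohortSummary(stats=frame, plan_ids=plan_ids)
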
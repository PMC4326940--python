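"""Group-comparison layer over per-cell / per-field metric tables.

Tables are tidy: one row per observation with columns ``group``, ``id``,
``metric``, ``value``.  Two groups are compared by Student's two-sample
t-test (Welch optional); three or more by one-way ANOVA with Tukey's HSD
post hoc.  Summaries report mean ± SEM per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import ParameterError

__all__ = ["TwoSampleResult", "AnovaResult", "make_table", "compare_two",
           "compare_many", "group_summary"]


@dataclass
class TwoSampleResult:
    metric: str
    groups: tuple[str, str]
    t: float
    p: float
    means: dict[str, float]
    sems: dict[str, float]
    ns: dict[str, int]
    equal_var: bool


@dataclass
class AnovaResult:
    metric: str
    f: float
    p: float
    means: dict[str, float]
    sems: dict[str, float]
    tukey: pd.DataFrame  # pairwise comparisons with Tukey-adjusted p-values


def make_table(values_by_group: dict[str, list[float]], metric: str) -> pd.DataFrame:
    """Build a tidy table from {group: values}."""
    rows = [
        {"group": g, "id": f"{g}_{i}", "metric": metric, "value": float(v)}
        for g, vals in values_by_group.items()
        for i, v in enumerate(vals)
    ]
    return pd.DataFrame(rows)


def _metric_groups(table: pd.DataFrame, metric: str) -> dict[str, np.ndarray]:
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ParameterError(f"metric {metric!r} not present in table")
    vals = {g: d["value"].to_numpy(float) for g, d in sub.groupby("group")}
    for g, v in vals.items():
        if not np.isfinite(v).all():
            raise ParameterError(f"non-finite values in group {g!r}")
    return vals


def group_summary(table: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Mean ± SEM and n per group for one metric."""
    vals = _metric_groups(table, metric)
    return pd.DataFrame(
        [
            {
                "group": g,
                "n": len(v),
                "mean": float(np.mean(v)),
                "sem": float(sps.sem(v)) if len(v) > 1 else np.nan,
            }
            for g, v in vals.items()
        ]
    )


def compare_two(
    table: pd.DataFrame, metric: str, equal_var: bool = True
) -> TwoSampleResult:
    """Two-sample t-test on one metric; equal-variance by default with a
    Welch option."""
    vals = _metric_groups(table, metric)
    if len(vals) != 2:
        raise ParameterError(
            f"compare_two needs exactly 2 groups, table has {len(vals)}"
        )
    (g1, v1), (g2, v2) = sorted(vals.items())
    if len(v1) < 2 or len(v2) < 2:
        raise ParameterError("each group needs n ≥ 2")
    t, p = sps.ttest_ind(v1, v2, equal_var=equal_var)
    return TwoSampleResult(
        metric=metric,
        groups=(g1, g2),
        t=float(t),
        p=float(p),
        means={g1: float(v1.mean()), g2: float(v2.mean())},
        sems={g1: float(sps.sem(v1)), g2: float(sps.sem(v2))},
        ns={g1: len(v1), g2: len(v2)},
        equal_var=equal_var,
    )


def compare_many(table: pd.DataFrame, metric: str, alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA with Tukey's HSD pairwise post hoc comparisons."""
    vals = _metric_groups(table, metric)
    if len(vals) < 3:
        raise ParameterError(
            "compare_many needs ≥ 3 groups; use compare_two for two groups"
        )
    for g, v in vals.items():
        if len(v) < 2:
            raise ParameterError(f"group {g!r} needs n ≥ 2")
    f, p = sps.f_oneway(*vals.values())
    flat = np.concatenate(list(vals.values()))
    labels = np.concatenate([[g] * len(v) for g, v in vals.items()])
    tk = pairwise_tukeyhsd(flat, labels, alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=tk.summary().data[0]
    )
    return AnovaResult(
        metric=metric,
        f=float(f),
        p=float(p),
        means={g: float(v.mean()) for g, v in vals.items()},
        sems={g: float(sps.sem(v)) for g, v in vals.items()},
        tukey=tukey,
    )
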
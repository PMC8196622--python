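"""Group comparison utilities: Mann-Whitney U and ANOVA + Tukey.

Results are reported the way culture studies print them: median (Q1; Q3) per
group, with two-sided tests at alpha = 0.05 and no multiple-testing
correction across metrics.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = ["GroupComparison", "compare_groups", "median_iqr",
           "format_median_iqr"]


def median_iqr(sample: Sequence[float]) -> tuple[float, float, float]:
    """Median and second/third quartiles (linear interpolation)."""
    arr = np.asarray(sample, dtype=float)
    return (float(np.median(arr)),
            float(np.percentile(arr, 25)),
            float(np.percentile(arr, 75)))


def format_median_iqr(sample: Sequence[float], digits: int = 2) -> str:
    """Render a sample as ``median (Q1; Q3)``."""
    m, q1, q3 = median_iqr(sample)
    return f"{m:.{digits}f} ({q1:.{digits}f}; {q3:.{digits}f})"


@dataclasses.dataclass
class GroupComparison:
    """Outcome of one metric's group comparison.

    ``p_value`` is the two-sided Mann-Whitney p for two groups or the one-way
    ANOVA p for more; ``pairwise`` holds per-pair p-values (Tukey HSD after
    ANOVA, Mann-Whitney otherwise).  Group samples are stored so every summary
    is recomputable.
    """

    metric: str
    test: str
    statistic: float
    p_value: float
    groups: dict[str, np.ndarray]
    medians: dict[str, tuple[float, float, float]]
    pairwise: pd.DataFrame

    def summary(self) -> str:
        parts = [f"{name}: {format_median_iqr(vals)}"
                 for name, vals in self.groups.items()]
        return (f"{self.metric or 'metric'} [{self.test}] p={self.p_value:.4g} | "
                + "; ".join(parts))


def _pairwise_mannwhitney(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    names = list(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = sstats.mannwhitneyu(groups[a], groups[b],
                                      alternative="two-sided")
            rows.append({"group_a": a, "group_b": b,
                         "statistic": float(res.statistic),
                         "p_value": float(res.pvalue)})
    return pd.DataFrame(rows, columns=["group_a", "group_b", "statistic",
                                       "p_value"])


def compare_groups(samples_by_group: Mapping[str, Sequence[float]],
                   test: str = "auto",
                   metric: str = "") -> GroupComparison:
    """Compare a metric across >= 2 groups of >= 3 samples each.

    ``test``: ``"mannwhitney"``, ``"anova"`` (one-way + Tukey HSD post hoc)
    or ``"auto"`` — Mann-Whitney for two groups, ANOVA for more.
    """
    groups = {name: np.asarray(vals, dtype=float)
              for name, vals in samples_by_group.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in groups.items():
        if vals.size < 3:
            raise ValueError(f"group {name!r} has fewer than 3 samples")
    if test == "auto":
        test = "mannwhitney" if len(groups) == 2 else "anova"
    if test not in ("mannwhitney", "anova"):
        raise ValueError(f"unknown test {test!r}")

    medians = {name: median_iqr(vals) for name, vals in groups.items()}
    if test == "mannwhitney":
        pairwise = _pairwise_mannwhitney(groups)
        if len(groups) == 2:
            statistic = float(pairwise["statistic"].iloc[0])
            p_value = float(pairwise["p_value"].iloc[0])
        else:
            # No omnibus statistic; report the smallest pairwise p.
            statistic = float("nan")
            p_value = float(pairwise["p_value"].min())
        return GroupComparison(metric=metric, test="mannwhitney",
                               statistic=statistic, p_value=p_value,
                               groups=groups, medians=medians,
                               pairwise=pairwise)

    stat, p = sstats.f_oneway(*groups.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    values = np.concatenate(list(groups.values()))
    labels = np.concatenate([[name] * len(vals)
                             for name, vals in groups.items()])
    tukey = pairwise_tukeyhsd(values, labels)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    ).rename(columns={"group1": "group_a", "group2": "group_b",
                      "p-adj": "p_value"})
    return GroupComparison(metric=metric, test="anova+tukey",
                           statistic=float(stat), p_value=float(p),
                           groups=groups, medians=medians, pairwise=pairwise)
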
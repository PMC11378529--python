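"""Group statistics and significance annotation for simulated cohorts.

Reporting plumbing over scipy: D'Agostino-Pearson normality per group,
one-way ANOVA, Tukey's honestly-significant-difference post-hoc test, and
the conventional star annotation of the adjusted p-values:
**** <= 1e-4 < *** <= 1e-3 < ** <= 1e-2 < * <= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "significance_stars", "run_group_stats"]

_STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Star annotation of a p-value ('' above 0.05)."""
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p-value outside [0, 1]: {p}")
    for cut, stars in _STAR_THRESHOLDS:
        if p <= cut:
            return stars
    return ""


@dataclass
class GroupComparison:
    """Normality, ANOVA and Tukey HSD results for named groups."""

    labels: tuple[str, ...]
    values: dict[str, np.ndarray]
    normality_p: dict[str, float]
    anova_p: float
    pairwise: pd.DataFrame
    degenerate: bool = False


def run_group_stats(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Compare >= 2 groups of >= 3 values each.

    Constant (zero-variance) groups are flagged as degenerate and the tests
    are skipped rather than emitting undefined statistics.
    """
    groups = {str(k): np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    if any(g.size < 3 for g in groups.values()):
        raise ValueError("every group needs at least three values")
    labels = tuple(groups)

    degenerate = any(np.ptp(g) == 0.0 for g in groups.values())
    if degenerate:
        empty = pd.DataFrame(columns=["group_1", "group_2", "p", "stars"])
        return GroupComparison(labels, groups, {l: float("nan") for l in labels},
                               float("nan"), empty, degenerate=True)

    normality = {}
    for label, g in groups.items():
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normality[label] = float(sps.normaltest(g).pvalue)
        except ValueError:  # too few samples for the D'Agostino-Pearson test
            normality[label] = float("nan")

    anova_p = float(sps.f_oneway(*groups.values()).pvalue)
    hsd = sps.tukey_hsd(*groups.values())
    rows = []
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if j <= i:
                continue
            p = float(hsd.pvalue[i, j])
            rows.append({"group_1": a, "group_2": b, "p": p, "stars": significance_stars(p)})
    return GroupComparison(labels, groups, normality, anova_p, pd.DataFrame(rows))
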
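"""Group-comparison statistics for assay readouts.

Three designs cover the study's comparison layer: one-way ANOVA with
Dunnett's test against a designated control group (histology counts versus
the no-pathology group), one-way ANOVA with Bonferroni-adjusted pairwise
t tests (kinetic parameters, inclusion percentages, GFAP burden), and
two-way ANOVA with Dunnett comparisons of each condition against a control
condition within every group (the immunodepletion design).  Equal-variance
tests throughout; significance at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.formula.api import ols

__all__ = [
    "ALPHA",
    "GroupComparisonResult",
    "anova_oneway_dunnett",
    "anova_oneway_bonferroni",
    "anova_twoway_dunnett",
]

ALPHA = 0.05

# Dunnett p-values come from randomised multivariate-t integration; a fixed
# integration stream makes results reproducible (accuracy ~1e-4, far below
# any decision threshold used here).
_DUNNETT_RNG_SEED = 865210357


@dataclass(frozen=True)
class GroupComparisonResult:
    """Omnibus ANOVA plus a family-wise-adjusted post-hoc table.

    ``posthoc`` has one row per comparison with columns ``comparison``,
    ``estimate`` (difference of means), ``adjusted_p`` and ``significant``
    (at alpha = 0.05).
    """

    omnibus_F: float
    omnibus_p: float
    posthoc: pd.DataFrame

    def significant_comparisons(self) -> list[str]:
        return self.posthoc.loc[self.posthoc["significant"], "comparison"].tolist()


def _validate_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    out = {}
    for name, values in groups.items():
        arr = np.asarray(values, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")
        out[str(name)] = arr
    return out


def anova_oneway_dunnett(
    groups: Mapping[str, Sequence[float]], control_group: str
) -> GroupComparisonResult:
    """One-way ANOVA with Dunnett's many-to-one comparisons.

    Every non-control group is compared two-sidedly against
    ``control_group`` with family-wise adjustment over the comparisons.
    """
    data = _validate_groups(groups)
    if control_group not in data:
        raise ValueError(f"control group {control_group!r} not among groups")
    f_stat, f_p = stats.f_oneway(*data.values())
    control = data[control_group]
    names = [n for n in data if n != control_group]
    res = stats.dunnett(
        *(data[n] for n in names), control=control, rng=_DUNNETT_RNG_SEED
    )
    rows = [
        {
            "comparison": f"{n} vs {control_group}",
            "estimate": float(data[n].mean() - control.mean()),
            "adjusted_p": float(p),
            "significant": bool(p < ALPHA),
        }
        for n, p in zip(names, res.pvalue)
    ]
    return GroupComparisonResult(float(f_stat), float(f_p), pd.DataFrame(rows))


def anova_oneway_bonferroni(
    groups: Mapping[str, Sequence[float]]
) -> GroupComparisonResult:
    """One-way ANOVA with Bonferroni-adjusted all-pairwise t tests.

    Each pairwise equal-variance t-test p-value is multiplied by the number
    of comparisons and capped at 1.
    """
    data = _validate_groups(groups)
    f_stat, f_p = stats.f_oneway(*data.values())
    pairs = list(combinations(data, 2))
    rows = []
    for a, b in pairs:
        t_res = stats.ttest_ind(data[a], data[b], equal_var=True)
        adj = min(1.0, float(t_res.pvalue) * len(pairs))
        rows.append(
            {
                "comparison": f"{a} vs {b}",
                "estimate": float(data[a].mean() - data[b].mean()),
                "adjusted_p": adj,
                "significant": bool(adj < ALPHA),
            }
        )
    return GroupComparisonResult(float(f_stat), float(f_p), pd.DataFrame(rows))


def anova_twoway_dunnett(
    data: pd.DataFrame, control_condition: str
) -> GroupComparisonResult:
    """Two-way ANOVA with Dunnett comparisons against a control condition.

    ``data`` must be tidy with columns ``value``, ``group`` and
    ``condition`` and a complete factorial layout (every group crossed with
    every condition, each cell with at least two observations).  The
    omnibus row reported is the condition main effect; within each group,
    every non-control condition is compared against ``control_condition``
    with Dunnett adjustment.
    """
    required = {"value", "group", "condition"}
    if not required.issubset(data.columns):
        raise ValueError(f"data must have columns {sorted(required)}")
    groups = sorted(data["group"].unique())
    conditions = sorted(data["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least two conditions to compare")
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} not present")
    cells = data.groupby(["group", "condition"]).size()
    for g in groups:
        for c in conditions:
            if (g, c) not in cells.index or cells[(g, c)] < 2:
                raise ValueError(
                    f"incomplete factorial layout: cell ({g!r}, {c!r}) has "
                    f"fewer than 2 observations"
                )

    model = ols("value ~ C(group) * C(condition)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)
    omnibus_F = float(table.loc["C(condition)", "F"])
    omnibus_p = float(table.loc["C(condition)", "PR(>F)"])

    rows = []
    for g in groups:
        sub = data[data["group"] == g]
        control = sub.loc[sub["condition"] == control_condition, "value"].to_numpy()
        others = [c for c in conditions if c != control_condition]
        arrays = [
            sub.loc[sub["condition"] == c, "value"].to_numpy() for c in others
        ]
        res = stats.dunnett(*arrays, control=control, rng=_DUNNETT_RNG_SEED)
        for c, arr, p in zip(others, arrays, res.pvalue):
            rows.append(
                {
                    "comparison": f"{g}: {c} vs {control_condition}",
                    "estimate": float(arr.mean() - control.mean()),
                    "adjusted_p": float(p),
                    "significant": bool(p < ALPHA),
                }
            )
    return GroupComparisonResult(omnibus_F, omnibus_p, pd.DataFrame(rows))
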
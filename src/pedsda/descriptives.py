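"""Group-comparison and subgroup cross-validation summary tables.

Builds the two summary shapes of the analysis: a stratum comparison
(older vs working-age) with two-sample tests per study variable, and a
per-subgroup profile of a fitted SDA tree with one-way ANOVA /
chi-square tests of independence across the subgroups.  Percentages are
printed with half-up rounding to one decimal, matching published
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .registry import (GENDERS, ROAD_WIDTH_LEVELS, SEASONS, TIME_BINS,
                       RecordSet)
from .rounding import round_half_up
from .sda import SDATree

__all__ = [
    "GroupSummary",
    "compare_groups",
    "subgroup_profile",
    "pooled_proportion",
    "TABLE_VARIABLES",
]

log = logging.getLogger(__name__)

#: (variable, kind, levels) rows of the summary tables, in print order.
TABLE_VARIABLES: tuple[tuple[str, str, tuple[str, ...]], ...] = (
    ("age", "continuous", ()),
    ("gender", "categorical", GENDERS),
    ("severe", "categorical", ("True", "False")),
    ("time_bin", "categorical", TIME_BINS),
    ("season", "categorical", SEASONS),
    ("network_distance_m", "continuous", ()),
    ("national_road", "categorical", ("True", "False")),
    ("road_width_class", "categorical", ROAD_WIDTH_LEVELS),
    ("did", "categorical", ("True", "False")),
    ("aging_rate", "continuous", ()),
    ("low_ses_prop", "continuous", ()),
)


@dataclass
class GroupSummary:
    """A variables-by-groups summary table with per-variable test results.

    ``table`` holds one row per (variable, level) cell; ``tests`` maps a
    variable to ``(kind, statistic, p_value)`` where kind is "t",
    "anova" or "chi2" (statistic/p are None when a test was omitted).
    """

    grouping: str
    group_sizes: dict
    table: pd.DataFrame
    tests: dict

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        groups = list(self.group_sizes)
        width = max(24, *(len(str(g)) + 2 for g in groups))
        head = "variable".ljust(28) + "".join(
            f"{g} (n={self.group_sizes[g]})".ljust(width) for g in groups) + "p"
        lines = [head, "-" * len(head)]
        for _, row in self.table.iterrows():
            label = row["variable"] if not row["level"] else f"  {row['level']}"
            cells = "".join(str(row[str(g)]).ljust(width) for g in groups)
            p = row["p_value"] if row["p_value"] != "" else ""
            lines.append(label.ljust(28) + cells + str(p))
        return "\n".join(lines) + "\n"


def _fmt_p(p: Optional[float]) -> str:
    if p is None:
        return ""
    if p < 0.0001:
        return "<0.0001"
    return f"{p:.4f}"


def _summarize(df: pd.DataFrame, groups: dict[str, pd.DataFrame], grouping: str,
               variables=TABLE_VARIABLES, test_continuous="t") -> GroupSummary:
    rows: list[dict] = []
    tests: dict[str, tuple] = {}
    names = list(groups)
    for var, kind, levels in variables:
        if var not in df.columns or df[var].isna().all():
            continue
        if kind == "continuous":
            samples = [np.asarray(g[var].dropna(), dtype=float) for g in groups.values()]
            stat = p = None
            if all(len(s) >= 2 for s in samples) and len(samples) >= 2:
                if test_continuous == "t" and len(samples) == 2:
                    stat, p = sps.ttest_ind(samples[0], samples[1], equal_var=True)
                elif test_continuous == "welch" and len(samples) == 2:
                    stat, p = sps.ttest_ind(samples[0], samples[1], equal_var=False)
                else:
                    stat, p = sps.f_oneway(*samples)
                stat, p = float(stat), float(p)
                kind_label = "anova" if (test_continuous == "anova" or len(samples) > 2) else "t"
            else:
                kind_label = "t"
                if len(samples) >= 2:
                    log.warning("%s: group below size 2, test omitted", var)
            tests[var] = (kind_label, stat, p)
            cell = {}
            for name, g in groups.items():
                vals = np.asarray(g[var].dropna(), dtype=float)
                if len(vals) == 0:
                    cell[str(name)] = ""
                else:
                    mean = round_half_up(float(np.mean(vals)), 2)
                    sd = round_half_up(float(np.std(vals, ddof=1)), 2) if len(vals) > 1 else 0.0
                    cell[str(name)] = f"{mean} ({sd})"
            rows.append({"variable": var, "level": "", **cell, "p_value": _fmt_p(p)})
        else:
            observed = []
            for g in groups.values():
                s = g[var].astype(str)
                observed.append([int((s == lev).sum()) for lev in levels])
            counts = np.array(observed).T  # levels x groups
            keep = counts.sum(axis=1) > 0
            stat = p = None
            if keep.sum() >= 2 and len(groups) >= 2 and (counts.sum(axis=0) > 0).all():
                stat, p, _, _ = sps.chi2_contingency(counts[keep], correction=False)
                stat, p = float(stat), float(p)
            tests[var] = ("chi2", stat, p)
            first = True
            for li, lev in enumerate(levels):
                cell = {}
                for gi, name in enumerate(names):
                    n_g = len(groups[name])
                    cnt = counts[li, gi]
                    pct = round_half_up(100.0 * cnt / n_g, 1) if n_g else 0.0
                    cell[str(name)] = f"{cnt} ({pct}%)"
                rows.append({"variable": var if first else "", "level": lev, **cell,
                             "p_value": _fmt_p(p) if first else ""})
                first = False
    table = pd.DataFrame(rows)
    return GroupSummary(grouping=grouping,
                        group_sizes={str(k): len(v) for k, v in groups.items()},
                        table=table, tests=tests)


def compare_groups(records, grouping: str = "age_group",
                   variables=TABLE_VARIABLES, test_continuous: str = "t") -> GroupSummary:
    """Two-group (or k-group) comparison table over the study variables.

    Continuous variables get a pooled-variance two-sample t-test
    (``test_continuous="welch"`` switches to Welch, ``"anova"`` forces
    one-way ANOVA); categorical variables get a Pearson chi-square test
    of independence on the full R x C table.
    """
    df = records.to_frame() if isinstance(records, RecordSet) else records
    level_names = [g for g, _ in df.groupby(grouping, sort=True)]
    if len(level_names) < 2:
        raise ValueError(f"grouping {grouping!r} yields fewer than two groups")
    groups = {str(g): sub for g, sub in df.groupby(grouping, sort=True)}
    return _summarize(df, groups, grouping, variables, test_continuous)


def subgroup_profile(records, tree: SDATree, variables=TABLE_VARIABLES) -> GroupSummary:
    """Tables-2/3-style profile: variables by leaf subgroups of a tree.

    Continuous variables are compared across subgroups with one-way
    ANOVA, categorical variables with a chi-square test on the k-group
    table; the severity row doubles as the per-subgroup severe
    proportion.  With a single leaf the ANOVA is omitted.
    """
    df = records.to_frame() if isinstance(records, RecordSet) else records
    leaf_ids = tree.assign_frame(df)
    order = [leaf.node_id for leaf in tree.leaves()]
    groups = {lid: df[leaf_ids == lid] for lid in order if (leaf_ids == lid).any()}
    if len(groups) == 1:
        only = next(iter(groups))
        summary = _summarize(df, groups, grouping=f"subgroup[{only}]",
                             variables=variables, test_continuous="anova")
        summary.tests = {k: (kind, None, None) for k, (kind, *_rest) in summary.tests.items()}
        summary.table["p_value"] = ""
        return summary
    return _summarize(df, groups, grouping="subgroup", variables=variables,
                      test_continuous="anova")


def pooled_proportion(subgroups: Sequence[tuple[int, float]]) -> float:
    """Pool subgroup percentages back into one percentage.

    Each subgroup is ``(n, prop)`` with prop in percent; event counts are
    reconstructed as round(n * prop / 100) (half-up) and pooled, and the
    result is returned in percent to one decimal.
    """
    total_n = 0
    total_events = 0
    for n, prop in subgroups:
        if n < 1:
            raise ValueError(f"subgroup size must be >= 1, got {n}")
        if not 0.0 <= prop <= 100.0:
            raise ValueError(f"proportion must lie in [0, 100], got {prop}")
        total_n += n
        total_events += int(round_half_up(n * prop / 100.0, 0))
    return round_half_up(100.0 * total_events / total_n, 1)
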
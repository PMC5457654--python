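"""Signal detection analysis: weighted-kappa recursive partitioning.

Signal detection analysis (SDA) grows a binary tree over a set of
predictor variables to explain a binary outcome (here: severe vs minor
pedestrian injury).  At each node every admissible binary split of every
variable is scored by the weighted kappa coefficient of its 2x2
cross-classification with the outcome, and the maximum-kappa split is
adopted if it passes a Pearson chi-square gate and its kappa confidence
interval excludes zero.  Recursion continues into both children with the
full variable list until one of three stopping rules fires:

1. a prospective child subgroup would hold fewer than ``min_subgroup``
   (default 10) subjects,
2. the selected split is not significant at ``alpha`` (default 0.05), or
3. the lower limit of the ``ci_level`` (default 95%) confidence interval
   of the maximum weighted kappa is below zero.

Weighted kappa family for a 2x2 table with cells a (split+, outcome+),
b (split+, outcome-), c (split-, outcome+), d (split-, outcome-),
prevalence P = (a+c)/n and level Q = (a+b)/n::

    kappa(r) = (ad - bc) / n^2  /  [ r P (1-Q) + (1-r) (1-P) Q ]

``r`` in [0,1] weights false negatives against false positives:
kappa(0.5) is Cohen's kappa, kappa(1) the quality index of sensitivity
(SE - Q)/(1 - Q), kappa(0) the quality index of specificity
(SP - (1-Q))/Q.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .registry import (ROAD_WIDTH_LEVELS, SEASONS, TIME_BINS, GENDERS,
                       InjuryRecord, RecordSet)
from .rounding import round_half_up

__all__ = [
    "SDAError",
    "RoutingError",
    "ContingencyTable2x2",
    "weighted_kappa",
    "kappa_confidence_interval",
    "chi_square_test",
    "VariableSpec",
    "STUDY_VARIABLES",
    "SplitRule",
    "SplitCandidate",
    "SDAConfig",
    "SDANode",
    "SDATree",
    "enumerate_cutpoints",
    "best_split",
    "grow_tree",
    "assign_subgroup",
    "render_tree",
    "TreeRendering",
]


class SDAError(ValueError):
    """Invalid input to an SDA operation."""


class RoutingError(SDAError):
    """A record cannot be routed through a tree (missing variable value)."""


# ---------------------------------------------------------------------------
# 2x2 table statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Joint counts of a binary split indicator against the binary outcome.

    a: split-positive & outcome-positive (severe), b: split-positive &
    minor, c: split-negative & severe, d: split-negative & minor.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise SDAError(f"cell {name} must be a nonnegative integer, got {v}")
        if self.n < 1:
            raise SDAError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def prevalence(self) -> float:
        """P: proportion outcome-positive."""
        return (self.a + self.c) / self.n

    @property
    def level(self) -> float:
        """Q: proportion split-positive."""
        return (self.a + self.b) / self.n

    @property
    def sensitivity(self) -> float:
        return self.a / (self.a + self.c) if (self.a + self.c) else math.nan

    @property
    def specificity(self) -> float:
        return self.d / (self.b + self.d) if (self.b + self.d) else math.nan

    @classmethod
    def from_indicators(cls, split_pos, outcome_pos) -> "ContingencyTable2x2":
        split_pos = np.asarray(split_pos, dtype=bool)
        outcome_pos = np.asarray(outcome_pos, dtype=bool)
        return cls(
            a=int(np.sum(split_pos & outcome_pos)),
            b=int(np.sum(split_pos & ~outcome_pos)),
            c=int(np.sum(~split_pos & outcome_pos)),
            d=int(np.sum(~split_pos & ~outcome_pos)),
        )


def _kappa_arrays(a, b, c, d, r: float):
    """Vectorized weighted kappa over parallel count arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    p = (a + c) / n
    q = (a + b) / n
    num = (a * d - b * c) / (n * n)
    den = r * p * (1.0 - q) + (1.0 - r) * (1.0 - p) * q
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return kappa


def weighted_kappa(table: ContingencyTable2x2, r: float = 0.5) -> float:
    """Weighted kappa kappa(r) of a 2x2 table; 0 for degenerate margins."""
    if not 0.0 <= r <= 1.0:
        raise SDAError(f"r must lie in [0, 1], got {r}")
    return float(_kappa_arrays(table.a, table.b, table.c, table.d, r))


def _chi2_arrays(a, b, c, d):
    """Vectorized Pearson chi-square (1 df, no continuity correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    d = np.asarray(d, dtype=float)
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(margins > 0,
                        n * (a * d - b * c) ** 2 / np.where(margins > 0, margins, 1.0),
                        0.0)
    return stat


def chi_square_test(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square (1 df, no Yates correction); (0, 1) on a zero margin."""
    stat = float(_chi2_arrays(table.a, table.b, table.c, table.d))
    if stat == 0.0:
        return 0.0, 1.0
    return stat, float(sps.chi2.sf(stat, df=1))


def _fleiss_cohen_everitt_var(table: ContingencyTable2x2) -> float:
    """Large-sample variance of Cohen's kappa (Fleiss-Cohen-Everitt form).

    Treats the 2x2 table as an agreement table between the split
    indicator and the outcome.
    """
    n = table.n
    p = np.array([[table.a, table.b], [table.c, table.d]], dtype=float) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = p[0, 0] + p[1, 1]
    pe = float(row @ col)
    if pe >= 1.0:
        return 0.0
    kappa = (po - pe) / (1.0 - pe)
    term_a = sum(p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
                 for i in range(2))
    term_b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2) for j in range(2) if i != j)
    term_c = (kappa - pe * (1.0 - kappa)) ** 2
    return max(term_a + term_b - term_c, 0.0) / (n * (1.0 - pe) ** 2)


def kappa_confidence_interval(table: ContingencyTable2x2, r: float = 0.5,
                              level: float = 0.95, *, method: str = "auto",
                              n_boot: int = 1000, seed: int = 0) -> tuple[float, float]:
    """Confidence interval for kappa(r), clipped to [-1, 1].

    ``method="auto"`` uses the Fleiss-Cohen-Everitt asymptotic normal
    interval at r = 0.5 (where kappa is Cohen's kappa) and a seeded
    nonparametric bootstrap of the n subjects (multinomial resampling of
    the four cells, percentile interval) for any other r.
    """
    if table.n < 2:
        raise SDAError("confidence interval needs n >= 2")
    if not 0.0 < level < 1.0:
        raise SDAError(f"level must lie in (0, 1), got {level}")
    if method == "auto":
        method = "asymptotic" if r == 0.5 else "bootstrap"
    if method == "asymptotic":
        if r != 0.5:
            raise SDAError("asymptotic interval is only available at r = 0.5")
        k = weighted_kappa(table, 0.5)
        se = math.sqrt(_fleiss_cohen_everitt_var(table))
        z = sps.norm.ppf(0.5 + level / 2.0)
        lo, hi = k - z * se, k + z * se
    elif method == "bootstrap":
        if n_boot < 100:
            raise SDAError("bootstrap needs at least 100 resamples")
        rng = np.random.default_rng(seed)
        probs = np.array([table.a, table.b, table.c, table.d], dtype=float) / table.n
        draws = rng.multinomial(table.n, probs, size=n_boot)
        kappas = _kappa_arrays(draws[:, 0], draws[:, 1], draws[:, 2], draws[:, 3], r)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(kappas, [alpha, 1.0 - alpha])
    else:
        raise SDAError(f"unknown CI method {method!r}")
    return (float(max(lo, -1.0)), float(min(hi, 1.0)))


# ---------------------------------------------------------------------------
# Variables, rules, configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariableSpec:
    """A predictor variable and how to enumerate its binary splits."""

    name: str
    kind: str  # "continuous" | "ordinal" | "binary" | "nominal"
    levels: tuple[str, ...] = ()

    def __post_init__(self):
        if self.kind not in ("continuous", "ordinal", "binary", "nominal"):
            raise SDAError(f"unknown variable kind {self.kind!r}")
        if self.kind != "continuous" and len(self.levels) < 2:
            raise SDAError(f"{self.kind} variable {self.name!r} needs ordered levels")


#: The ten study predictors of the severity analysis.
STUDY_VARIABLES: tuple[VariableSpec, ...] = (
    VariableSpec("age", "continuous"),
    VariableSpec("gender", "binary", GENDERS),
    VariableSpec("time_bin", "ordinal", TIME_BINS),
    VariableSpec("season", "nominal", SEASONS),
    VariableSpec("network_distance_m", "continuous"),
    VariableSpec("national_road", "binary", ("False", "True")),
    VariableSpec("road_width_class", "ordinal", ROAD_WIDTH_LEVELS),
    VariableSpec("did", "binary", ("False", "True")),
    VariableSpec("aging_rate", "continuous"),
    VariableSpec("low_ses_prop", "continuous"),
)

_VARS_BY_NAME = {v.name: v for v in STUDY_VARIABLES}


@dataclass(frozen=True)
class SplitRule:
    """A binary condition on one variable; True is the split-positive side.

    Numeric ops: ``le``/``lt``/``ge``/``gt`` against a threshold.
    Categorical op: ``in`` against a tuple of level tokens (booleans are
    matched by their ``str()`` form).
    """

    variable: str
    op: str
    value: object  # float for numeric ops, tuple[str, ...] for "in"

    def __post_init__(self):
        if self.op not in ("le", "lt", "ge", "gt", "in"):
            raise SDAError(f"unknown rule op {self.op!r}")
        if self.op == "in":
            object.__setattr__(self, "value", tuple(str(v) for v in self.value))
        else:
            object.__setattr__(self, "value", float(self.value))

    def evaluate(self, data) -> np.ndarray:
        """Vectorized evaluation against a DataFrame (or Series-like mapping)."""
        col = data[self.variable]
        if self.op == "in":
            return np.asarray(col.astype(str).isin(self.value))
        arr = np.asarray(col, dtype=float)
        if self.op == "le":
            return arr <= self.value
        if self.op == "lt":
            return arr < self.value
        if self.op == "ge":
            return arr >= self.value
        return arr > self.value

    def matches(self, values: dict) -> bool:
        """Scalar evaluation for a single record's value mapping."""
        if self.variable not in values or values[self.variable] is None:
            raise RoutingError(f"missing value for variable {self.variable!r}")
        v = values[self.variable]
        if self.op == "in":
            return str(v) in self.value
        v = float(v)
        if math.isnan(v):
            raise RoutingError(f"missing value for variable {self.variable!r}")
        return {"le": v <= self.value, "lt": v < self.value,
                "ge": v >= self.value, "gt": v > self.value}[self.op]

    def describe(self) -> str:
        if self.op == "in":
            inner = ",".join(self.value)
            return f"{self.variable} in {{{inner}}}"
        sym = {"le": "<=", "lt": "<", "ge": ">=", "gt": ">"}[self.op]
        return f"{self.variable} {sym} {self.value:g}"


@dataclass(frozen=True)
class SplitCandidate:
    """A scored candidate split; statistics are None on planted rule trees."""

    rule: SplitRule
    kappa: Optional[float] = None
    kappa_ci: Optional[tuple[float, float]] = None
    chi2: Optional[float] = None
    p_value: Optional[float] = None


@dataclass(frozen=True)
class SDAConfig:
    """Tuning constants of the SDA search."""

    r: float = 0.5
    alpha: float = 0.05
    ci_level: float = 0.95
    min_subgroup: int = 10
    max_depth: Optional[int] = None
    cutpoint_rule: str = "midpoints_of_unique_values"
    nominal_policy: str = "one_vs_rest"
    n_boot: int = 1000
    bootstrap_seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise SDAError(f"r must lie in [0, 1], got {self.r}")
        if not 0.0 < self.alpha < 1.0:
            raise SDAError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0.0 < self.ci_level < 1.0:
            raise SDAError(f"ci_level must lie in (0, 1), got {self.ci_level}")
        if self.min_subgroup < 1:
            raise SDAError(f"min_subgroup must be >= 1, got {self.min_subgroup}")
        if self.cutpoint_rule != "midpoints_of_unique_values":
            raise SDAError(f"unknown cutpoint rule {self.cutpoint_rule!r}")
        if self.nominal_policy != "one_vs_rest":
            raise SDAError(f"unknown nominal policy {self.nominal_policy!r}")


# ---------------------------------------------------------------------------
# Tree structure
# ---------------------------------------------------------------------------

@dataclass
class SDANode:
    """A node of a fitted (or planted) SDA tree."""

    node_id: str
    n: int
    n_severe: int
    depth: int
    split: Optional[SplitCandidate] = None
    pos: Optional["SDANode"] = None  # split rule True
    neg: Optional["SDANode"] = None  # split rule False
    leaf_severe_p: Optional[float] = None  # planted trees only

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def severe_proportion(self) -> float:
        return self.n_severe / self.n if self.n else math.nan


@dataclass
class SDATree:
    """A fitted recursive-partitioning tree over the study variables."""

    root: SDANode
    outcome: str = "severe"
    variables: tuple[str, ...] = ()

    def nodes(self) -> Iterator[SDANode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.extend([node.neg, node.pos])

    def leaves(self) -> list[SDANode]:
        return [nd for nd in self.nodes() if nd.is_leaf]

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.nodes())

    @property
    def n_splits(self) -> int:
        return sum(1 for nd in self.nodes() if not nd.is_leaf)

    # ---- routing ------------------------------------------------------------

    def assign(self, values: dict) -> str:
        """Leaf node_id for one record's value mapping."""
        node = self.root
        while not node.is_leaf:
            node = node.pos if node.split.rule.matches(values) else node.neg
        return node.node_id

    def assign_frame(self, df: pd.DataFrame) -> pd.Series:
        """Vectorized leaf assignment for every row of an analysis frame."""
        out = pd.Series("", index=df.index, dtype=object)

        def walk(node: SDANode, mask: np.ndarray):
            if node.is_leaf:
                out.iloc[np.flatnonzero(mask)] = node.node_id
                return
            sub = df.iloc[np.flatnonzero(mask)]
            col = sub[node.split.rule.variable]
            if col.isna().any():
                bad = sub.index[col.isna()][0]
                raise RoutingError(
                    f"record {bad!r}: missing value for variable "
                    f"{node.split.rule.variable!r}")
            hit = node.split.rule.evaluate(sub)
            full_pos = mask.copy()
            full_pos[np.flatnonzero(mask)] = hit
            walk(node.pos, full_pos)
            walk(node.neg, mask & ~full_pos)

        walk(self.root, np.ones(len(df), dtype=bool))
        return out

    def leaf_probability(self, values: dict) -> float:
        """Planted-tree severe probability for one record."""
        node = self.root
        while not node.is_leaf:
            node = node.pos if node.split.rule.matches(values) else node.neg
        if node.leaf_severe_p is None:
            raise SDAError(f"leaf {node.node_id} carries no planted probability")
        return node.leaf_severe_p

    # ---- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        def node_dict(node: SDANode) -> dict:
            d = {
                "node_id": node.node_id,
                "n": node.n,
                "n_severe": node.n_severe,
                "severe_proportion": node.severe_proportion if node.n else None,
                "depth": node.depth,
            }
            if node.leaf_severe_p is not None:
                d["leaf_severe_p"] = node.leaf_severe_p
            if node.is_leaf:
                d["leaf"] = True
            else:
                sc = node.split
                d["split"] = {
                    "variable": sc.rule.variable,
                    "op": sc.rule.op,
                    "value": list(sc.rule.value) if sc.rule.op == "in" else sc.rule.value,
                    "kappa": sc.kappa,
                    "kappa_ci": list(sc.kappa_ci) if sc.kappa_ci else None,
                    "chi2": sc.chi2,
                    "p_value": sc.p_value,
                }
                d["pos"] = node_dict(node.pos)
                d["neg"] = node_dict(node.neg)
            return d

        return {"outcome": self.outcome, "variables": list(self.variables),
                "tree": node_dict(self.root)}

    @classmethod
    def from_dict(cls, doc: dict) -> "SDATree":
        def build(d: dict) -> SDANode:
            node = SDANode(node_id=d["node_id"], n=d["n"], n_severe=d["n_severe"],
                           depth=d["depth"], leaf_severe_p=d.get("leaf_severe_p"))
            if not d.get("leaf"):
                s = d["split"]
                rule = SplitRule(s["variable"], s["op"],
                                 tuple(s["value"]) if s["op"] == "in" else s["value"])
                ci = tuple(s["kappa_ci"]) if s.get("kappa_ci") else None
                node.split = SplitCandidate(rule=rule, kappa=s.get("kappa"),
                                            kappa_ci=ci, chi2=s.get("chi2"),
                                            p_value=s.get("p_value"))
                node.pos = build(d["pos"])
                node.neg = build(d["neg"])
            return node

        return cls(root=build(doc["tree"]), outcome=doc.get("outcome", "severe"),
                   variables=tuple(doc.get("variables", ())))

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "SDATree":
        return cls.from_dict(json.loads(text))

    def to_text(self) -> str:
        """Indented rendering: rule, subgroup size, % severe per node."""
        lines: list[str] = []

        def fmt(node: SDANode, label: str, indent: int):
            pct = round_half_up(100.0 * node.severe_proportion, 1) if node.n else 0.0
            tag = "leaf" if node.is_leaf else "split"
            stats = ""
            if not node.is_leaf and node.split.kappa is not None:
                stats = (f"  kappa={node.split.kappa:.3f}"
                         f"  p={node.split.p_value:.4g}")
            lines.append(f"{'  ' * indent}{label}: n={node.n}, "
                         f"severe={node.n_severe} ({pct}%) [{tag}]{stats}")
            if not node.is_leaf:
                fmt(node.pos, f"[+] {node.split.rule.describe()}", indent + 1)
                fmt(node.neg, f"[-] not({node.split.rule.describe()})", indent + 1)

        fmt(self.root, "root", 0)
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cut enumeration and split search
# ---------------------------------------------------------------------------

def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, RecordSet):
        return records.to_frame()
    return records


def _resolve_variable(variable) -> VariableSpec:
    if isinstance(variable, VariableSpec):
        return variable
    if variable in _VARS_BY_NAME:
        return _VARS_BY_NAME[variable]
    raise SDAError(f"unknown variable {variable!r}")


def enumerate_cutpoints(records, variable, config: SDAConfig = SDAConfig()) -> list[SplitRule]:
    """Canonical (positive = lower/one-level side) candidate rules.

    Continuous: midpoints between consecutive sorted distinct values.
    Ordinal: the k-1 class boundaries.  Binary: the single split.
    Nominal: one one-vs-rest rule per level.  A constant continuous
    variable yields an empty list.
    """
    spec = _resolve_variable(variable)
    df = _as_frame(records)
    if spec.name not in df.columns:
        raise SDAError(f"variable {spec.name!r} not present in the data")
    if spec.kind == "continuous":
        values = np.unique(np.asarray(df[spec.name], dtype=float))
        cuts = (values[:-1] + values[1:]) / 2.0
        return [SplitRule(spec.name, "le", c) for c in cuts]
    if spec.kind == "ordinal":
        return [SplitRule(spec.name, "in", spec.levels[:i + 1])
                for i in range(len(spec.levels) - 1)]
    if spec.kind == "binary":
        return [SplitRule(spec.name, "in", (spec.levels[0],))]
    return [SplitRule(spec.name, "in", (lev,)) for lev in spec.levels]


def _complement(rule: SplitRule, spec: VariableSpec) -> SplitRule:
    if rule.op == "le":
        return SplitRule(rule.variable, "gt", rule.value)
    if rule.op == "gt":
        return SplitRule(rule.variable, "le", rule.value)
    rest = tuple(lev for lev in spec.levels if lev not in rule.value)
    return SplitRule(rule.variable, "in", rest)


def _candidate_tables(df: pd.DataFrame, y: np.ndarray, spec: VariableSpec,
                      config: SDAConfig):
    """Yield (rule, cut_order, a, b, c, d) for every canonical candidate.

    ``a..d`` are arrays aligned with the rules (vectorized over cuts for
    numeric variables).
    """
    n = len(df)
    total_severe = int(y.sum())
    col = df[spec.name]
    if spec.kind in ("continuous", "ordinal"):
        if spec.kind == "continuous":
            v = np.asarray(col, dtype=float)
        else:
            code = {lev: i for i, lev in enumerate(spec.levels)}
            v = col.astype(str).map(code).to_numpy(dtype=float)
        order = np.argsort(v, kind="stable")
        v_sorted = v[order]
        y_sorted = y[order]
        cum = np.cumsum(y_sorted)
        if spec.kind == "continuous":
            boundary = np.flatnonzero(np.diff(v_sorted) != 0)
            cuts = (v_sorted[boundary] + v_sorted[boundary + 1]) / 2.0
            rules = [SplitRule(spec.name, "le", c) for c in cuts]
            cut_order = cuts
        else:
            k = len(spec.levels)
            # boundary after code i: count of values <= i
            counts_le = np.searchsorted(v_sorted, np.arange(k - 1) + 0.5)
            boundary = counts_le - 1  # index into cum; -1 means empty side
            rules = [SplitRule(spec.name, "in", spec.levels[:i + 1])
                     for i in range(k - 1)]
            cut_order = np.arange(k - 1, dtype=float)
        n_pos = boundary + 1
        a = np.where(n_pos > 0, cum[np.clip(boundary, 0, None)], 0)
        a = np.where(n_pos > 0, a, 0)
        b = n_pos - a
        c = total_severe - a
        d = n - n_pos - c
        return rules, cut_order, a, b, c, d
    # binary / nominal
    rules = enumerate_cutpoints(df, spec, config)
    a_list, b_list, c_list, d_list = [], [], [], []
    s = col.astype(str)
    for rule in rules:
        pos = s.isin(rule.value).to_numpy()
        a_ = int(np.sum(pos & y))
        b_ = int(np.sum(pos & ~y))
        a_list.append(a_)
        b_list.append(b_)
        c_list.append(total_severe - a_)
        d_list.append(n - a_ - b_ - (total_severe - a_))
    return (rules, np.arange(len(rules), dtype=float),
            np.array(a_list), np.array(b_list), np.array(c_list), np.array(d_list))


def best_split(records, variables: Sequence = STUDY_VARIABLES,
               config: SDAConfig = SDAConfig(), outcome: str = "severe",
               ) -> Optional[SplitCandidate]:
    """Maximum weighted-kappa admissible split, gated by the stopping rules.

    Every candidate split of every variable is scored in both
    orientations; candidates producing a child smaller than
    ``min_subgroup`` are inadmissible.  The maximum-kappa candidate (ties
    broken by smaller p, then variable order, then smaller cut, then
    canonical orientation) is returned only if its chi-square p-value is
    below ``alpha`` and the lower limit of its kappa confidence interval
    is above zero; otherwise None.
    """
    df = _as_frame(records)
    if len(df) == 0:
        raise SDAError("best_split needs a nonempty record set")
    y = np.asarray(df[outcome], dtype=bool)
    if y.all() or not y.any():
        return None

    specs = [_resolve_variable(v) for v in variables]
    best_key = None
    best_data = None
    for var_idx, spec in enumerate(specs):
        if spec.name not in df.columns:
            raise SDAError(f"variable {spec.name!r} not present in the data")
        if df[spec.name].isna().any():
            continue  # variable ineligible at this node (no surrogate splits)
        rules, cut_order, a, b, c, d = _candidate_tables(df, y, spec, config)
        if len(rules) == 0:
            continue
        n_pos = a + b
        n_neg = c + d
        admissible = (n_pos >= config.min_subgroup) & (n_neg >= config.min_subgroup)
        if not admissible.any():
            continue
        chi2 = _chi2_arrays(a, b, c, d)
        pvals = np.where(chi2 > 0, sps.chi2.sf(chi2, df=1), 1.0)
        for orient, (aa, bb, cc, dd) in enumerate(((a, b, c, d), (c, d, a, b))):
            kappas = _kappa_arrays(aa, bb, cc, dd, config.r)
            masked = np.where(admissible, kappas, -np.inf)
            top = masked.max()
            if top == -np.inf:
                continue
            ties = np.flatnonzero(masked == top)
            ties = ties[np.lexsort((cut_order[ties], pvals[ties]))]
            i = int(ties[0])
            key = (-kappas[i], pvals[i], var_idx, cut_order[i], orient)
            if best_key is None or key < best_key:
                best_key = key
                best_data = (rules[i], orient, spec,
                             int(aa[i]), int(bb[i]), int(cc[i]), int(dd[i]),
                             float(kappas[i]), float(chi2[i]), float(pvals[i]))
    if best_data is None:
        return None

    rule, orient, spec, a_, b_, c_, d_, kappa, chi2_, p_ = best_data
    if orient == 1:
        rule = _complement(rule, spec)
    table = ContingencyTable2x2(a_, b_, c_, d_)
    ci = kappa_confidence_interval(table, config.r, config.ci_level,
                                   n_boot=config.n_boot, seed=config.bootstrap_seed)
    if not (p_ < config.alpha and ci[0] > 0):
        return None
    return SplitCandidate(rule=rule, kappa=kappa, kappa_ci=ci, chi2=chi2_, p_value=p_)


def grow_tree(records, variables: Sequence = STUDY_VARIABLES,
              config: SDAConfig = SDAConfig(), outcome: str = "severe") -> SDATree:
    """Recursively partition the records; both children keep all variables.

    A node becomes a leaf when it is too small to admit two children of
    ``min_subgroup``, when ``max_depth`` is reached, or when
    :func:`best_split` returns None (stopping rules).  Deterministic
    given the records, variable order and config.
    """
    df = _as_frame(records)
    if len(df) == 0:
        raise SDAError("grow_tree needs a nonempty record set")
    y = np.asarray(df[outcome], dtype=bool)
    specs = [_resolve_variable(v) for v in variables]

    def build(sub: pd.DataFrame, ysub: np.ndarray, depth: int, node_id: str) -> SDANode:
        node = SDANode(node_id=node_id, n=len(sub), n_severe=int(ysub.sum()), depth=depth)
        if len(sub) < 2 * config.min_subgroup:
            return node
        if config.max_depth is not None and depth >= config.max_depth:
            return node
        cand = best_split(sub, specs, config, outcome=outcome)
        if cand is None:
            return node
        mask = cand.rule.evaluate(sub)
        node.split = cand
        node.pos = build(sub[mask], ysub[mask], depth + 1, node_id + "P")
        node.neg = build(sub[~mask], ysub[~mask], depth + 1, node_id + "N")
        return node

    root = build(df, y, 0, "n0")
    return SDATree(root=root, outcome=outcome, variables=tuple(s.name for s in specs))


def _record_values(record) -> dict:
    if isinstance(record, InjuryRecord):
        return {
            "age": record.age, "gender": record.gender,
            "time_bin": record.time_bin, "season": record.season,
            "network_distance_m": record.network_distance_m,
            "national_road": record.national_road,
            "road_width_class": record.road_width_class, "did": record.did,
            "aging_rate": record.aging_rate, "low_ses_prop": record.low_ses_prop,
        }
    return dict(record)


def assign_subgroup(tree: SDATree, record) -> str:
    """Leaf node_id that the record routes to."""
    return tree.assign(_record_values(record))


@dataclass(frozen=True)
class TreeRendering:
    """JSON document plus indented text rendering of a tree."""

    json: str
    text: str


def render_tree(tree: SDATree) -> TreeRendering:
    return TreeRendering(json=tree.to_json(), text=tree.to_text())
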
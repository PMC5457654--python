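"""Synthetic road networks and injury registries with planted structure.

The generator emulates the statistical shape of a suburban Japanese EMS
injury registry: two age strata (older >= 65, working-age 18-64) whose
covariate marginals match the published stratum summaries, a jittered
grid road network, residence-to-injury network distances drawn from a
moment-matched lognormal (the published distance SDs exceed their means,
ruling out symmetric models), and a *planted* subgroup tree that assigns
each record's severe-injury probability from the leaf it falls in.  The
default planted trees mirror the published subgroup structure:

* older: SES < 35.21 -> 56.3% severe; else narrow road (< 5.5 m/lane)
  -> 17.6%; else aging rate > 20.3 -> 45.5%, otherwise 27.0%.
* working-age: network distance >= 132.84 m and aging rate >= 21.05
  -> 19.7%; distance >= 132.84 and lower aging -> 8.2%; shorter
  distance -> 0.0%.

Covariates are mutually independent by default (the published material
reports no correlations); everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime

import numpy as np

from . import reference
from .geo import RoadNetwork
from .registry import (ROAD_WIDTH_LEVELS, SEASONS, TIME_BINS, InjuryRecord,
                       RecordSet)
from .sda import SDANode, SDATree, SplitCandidate, SplitRule

__all__ = [
    "GridSpec",
    "StratumSpec",
    "GeneratorConfig",
    "default_config",
    "older_planted_tree",
    "working_planted_tree",
    "single_split_tree",
    "flat_tree",
    "generate_road_network",
    "generate_registry",
    "planted_truth",
]

_SEASON_MONTHS = {"spring": (3, 4, 5), "summer": (6, 7, 8),
                  "fall": (9, 10, 11), "winter": (12, 1, 2)}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Rectangular road grid: nx x ny nodes, spacing metres, node jitter."""

    nx: int = 30
    ny: int = 30
    spacing_m: float = 100.0
    jitter_m: float = 10.0

    def __post_init__(self):
        if self.nx < 2 or self.ny < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.spacing_m <= 0:
            raise ValueError("spacing must be positive")
        if not 0 <= self.jitter_m < self.spacing_m / 4:
            raise ValueError("jitter must be nonnegative and below spacing/4")


@dataclass(frozen=True)
class StratumSpec:
    """Marginal distributions and planted tree for one age stratum."""

    n: int
    age_mean: float
    age_sd: float
    age_min: int
    age_max: int
    male_p: float
    time_bin_probs: tuple[float, ...]
    season_probs: tuple[float, ...]
    dist_mean_m: float
    dist_sd_m: float
    national_road_p: float
    road_width_probs: tuple[float, ...]
    did_p: float
    aging_mean: float
    aging_sd: float
    ses_mean: float
    ses_sd: float
    planted: SDATree

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("stratum size must be >= 1")
        for name in ("male_p", "national_road_p", "did_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name, k in (("time_bin_probs", len(TIME_BINS)),
                        ("season_probs", len(SEASONS)),
                        ("road_width_probs", len(ROAD_WIDTH_LEVELS))):
            probs = getattr(self, name)
            if len(probs) != k or any(p < 0 for p in probs):
                raise ValueError(f"{name} must be {k} nonnegative weights")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full generator configuration: both strata, network, seed."""

    seed: int = 0
    older: StratumSpec = None
    working: StratumSpec = None
    network: GridSpec = GridSpec()
    coordinate_noise_m: float = 10.0
    year_range: tuple[int, int] = (2002, 2008)

    def __post_init__(self):
        if self.coordinate_noise_m < 0:
            raise ValueError("coordinate noise must be >= 0")
        # points must snap back to the node they were jittered from
        if (self.coordinate_noise_m + 2 * self.network.jitter_m
                >= self.network.spacing_m / 2):
            raise ValueError("coordinate noise too large for the grid spacing")


# ---------------------------------------------------------------------------
# Planted trees
# ---------------------------------------------------------------------------

def _leaf(node_id: str, depth: int, p: float) -> SDANode:
    return SDANode(node_id=node_id, n=0, n_severe=0, depth=depth, leaf_severe_p=p)


def _split(node_id: str, depth: int, rule: SplitRule, pos: SDANode,
           neg: SDANode) -> SDANode:
    return SDANode(node_id=node_id, n=0, n_severe=0, depth=depth,
                   split=SplitCandidate(rule=rule), pos=pos, neg=neg)


def older_planted_tree(p1: float = 0.563, p2: float = 0.176, p3: float = 0.455,
                       p4: float = 0.270) -> SDATree:
    """Four-leaf older-stratum truth (SES, road width, aging rate)."""
    wide = tuple(ROAD_WIDTH_LEVELS[2:])  # 5.5 m per lane and up
    aging = _split("n0NP", 2, SplitRule("aging_rate", "gt",
                                        reference.CUTPOINTS["older_aging_rate"]),
                   pos=_leaf("n0NPP", 3, p3), neg=_leaf("n0NPN", 3, p4))
    # positive branch of the width split is "wide" (aging-rate children);
    # narrow road is the negative leaf
    width = _split("n0N", 1, SplitRule("road_width_class", "in", wide),
                   pos=aging, neg=_leaf("n0NN", 2, p2))
    root = _split("n0", 0, SplitRule("low_ses_prop", "lt",
                                     reference.CUTPOINTS["older_low_ses_prop"]),
                  pos=_leaf("n0P", 1, p1), neg=width)
    return SDATree(root=root, variables=("low_ses_prop", "road_width_class", "aging_rate"))


def working_planted_tree(p1: float = 0.197, p2: float = 0.082,
                         p3: float = 0.0) -> SDATree:
    """Three-leaf working-age truth (network distance, aging rate)."""
    aging = _split("n0P", 1, SplitRule("aging_rate", "ge",
                                       reference.CUTPOINTS["working_aging_rate"]),
                   pos=_leaf("n0PP", 2, p1), neg=_leaf("n0PN", 2, p2))
    root = _split("n0", 0, SplitRule("network_distance_m", "ge",
                                     reference.CUTPOINTS["working_network_distance_m"]),
                  pos=aging, neg=_leaf("n0N", 1, p3))
    return SDATree(root=root, variables=("network_distance_m", "aging_rate"))


def single_split_tree(variable: str = "low_ses_prop", cut: float = 35.0,
                      p_low: float = 0.55, p_high: float = 0.20) -> SDATree:
    """One-split truth: ``variable <= cut`` -> p_low, else p_high."""
    root = _split("n0", 0, SplitRule(variable, "le", cut),
                  pos=_leaf("n0P", 1, p_low), neg=_leaf("n0N", 1, p_high))
    return SDATree(root=root, variables=(variable,))


def flat_tree(p: float = 0.3) -> SDATree:
    """Null truth: a single leaf, severity independent of all variables."""
    return SDATree(root=_leaf("n0", 0, p), variables=())


# ---------------------------------------------------------------------------
# Defaults (published stratum marginals)
# ---------------------------------------------------------------------------

def default_config(seed: int = 0, n_older: int = reference.OLDER_N,
                   n_working: int = reference.WORKING_N,
                   network: GridSpec = GridSpec()) -> GeneratorConfig:
    """Default study conditions: published marginals and planted trees."""
    older = StratumSpec(
        n=n_older, age_mean=75.0, age_sd=6.0, age_min=65, age_max=100,
        male_p=0.332,
        time_bin_probs=(0.013, 0.144, 0.262, 0.148, 0.341, 0.092),
        season_probs=(0.310, 0.236, 0.162, 0.293),
        dist_mean_m=1128.0, dist_sd_m=1837.0,
        national_road_p=0.189,
        road_width_probs=(0.035, 0.328, 0.467, 0.166),
        did_p=0.742, aging_mean=19.64, aging_sd=5.17,
        ses_mean=40.80, ses_sd=6.50,
        planted=older_planted_tree(),
    )
    working = StratumSpec(
        n=n_working, age_mean=44.0, age_sd=13.0, age_min=18, age_max=64,
        male_p=0.505,
        time_bin_probs=(0.088, 0.082, 0.139, 0.091, 0.353, 0.246),
        season_probs=(0.271, 0.221, 0.240, 0.268),
        dist_mean_m=1939.0, dist_sd_m=2487.0,
        national_road_p=0.188,
        road_width_probs=(0.050, 0.401, 0.303, 0.246),
        did_p=0.808, aging_mean=17.80, aging_sd=4.93,
        ses_mean=41.51, ses_sd=7.53,
        planted=working_planted_tree(),
    )
    return GeneratorConfig(seed=seed, older=older, working=working, network=network)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _streams(config: GeneratorConfig):
    net_ss, older_ss, working_ss = np.random.SeedSequence(config.seed).spawn(3)
    return (np.random.default_rng(net_ss), np.random.default_rng(older_ss),
            np.random.default_rng(working_ss))


def generate_road_network(config: GeneratorConfig) -> RoadNetwork:
    """Jittered rectangular grid; edge length = chord length.

    Deterministic given the config seed.
    """
    rng, _, _ = _streams(config)
    grid = config.network
    nodes: dict[str, tuple[float, float]] = {}
    for i in range(grid.nx):
        for j in range(grid.ny):
            jitter = rng.uniform(-grid.jitter_m, grid.jitter_m, size=2) \
                if grid.jitter_m > 0 else np.zeros(2)
            nodes[f"n{i:03d}_{j:03d}"] = (i * grid.spacing_m + jitter[0],
                                          j * grid.spacing_m + jitter[1])
    edges = []
    for i in range(grid.nx):
        for j in range(grid.ny):
            u = f"n{i:03d}_{j:03d}"
            if i + 1 < grid.nx:
                v = f"n{i + 1:03d}_{j:03d}"
                edges.append((u, v, math.dist(nodes[u], nodes[v])))
            if j + 1 < grid.ny:
                v = f"n{i:03d}_{j + 1:03d}"
                edges.append((u, v, math.dist(nodes[u], nodes[v])))
    return RoadNetwork(nodes, edges)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Draw-until-accept truncated normal (bounds are far in the defaults)."""
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _generate_stratum(rng, spec: StratumSpec, network: RoadNetwork,
                      config: GeneratorConfig, prefix: str) -> list[InjuryRecord]:
    n = spec.n
    node_ids, dmat = network.distance_matrix()
    finite = dmat[np.isfinite(dmat)]
    if finite.max() < spec.dist_mean_m:
        raise ValueError(
            f"network too small: maximal reachable distance {finite.max():.0f} m is "
            f"below the target mean {spec.dist_mean_m:.0f} m; use a larger grid")
    pos = np.array([network.position(nid) for nid in node_ids])

    ages = np.rint(_truncated_normal(rng, spec.age_mean, spec.age_sd,
                                     spec.age_min, spec.age_max, n)).astype(int)
    male = rng.random(n) < spec.male_p
    tb = np.asarray(spec.time_bin_probs, dtype=float)
    time_bins = rng.choice(len(TIME_BINS), size=n, p=tb / tb.sum())
    sp = np.asarray(spec.season_probs, dtype=float)
    seasons = rng.choice(len(SEASONS), size=n, p=sp / sp.sum())
    national = rng.random(n) < spec.national_road_p
    wp = np.asarray(spec.road_width_probs, dtype=float)
    widths = rng.choice(len(ROAD_WIDTH_LEVELS), size=n, p=wp / wp.sum())
    did = rng.random(n) < spec.did_p
    aging = _truncated_normal(rng, spec.aging_mean, spec.aging_sd, 0.0, 100.0, n)
    ses = _truncated_normal(rng, spec.ses_mean, spec.ses_sd, 0.0, 100.0, n)

    mu, sigma = _lognormal_params(spec.dist_mean_m, spec.dist_sd_m)
    targets = rng.lognormal(mu, sigma, size=n)
    res_idx = rng.integers(0, len(node_ids), size=n)
    # injury node: the node whose network distance from the residence is
    # closest to the lognormal target (first index wins ties; rows are in
    # lexicographic node order, so ties go to the smallest node id)
    inj_idx = np.empty(n, dtype=int)
    for i in range(n):
        row = dmat[res_idx[i]]
        diff = np.abs(row - targets[i])
        diff[~np.isfinite(row)] = np.inf
        inj_idx[i] = int(np.argmin(diff))
    net_dist = dmat[res_idx, inj_idx]

    noise = config.coordinate_noise_m
    res_xy = pos[res_idx] + rng.uniform(-noise, noise, size=(n, 2))
    inj_xy = pos[inj_idx] + rng.uniform(-noise, noise, size=(n, 2))

    years = rng.integers(config.year_range[0], config.year_range[1] + 1, size=n)
    month_pick = rng.integers(0, 3, size=n)
    days = rng.integers(1, 29, size=n)
    hour_offsets = rng.integers(0, 4, size=n)
    minutes = rng.integers(0, 60, size=n)

    records = []
    uniform = rng.random(n)
    for i in range(n):
        season = SEASONS[seasons[i]]
        month = _SEASON_MONTHS[season][month_pick[i]]
        hour = int(time_bins[i]) * 4 + int(hour_offsets[i])
        dt = datetime(int(years[i]), int(month), int(days[i]), hour, int(minutes[i]))
        values = {
            "age": int(ages[i]),
            "gender": "male" if male[i] else "female",
            "time_bin": TIME_BINS[time_bins[i]],
            "season": season,
            "network_distance_m": float(net_dist[i]),
            "national_road": bool(national[i]),
            "road_width_class": ROAD_WIDTH_LEVELS[widths[i]],
            "did": bool(did[i]),
            "aging_rate": float(aging[i]),
            "low_ses_prop": float(ses[i]),
        }
        p_severe = spec.planted.leaf_probability(values)
        records.append(InjuryRecord(
            record_id=f"{prefix}{i + 1:05d}",
            age=int(ages[i]),
            gender=values["gender"],
            injury_datetime=dt,
            residence_xy=(float(res_xy[i, 0]), float(res_xy[i, 1])),
            injury_xy=(float(inj_xy[i, 0]), float(inj_xy[i, 1])),
            national_road=bool(national[i]),
            road_width_class=values["road_width_class"],
            did=bool(did[i]),
            aging_rate=float(aging[i]),
            low_ses_prop=float(ses[i]),
            severity="severe" if uniform[i] < p_severe else "minor",
            network_distance_m=float(net_dist[i]),
            euclidean_distance_m=float(math.dist(res_xy[i], inj_xy[i])),
        ))
    return records


def generate_registry(config: GeneratorConfig,
                      network: RoadNetwork | None = None) -> RecordSet:
    """Draw a full two-stratum registry; deterministic given the seed.

    Covariates are drawn per stratum from the configured marginals,
    residence nodes uniformly on the network, injury nodes so that the
    realized network distance tracks a moment-matched lognormal, and
    severity as a Bernoulli draw from the planted tree's leaf
    probability evaluated on the record's *realized* covariates.
    """
    if network is None:
        network = generate_road_network(config)
    _, rng_older, rng_working = _streams(config)
    records = _generate_stratum(rng_older, config.older, network, config, "O")
    records += _generate_stratum(rng_working, config.working, network, config, "W")
    return RecordSet(records, provenance=f"synthetic(seed={config.seed})")


def planted_truth(config: GeneratorConfig, stratum: str = "older") -> SDATree:
    """The generating rule set of one stratum, as a tree for recovery scoring."""
    if stratum == "older":
        return config.older.planted
    if stratum == "working":
        return config.working.planted
    raise ValueError(f"stratum must be 'older' or 'working', got {stratum!r}")
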
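"""Cut enumeration, split search, tree growth, routing and rendering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from pedsda.sda import (STUDY_VARIABLES, ContingencyTable2x2, RoutingError,
                        SDAConfig, SDAError, SDATree, _complement,
                        assign_subgroup, best_split, chi_square_test,
                        enumerate_cutpoints, grow_tree, render_tree,
                        weighted_kappa)
from pedsda.synthetic import older_planted_tree

from conftest import one_split_cohort


def make_frame(n=40, seed=0, **columns) -> pd.DataFrame:
    """Minimal analysis frame; unspecified study variables get constants."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "age": rng.integers(65, 90, n),
        "gender": rng.choice(["male", "female"], n),
        "time_bin": "08-12",
        "season": "spring",
        "network_distance_m": rng.uniform(0, 2000, n),
        "national_road": False,
        "road_width_class": "w3to5_5",
        "did": True,
        "aging_rate": rng.uniform(5, 35, n),
        "low_ses_prop": rng.uniform(20, 60, n),
        "severe": False,
    })
    for k, v in columns.items():
        df[k] = v
    return df


# ---- enumerate_cutpoints ---------------------------------------------------

def test_cutpoints_continuous_midpoints():
    df = make_frame(6, aging_rate=[1, 1, 3, 3, 7, 7])
    rules = enumerate_cutpoints(df, "aging_rate")
    assert [(r.op, r.value) for r in rules] == [("le", 2.0), ("le", 5.0)]


def test_cutpoints_ordinal_binary_nominal():
    df = make_frame(8)
    width = enumerate_cutpoints(df, "road_width_class")
    assert len(width) == 3
    assert width[0].value == ("lt3",)
    assert width[2].value == ("lt3", "w3to5_5", "w5_5to13")
    assert len(enumerate_cutpoints(df, "season")) == 4
    assert len(enumerate_cutpoints(df, "gender")) == 1


def test_cutpoints_constant_variable_empty():
    df = make_frame(5, aging_rate=20.0)
    assert enumerate_cutpoints(df, "aging_rate") == []


def test_cutpoints_unknown_variable():
    with pytest.raises(SDAError, match="unknown variable"):
        enumerate_cutpoints(make_frame(5), "not_a_variable")


# ---- best_split ------------------------------------------------------------

def test_best_split_degenerate_outcome_is_none():
    df = make_frame(40, severe=False)
    assert best_split(df, STUDY_VARIABLES, SDAConfig()) is None


def test_best_split_perfect_binary_predictor():
    """A binary variable that exactly predicts severity: kappa 1."""
    df = make_frame(40)
    df["did"] = [True] * 20 + [False] * 20
    df["severe"] = [True] * 20 + [False] * 20
    cand = best_split(df, STUDY_VARIABLES, SDAConfig())
    assert cand is not None
    assert cand.rule.variable == "did"
    assert cand.kappa == pytest.approx(1.0)
    assert cand.p_value < 1e-6
    assert cand.kappa_ci[0] > 0


def test_best_split_matches_exhaustive_oracle():
    """The vectorized search equals a brute-force loop over every
    candidate rule of every variable in both orientations."""
    df = one_split_cohort(seed=5, n=200)
    y = df["severe"].to_numpy(bool)
    config = SDAConfig()

    best = None
    for vi, vs in enumerate(STUDY_VARIABLES):
        for rule in enumerate_cutpoints(df, vs):
            for orient, r in enumerate((rule, _complement(rule, vs))):
                pos = r.evaluate(df)
                t = ContingencyTable2x2.from_indicators(pos, y)
                if min(t.a + t.b, t.c + t.d) < config.min_subgroup:
                    continue
                k = weighted_kappa(t, config.r)
                _, p = chi_square_test(t)
                key = (-k, p, vi)
                if best is None or key < best[0]:
                    best = (key, r, k, p)

    cand = best_split(df, STUDY_VARIABLES, config)
    assert cand is not None
    assert cand.rule == best[1]
    assert cand.kappa == pytest.approx(best[2], abs=1e-12)
    assert cand.p_value == pytest.approx(best[3], rel=1e-9)


def test_best_split_skips_variables_with_missing_values():
    df = make_frame(60)
    df["did"] = pd.Series([True] * 30 + [False] * 30, index=df.index, dtype=object)
    df["severe"] = [True] * 30 + [False] * 30
    df.loc[df.index[0], "did"] = None
    cand = best_split(df, STUDY_VARIABLES, SDAConfig())
    assert cand is None or cand.rule.variable != "did"


# ---- grow_tree -------------------------------------------------------------

def test_small_sample_yields_single_leaf():
    """15 records cannot produce two children of 10: no split at all."""
    df = make_frame(15)
    df["severe"] = [True] * 7 + [False] * 8
    tree = grow_tree(df, STUDY_VARIABLES, SDAConfig(min_subgroup=10))
    assert tree.root.is_leaf
    assert tree.n_nodes == 1


def test_planted_single_split_recovered():
    df = one_split_cohort(seed=0, n=400)
    tree = grow_tree(df, STUDY_VARIABLES, SDAConfig())
    assert tree.root.split.rule.variable == "low_ses_prop"
    assert abs(tree.root.split.rule.value - 35.0) < 2.0


def test_planted_cut_recovery_rate():
    """Across 50 seeded replicates the root cut stays inside the small
    neighbourhood of the generating threshold in >= 90% of runs."""
    hits = 0
    for seed in range(50):
        df = one_split_cohort(seed=seed, n=400)
        cand = best_split(df, STUDY_VARIABLES, SDAConfig())
        if (cand is not None and cand.rule.variable == "low_ses_prop"
                and abs(cand.rule.value - 35.0) < 2.0):
            hits += 1
    assert hits >= 45


def test_tree_audit_and_partition(default_cohort):
    """Stopping rules hold at every internal node; leaves partition the
    sample; record order does not change the fitted tree."""
    _, _, records = default_cohort
    df = records.to_frame()
    older = df[df.age_group == "older"]
    config = SDAConfig()
    tree = grow_tree(older, STUDY_VARIABLES, config)

    for node in tree.nodes():
        if not node.is_leaf:
            assert node.pos.n >= config.min_subgroup
            assert node.neg.n >= config.min_subgroup
            assert node.pos.n + node.neg.n == node.n
            assert node.pos.n_severe + node.neg.n_severe == node.n_severe
            assert node.split.p_value < config.alpha
            assert node.split.kappa_ci[0] > 0

    leaves = tree.leaves()
    assert sum(l.n for l in leaves) == len(older)
    assert sum(l.n_severe for l in leaves) == int(older["severe"].sum())

    shuffled = older.sample(frac=1.0, random_state=99)
    tree2 = grow_tree(shuffled, STUDY_VARIABLES, config)
    assert tree2.to_dict() == tree.to_dict()


def test_max_depth_cap():
    df = one_split_cohort(seed=1, n=400)
    tree = grow_tree(df, STUDY_VARIABLES, SDAConfig(max_depth=1))
    assert all(node.depth <= 1 for node in tree.nodes())
    assert tree.root.pos.is_leaf and tree.root.neg.is_leaf


# ---- routing ---------------------------------------------------------------

def test_assign_single_leaf_tree():
    df = make_frame(15)
    df["severe"] = [True] * 7 + [False] * 8
    tree = grow_tree(df, STUDY_VARIABLES, SDAConfig())
    assert assign_subgroup(tree, df.iloc[0].to_dict()) == tree.root.node_id


def test_assign_reference_shaped_tree():
    """On the published older-stratum rule shape, a record from a
    higher-SES area (low_ses_prop 30 < 35.21) routes to the first leaf."""
    tree = older_planted_tree()
    values = {"low_ses_prop": 30.0, "road_width_class": "gt13", "aging_rate": 25.0}
    assert tree.assign(values) == "n0P"
    values = {"low_ses_prop": 50.0, "road_width_class": "w3to5_5", "aging_rate": 25.0}
    assert tree.assign(values) == "n0NN"


def test_assign_partitions_record_set(default_cohort):
    _, _, records = default_cohort
    df = records.to_frame()
    working = df[df.age_group == "working_age"]
    tree = grow_tree(working, STUDY_VARIABLES, SDAConfig())
    leaf_ids = tree.assign_frame(working)
    sizes = leaf_ids.value_counts()
    assert sizes.sum() == len(working)
    assert set(sizes.index) <= {l.node_id for l in tree.leaves()}
    by_leaf = {l.node_id: l.n for l in tree.leaves()}
    for leaf_id, size in sizes.items():
        assert by_leaf[leaf_id] == size


def test_assign_missing_variable_raises():
    tree = older_planted_tree()
    with pytest.raises(RoutingError, match="low_ses_prop"):
        tree.assign({"road_width_class": "gt13", "aging_rate": 25.0})


# ---- rendering -------------------------------------------------------------

def test_single_leaf_rendering_shows_zero_percent():
    """A 31-record all-minor subgroup renders as 0.0% severe."""
    from pedsda.sda import SDANode

    single = SDATree(root=SDANode(node_id="n0", n=31, n_severe=0, depth=0))
    rendering = render_tree(single)
    assert "0.0%" in rendering.text
    assert "n=31" in rendering.text


def test_json_round_trip_identity(default_cohort):
    _, _, records = default_cohort
    df = records.to_frame()
    tree = grow_tree(df[df.age_group == "older"], STUDY_VARIABLES, SDAConfig())
    back = SDATree.from_json(tree.to_json())
    assert back.to_dict() == tree.to_dict()
    assert back.root == tree.root


def test_node_count_arithmetic(default_cohort):
    _, _, records = default_cohort
    df = records.to_frame()
    tree = grow_tree(df[df.age_group == "older"], STUDY_VARIABLES, SDAConfig())
    assert tree.n_nodes == 2 * tree.n_splits + 1
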
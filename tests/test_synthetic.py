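"""Synthetic network and registry generator: determinism and calibration."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest

from pedsda.geo import network_distance
from pedsda.registry import write_registry
from pedsda.synthetic import (GeneratorConfig, GridSpec, default_config,
                              generate_registry, generate_road_network,
                              planted_truth, _lognormal_params)


def grid_config(seed=0, **grid_kwargs) -> GeneratorConfig:
    cfg = default_config(seed=seed)
    return dataclasses.replace(cfg, network=GridSpec(**grid_kwargs))


# ---- road network ----------------------------------------------------------

def test_minimal_grid_shape():
    cfg = grid_config(nx=2, ny=2, spacing_m=100.0, jitter_m=0.0)
    net = generate_road_network(cfg)
    assert net.n_nodes == 4
    assert net.n_edges == 4
    for _, _, data in net.graph.edges(data=True):
        assert data["length"] == pytest.approx(100.0)


def test_grid_corner_distance_without_jitter():
    cfg = grid_config(nx=5, ny=5, spacing_m=100.0, jitter_m=0.0)
    net = generate_road_network(cfg)
    assert network_distance(net, "n000_000", "n004_004") == pytest.approx(800.0)


def test_network_determinism():
    a = generate_road_network(default_config(seed=7))
    b = generate_road_network(default_config(seed=7))
    assert a.node_ids == b.node_ids
    for node in a.node_ids:
        assert a.position(node) == b.position(node)


def test_degenerate_grid_rejected():
    with pytest.raises(ValueError):
        GridSpec(nx=1, ny=5)


# ---- registry --------------------------------------------------------------

def test_registry_determinism_byte_identical(tmp_path):
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_registry(generate_registry(default_config(seed=3)), p1)
    write_registry(generate_registry(default_config(seed=3)), p2)
    assert p1.read_bytes() == p2.read_bytes()
    write_registry(generate_registry(default_config(seed=4)), p2)
    assert p1.read_bytes() != p2.read_bytes()


def test_stratum_sizes_and_schema(default_cohort):
    cfg, _, records = default_cohort
    df = records.to_frame()
    assert (df.age_group == "older").sum() == cfg.older.n
    assert (df.age_group == "working_age").sum() == cfg.working.n
    assert df.age.min() >= 18
    assert df.network_distance_m.notna().all()


def test_marginals_converge_at_large_n():
    """Directly drawn covariates match the configured marginals within
    3 standard errors at n = 10^4 per stratum."""
    cfg = default_config(seed=42, n_older=10_000, n_working=10_000)
    df = generate_registry(cfg).to_frame()
    for group, spec in (("older", cfg.older), ("working_age", cfg.working)):
        sub = df[df.age_group == group]
        n = len(sub)
        for col, mean, sd in (("aging_rate", spec.aging_mean, spec.aging_sd),
                              ("low_ses_prop", spec.ses_mean, spec.ses_sd)):
            assert sub[col].mean() == pytest.approx(mean, abs=3 * sd / math.sqrt(n))
            assert sub[col].std(ddof=1) == pytest.approx(
                sd, abs=3 * sd / math.sqrt(2 * n))
        for indicator, p in ((sub.gender == "male", spec.male_p),
                             (sub.did, spec.did_p),
                             (sub.national_road, spec.national_road_p)):
            se = math.sqrt(p * (1 - p) / n)
            assert indicator.mean() == pytest.approx(p, abs=3 * se)
        wp = np.asarray(spec.road_width_probs) / sum(spec.road_width_probs)
        observed = sub.road_width_class.value_counts(normalize=True)
        for level, p in zip(("lt3", "w3to5_5", "w5_5to13", "gt13"), wp):
            se = math.sqrt(p * (1 - p) / n)
            assert observed.get(level, 0.0) == pytest.approx(p, abs=3 * se)


def test_distance_targets_are_moment_matched():
    """The lognormal target law reproduces the configured mean/SD exactly
    in its parameters, and the realized network distance matches the
    analytic expectation E[min(X, Dmax)] of the target clipped at each
    residence node's maximal reachable distance (grid truncation)."""
    from scipy.stats import norm

    for mean, sd in ((1128.0, 1837.0), (1939.0, 2487.0)):
        mu, sigma = _lognormal_params(mean, sd)
        assert math.exp(mu + sigma ** 2 / 2) == pytest.approx(mean)
        var = (math.exp(sigma ** 2) - 1) * math.exp(2 * mu + sigma ** 2)
        assert math.sqrt(var) == pytest.approx(sd)

    cfg = default_config(seed=6, n_older=4000, n_working=4000)
    net = generate_road_network(cfg)
    _, dmat = net.distance_matrix()
    dmax = np.nanmax(np.where(np.isfinite(dmat), dmat, np.nan), axis=1)
    df = generate_registry(cfg, net).to_frame()
    for group, spec in (("older", cfg.older), ("working_age", cfg.working)):
        mu, sigma = _lognormal_params(spec.dist_mean_m, spec.dist_sd_m)
        clipped_mean = np.mean(
            math.exp(mu + sigma ** 2 / 2)
            * norm.cdf((np.log(dmax) - mu - sigma ** 2) / sigma)
            + dmax * (1 - norm.cdf((np.log(dmax) - mu) / sigma)))
        realized = df[df.age_group == group]["network_distance_m"].mean()
        assert realized == pytest.approx(clipped_mean, rel=0.05)


def test_severe_rates_near_planted_expectation(default_cohort):
    """Stratum severe rates stay within 4 points of the analytic
    leaf-occupancy x leaf-probability expectation at n = 1000."""
    cfg = default_config(seed=11, n_older=1000, n_working=1000)
    df = generate_registry(cfg).to_frame()
    # analytic expectation under independent covariates
    from scipy.stats import norm
    o = cfg.older
    p_ses = norm.cdf((35.21 - o.ses_mean) / o.ses_sd)
    wp = np.asarray(o.road_width_probs) / sum(o.road_width_probs)
    p_wide = wp[2] + wp[3]
    p_aging = 1 - norm.cdf((20.3 - o.aging_mean) / o.aging_sd)
    expect_older = (p_ses * 0.563
                    + (1 - p_ses) * (1 - p_wide) * 0.176
                    + (1 - p_ses) * p_wide * (p_aging * 0.455 + (1 - p_aging) * 0.270))
    w = cfg.working
    p_aging_w = 1 - norm.cdf((21.05 - w.aging_mean) / w.aging_sd)
    # almost all mass sits above the 132.84 m distance cut
    expect_working = p_aging_w * 0.197 + (1 - p_aging_w) * 0.082
    older_rate = df[df.age_group == "older"]["severe"].mean()
    working_rate = df[df.age_group == "working_age"]["severe"].mean()
    assert abs(older_rate - expect_older) < 0.04
    assert abs(working_rate - expect_working) < 0.04


def test_every_planted_leaf_occupied(default_cohort):
    cfg, _, records = default_cohort
    df = records.to_frame()
    for stratum, group in (("older", "older"), ("working", "working_age")):
        truth = planted_truth(cfg, stratum)
        leaves = truth.assign_frame(df[df.age_group == group])
        assert set(leaves) == {l.node_id for l in truth.leaves()}


def test_zero_probability_leaf_has_zero_severe(default_cohort):
    cfg, _, records = default_cohort
    df = records.to_frame()
    working = df[df.age_group == "working_age"]
    truth = planted_truth(cfg, "working")
    leaves = truth.assign_frame(working)
    short = working[leaves == "n0N"]  # distance < 132.84 leaf, planted p = 0
    assert len(short) > 0
    assert not short["severe"].any()


def test_planted_truth_shapes():
    cfg = default_config(seed=0)
    older = planted_truth(cfg, "older")
    assert older.root.split.rule.variable == "low_ses_prop"
    assert older.root.split.rule.value == pytest.approx(35.21)
    working = planted_truth(cfg, "working")
    assert working.root.split.rule.variable == "network_distance_m"
    assert working.root.split.rule.value == pytest.approx(132.84)
    from pedsda.synthetic import flat_tree
    assert flat_tree(0.3).root.is_leaf
    with pytest.raises(ValueError):
        planted_truth(cfg, "children")


def test_snapped_coordinates_reproduce_generator_distances(default_cohort):
    """Re-annotating generated records through the Dijkstra path recovers
    the generator's distances (scipy matrix vs networkx agreement)."""
    from pedsda.geo import annotate_distances

    _, network, records = default_cohort
    sample = records.subset(lambda r: r.record_id in
                            {f"O{i:05d}" for i in range(1, 16)})
    re_annotated = annotate_distances(sample, network)
    for old, new in zip(sample, re_annotated):
        assert new.network_distance_m == pytest.approx(old.network_distance_m)


def test_too_small_network_raises():
    cfg = dataclasses.replace(default_config(seed=0),
                              network=GridSpec(nx=2, ny=2, spacing_m=10.0, jitter_m=0.0),
                              coordinate_noise_m=1.0)
    with pytest.raises(ValueError, match="larger grid"):
        generate_registry(cfg)
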
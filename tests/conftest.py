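"""Shared fixtures: tiny registries, grid networks, generated cohorts."""

from __future__ import annotations

import dataclasses

import pytest

from pedsda.geo import RoadNetwork
from pedsda.synthetic import (default_config, flat_tree, generate_registry,
                              generate_road_network, single_split_tree)

HEADER = ("record_id,age,gender,injury_datetime,residence_x,residence_y,"
          "injury_x,injury_y,national_road,road_width_m,did,aging_rate,"
          "low_ses_prop,severity")


def registry_row(record_id="r1", age=70, gender="female",
                 injury_datetime="2005-04-12T09:30:00", residence_x=0.0,
                 residence_y=0.0, injury_x=300.0, injury_y=400.0,
                 national_road=0, road_width_m=6.0, did=1, aging_rate=21.5,
                 low_ses_prop=40.0, severity="minor") -> str:
    return (f"{record_id},{age},{gender},{injury_datetime},{residence_x},"
            f"{residence_y},{injury_x},{injury_y},{national_road},"
            f"{road_width_m},{did},{aging_rate},{low_ses_prop},{severity}")


@pytest.fixture
def registry_csv(tmp_path):
    """Factory writing a registry CSV from row strings; returns the path."""

    def write(rows, header=HEADER, name="registry.csv"):
        path = tmp_path / name
        path.write_text(header + "\n" + "\n".join(rows) + "\n")
        return path

    return write


@pytest.fixture
def unit_grid():
    """3 x 3 unit-spaced grid network with string node ids."""
    nodes = {f"g{i}{j}": (float(i), float(j)) for i in range(3) for j in range(3)}
    edges = []
    for i in range(3):
        for j in range(3):
            if i < 2:
                edges.append((f"g{i}{j}", f"g{i + 1}{j}", 1.0))
            if j < 2:
                edges.append((f"g{i}{j}", f"g{i}{j + 1}", 1.0))
    return RoadNetwork(nodes, edges)


@pytest.fixture(scope="session")
def default_cohort():
    """One default-size synthetic cohort (seed 0) shared across tests."""
    cfg = default_config(seed=0)
    network = generate_road_network(cfg)
    records = generate_registry(cfg, network)
    return cfg, network, records


def one_split_cohort(seed: int, n: int = 400, cut: float = 35.0,
                     p_low: float = 0.55, p_high: float = 0.20):
    """Single-stratum cohort whose severity depends only on low_ses_prop."""
    cfg = default_config(seed=seed, n_older=n, n_working=1)
    planted = single_split_tree("low_ses_prop", cut, p_low, p_high)
    cfg = dataclasses.replace(
        cfg, older=dataclasses.replace(cfg.older, planted=planted))
    frame = generate_registry(cfg).to_frame()
    return frame[frame.age_group == "older"]


def null_cohort(seed: int, n: int = 400, rate: float = 0.3):
    """Single-stratum cohort with severity independent of all variables."""
    cfg = default_config(seed=seed, n_older=n, n_working=1)
    cfg = dataclasses.replace(
        cfg, older=dataclasses.replace(cfg.older, planted=flat_tree(rate)))
    frame = generate_registry(cfg).to_frame()
    return frame[frame.age_group == "older"]
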
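"""Euclidean and road-network shortest-path distances.

The exposure measure of interest is the network distance travelled: the
length of the shortest route along the road network between a subject's
residence and the injury site, as opposed to the straight-line
(Euclidean) distance.  Coordinates are planar metres in a projected
frame; projection happens upstream.

Snapping of an arbitrary point onto the network is to the nearest
*node* (ties broken by lexicographically smallest node id).  This is a
documented simplification of GIS network analysts that snap to interior
edge points; synthetic networks can be densified to compensate.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, replace
from typing import Hashable, Iterable, Mapping, Optional

import networkx as nx
import numpy as np

from .registry import RecordSet

__all__ = [
    "UNREACHABLE",
    "GeoError",
    "RoadNetwork",
    "DistancePair",
    "euclidean_distance",
    "snap_to_network",
    "network_distance",
    "annotate_distances",
]

log = logging.getLogger(__name__)

#: Marker for a residence/injury pair whose snapped nodes are in
#: different components of the road network.
UNREACHABLE = math.inf


class GeoError(ValueError):
    """Invalid geometry or network input."""


def euclidean_distance(p1, p2) -> float:
    """Straight-line distance d with d^2 = (x1-x2)^2 + (y1-y2)^2."""
    x1, y1 = p1
    x2, y2 = p2
    for v in (x1, y1, x2, y2):
        if not math.isfinite(v):
            raise GeoError(f"coordinates must be finite, got {p1!r}, {p2!r}")
    return math.hypot(x1 - x2, y1 - y2)


@dataclass(frozen=True)
class DistancePair:
    """Euclidean and network distance for one residence/injury pair."""

    euclidean_m: float
    network_m: float  # UNREACHABLE (inf) when the pair is disconnected

    @property
    def reachable(self) -> bool:
        return math.isfinite(self.network_m)


class RoadNetwork:
    """Undirected road graph with planar node coordinates and edge lengths.

    Invariants enforced on construction: every edge endpoint is a known
    node, lengths are positive and finite, and each edge is at least as
    long as the straight-line chord between its endpoints (a road cannot
    be shorter than the crow flies).  The graph may be disconnected.
    """

    _CHORD_TOL = 1e-9

    def __init__(self, nodes: Mapping[Hashable, tuple[float, float]],
                 edges: Iterable[tuple[Hashable, Hashable, float]]):
        if not nodes:
            raise GeoError("a road network needs at least one node")
        g = nx.Graph()
        for node, (x, y) in nodes.items():
            if not (math.isfinite(x) and math.isfinite(y)):
                raise GeoError(f"node {node!r} has non-finite coordinates")
            g.add_node(node, pos=(float(x), float(y)))
        for u, v, length in edges:
            if u not in g or v not in g:
                raise GeoError(f"edge ({u!r}, {v!r}) references an unknown node")
            length = float(length)
            if not math.isfinite(length) or length <= 0:
                raise GeoError(f"edge ({u!r}, {v!r}) has non-positive length {length}")
            chord = euclidean_distance(g.nodes[u]["pos"], g.nodes[v]["pos"])
            if length < chord - self._CHORD_TOL:
                raise GeoError(
                    f"edge ({u!r}, {v!r}) length {length} shorter than its chord {chord}")
            g.add_edge(u, v, length=length)
        self.graph = g
        self._sorted_nodes = sorted(g.nodes, key=str)
        self._apsp: Optional[np.ndarray] = None

    # ---- basic accessors ----------------------------------------------------

    def __contains__(self, node) -> bool:
        return node in self.graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def position(self, node) -> tuple[float, float]:
        try:
            return self.graph.nodes[node]["pos"]
        except KeyError as exc:
            raise GeoError(f"unknown node {node!r}") from exc

    @property
    def node_ids(self) -> list:
        """Node ids sorted lexicographically by string form."""
        return list(self._sorted_nodes)

    # ---- loading ------------------------------------------------------------

    @classmethod
    def from_edge_csvs(cls, node_csv, edge_csv) -> "RoadNetwork":
        """Load from a node CSV (node_id,x,y) and an edge CSV (node_u,node_v,length_m)."""
        nodes: dict[str, tuple[float, float]] = {}
        with open(node_csv, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                nodes[row["node_id"]] = (float(row["x"]), float(row["y"]))
        edges = []
        with open(edge_csv, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                edges.append((row["node_u"], row["node_v"], float(row["length_m"])))
        return cls(nodes, edges)

    @classmethod
    def from_geojson(cls, path) -> "RoadNetwork":
        """Load LineString features; each vertex becomes a node keyed by its
        coordinates, so intersecting features sharing a vertex connect."""
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        nodes: dict[str, tuple[float, float]] = {}
        edges: list[tuple[str, str, float]] = []

        def key(pt):  # stable id from coordinates
            return f"{pt[0]!r},{pt[1]!r}"

        for feature in doc.get("features", []):
            geom = feature.get("geometry", {})
            if geom.get("type") != "LineString":
                continue
            coords = geom.get("coordinates", [])
            for p, q in zip(coords, coords[1:]):
                kp, kq = key(p), key(q)
                nodes.setdefault(kp, (float(p[0]), float(p[1])))
                nodes.setdefault(kq, (float(q[0]), float(q[1])))
                edges.append((kp, kq, euclidean_distance(p, q)))
        if not nodes:
            raise GeoError(f"no LineString features found in {path}")
        return cls(nodes, edges)

    def write_csvs(self, node_csv, edge_csv) -> None:
        with open(node_csv, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["node_id", "x", "y"])
            for node in self._sorted_nodes:
                x, y = self.graph.nodes[node]["pos"]
                w.writerow([node, repr(x), repr(y)])
        with open(edge_csv, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["node_u", "node_v", "length_m"])
            for u, v, data in sorted(self.graph.edges(data=True),
                                     key=lambda e: (str(e[0]), str(e[1]))):
                w.writerow([u, v, repr(data["length"])])

    # ---- distances ----------------------------------------------------------

    def nearest_node(self, point):
        """Node minimizing Euclidean distance to ``point``; ties go to the
        lexicographically smallest node id."""
        px, py = float(point[0]), float(point[1])
        if not (math.isfinite(px) and math.isfinite(py)):
            raise GeoError(f"point must be finite, got {point!r}")
        best = None
        best_d = math.inf
        for node in self._sorted_nodes:  # sorted order makes ties lexicographic
            x, y = self.graph.nodes[node]["pos"]
            d = math.hypot(px - x, py - y)
            if d < best_d:
                best, best_d = node, d
        return best

    def shortest_path_length(self, origin, dest) -> float:
        """Dijkstra shortest-path length; UNREACHABLE for disconnected pairs."""
        for node in (origin, dest):
            if node not in self.graph:
                raise GeoError(f"unknown node {node!r}")
        if origin == dest:
            return 0.0
        try:
            return float(nx.dijkstra_path_length(self.graph, origin, dest, weight="length"))
        except nx.NetworkXNoPath:
            return UNREACHABLE

    def distance_matrix(self) -> tuple[list, np.ndarray]:
        """All-pairs shortest-path matrix over ``node_ids`` order.

        Uses scipy's sparse-graph Dijkstra for speed; entries are inf for
        disconnected pairs.  Cached after the first call.
        """
        if self._apsp is None:
            from scipy.sparse import csr_matrix
            from scipy.sparse.csgraph import dijkstra as _dijkstra

            index = {node: i for i, node in enumerate(self._sorted_nodes)}
            n = len(index)
            rows, cols, vals = [], [], []
            for u, v, data in self.graph.edges(data=True):
                i, j = index[u], index[v]
                rows += [i, j]
                cols += [j, i]
                vals += [data["length"], data["length"]]
            adj = csr_matrix((vals, (rows, cols)), shape=(n, n))
            self._apsp = _dijkstra(adj, directed=False)
        return list(self._sorted_nodes), self._apsp


def snap_to_network(point, network: RoadNetwork):
    """Functional alias of :meth:`RoadNetwork.nearest_node`."""
    return network.nearest_node(point)


def network_distance(network: RoadNetwork, origin, dest) -> float:
    """Functional alias of :meth:`RoadNetwork.shortest_path_length`."""
    return network.shortest_path_length(origin, dest)


def distance_pair(network: RoadNetwork, residence_xy, injury_xy) -> DistancePair:
    """Euclidean and snapped network distance for one coordinate pair."""
    eu = euclidean_distance(residence_xy, injury_xy)
    o = network.nearest_node(residence_xy)
    d = network.nearest_node(injury_xy)
    return DistancePair(euclidean_m=eu, network_m=network.shortest_path_length(o, d))


def annotate_distances(records: RecordSet, network: RoadNetwork) -> RecordSet:
    """Return a new RecordSet with per-record Euclidean and network distances.

    Unreachable pairs get ``network_distance_m = inf`` and are counted in
    the module log; callers exclude them from distance summaries.
    """
    out = []
    unreachable = 0
    for rec in records:
        pair = distance_pair(network, rec.residence_xy, rec.injury_xy)
        if not pair.reachable:
            unreachable += 1
            log.warning("record %s: snapped nodes are disconnected", rec.record_id)
        out.append(replace(rec, euclidean_distance_m=pair.euclidean_m,
                           network_distance_m=pair.network_m))
    if unreachable:
        log.info("annotate_distances: %d of %d pairs unreachable", unreachable, len(out))
    return RecordSet(out, provenance=records.provenance)
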
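"""Actor influence networks and their indicators.

Interviews classified how strongly each actor influences each other actor's
decisions, per topic, on an ordinal scale: none, low (advisory), high
(e.g. financial dependency), mandatory.  The levels map onto edge weights
0/1/2/3; a "none" entry creates no edge.  Three indicators are computed per
actor: weighted indegree (influence experienced), weighted outdegree
(influence exerted), and unnormalized betweenness centrality on the
unweighted directed graph (the influence weights are ordinal, not
distances, so shortest paths are hop counts).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

import networkx as nx
import pandas as pd

__all__ = [
    "INFLUENCE_WEIGHTS",
    "InfluenceMatrix",
    "build_topic_network",
    "weighted_degree",
    "betweenness_centrality",
    "network_indicators",
    "export_graphml",
    "import_graphml",
    "load_fixture_matrix",
    "read_matrix_csv",
]

INFLUENCE_WEIGHTS = {"none": 0, "low": 1, "high": 2, "mandatory": 3}

TOPICS = ("FoA1_3", "FoA2", "FoA4")

#: Actor roster of the influence network.  Unlike the belief network, the
#: influence network keeps Farmers and Farmer organizations as their own
#: nodes.
ROSTER = (
    "Farmers", "Consumers", "Retail", "Province", "NL&EU",
    "Network", "Farmer organizations", "Labels",
)


@dataclass
class InfluenceMatrix:
    """Qualitative source -> target influence entries for one topic."""

    topic: str
    roster: tuple[str, ...] = ROSTER
    entries: dict = field(default_factory=dict)  # (source, target) -> level

    def set(self, source: str, target: str, level: str) -> None:
        if source == target:
            raise ValueError("self-influence entries are not allowed")
        for actor in (source, target):
            if actor not in self.roster:
                raise KeyError(f"actor {actor!r} not in roster")
        if level not in INFLUENCE_WEIGHTS:
            raise ValueError(f"unknown influence level {level!r}")
        self.entries[(source, target)] = level


def build_topic_network(matrix: InfluenceMatrix) -> nx.DiGraph:
    """Directed weighted graph over the full roster (isolates included)."""
    g = nx.DiGraph(topic=matrix.topic)
    g.add_nodes_from(matrix.roster)
    for (source, target), level in matrix.entries.items():
        for actor in (source, target):
            if actor not in matrix.roster:
                raise KeyError(f"actor {actor!r} not in roster")
        w = INFLUENCE_WEIGHTS[level]
        if w > 0:
            g.add_edge(source, target, weight=w, level=level)
    return g


def weighted_degree(graph: nx.DiGraph, actor: str, direction: str = "in") -> float:
    """Sum of incident edge weights (``direction`` 'in' or 'out')."""
    if actor not in graph:
        raise KeyError(f"actor {actor!r} not in graph")
    if direction == "in":
        return float(graph.in_degree(actor, weight="weight"))
    if direction == "out":
        return float(graph.out_degree(actor, weight="weight"))
    raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")


def betweenness_centrality(graph: nx.DiGraph) -> dict[str, float]:
    """Unnormalized betweenness on the unweighted directed graph.

    Counts, for each node, the ordered source-target pairs whose shortest
    paths pass through it, with fractional credit when several shortest
    paths exist.
    """
    return nx.betweenness_centrality(graph, normalized=False, weight=None)


def network_indicators(graph: nx.DiGraph) -> pd.DataFrame:
    """Per-actor indicator table (weighted in/outdegree, betweenness)."""
    btw = betweenness_centrality(graph)
    rows = [
        {
            "actor": a,
            "weighted_indegree": weighted_degree(graph, a, "in"),
            "weighted_outdegree": weighted_degree(graph, a, "out"),
            "betweenness": btw[a],
        }
        for a in graph.nodes
    ]
    return pd.DataFrame(rows)


def export_graphml(graph: nx.DiGraph, path) -> None:
    nx.write_graphml(graph, path)


def import_graphml(path) -> nx.DiGraph:
    g = nx.read_graphml(path)
    out = nx.DiGraph(**g.graph)
    out.add_nodes_from(g.nodes)
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, weight=int(d.get("weight", 1)), level=d.get("level", ""))
    return out


def read_matrix_csv(path_or_buffer, topic: str, roster=ROSTER) -> InfluenceMatrix:
    """Read entries for one topic from a CSV with columns
    source,target,topic,level."""
    matrix = InfluenceMatrix(topic=topic, roster=tuple(roster))
    if hasattr(path_or_buffer, "read"):
        rows = list(csv.DictReader(path_or_buffer))
    else:
        with open(path_or_buffer, newline="") as fh:
            rows = list(csv.DictReader(fh))
    for row in rows:
        if row["topic"] != topic:
            continue
        matrix.set(row["source"], row["target"], row["level"])
    return matrix


def load_fixture_matrix(topic: str) -> InfluenceMatrix:
    """The packaged influence matrix for one topic.

    The empirical matrix is not public; the shipped matrix is a synthetic
    reconstruction consistent with the qualitative findings: farmers have
    the highest weighted indegree on every topic, and on direct sales
    (FoA4) additionally the highest outdegree and betweenness.
    """
    ref = resources.files("siactors").joinpath("data/influence_matrix_synthetic.csv")
    with ref.open("r", newline="") as fh:
        return read_matrix_csv(fh, topic)
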
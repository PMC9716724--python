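"""Indirect-association social networks and relatedness-based genetic networks.

The social network follows the gambit of the group over survey occasions:
every pair of individuals detected on the same occasion is considered
associated, and an edge's weight is the number of occasions on which the
pair co-occurred. The genetic network links pairs whose pairwise
relatedness reaches the relatedness cutoff (default 0.125), weighting
edges by R itself (or optionally by kin-class rank). Both are undirected
:class:`networkx.Graph` objects carrying per-node sex and age-class
attributes and a ``kind`` graph attribute.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genotyping import IndividualRecord
from .relatedness import RelatednessMatrix, classify_kin
from .simdata import SurveyDetection

__all__ = [
    "build_social_network",
    "build_genetic_network",
    "network_metrics",
    "NetworkMetrics",
    "summary_from_counts",
    "association_matrix",
]


def _add_nodes(net: nx.Graph, individuals: Sequence[IndividualRecord]) -> None:
    for ind in sorted(individuals, key=lambda i: i.individual_id):
        net.add_node(ind.individual_id, sex=ind.sex, age_class=ind.age_class)


def build_social_network(
    detections: Iterable[SurveyDetection | tuple[str, str]],
    individuals: Sequence[IndividualRecord],
) -> nx.Graph:
    """Social network from per-survey detections (gambit of the group).

    All individuals detected on one survey occasion are pairwise
    associated; the edge weight counts the occasions on which a pair
    co-occurred. Individuals never detected remain isolated nodes.
    Detections of individuals absent from the individuals table are an
    error (they indicate an upstream bookkeeping bug).
    """
    known = {ind.individual_id for ind in individuals}
    by_survey: dict[str, set[str]] = {}
    offenders = set()
    for det in detections:
        survey, ind_id = (
            (det.survey_id, det.individual_id)
            if isinstance(det, SurveyDetection)
            else (det[0], det[1])
        )
        if ind_id not in known:
            offenders.add(ind_id)
            continue
        by_survey.setdefault(survey, set()).add(ind_id)
    if offenders:
        raise ValueError(
            f"detections reference unknown individuals: {sorted(offenders)}"
        )

    net = nx.Graph(kind="social")
    _add_nodes(net, individuals)
    for members in by_survey.values():
        for a, b in itertools.combinations(sorted(members), 2):
            if net.has_edge(a, b):
                net[a][b]["weight"] += 1
            else:
                net.add_edge(a, b, weight=1)
    return net


def build_genetic_network(
    matrix: RelatednessMatrix,
    individuals: Sequence[IndividualRecord],
    threshold: float = 0.125,
    weight_by: str = "r",
) -> nx.Graph:
    """Genetic network: edge iff R >= threshold, weighted by R.

    The kin class of each edge is stored as an edge attribute.
    ``weight_by='class_rank'`` weights first/second/third-class edges
    3/2/1 instead of by R. Masked pairs contribute no edge.
    """
    if len(matrix.ids) < 2:
        raise ValueError("genetic network requires >= 2 individuals")
    if weight_by not in ("r", "class_rank"):
        raise ValueError("weight_by must be 'r' or 'class_rank'")
    by_id = {ind.individual_id: ind for ind in individuals}
    net = nx.Graph(kind="genetic")
    _add_nodes(net, [by_id[i] for i in matrix.ids])
    rank = {"first": 3.0, "second": 2.0, "third": 1.0}
    n_masked = 0
    for a, b, r in matrix.pairs():
        if not np.isfinite(r):
            n_masked += 1
            continue
        if r >= threshold:
            cls = classify_kin(r, unrelated_cutoff=threshold)
            w = r if weight_by == "r" else rank.get(cls, 1.0)
            net.add_edge(a, b, weight=w, kin_class=cls, r=r)
    net.graph["n_masked_pairs"] = n_masked
    return net


@dataclass
class NetworkMetrics:
    """Node- and graph-level summaries of an attributed network."""

    nodes: pd.DataFrame  # node, degree, strength, degree_centrality
    n_nodes: int
    n_edges: int
    connectance: float
    mean_degree: float
    sd_degree: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "connectance": self.connectance,
            "mean_degree": self.mean_degree,
            "sd_degree": self.sd_degree,
        }


def network_metrics(net: nx.Graph) -> NetworkMetrics:
    """Degree, strength (weighted degree) and degree centrality per node;
    edge count, connectance and mean +- SD degree for the graph."""
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("metrics require >= 2 nodes")
    order = sorted(net.nodes)
    degree = np.array([net.degree(v) for v in order], dtype=float)
    strength = np.array([net.degree(v, weight="weight") for v in order], dtype=float)
    centrality = nx.degree_centrality(net)
    nodes = pd.DataFrame(
        {
            "node": order,
            "degree": degree.astype(int),
            "strength": strength,
            "degree_centrality": [centrality[v] for v in order],
        }
    )
    m = net.number_of_edges()
    return NetworkMetrics(
        nodes=nodes,
        n_nodes=n,
        n_edges=m,
        connectance=m / (n * (n - 1) / 2),
        mean_degree=float(degree.mean()),
        sd_degree=float(degree.std(ddof=1)) if n > 1 else 0.0,
    )


def summary_from_counts(n_nodes: int, n_edges: int) -> dict[str, float]:
    """Connectance and mean degree implied by node and edge counts alone.

    Used to validate reported whole-network summaries: e.g. a survey of 33
    individuals with 336 associated dyads implies connectance
    336/528 = 0.636 and mean degree 2*336/33 = 20.364.
    """
    if n_nodes < 2:
        raise ValueError("need >= 2 nodes")
    return {
        "connectance": n_edges / (n_nodes * (n_nodes - 1) / 2),
        "mean_degree": 2 * n_edges / n_nodes,
    }


def association_matrix(net: nx.Graph, ids: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Square weighted adjacency (association count / R) matrix of a network."""
    order = list(ids) if ids is not None else sorted(net.nodes)
    mat = nx.to_numpy_array(net, nodelist=order, weight="weight")
    return order, mat
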
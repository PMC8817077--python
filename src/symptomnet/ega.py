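"""Exploratory graph analysis: community detection on the estimated network.

EGA assesses the dimensionality of a questionnaire by estimating a
regularised partial-correlation network and detecting its communities with
the walktrap algorithm: short random walks tend to stay inside densely
connected clusters, and agglomerative merging driven by walk distances
builds a dendrogram whose maximum-modularity cut is returned.  Each
community is read as one latent symptom dimension.

Random-walk transition probabilities require non-negative weights, so
walktrap runs on the absolute partial correlations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import igraph as ig
import networkx as nx
import numpy as np

from .data import ResponseMatrix
from .glasso import Network, correlation, ebic_glasso

__all__ = ["Partition", "EGAResult", "EGAConfig", "walktrap", "layout_fr", "ega"]


@dataclass
class Partition:
    """Item -> community assignment with contiguous ids 1..K."""

    assignment: dict[str, int]
    n_communities: int
    modularity: float

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids != list(range(1, self.n_communities + 1)):
            raise ValueError("community ids must be contiguous 1..K")

    def membership(self, node_codes: tuple[str, ...]) -> np.ndarray:
        return np.array([self.assignment[c] for c in node_codes], dtype=int)

    def items_in(self, community: int) -> frozenset[str]:
        return frozenset(
            c for c, k in self.assignment.items() if k == community
        )


@dataclass
class EGAConfig:
    """Knobs of the EGA pipeline with the conventional defaults."""

    corr_method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.1
    steps: int = 4
    layout_seed: int = 0
    #: A multi-community walktrap solution whose modularity falls below this
    #: value is treated as structureless and collapsed to one community
    #: (unidimensional data otherwise picks up spurious near-zero-Q splits).
    min_modularity: float = 0.05


@dataclass
class EGAResult:
    network: Network
    partition: Partition
    layout: Optional[np.ndarray] = None  # p x 2 coordinates


def _relabel_first_appearance(membership: np.ndarray) -> np.ndarray:
    """Deterministic labels: community 1 is the first node's community, etc."""
    mapping: dict[int, int] = {}
    out = np.empty_like(membership)
    for i, c in enumerate(membership):
        if c not in mapping:
            mapping[c] = len(mapping) + 1
        out[i] = mapping[c]
    return out


def _weighted_graph(network: Network) -> tuple[ig.Graph, list[float]]:
    A = np.abs(network.weights)
    p = network.p
    g = ig.Graph()
    g.add_vertices(p)
    edges, weights = [], []
    for i in range(p):
        for j in range(i + 1, p):
            if A[i, j] > 0:
                edges.append((i, j))
                weights.append(float(A[i, j]))
    g.add_edges(edges)
    return g, weights


def walktrap(network: Network, steps: int = 4) -> Partition:
    """Random-walk community detection on absolute edge weights.

    Returns the maximum-modularity partition of the walktrap merge tree;
    isolated nodes end up as singleton communities.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    g, weights = _weighted_graph(network)
    if not weights:
        warnings.warn("network has no edges; every node is its own community")
        membership = np.arange(1, network.p + 1)
        return Partition(
            assignment=dict(zip(network.node_codes, membership.tolist())),
            n_communities=network.p,
            modularity=0.0,
        )
    dendrogram = g.community_walktrap(weights=weights, steps=steps)
    clustering = dendrogram.as_clustering()
    membership = _relabel_first_appearance(np.asarray(clustering.membership))
    q = g.modularity(clustering.membership, weights=weights)
    return Partition(
        assignment=dict(zip(network.node_codes, membership.tolist())),
        n_communities=int(membership.max()),
        modularity=float(q),
    )


def layout_fr(network: Network, seed: int = 0) -> np.ndarray:
    """Force-directed (Fruchterman-Reingold) coordinates, deterministic per seed."""
    G = nx.Graph()
    G.add_nodes_from(range(network.p))
    A = np.abs(network.weights)
    for i in range(network.p):
        for j in range(i + 1, network.p):
            if A[i, j] > 0:
                G.add_edge(i, j, weight=float(A[i, j]))
    pos = nx.spring_layout(G, weight="weight", seed=seed)
    return np.array([pos[i] for i in range(network.p)], dtype=float)


def ega(
    m: ResponseMatrix,
    config: Optional[EGAConfig] = None,
    compute_layout: bool = True,
) -> EGAResult:
    """Full exploratory graph analysis of a complete-case, scored matrix.

    correlation -> EBIC-selected graphical lasso -> walktrap -> layout.
    """
    cfg = config or EGAConfig()
    S = correlation(m, method=cfg.corr_method)
    network = ebic_glasso(
        S,
        gamma=cfg.gamma,
        n_lambda=cfg.n_lambda,
        lambda_min_ratio=cfg.lambda_min_ratio,
    )
    partition = walktrap(network, steps=cfg.steps)
    if (
        1 < partition.n_communities < network.p
        and partition.modularity < cfg.min_modularity
    ):
        partition = Partition(
            assignment={c: 1 for c in network.node_codes},
            n_communities=1,
            modularity=0.0,
        )
    layout = layout_fr(network, seed=cfg.layout_seed) if compute_layout else None
    return EGAResult(network=network, partition=partition, layout=layout)
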
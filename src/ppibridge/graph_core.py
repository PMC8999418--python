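"""Undirected, confidence-weighted protein-interaction graph and its primitive queries.

The network model is deliberately simple: genes are nodes, each evidenced
protein-protein association is a single undirected edge carrying one combined
confidence in [0, 1], and edges below a retention threshold are discarded at
construction time.  Directionality and evidence-channel decomposition are out
of scope — the downstream classification and label-propagation steps only ask
"who interacts with whom, and how confidently".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["PPINetwork", "Component", "build_network", "neighbors", "connected_components"]


@dataclass
class PPINetwork:
    """A simple undirected PPI graph with per-edge confidence scores.

    Parameters
    ----------
    graph
        The underlying :class:`networkx.Graph`; every edge carries a
        ``confidence`` attribute in ``[threshold, 1]``.
    threshold
        Minimum confidence retained at construction.  Kept on the network so
        downstream steps (bridge validity, manifests) can refer to it.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    threshold: float = 0.4

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def has_node(self, gene: str) -> bool:
        return self.graph.has_node(gene)

    def has_edge(self, a: str, b: str) -> bool:
        return self.graph.has_edge(a, b)

    def confidence(self, a: str, b: str) -> float:
        """Confidence of the (unordered) edge {a, b}; KeyError if absent."""
        if not self.graph.has_edge(a, b):
            raise KeyError(f"no edge between {a!r} and {b!r}")
        return self.graph.edges[a, b]["confidence"]

    def edges(self) -> Iterable[tuple[str, str, float]]:
        for a, b, conf in self.graph.edges(data="confidence"):
            yield a, b, conf


@dataclass(frozen=True)
class Component:
    """A connected component: a set of genes whose induced subgraph is connected."""

    members: frozenset[str]

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members


def build_network(records: Iterable, threshold: float = 0.4) -> PPINetwork:
    """Build a thresholded PPI graph from edge records.

    Records may be :class:`~ppibridge.network_io.EdgeRecord` instances or any
    ``(gene_a, gene_b, confidence)`` triples.  Duplicate pairs (including the
    reversed orientation, which STRING flat files always list) are merged
    keeping the maximum confidence; edges whose merged confidence falls below
    ``threshold`` are excluded, but their endpoints are retained as isolated
    declared nodes.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    g = nx.Graph()
    n_merged = 0
    for rec in records:
        a, b, conf = rec[0], rec[1], float(rec[2])
        if a == b:
            raise ValueError(f"self-loop {a!r} reached build_network; drop at parse")
        g.add_node(a)
        g.add_node(b)
        if g.has_edge(a, b):
            n_merged += 1
            if conf > g.edges[a, b]["confidence"]:
                g.edges[a, b]["confidence"] = conf
        else:
            g.add_edge(a, b, confidence=conf)
    if n_merged:
        logger.debug("merged %d duplicate edge rows (max confidence kept)", n_merged)
    below = [(a, b) for a, b, c in g.edges(data="confidence") if c < threshold]
    g.remove_edges_from(below)
    if below:
        logger.debug("excluded %d edges below threshold %.3f", len(below), threshold)
    return PPINetwork(graph=g, threshold=threshold)


def neighbors(network: PPINetwork, gene: str) -> dict[str, float]:
    """Map each interaction partner of ``gene`` to the edge confidence."""
    if not network.has_node(gene):
        raise KeyError(f"gene {gene!r} is not in the network")
    return {nbr: data["confidence"] for nbr, data in network.graph[gene].items()}


def connected_components(
    network: PPINetwork, restrict_to: Optional[set[str]] = None
) -> list[Component]:
    """Connected components, optionally on the subgraph induced by ``restrict_to``.

    Ordering is deterministic: descending size, ties broken by the
    lexicographically smallest member, so reports are reproducible
    byte-for-byte.
    """
    if restrict_to is not None:
        missing = set(restrict_to) - network.nodes
        if missing:
            raise KeyError(f"restriction set contains unknown genes: {sorted(missing)}")
        g = network.graph.subgraph(restrict_to)
    else:
        g = network.graph
    comps = [Component(frozenset(c)) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), min(c.members)))
    return comps
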
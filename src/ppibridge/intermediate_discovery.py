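"""Connectivity classification and bridge (intermediate) gene selection.

Given a disease gene list and a thresholded PPI network, input genes are
sorted into connectivity classes:

* **Group A** — input genes with at least one direct interaction with another
  input gene; the largest connected component of their induced subgraph is the
  *main component* (the disease module's core).
* **Group B** — input genes outside Group A for which a single intermediate
  gene can be found that links them to the main component.
* **Group C** — input genes that cannot be bridged even through an
  intermediate.
* **Group D** — the selected intermediates themselves: genes outside the input
  list that interact both with a Group B gene and with the main component.
  These are the candidate novel disease genes the protocol proposes.

Exactly one intermediate is paired with each Group B gene, chosen to maximize
a confidence-based bridge score; distinct B genes may share an intermediate,
which keeps the augmented map small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .graph_core import PPINetwork, connected_components, neighbors
from .network_io import GeneList

logger = logging.getLogger(__name__)

__all__ = [
    "GeneClassification",
    "BridgeCandidate",
    "SCORE_STRATEGIES",
    "classify_connectivity",
    "enumerate_bridge_candidates",
    "select_intermediates",
    "assemble_augmented_network",
]


@dataclass(frozen=True)
class BridgeCandidate:
    """A scored candidate intermediate for one disconnected input gene.

    ``score`` under the default strategy is the sum of the two legs every
    bridge must have: the confidence to the B gene plus the best confidence
    into the main component.
    """

    candidate: str
    b_gene: str
    conf_to_b: float
    best_conf_to_main: float
    links_to_main: int
    score: float


@dataclass
class GeneClassification:
    """Partition of the input genes into A/B/C plus the B -> D bridge pairing."""

    group_a: set[str] = field(default_factory=set)
    group_b: set[str] = field(default_factory=set)
    group_c: set[str] = field(default_factory=set)
    bridges: dict[str, str] = field(default_factory=dict)
    main_component: set[str] = field(default_factory=set)
    #: full scoring detail for each selected bridge, keyed by B gene
    bridge_details: dict[str, BridgeCandidate] = field(default_factory=dict)
    complete: bool = False

    @property
    def intermediates(self) -> set[str]:
        return set(self.bridges.values())

    @property
    def input_genes(self) -> set[str]:
        return self.group_a | self.group_b | self.group_c


# Pluggable bridge scores.  Each takes (conf_to_b, confs_to_main) where
# confs_to_main are the candidate's edge confidences into the main component.
SCORE_STRATEGIES: dict[str, Callable[[float, list[float]], float]] = {
    # two strongest legs: confidence to the B gene + best confidence to core
    "two_leg_sum": lambda cb, cm: cb + max(cm),
    # reward many strong anchors in the core
    "all_links_sum": lambda cb, cm: cb + sum(cm),
    # conservative: a bridge is only as good as its weakest leg
    "min_leg": lambda cb, cm: min(cb, max(cm)),
}


def classify_connectivity(network: PPINetwork, input_genes: GeneList) -> GeneClassification:
    """Split input genes into directly-connected (A) and disconnected sets.

    A gene is Group A iff it has at least one retained edge to another input
    gene.  All remaining genes are provisionally placed in Group B; bridge
    selection (:func:`select_intermediates`) later demotes the unbridgeable
    ones to Group C.  The main component is the largest connected component of
    the subgraph induced on Group A (size ties broken by the component
    containing the lexicographically smallest gene).
    """
    gene_set = set(input_genes)
    missing = sorted(g for g in gene_set if not network.has_node(g))
    if missing:
        raise KeyError(
            f"input genes absent from network (run apply_alias_map first): {missing}"
        )
    group_a = {
        g for g in gene_set if any(nbr in gene_set for nbr in network.graph[g])
    }
    non_a = gene_set - group_a
    main: set[str] = set()
    if group_a:
        comps = connected_components(network, restrict_to=group_a)
        main = set(comps[0].members)
    logger.info(
        "classify_connectivity: %d/%d genes directly connected, %d disconnected, "
        "main component size %d",
        len(group_a), len(gene_set), len(non_a), len(main),
    )
    return GeneClassification(
        group_a=group_a, group_b=set(non_a), main_component=main
    )


def enumerate_bridge_candidates(
    network: PPINetwork,
    b_gene: str,
    main_component: set[str],
    input_genes: set[str],
    strategy: str = "two_leg_sum",
) -> list[BridgeCandidate]:
    """All valid intermediates for one disconnected gene, best first.

    Valid candidates are exactly the non-input neighbors of ``b_gene`` that
    also have at least one edge into the main component.  Ordering is by
    descending score, then more links into the main component, then
    lexicographically smaller symbol — fully deterministic.
    """
    if b_gene in main_component:
        raise ValueError(f"{b_gene} is already in the main component")
    score_fn = SCORE_STRATEGIES[strategy]
    out: list[BridgeCandidate] = []
    for cand, conf_to_b in neighbors(network, b_gene).items():
        if cand in input_genes:
            continue
        confs_to_main = [
            c for nbr, c in neighbors(network, cand).items() if nbr in main_component
        ]
        if not confs_to_main:
            continue
        out.append(
            BridgeCandidate(
                candidate=cand,
                b_gene=b_gene,
                conf_to_b=conf_to_b,
                best_conf_to_main=max(confs_to_main),
                links_to_main=len(confs_to_main),
                score=score_fn(conf_to_b, confs_to_main),
            )
        )
    out.sort(key=lambda c: (-c.score, -c.links_to_main, c.candidate))
    return out


def select_intermediates(
    network: PPINetwork,
    classification: GeneClassification,
    strategy: str = "two_leg_sum",
) -> GeneClassification:
    """Pair each disconnected input gene with its best-scoring intermediate.

    Genes with no valid candidate move to Group C.  Intermediates may be
    shared between B genes (this keeps the augmented map minimal).  The
    completed classification satisfies: every bridge touches its B gene and
    the main component at the network threshold.
    """
    input_genes = classification.input_genes
    group_b: set[str] = set()
    group_c: set[str] = set()
    bridges: dict[str, str] = {}
    details: dict[str, BridgeCandidate] = {}
    for gene in sorted(classification.group_b | classification.group_c):
        cands = enumerate_bridge_candidates(
            network, gene, classification.main_component, input_genes, strategy
        )
        if cands:
            best = cands[0]
            group_b.add(gene)
            bridges[gene] = best.candidate
            details[gene] = best
        else:
            group_c.add(gene)
    if group_c:
        logger.warning("select_intermediates: %d unbridgeable genes: %s",
                       len(group_c), sorted(group_c))
    logger.info("select_intermediates: %d bridges selected (%d distinct intermediates)",
                len(bridges), len(set(bridges.values())))
    return GeneClassification(
        group_a=set(classification.group_a),
        group_b=group_b,
        group_c=group_c,
        bridges=bridges,
        main_component=set(classification.main_component),
        bridge_details=details,
        complete=True,
    )


def assemble_augmented_network(
    network: PPINetwork, classification: GeneClassification
) -> PPINetwork:
    """Induce the subnetwork on input genes plus selected intermediates.

    If Group C is empty, the augmented graph restricted to A, B and the
    intermediates is connected through the main component.  Unbridgeable genes
    remain as isolated, flagged nodes.
    """
    if not classification.complete:
        raise ValueError("classification is incomplete; run select_intermediates first")
    keep = classification.input_genes | classification.intermediates
    sub = network.graph.subgraph(keep).copy()
    return PPINetwork(graph=sub, threshold=network.threshold)
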
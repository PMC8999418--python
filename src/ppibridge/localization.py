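"""Iterative localization-group assignment and inter/intragroup connectivity.

Genes are assigned to cellular-localization groups (in the retinal preset:
1 = retinal pigment epithelium, 2 = photoreceptor outer segment, 3 = connecting
cilium, 4 = nucleus) by iterated PPI-count majority against an initial seed
assignment.  The biological premise is that interacting proteins tend to
reside in the same or adjacent compartments, so a gene's interaction partners
vote for its compartment.

Rounds are batch-synchronous: within a round every still-unassigned gene is
evaluated against the assignment frozen at round start, which makes the result
independent of gene enumeration order.  A gene joins the group with the most
edges among already-assigned genes; a tie in edge count is broken by the
larger sum of edge confidences; a residual tie defers the gene one round and,
if it ties again, forces the lowest tied group index with a warning.  Genes
with no edge into any assigned group stay unassigned and are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .graph_core import PPINetwork
from .intermediate_discovery import GeneClassification

logger = logging.getLogger(__name__)

__all__ = [
    "LocalizationAssignment",
    "ConnectivityMatrix",
    "GROUP_NAMES_RETINAL",
    "assign_groups",
    "place_intermediates",
    "connectivity_matrix",
]

GROUP_NAMES_RETINAL = {1: "RPE", 2: "OS", 3: "connecting_cilium", 4: "nucleus"}


@dataclass
class LocalizationAssignment:
    """Gene -> group map with seed flags and the round each gene was assigned.

    ``iteration_assigned`` is 0 for seeds; ``unassigned`` holds genes that
    never gained an edge into any assigned group.
    """

    assignment: dict[str, int] = field(default_factory=dict)
    is_seed: dict[str, bool] = field(default_factory=dict)
    iteration_assigned: dict[str, int] = field(default_factory=dict)
    unassigned: set[str] = field(default_factory=set)
    n_groups: int = 4


def assign_groups(
    network: PPINetwork,
    universe: set[str],
    seeds: Mapping[str, int],
    max_iterations: int = 100,
    n_groups: Optional[int] = None,
) -> LocalizationAssignment:
    """Propagate seed group labels through the PPI network by count majority.

    Parameters
    ----------
    network
        The thresholded PPI network.
    universe
        Genes to assign (must all be network nodes).
    seeds
        Initial gene -> group assignment; seeds are never reassigned.
    max_iterations
        Upper bound on propagation rounds.
    n_groups
        Number of groups; defaults to the largest seed group index (at least 4
        in the retinal preset sense only if seeds say so).
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    missing_seeds = sorted(set(seeds) - set(universe))
    if missing_seeds:
        raise KeyError(f"seed genes absent from universe: {missing_seeds}")
    missing_nodes = sorted(set(universe) - network.nodes)
    if missing_nodes:
        raise KeyError(f"universe genes absent from network: {missing_nodes}")
    if n_groups is None:
        n_groups = max(seeds.values(), default=0)
    if any(not 1 <= g <= n_groups for g in seeds.values()):
        raise ValueError(f"seed group indices must be in 1..{n_groups}")

    assignment: dict[str, int] = dict(seeds)
    iteration_assigned: dict[str, int] = {g: 0 for g in seeds}
    pending = set(universe) - set(seeds)
    deferred_ties: set[str] = set()

    for rnd in range(1, max_iterations + 1):
        frozen = dict(assignment)
        newly: dict[str, int] = {}
        next_deferred: set[str] = set()
        for gene in sorted(pending):
            counts = np.zeros(n_groups, dtype=int)
            conf_sums = np.zeros(n_groups, dtype=float)
            for nbr, data in network.graph[gene].items():
                grp = frozen.get(nbr)
                if grp is not None:
                    counts[grp - 1] += 1
                    conf_sums[grp - 1] += data["confidence"]
            if counts.sum() == 0:
                continue
            best = counts.max()
            tied = np.flatnonzero(counts == best)
            if len(tied) > 1:
                best_conf = conf_sums[tied].max()
                tied = tied[np.isclose(conf_sums[tied], best_conf)]
            if len(tied) > 1:
                if gene in deferred_ties:
                    group = int(tied[0]) + 1
                    logger.warning(
                        "assign_groups: residual tie for %s among groups %s; "
                        "forcing lowest index %d",
                        gene, [int(t) + 1 for t in tied], group,
                    )
                else:
                    next_deferred.add(gene)
                    continue
            else:
                group = int(tied[0]) + 1
            newly[gene] = group
        for gene, group in newly.items():
            assignment[gene] = group
            iteration_assigned[gene] = rnd
        pending -= set(newly)
        deferred_ties = next_deferred
        if not pending:
            break
        if not newly and not next_deferred:
            break  # deadlock: remaining genes have no edge to any assigned gene

    if pending:
        logger.warning("assign_groups: %d genes left unassigned: %s",
                       len(pending), sorted(pending))
    return LocalizationAssignment(
        assignment=assignment,
        is_seed={g: (g in seeds) for g in assignment},
        iteration_assigned=iteration_assigned,
        unassigned=set(pending),
        n_groups=n_groups,
    )


def place_intermediates(
    assignment: LocalizationAssignment, classification: GeneClassification
) -> LocalizationAssignment:
    """Place each intermediate in the group of its paired disconnected gene.

    Inheritance only — the intermediate's group is not used for further
    propagation.  An intermediate shared by B genes in different groups
    inherits from the lexicographically smallest partner, with a warning.
    """
    partners: dict[str, list[str]] = {}
    for b_gene, bridge in classification.bridges.items():
        partners.setdefault(bridge, []).append(b_gene)

    out = LocalizationAssignment(
        assignment=dict(assignment.assignment),
        is_seed=dict(assignment.is_seed),
        iteration_assigned=dict(assignment.iteration_assigned),
        unassigned=set(assignment.unassigned),
        n_groups=assignment.n_groups,
    )
    for bridge, b_genes in sorted(partners.items()):
        b_genes = sorted(b_genes)
        unplaced = [b for b in b_genes if b not in assignment.assignment]
        if unplaced:
            raise KeyError(
                f"bridge partner(s) unassigned for intermediate {bridge}: {unplaced}"
            )
        groups = {assignment.assignment[b] for b in b_genes}
        chosen_partner = b_genes[0]
        group = assignment.assignment[chosen_partner]
        if len(groups) > 1:
            logger.warning(
                "place_intermediates: %s shared by partners in groups %s; "
                "inheriting group %d from %s",
                bridge, sorted(groups), group, chosen_partner,
            )
        out.assignment[bridge] = group
        out.is_seed[bridge] = False
        out.iteration_assigned[bridge] = assignment.iteration_assigned[chosen_partner]
    return out


@dataclass
class ConnectivityMatrix:
    """Symmetric group-by-group edge-count summary.

    ``counts[i, j]`` (0-based) is the number of network edges with one
    endpoint assigned to group ``i+1`` and the other to group ``j+1``; the
    diagonal holds intragroup edges, each counted once.  ``intermediate_links``
    counts, per group, the gene-side incidences of edges that touch an
    intermediate gene (reported separately; intermediates also contribute to
    ``counts`` through their inherited group).
    """

    counts: np.ndarray
    intermediate_links: np.ndarray
    n_groups: int = 4

    def lower_triangular_total(self) -> int:
        return int(np.tril(self.counts).sum())

    def to_dataframe(self):
        import pandas as pd

        labels = [str(i + 1) for i in range(self.n_groups)]
        df = pd.DataFrame(self.counts, index=labels, columns=labels)
        df.loc["intermediate_links"] = self.intermediate_links
        return df


def connectivity_matrix(
    network: PPINetwork,
    assignment: LocalizationAssignment,
    classification: Optional[GeneClassification] = None,
) -> ConnectivityMatrix:
    """Count inter- and intragroup edges of a fully assigned network.

    Every undirected edge whose endpoints are both assigned contributes
    exactly once to the symmetric count matrix.  An edge with an unassigned
    endpoint is an error (listing the offenders) — run assignment and
    intermediate placement first, or pass the augmented network only.
    """
    n = assignment.n_groups
    counts = np.zeros((n, n), dtype=int)
    inter_links = np.zeros(n, dtype=int)
    intermediates = classification.intermediates if classification is not None else set()

    unassigned: set[str] = set()
    for a, b, _conf in network.edges():
        ga = assignment.assignment.get(a)
        gb = assignment.assignment.get(b)
        if ga is None or gb is None:
            unassigned.update(x for x, g in ((a, ga), (b, gb)) if g is None)
            continue
        i, j = sorted((ga - 1, gb - 1))
        counts[i, j] += 1
        if i != j:
            counts[j, i] += 1
        if a in intermediates or b in intermediates:
            # count the incidence on each non-intermediate endpoint's group;
            # an intermediate-intermediate edge counts on both inherited groups
            for x, gx in ((a, ga), (b, gb)):
                other = b if x == a else a
                if other in intermediates:
                    inter_links[gx - 1] += 1
    if unassigned:
        raise KeyError(f"edges touch unassigned genes: {sorted(unassigned)}")
    return ConnectivityMatrix(counts=counts, intermediate_links=inter_links, n_groups=n)
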
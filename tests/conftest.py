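"""Shared fixtures and independent brute-force oracles.

The oracles work directly on raw ``(gene_a, gene_b, confidence)`` triples with
hand-rolled adjacency and union-find, so they share no code path with the
package's networkx-backed implementation.
"""

from __future__ import annotations

import random

import pytest
from hypothesis import settings

from ppibridge.graph_core import build_network
from ppibridge.network_io import EdgeRecord, GeneList

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def oracle_adjacency(records, threshold):
    """Adjacency dict from raw triples: max-merged, thresholded."""
    adj: dict[str, dict[str, float]] = {}
    for a, b, conf in records:
        adj.setdefault(a, {})
        adj.setdefault(b, {})
        if b in adj[a]:
            conf = max(conf, adj[a][b])
        adj[a][b] = conf
        adj[b][a] = conf
    for a in adj:
        adj[a] = {b: c for b, c in adj[a].items() if c >= threshold}
    return adj


def oracle_components(nodes, adj):
    """Union-find connected components restricted to ``nodes``."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in nodes:
        for b in adj.get(a, {}):
            if b in parent:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)
    return sorted(comps.values(), key=lambda c: (-len(c), min(c)))


def oracle_classify_and_bridge(records, threshold, input_genes):
    """Exhaustive A/B/C + best-bridge selection on raw triples.

    Candidate enumeration scans *every* node of the graph rather than the
    implementation's one-hop neighbor shortcut; selection maximizes
    conf_to_b + best_conf_to_main with (links_to_main desc, symbol asc)
    tie-breaks.
    """
    adj = oracle_adjacency(records, threshold)
    input_set = set(input_genes)
    group_a = {
        g for g in input_set
        if any(nbr in input_set for nbr in adj.get(g, {}))
    }
    comps = oracle_components(group_a, adj) if group_a else []
    main = comps[0] if comps else set()
    bridges = {}
    group_b, group_c = set(), set()
    for gene in sorted(input_set - group_a):
        best = None
        for cand in sorted(adj):
            if cand in input_set:
                continue
            if gene not in adj.get(cand, {}):
                continue
            main_confs = [c for nbr, c in adj[cand].items() if nbr in main]
            if not main_confs:
                continue
            score = adj[cand][gene] + max(main_confs)
            key = (-score, -len(main_confs), cand)
            if best is None or key < best[0]:
                best = (key, cand)
        if best is None:
            group_c.add(gene)
        else:
            group_b.add(gene)
            bridges[gene] = best[1]
    return group_a, group_b, group_c, bridges, main


def oracle_group_edge_counts(edges, assignment, n_groups):
    """Double-loop edge scan into a symmetric group count matrix (list-of-lists)."""
    counts = [[0] * n_groups for _ in range(n_groups)]
    for a, b, _conf in edges:
        if a in assignment and b in assignment:
            i, j = sorted((assignment[a] - 1, assignment[b] - 1))
            counts[i][j] += 1
            if i != j:
                counts[j][i] += 1
    return counts


def random_records(rng: random.Random, n_nodes=None, n_edges=None):
    """A random scored edge list over <= 50 nodes, duplicates included."""
    n_nodes = n_nodes or rng.randint(5, 50)
    nodes = [f"G{i:02d}" for i in range(n_nodes)]
    n_edges = n_edges if n_edges is not None else rng.randint(0, 3 * n_nodes)
    records = []
    for _ in range(n_edges):
        a, b = rng.sample(nodes, 2)
        records.append(EdgeRecord(a, b, round(rng.uniform(0.05, 1.0), 3)))
    return nodes, records


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


@pytest.fixture
def toy_network():
    """Main pair A-B, disconnected gene X reachable only via candidate M."""
    records = [
        EdgeRecord("AAA", "BBB", 0.9),
        EdgeRecord("XXX", "MMM", 0.8),
        EdgeRecord("MMM", "AAA", 0.7),
    ]
    return build_network(records, threshold=0.4)


@pytest.fixture
def toy_gene_list():
    return GeneList(["AAA", "BBB", "XXX"], source_label="toy")
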
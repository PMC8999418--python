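"""Readers and writers for the pipeline's file formats.

Formats handled here:

* plain-text gene lists (one symbol per line, ``#`` comments),
* scored edge tables — the STRING protein-links dialect (whitespace-delimited,
  integer ``combined_score`` 0-999) and a generic 3-column TSV with float
  confidences in [0, 1],
* alias maps (2-column TSV: alias -> canonical symbol),
* seed localization-group files (2-column TSV: gene, group index),
* annotated network exports in GraphML, DOT and TSV.

Gene symbols are normalized on every read path: uppercased, stripped of
surrounding whitespace, and validated against ``[A-Z0-9_.-]+``.  Gene symbols
are case-insensitive in practice and source lists mix cases, so normalization
happens before any identity comparison.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import networkx as nx

from .graph_core import PPINetwork

logger = logging.getLogger(__name__)

__all__ = [
    "GeneList",
    "EdgeRecord",
    "ParsedEdgeTable",
    "normalize_symbol",
    "read_gene_list",
    "read_edge_table",
    "read_alias_map",
    "read_seed_groups",
    "apply_alias_map",
    "write_annotated_network",
    "read_annotated_graphml",
    "ROLE_COLORS",
    "GROUP_COLORS",
]

_SYMBOL_RE = re.compile(r"^[A-Z0-9_.\-]+$")

#: Node colors by connectivity role (direct = already-connected input gene,
#: bridged = input gene attached via an intermediate, intermediate = selected
#: bridge gene outside the input list, unbridgeable = no valid bridge found).
ROLE_COLORS = {
    "direct": "white",
    "bridged": "yellow",
    "intermediate": "green",
    "unbridgeable": "gray",
}

#: Edge endpoint colors by localization group (1=RPE, 2=OS, 3=connecting
#: cilium, 4=nucleus in the retinal preset).  Groups beyond 4 fall back to gray.
GROUP_COLORS = {1: "red", 2: "blue", 3: "green", 4: "purple"}


def normalize_symbol(raw: str) -> str:
    """Uppercase + strip a gene symbol; reject empty or malformed symbols."""
    sym = raw.strip().upper()
    if not sym:
        raise ValueError("empty gene symbol")
    if not _SYMBOL_RE.match(sym):
        raise ValueError(f"malformed gene symbol {raw!r}")
    return sym


@dataclass
class GeneList:
    """An ordered, duplicate-free list of normalized gene symbols."""

    genes: list[str]
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes


class EdgeRecord(NamedTuple):
    gene_a: str
    gene_b: str
    confidence: float


class ParsedEdgeTable(list):
    """A list of :class:`EdgeRecord` plus parse bookkeeping.

    Attributes
    ----------
    rejected_lines
        1-based line numbers of rows whose score could not be parsed.
    self_loops_dropped
        Number of rows dropped because both endpoints were the same gene.
    """

    def __init__(self, records: Iterable[EdgeRecord] = ()):
        super().__init__(records)
        self.rejected_lines: list[int] = []
        self.self_loops_dropped: int = 0


def read_gene_list(path: str | Path, source_label: Optional[str] = None) -> GeneList:
    """Read a one-symbol-per-line gene list.

    Lines starting with ``#`` are comments/headers; blank lines are skipped.
    Symbols are normalized and de-duplicated keeping the first occurrence, so
    ``RHO`` and ``rho`` collapse to one entry.  A file with no symbols at all
    is an error.
    """
    path = Path(path)
    text = path.read_text()
    genes: list[str] = []
    seen: set[str] = set()
    dropped = 0
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        token = re.split(r"[,\s]+", line)[0]
        if not token:
            continue
        sym = normalize_symbol(token)
        if sym in seen:
            dropped += 1
            continue
        seen.add(sym)
        genes.append(sym)
    if not genes:
        raise ValueError(f"empty gene list: {path}")
    if dropped:
        logger.warning("read_gene_list: dropped %d duplicate symbols from %s", dropped, path)
    return GeneList(genes=genes, source_label=source_label or path.name)


def read_edge_table(
    path: str | Path,
    dialect: str = "generic_tsv",
    score_scale: Optional[str] = None,
) -> ParsedEdgeTable:
    """Read a scored edge table into normalized :class:`EdgeRecord` rows.

    Parameters
    ----------
    dialect
        ``"string_links"`` for STRING protein-links flat files
        (whitespace-delimited, header line, integer combined_score 0-999) or
        ``"generic_tsv"`` (>= 3 whitespace/tab-separated columns).
    score_scale
        ``"int_0_999"`` or ``"float_0_1"``.  Defaults to the dialect's
        convention (0-999 for STRING, 0-1 for generic TSV).  Integer scores
        are divided by 1000.

    Rows with an unparseable score are rejected and recorded by line number;
    a parseable score outside the declared scale raises, naming the line.
    Self-loops are dropped with a warning count.  A header row is detected
    automatically (non-numeric third column on line 1).
    """
    if dialect not in ("string_links", "generic_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    if score_scale is None:
        score_scale = "int_0_999" if dialect == "string_links" else "float_0_1"
    if score_scale not in ("int_0_999", "float_0_1"):
        raise ValueError(f"unknown score_scale {score_scale!r}")

    path = Path(path)
    table = ParsedEdgeTable()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
            raw_score = fields[2]
            try:
                score = float(raw_score)
            except ValueError:
                if lineno == 1:  # header row
                    continue
                table.rejected_lines.append(lineno)
                continue
            if score_scale == "int_0_999":
                if not 0 <= score <= 999:
                    raise ValueError(
                        f"{path}:{lineno}: score {raw_score} outside declared scale 0-999"
                    )
                conf = score / 1000.0
            else:
                if not 0.0 <= score <= 1.0:
                    raise ValueError(
                        f"{path}:{lineno}: score {raw_score} outside declared scale [0, 1]"
                    )
                conf = score
            a = normalize_symbol(fields[0])
            b = normalize_symbol(fields[1])
            if a == b:
                table.self_loops_dropped += 1
                continue
            table.append(EdgeRecord(a, b, conf))
    if table.self_loops_dropped:
        logger.warning(
            "read_edge_table: dropped %d self-loop rows from %s", table.self_loops_dropped, path
        )
    if table.rejected_lines:
        logger.warning(
            "read_edge_table: rejected %d rows with unparseable scores in %s (lines %s)",
            len(table.rejected_lines),
            path,
            table.rejected_lines,
        )
    return table


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column alias TSV (alias, canonical) and flatten alias chains.

    Chains like ``A -> B -> C`` are resolved so every value in the returned
    mapping is itself canonical.  A cycle is an error.
    """
    path = Path(path)
    raw: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            alias = normalize_symbol(fields[0])
            canonical = normalize_symbol(fields[1])
            if alias in raw and raw[alias] != canonical:
                raise ValueError(f"{path}:{lineno}: conflicting targets for alias {alias}")
            raw[alias] = canonical

    resolved: dict[str, str] = {}
    for alias, target in raw.items():
        seen = {alias}
        while target in raw:
            if target in seen:
                raise ValueError(f"alias cycle involving {alias!r} in {path}")
            seen.add(target)
            target = raw[target]
        resolved[alias] = target
    return resolved


def read_seed_groups(path: str | Path, n_groups: int = 4) -> dict[str, int]:
    """Read a seed localization file: TSV of (gene, group index in 1..n_groups)."""
    path = Path(path)
    seeds: dict[str, int] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns (gene, group)")
            gene = normalize_symbol(fields[0])
            try:
                group = int(fields[1])
            except ValueError:
                if lineno == 1:
                    continue
                raise ValueError(f"{path}:{lineno}: group index {fields[1]!r} is not an integer")
            if not 1 <= group <= n_groups:
                raise ValueError(f"{path}:{lineno}: group {group} outside 1..{n_groups}")
            if gene in seeds and seeds[gene] != group:
                raise ValueError(f"{path}:{lineno}: gene {gene} assigned to two groups")
            seeds[gene] = group
    return seeds


def apply_alias_map(
    genes: GeneList,
    aliases: Mapping[str, str],
    universe: set[str],
) -> tuple[GeneList, dict[str, str], GeneList]:
    """Resolve input gene symbols against an alias map and a node universe.

    Returns ``(recognized, renamed, unrecognized)``.  A gene already present
    in ``universe`` passes through; a gene listed as an alias is renamed to
    its canonical symbol (reported in ``renamed``); anything else lands in
    ``unrecognized``.  The two output lists partition the input.
    """
    recognized: list[str] = []
    renamed: dict[str, str] = {}
    unrecognized: list[str] = []
    for gene in genes:
        if gene in aliases:
            target = aliases[gene]
            renamed[gene] = target
            recognized.append(target)
        elif gene in universe:
            recognized.append(gene)
        else:
            unrecognized.append(gene)
    if renamed:
        logger.info("apply_alias_map: renamed %s", renamed)
    if unrecognized:
        logger.warning("apply_alias_map: %d unrecognized genes: %s", len(unrecognized), unrecognized)
    return (
        GeneList(recognized, source_label=genes.source_label),
        renamed,
        GeneList(unrecognized, source_label=genes.source_label),
    )


# ---------------------------------------------------------------------------
# Annotated network export
# ---------------------------------------------------------------------------


def _annotate(network: PPINetwork, classification, localization) -> nx.Graph:
    g = nx.Graph()
    intermediates: set[str] = set()
    roles: dict[str, str] = {}
    if classification is not None:
        intermediates = set(classification.bridges.values())
        for gene in classification.group_a:
            roles[gene] = "direct"
        for gene in classification.group_b:
            roles[gene] = "bridged"
        for gene in classification.group_c:
            roles[gene] = "unbridgeable"
        for gene in intermediates:
            roles[gene] = "intermediate"
        missing = set(roles) - network.nodes
        if missing:
            raise KeyError(f"classified genes absent from network: {sorted(missing)}")
    assignment: Mapping[str, int] = {}
    if localization is not None:
        assignment = localization.assignment
        missing = set(assignment) - network.nodes
        if missing:
            raise KeyError(f"localized genes absent from network: {sorted(missing)}")

    for gene in sorted(network.nodes):
        role = roles.get(gene, "")
        group = assignment.get(gene, 0)
        g.add_node(
            gene,
            role=role,
            color=ROLE_COLORS.get(role, ""),
            group=group,
        )
    for a, b, conf in network.edges():
        # PPIs are bidirectional: one color attribute per endpoint, keyed by
        # that endpoint's localization group.  Edges touching an intermediate
        # are grayed out on both ends.
        if a in intermediates or b in intermediates:
            color_a = color_b = "gray"
        else:
            color_a = GROUP_COLORS.get(assignment.get(a, 0), "gray")
            color_b = GROUP_COLORS.get(assignment.get(b, 0), "gray")
        g.add_edge(a, b, confidence=conf, color_a=color_a, color_b=color_b)
    return g


def _write_dot(g: nx.Graph, path: Path) -> None:
    lines = ["graph ppi {"]
    for node in sorted(g.nodes):
        attrs = g.nodes[node]
        parts = [f'label="{node}"']
        if attrs.get("color"):
            parts.append(f'fillcolor="{attrs["color"]}"')
            parts.append("style=filled")
        if attrs.get("group"):
            parts.append(f'group="{attrs["group"]}"')
        lines.append(f'  "{node}" [{", ".join(parts)}];')
    for a, b in sorted(g.edges):
        d = g.edges[a, b]
        lines.append(
            f'  "{a}" -- "{b}" [confidence="{d["confidence"]:.3f}", '
            f'color_a="{d["color_a"]}", color_b="{d["color_b"]}"];'
        )
    lines.append("}")
    path.write_text("\n".join(lines) + "\n")


def _write_tsv(g: nx.Graph, path: Path) -> None:
    rows = ["gene_a\tgene_b\tconfidence\trole_a\tgroup_a\tcolor_a\trole_b\tgroup_b\tcolor_b"]
    for a, b in sorted(g.edges):
        d = g.edges[a, b]
        na, nb = g.nodes[a], g.nodes[b]
        rows.append(
            f"{a}\t{b}\t{d['confidence']:.3f}\t{na['role']}\t{na['group']}\t{d['color_a']}"
            f"\t{nb['role']}\t{nb['group']}\t{d['color_b']}"
        )
    for node in sorted(g.nodes):
        if g.degree[node] == 0:
            n = g.nodes[node]
            rows.append(f"{node}\t\t\t{n['role']}\t{n['group']}\t\t\t\t")
    path.write_text("\n".join(rows) + "\n")


def write_annotated_network(
    network: PPINetwork,
    classification,
    localization,
    path: str | Path,
    format: str = "graphml",
) -> Path:
    """Export the network with role/group/color annotations.

    ``classification`` (a :class:`~ppibridge.intermediate_discovery.GeneClassification`)
    and ``localization`` (a :class:`~ppibridge.localization.LocalizationAssignment`)
    may each be ``None`` for a plain export.  Node attributes: ``role``
    (direct/bridged/unbridgeable/intermediate), ``color`` (white/yellow/gray/
    green) and ``group`` (localization index, 0 if unassigned).  Edge
    attributes: ``confidence`` plus one color per endpoint.
    """
    path = Path(path)
    g = _annotate(network, classification, localization)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "dot":
        _write_dot(g, path)
    elif format == "tsv":
        _write_tsv(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")
    return path


def read_annotated_graphml(path: str | Path) -> nx.Graph:
    """Re-read an annotated GraphML export (round-trip counterpart)."""
    return nx.read_graphml(str(path))
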
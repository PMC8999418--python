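"""Planted-structure PPI network generator with ground truth.

The generator emulates the statistical structure the pipeline assumes in real
interactomes: localization groups are dense blocks of interactions
(planted-partition topology, intra-block edge probability ``p_intra`` well
above the inter-block ``p_inter``); a subset of each block's genes are
"disease" genes forming the input list; a handful of disease genes are
*isolated* — no interaction with any other disease gene — and each is wired to
one or more planted bridge genes that also touch the disease-gene core.  Every
pipeline stage can therefore be tested offline against exact ground truth.

Layout of a generated scenario:

* block genes ``B{k}D{i}`` (disease) and ``B{k}N{i}`` (non-disease context),
  block index k starting at 1;
* isolated disease genes ``ISO{i}`` whose only edges go to their bridges;
* bridge genes ``BRG{i}`` wired to their isolated gene and to 1-3 disease
  genes in the main block (the block with the most disease genes, which is the
  largest component of the disease-gene subgraph by construction).

A deterministic confidence-scored chain over each block's disease genes
guarantees that each block's disease genes form a single connected component
regardless of the random draws, so the "main component" of the connectivity
classifier is well defined and bridge targets verifiably sit inside it.
Planted edge confidences are drawn at or above the pipeline threshold so the
planted structure survives thresholding.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .graph_core import PPINetwork, build_network
from .network_io import EdgeRecord, GeneList

logger = logging.getLogger(__name__)

__all__ = ["SyntheticScenario", "GroundTruth", "generate", "write_scenario", "read_scenario"]


@dataclass
class SyntheticScenario:
    """Parameters of one planted scenario.

    Defaults mirror the retinitis pigmentosa study conditions structurally:
    4 localization blocks, 149 connected disease genes (38/37/37/37 per
    block), 10 isolated disease genes with one planted bridge each — 159
    input genes in total — and roughly 20% of connected disease genes as
    localization seeds (the 30-of-149 seed ratio).
    """

    n_groups: int = 4
    block_sizes: tuple[int, ...] = (60, 55, 55, 55)
    p_intra: float = 0.30
    p_inter: float = 0.02
    confidence_law: tuple = ("uniform", 0.40, 0.95)
    n_disease_genes_per_block: tuple[int, ...] = (38, 37, 37, 37)
    n_isolated_disease_genes: int = 10
    bridges_per_isolated: int = 1
    seed_fraction: float = 0.20
    rng_seed: int = 0
    threshold: float = 0.40

    def validate(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups must be >= 1")
        if len(self.block_sizes) != self.n_groups:
            raise ValueError("block_sizes length must equal n_groups")
        if len(self.n_disease_genes_per_block) != self.n_groups:
            raise ValueError("n_disease_genes_per_block length must equal n_groups")
        for size, nd in zip(self.block_sizes, self.n_disease_genes_per_block):
            if nd > size:
                raise ValueError(
                    f"block of size {size} cannot hold {nd} disease genes"
                )
            if nd < 0 or size < 1:
                raise ValueError("block sizes must be >= 1, disease counts >= 0")
        if not (0.0 <= self.p_inter <= self.p_intra <= 1.0):
            raise ValueError("require 0 <= p_inter <= p_intra <= 1")
        law = self.confidence_law
        if law[0] == "uniform":
            lo, hi = law[1], law[2]
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("uniform confidence bounds must satisfy 0 <= lo <= hi <= 1")
            if lo < self.threshold:
                raise ValueError(
                    "confidence law lower bound below threshold: planted edges "
                    "would not survive thresholding"
                )
        elif law[0] == "fixed":
            if not self.threshold <= law[1] <= 1.0:
                raise ValueError("fixed confidence must be in [threshold, 1]")
        else:
            raise ValueError(f"unknown confidence law {law[0]!r}")
        if self.bridges_per_isolated < 1:
            raise ValueError("bridges_per_isolated must be >= 1")
        if not 0.0 < self.seed_fraction <= 1.0:
            raise ValueError("seed_fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """Planted truth for a generated scenario.

    ``block_of`` maps every gene (including isolated disease genes, which are
    credited to the main block their bridge anchors into, and the bridges
    themselves) to its planted group.  ``planted_bridges`` maps each isolated
    gene to the tuple of its planted bridge genes (length 1 unless
    ``bridges_per_isolated`` > 1).
    """

    block_of: dict[str, int]
    disease_genes: GeneList
    planted_bridges: dict[str, tuple[str, ...]]
    seed_file: dict[str, int]
    main_block: int


def _draw_conf(rng: np.random.Generator, law: tuple) -> float:
    if law[0] == "uniform":
        return float(rng.uniform(law[1], law[2]))
    return float(law[1])


def generate(scenario: SyntheticScenario) -> tuple[PPINetwork, GroundTruth]:
    """Generate a scenario's network and ground truth, reproducibly.

    Isolated disease genes have zero edges to other disease genes; each is
    wired to its planted bridge(s), and each planted bridge is wired into the
    main block's disease genes.  With ``bridges_per_isolated = 1`` the planted
    bridge is the unique valid candidate for its gene, so bridge selection
    must recover it exactly.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.rng_seed)
    law = scenario.confidence_law

    blocks: list[list[str]] = []
    disease_by_block: list[list[str]] = []
    block_of: dict[str, int] = {}
    for k, (size, nd) in enumerate(
        zip(scenario.block_sizes, scenario.n_disease_genes_per_block), start=1
    ):
        disease = [f"B{k}D{i:03d}" for i in range(1, nd + 1)]
        context = [f"B{k}N{i:03d}" for i in range(1, size - nd + 1)]
        members = disease + context
        blocks.append(members)
        disease_by_block.append(disease)
        for g in members:
            block_of[g] = k

    # main block = most disease genes; first index wins ties, matching the
    # classifier's deterministic tie-break (block-1 names sort first)
    main_block = int(np.argmax(scenario.n_disease_genes_per_block)) + 1
    main_disease = disease_by_block[main_block - 1]
    if scenario.n_isolated_disease_genes > 0 and not main_disease:
        raise ValueError("isolated disease genes need a non-empty main block to bridge into")

    records: list[EdgeRecord] = []
    seen: set[tuple[str, str]] = set()

    def add_edge(a: str, b: str, conf: Optional[float] = None) -> None:
        key = (a, b) if a < b else (b, a)
        if key in seen or a == b:
            return
        seen.add(key)
        records.append(EdgeRecord(key[0], key[1], conf if conf is not None else _draw_conf(rng, law)))

    # deterministic chain over each block's disease genes: guarantees one
    # A-component per block independent of the random draws
    for disease in disease_by_block:
        for a, b in zip(disease, disease[1:]):
            add_edge(a, b)

    # planted-partition background over all block members
    all_block_genes = [g for members in blocks for g in members]
    for i, u in enumerate(all_block_genes):
        for v in all_block_genes[i + 1:]:
            p = scenario.p_intra if block_of[u] == block_of[v] else scenario.p_inter
            if p > 0 and rng.random() < p:
                add_edge(u, v)

    # isolated disease genes + planted bridges
    isolated = [f"ISO{i:02d}" for i in range(1, scenario.n_isolated_disease_genes + 1)]
    planted: dict[str, tuple[str, ...]] = {}
    bridge_idx = 0
    for iso in isolated:
        block_of[iso] = main_block
        mine: list[str] = []
        for _ in range(scenario.bridges_per_isolated):
            bridge_idx += 1
            brg = f"BRG{bridge_idx:02d}"
            block_of[brg] = main_block
            add_edge(iso, brg)
            n_anchors = int(rng.integers(1, min(3, len(main_disease)) + 1))
            anchors = rng.choice(len(main_disease), size=n_anchors, replace=False)
            for ai in sorted(int(a) for a in anchors):
                add_edge(brg, main_disease[ai])
            mine.append(brg)
        planted[iso] = tuple(mine)

    disease_genes = GeneList(
        [g for d in disease_by_block for g in d] + isolated,
        source_label="synthetic",
    )

    # seeds: a deterministic fraction of each block's connected disease genes
    seed_file: dict[str, int] = {}
    for k, disease in enumerate(disease_by_block, start=1):
        if not disease:
            continue
        n_seed = max(1, int(round(scenario.seed_fraction * len(disease))))
        picks = rng.choice(len(disease), size=min(n_seed, len(disease)), replace=False)
        for pi in sorted(int(p) for p in picks):
            seed_file[disease[pi]] = k

    network = build_network(records, threshold=scenario.threshold)
    # declare every gene as a node even if it drew no edges
    for g in block_of:
        network.graph.add_node(g)

    truth = GroundTruth(
        block_of=block_of,
        disease_genes=disease_genes,
        planted_bridges=planted,
        seed_file=seed_file,
        main_block=main_block,
    )
    logger.info(
        "generate: %d genes, %d edges, %d disease genes (%d isolated), %d bridges",
        len(network.nodes), network.n_edges, len(disease_genes),
        len(isolated), bridge_idx,
    )
    return network, truth


def write_scenario(
    network: PPINetwork,
    truth: GroundTruth,
    out_dir: str | Path,
    scenario: Optional[SyntheticScenario] = None,
) -> dict[str, Path]:
    """Write a scenario as CLI-consumable files.

    Emits ``edges.tsv`` (generic TSV, confidences in [0,1]), ``genes.txt``,
    ``seeds.tsv``, ``ground_truth.json`` and, when the scenario is given,
    ``run_config.yaml`` referencing the files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    edges_path = out_dir / "edges.tsv"
    lines = ["gene_a\tgene_b\tconfidence"]
    for a, b, conf in sorted(network.edges()):
        lines.append(f"{a}\t{b}\t{conf:.6f}")
    edges_path.write_text("\n".join(lines) + "\n")
    paths["edges"] = edges_path

    genes_path = out_dir / "genes.txt"
    genes_path.write_text(
        "# synthetic disease gene list\n" + "\n".join(truth.disease_genes) + "\n"
    )
    paths["genes"] = genes_path

    seeds_path = out_dir / "seeds.tsv"
    seed_lines = ["gene\tgroup"] + [
        f"{g}\t{grp}" for g, grp in sorted(truth.seed_file.items())
    ]
    seeds_path.write_text("\n".join(seed_lines) + "\n")
    paths["seeds"] = seeds_path

    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(
        json.dumps(
            {
                "block_of": truth.block_of,
                "disease_genes": list(truth.disease_genes),
                "planted_bridges": {k: list(v) for k, v in truth.planted_bridges.items()},
                "seed_file": truth.seed_file,
                "main_block": truth.main_block,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    paths["ground_truth"] = truth_path

    if scenario is not None:
        import yaml

        cfg = {
            "genes": str(genes_path),
            "edges": str(edges_path),
            "dialect": "generic_tsv",
            "seeds": str(seeds_path),
            "threshold": scenario.threshold,
            "score_strategy": "two_leg_sum",
        }
        cfg_path = out_dir / "run_config.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        paths["config"] = cfg_path
    return paths


def read_scenario(out_dir: str | Path) -> GroundTruth:
    """Re-read a written scenario's ground truth."""
    data = json.loads((Path(out_dir) / "ground_truth.json").read_text())
    return GroundTruth(
        block_of={k: int(v) for k, v in data["block_of"].items()},
        disease_genes=GeneList(data["disease_genes"], source_label="synthetic"),
        planted_bridges={k: tuple(v) for k, v in data["planted_bridges"].items()},
        seed_file={k: int(v) for k, v in data["seed_file"].items()},
        main_block=int(data["main_block"]),
    )
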
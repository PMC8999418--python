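"""Label propagation by PPI-count majority and the group connectivity matrix."""

import numpy as np
import pytest

from conftest import oracle_group_edge_counts
from ppibridge.graph_core import build_network
from ppibridge.intermediate_discovery import (
    classify_connectivity,
    select_intermediates,
)
from ppibridge.localization import (
    LocalizationAssignment,
    assign_groups,
    connectivity_matrix,
    place_intermediates,
)
from ppibridge.network_io import EdgeRecord, GeneList
from ppibridge.synthetic_data import SyntheticScenario, generate


def _net(records, extra_nodes=(), threshold=0.4):
    net = build_network(records, threshold=threshold)
    for n in extra_nodes:
        net.graph.add_node(n)
    return net


class TestAssignGroups:
    def test_majority_of_ppi_counts_wins(self):
        records = [("GENE", f"S2{i}", 0.5) for i in range(3)]
        records += [("GENE", "S4A", 0.99)]
        seeds = {f"S2{i}": 2 for i in range(3)} | {"S4A": 4}
        net = _net(records)
        asg = assign_groups(net, set(seeds) | {"GENE"}, seeds)
        assert asg.assignment["GENE"] == 2
        assert asg.iteration_assigned["GENE"] == 1

    def test_count_tie_broken_by_confidence_sum(self):
        records = [("GENE", "S1A", 0.9), ("GENE", "S3A", 0.5)]
        seeds = {"S1A": 1, "S3A": 3}
        asg = assign_groups(_net(records), {"GENE", "S1A", "S3A"}, seeds)
        assert asg.assignment["GENE"] == 1

    def test_residual_tie_deferred_then_lowest_group_index(self, caplog):
        records = [("GENE", "S2A", 0.7), ("GENE", "S4A", 0.7)]
        seeds = {"S2A": 2, "S4A": 4}
        with caplog.at_level("WARNING"):
            asg = assign_groups(_net(records), {"GENE", "S2A", "S4A"}, seeds)
        assert asg.assignment["GENE"] == 2
        assert asg.iteration_assigned["GENE"] == 2  # one deferred round
        assert "residual tie" in caplog.text

    def test_multi_round_expansion(self):
        # chain seed -> g1 -> g2: g2 only reachable after g1 is assigned
        records = [("SEED", "GA1", 0.9), ("GA1", "GA2", 0.9)]
        asg = assign_groups(_net(records), {"SEED", "GA1", "GA2"}, {"SEED": 1})
        assert asg.assignment == {"SEED": 1, "GA1": 1, "GA2": 1}
        assert asg.iteration_assigned == {"SEED": 0, "GA1": 1, "GA2": 2}

    def test_seeds_never_reassigned(self):
        # seed S1A is surrounded by group-2 genes but must keep its label
        records = [("S1A", "S2A", 0.9), ("S1A", "S2B", 0.9), ("S2A", "S2B", 0.9)]
        seeds = {"S1A": 1, "S2A": 2, "S2B": 2}
        asg = assign_groups(_net(records), set(seeds), seeds)
        assert {g: asg.assignment[g] for g in seeds} == seeds
        assert all(asg.is_seed[g] for g in seeds)

    def test_deadlocked_genes_reported_unassigned(self):
        records = [("S1A", "GA1", 0.9)]
        net = _net(records, extra_nodes=["LONER"])
        asg = assign_groups(net, {"S1A", "GA1", "LONER"}, {"S1A": 1})
        assert asg.unassigned == {"LONER"}
        assert "LONER" not in asg.assignment

    def test_batch_rounds_independent_of_insertion_order(self):
        records = [
            ("S1A", "GA1", 0.9), ("S2A", "GA1", 0.8),
            ("S1A", "GA2", 0.6), ("GA1", "GA2", 0.7),
        ]
        seeds = {"S1A": 1, "S2A": 2}
        universe = {"S1A", "S2A", "GA1", "GA2"}
        base = assign_groups(_net(records), universe, seeds)
        flipped = assign_groups(_net(list(reversed(records))), universe, seeds)
        assert base.assignment == flipped.assignment
        assert base.iteration_assigned == flipped.iteration_assigned

    def test_assignment_time_support_replay(self):
        """Every non-seed gene had an edge into its group in a strictly earlier round."""
        scenario = SyntheticScenario(
            block_sizes=(15, 12, 12, 12),
            n_disease_genes_per_block=(8, 6, 6, 6),
            n_isolated_disease_genes=0,
            p_inter=0.05,
            rng_seed=13,
        )
        net, truth = generate(scenario)
        asg = assign_groups(net, set(truth.disease_genes), truth.seed_file)
        for gene, grp in asg.assignment.items():
            if asg.is_seed[gene]:
                continue
            rnd = asg.iteration_assigned[gene]
            support = [
                nbr for nbr in net.graph[gene]
                if asg.assignment.get(nbr) == grp
                and asg.iteration_assigned.get(nbr, 10**9) < rnd
            ]
            assert support, f"{gene} lacked same-group support at round {rnd}"

    def test_planted_blocks_recovered_without_noise(self):
        scenario = SyntheticScenario(
            block_sizes=(20, 20, 20, 20),
            n_disease_genes_per_block=(12, 12, 12, 12),
            n_isolated_disease_genes=0,
            p_inter=0.0,
            seed_fraction=0.2,
            rng_seed=2024,
        )
        net, truth = generate(scenario)
        asg = assign_groups(net, set(truth.disease_genes), truth.seed_file)
        assert asg.unassigned == set()
        assert all(
            asg.assignment[g] == truth.block_of[g] for g in truth.disease_genes
        )

    def test_input_validation(self, toy_network):
        with pytest.raises(ValueError, match="max_iterations"):
            assign_groups(toy_network, {"AAA"}, {"AAA": 1}, max_iterations=0)
        with pytest.raises(KeyError, match="seed genes absent"):
            assign_groups(toy_network, {"AAA"}, {"ZZZ": 1})
        with pytest.raises(KeyError, match="universe genes absent"):
            assign_groups(toy_network, {"NOPE"}, {})


class TestPlaceIntermediates:
    def _toy(self):
        records = [
            ("A1", "A2", 0.9),
            ("X1", "M1", 0.9), ("M1", "A1", 0.9),
        ]
        net = _net(records)
        cls = select_intermediates(
            net, classify_connectivity(net, GeneList(["A1", "A2", "X1"]))
        )
        return net, cls

    def test_bridge_inherits_partner_group(self):
        net, cls = self._toy()
        asg = LocalizationAssignment(
            assignment={"A1": 1, "A2": 1, "X1": 3},
            is_seed={"A1": True, "A2": True, "X1": False},
            iteration_assigned={"A1": 0, "A2": 0, "X1": 1},
        )
        out = place_intermediates(asg, cls)
        assert out.assignment["M1"] == 3
        assert not out.is_seed["M1"]

    def test_shared_bridge_takes_lexicographically_smallest_partner(self, caplog):
        records = [
            ("A1", "A2", 0.9),
            ("X1", "HUB", 0.9), ("X2", "HUB", 0.9), ("HUB", "A1", 0.9),
        ]
        net = _net(records)
        cls = select_intermediates(
            net, classify_connectivity(net, GeneList(["A1", "A2", "X1", "X2"]))
        )
        assert cls.bridges == {"X1": "HUB", "X2": "HUB"}
        asg = LocalizationAssignment(
            assignment={"A1": 1, "A2": 1, "X1": 2, "X2": 1},
            is_seed={}, iteration_assigned={"A1": 0, "A2": 0, "X1": 1, "X2": 1},
        )
        with caplog.at_level("WARNING"):
            out = place_intermediates(asg, cls)
        assert out.assignment["HUB"] == 2  # X1 < X2
        assert "shared by partners" in caplog.text

    def test_unassigned_partner_is_error(self):
        net, cls = self._toy()
        asg = LocalizationAssignment(assignment={"A1": 1, "A2": 1})
        with pytest.raises(KeyError, match="unassigned"):
            place_intermediates(asg, cls)


class TestConnectivityMatrix:
    def test_toy_counts(self):
        records = [("G1A", "G2A", 0.9), ("G2A", "G2B", 0.9)]
        net = _net(records, extra_nodes=["G3A", "G4A"])
        asg = LocalizationAssignment(
            assignment={"G1A": 1, "G2A": 2, "G2B": 2, "G3A": 3, "G4A": 4}
        )
        m = connectivity_matrix(net, asg)
        assert m.counts[0, 1] == 1 and m.counts[1, 0] == 1
        assert m.counts[1, 1] == 1
        assert m.counts.sum() == 3  # symmetric off-diagonal counted twice
        assert m.lower_triangular_total() == 2

    def test_empty_edge_set_gives_zero_matrix(self):
        net = _net([], extra_nodes=["G1A"])
        m = connectivity_matrix(net, LocalizationAssignment(assignment={"G1A": 1}))
        assert m.counts.sum() == 0

    def test_unassigned_endpoint_error_lists_genes(self):
        net = _net([("G1A", "MYSTERY", 0.9)])
        asg = LocalizationAssignment(assignment={"G1A": 1})
        with pytest.raises(KeyError, match="MYSTERY"):
            connectivity_matrix(net, asg)

    def test_matrix_matches_edge_scan_oracle_and_conserves_edges(self):
        scenario = SyntheticScenario(
            block_sizes=(12, 10, 10, 10),
            n_disease_genes_per_block=(6, 5, 5, 5),
            n_isolated_disease_genes=3,
            p_inter=0.0,
            rng_seed=314,
        )
        net, truth = generate(scenario)
        cls = select_intermediates(net, classify_connectivity(net, truth.disease_genes))
        universe = set(truth.disease_genes) | cls.intermediates
        asg = assign_groups(net, universe, truth.seed_file)
        asg = place_intermediates(asg, cls)
        from ppibridge.intermediate_discovery import assemble_augmented_network

        aug = assemble_augmented_network(net, cls)
        m = connectivity_matrix(aug, asg, cls)
        expected = oracle_group_edge_counts(list(aug.edges()), asg.assignment, 4)
        assert m.counts.tolist() == expected
        n_assigned_edges = sum(
            1 for a, b, _ in aug.edges()
            if a in asg.assignment and b in asg.assignment
        )
        assert m.lower_triangular_total() == n_assigned_edges

    def test_intermediate_links_counted_per_partner_group(self):
        records = [("X1", "M1", 0.9), ("M1", "A1", 0.9), ("A1", "A2", 0.9)]
        net = _net(records)
        cls = select_intermediates(
            net, classify_connectivity(net, GeneList(["A1", "A2", "X1"]))
        )
        asg = LocalizationAssignment(
            assignment={"A1": 1, "A2": 1, "X1": 2, "M1": 2}
        )
        m = connectivity_matrix(net, asg, cls)
        # edges X1-M1 and M1-A1 touch the intermediate: one incidence in
        # group 2 (X1) and one in group 1 (A1)
        assert m.intermediate_links.tolist() == [1, 1, 0, 0]
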
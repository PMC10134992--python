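"""Sign partitions, antagonistic pair extraction, biotype summaries."""

import numpy as np
import pytest

from tmwas import antagonism as ant
from tmwas import netcomm
from tmwas.types import AssociationEdge, Block, CommunityAssignment


def toy_assignment():
    """One community around anchor A: genes g1[+] g2[+] g3[-],
    metabolites m1[+] m2[-] m3[-], plus m4 with no direct anchor edge."""
    edges = [
        AssociationEdge("A", "g1", Block.FUNCTIONAL, Block.TRANSCRIPTOME,
                        r=0.95, p=0.001, n=6),
        AssociationEdge("A", "g2", Block.FUNCTIONAL, Block.TRANSCRIPTOME,
                        r=0.85, p=0.03, n=6),
        AssociationEdge("A", "g3", Block.FUNCTIONAL, Block.TRANSCRIPTOME,
                        r=-0.9, p=0.01, n=6),
        AssociationEdge("A", "m1", Block.FUNCTIONAL, Block.METABOLOME,
                        r=0.88, p=0.02, n=6),
        AssociationEdge("A", "m2", Block.FUNCTIONAL, Block.METABOLOME,
                        r=-0.97, p=0.001, n=6),
        AssociationEdge("A", "m3", Block.FUNCTIONAL, Block.METABOLOME,
                        r=-0.83, p=0.04, n=6),
        AssociationEdge("m4", "g1", Block.METABOLOME, Block.TRANSCRIPTOME,
                        r=0.9, p=0.01, n=6),
        AssociationEdge("m2", "g1", Block.METABOLOME, Block.TRANSCRIPTOME,
                        r=-0.86, p=0.02, n=6),
    ]
    graph = netcomm.build_graph([edges])
    # one hand-built community containing everything: these tests exercise
    # the partition/pair logic, not community detection
    nodes = sorted(graph.nodes)
    assignment = CommunityAssignment(
        membership={n: 0 for n in nodes},
        node_block={n: Block(graph.nodes[n]["block"]) for n in nodes},
        signs={(nbr, "A"): int(graph.edges["A", nbr]["sign"])
               for nbr in graph.neighbors("A")},
        anchor_map={0: ["A"]}, modularity=0.0)
    return graph, assignment


class TestSignPartition:
    def test_counts(self):
        _, assignment = toy_assignment()
        part = ant.sign_partition(assignment, "A")
        assert part.positive[Block.TRANSCRIPTOME] == ["g1", "g2"]
        assert part.negative[Block.TRANSCRIPTOME] == ["g3"]
        assert part.positive[Block.METABOLOME] == ["m1"]
        assert part.negative[Block.METABOLOME] == ["m2", "m3"]

    def test_indirect_bucket(self):
        _, assignment = toy_assignment()
        part = ant.sign_partition(assignment, "A")
        assert part.indirect[Block.METABOLOME] == ["m4"]

    def test_partition_is_exhaustive(self):
        _, assignment = toy_assignment()
        part = ant.sign_partition(assignment, "A")
        cid = assignment.membership["A"]
        for block in (Block.METABOLOME, Block.TRANSCRIPTOME):
            members = [n for n, c in assignment.membership.items()
                       if c == cid and assignment.node_block[n] is block]
            covered = (len(part.positive.get(block, []))
                       + len(part.negative.get(block, []))
                       + len(part.indirect.get(block, []))
                       + len(part.discordant.get(block, [])))
            assert covered == len(members)

    def test_missing_anchor_errors(self):
        _, assignment = toy_assignment()
        with pytest.raises(KeyError):
            ant.sign_partition(assignment, "nope")

    def test_zero_noise_partition_equals_planted_signs(self, zero_noise_run):
        truth = zero_noise_run["truth"]
        assignment = zero_noise_run["assignment"]
        checked = 0
        for anchor in ("Mn", "thiols", "bOCR"):
            part = ant.sign_partition(assignment, anchor)
            for block in (Block.METABOLOME, Block.TRANSCRIPTOME):
                for member in part.positive.get(block, []):
                    assert truth.sign[member] == 1
                    checked += 1
                for member in part.negative.get(block, []):
                    assert truth.sign[member] == -1
                    checked += 1
        assert checked > 0

    def test_discordant_flag_for_disagreeing_anchor_group(self):
        membership = {"A1": 0, "A2": 0, "g1": 0}
        node_block = {"A1": Block.FUNCTIONAL, "A2": Block.FUNCTIONAL,
                      "g1": Block.TRANSCRIPTOME}
        signs = {("g1", "A1"): 1, ("g1", "A2"): -1}
        assignment = CommunityAssignment(
            membership=membership, node_block=node_block, signs=signs,
            anchor_map={0: ["A1", "A2"]}, modularity=0.0)
        part = ant.sign_partition(assignment, ["A1", "A2"])
        assert part.discordant[Block.TRANSCRIPTOME] == ["g1"]


class TestAntagonisticPairs:
    def test_cross_product_count(self):
        graph, assignment = toy_assignment()
        pairs = ant.antagonistic_pairs(graph, assignment, "A")
        # closed form: |g+|*|m-| + |g-|*|m+| = 2*2 + 1*1
        assert len(pairs) == 2 * 2 + 1 * 1

    def test_all_same_sign_empty(self):
        edges = [AssociationEdge("A", "g1", Block.FUNCTIONAL,
                                 Block.TRANSCRIPTOME, r=0.9, p=0.01, n=6),
                 AssociationEdge("A", "m1", Block.FUNCTIONAL,
                                 Block.METABOLOME, r=0.92, p=0.01, n=6)]
        graph = netcomm.build_graph([edges])
        assignment = netcomm.detect_communities(graph)
        assert ant.antagonistic_pairs(graph, assignment, "A") == []

    def test_ranking_matches_hand_sort(self):
        graph, assignment = toy_assignment()
        pairs = ant.antagonistic_pairs(graph, assignment, "A")
        ranked = [(p.gene_id, p.metabolite_id) for p in pairs]
        # rank_score = min(|gene_r|, |met_r|):
        # (g1,m2)=0.95^0.97->0.95; (g3,m1)=0.9^0.88->0.88;
        # (g2,m2)=0.85; (g1,m3)=0.83; (g2,m3)=0.83 — tie broken by gene id
        assert ranked == [("g1", "m2"), ("g3", "m1"), ("g2", "m2"),
                          ("g1", "m3"), ("g2", "m3")]
        scores = [p.rank_score for p in pairs]
        assert scores == sorted(scores, reverse=True)

    def test_direct_pair_edge_attached(self):
        graph, assignment = toy_assignment()
        pairs = ant.antagonistic_pairs(graph, assignment, "A")
        by_pair = {(p.gene_id, p.metabolite_id): p for p in pairs}
        assert by_pair[("g1", "m2")].pair_r == pytest.approx(-0.86)
        assert by_pair[("g2", "m2")].pair_r is None

    def test_top_k_truncation(self):
        graph, assignment = toy_assignment()
        assert len(ant.antagonistic_pairs(graph, assignment, "A", top_k=2)) == 2

    def test_recovers_planted_opposite_sign_pairs(self, default_run):
        truth = default_run["truth"]
        assignment = default_run["assignment"]
        graph = default_run["graph"]
        total = found = 0
        for anchor in ("Mn", "thiols", "bOCR"):
            pairs = ant.antagonistic_pairs(graph, assignment, anchor)
            got = {(p.gene_id, p.metabolite_id) for p in pairs}
            members = [f for f, a in truth.anchor_assignment.items()
                       if a == anchor and f in assignment.membership
                       and assignment.membership[f] ==
                       assignment.membership[anchor]
                       and (f, anchor) in assignment.signs]
            genes = [f for f in members if f.startswith("tx_")]
            mets = [f for f in members if f.startswith("met_")]
            for g in genes:
                for m in mets:
                    if truth.sign[g] != truth.sign[m]:
                        total += 1
                        found += (g, m) in got
        assert total > 0
        assert found / total >= 0.95


class TestBiotypeSummary:
    def test_counts(self):
        _, assignment = toy_assignment()
        table = ant.biotype_summary(assignment, {"g1": "mRNA", "g2": "mRNA"})
        cid = assignment.membership["A"]
        rows = table[table["community"] == cid]
        counts = dict(zip(rows["biotype"], rows["count"]))
        assert counts == {"mRNA": 2, "unknown": 1}

    def test_total_conserved_under_shuffling(self):
        _, assignment = toy_assignment()
        rng = np.random.default_rng(0)
        genes = ["g1", "g2", "g3"]
        labels = ["mRNA", "lncRNA", "miRNA"]
        totals = set()
        for _ in range(5):
            perm = rng.permutation(labels)
            table = ant.biotype_summary(assignment, dict(zip(genes, perm)))
            totals.add(int(table["count"].sum()))
        assert totals == {3}

    def test_empty_annotation_all_unknown(self):
        _, assignment = toy_assignment()
        table = ant.biotype_summary(assignment)
        assert set(table["biotype"]) == {"unknown"}
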
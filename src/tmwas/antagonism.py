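"""Opposing-direction gene-metabolite pairs within anchored communities.

A community member's direction is the sign of its association with the
community's functional anchor ([+] or [-]). An antagonistic pair is a
gene and a metabolite in the same community pointing in opposite
directions relative to that anchor — the readout that separates adaptive
from adverse signaling arms of one functional response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import pandas as pd

from .types import AntagonisticPair, Block, CommunityAssignment


@dataclass
class SignPartition:
    """Community members split by direction relative to an anchor (group).

    Per omics block: ``positive`` / ``negative`` members with a direct,
    sign-consistent anchor edge; ``indirect`` members with no direct edge
    to any anchor of the group; ``discordant`` members whose signs
    disagree across the group's anchors.
    """

    anchor_ids: tuple[str, ...]
    community: int
    positive: dict[Block, list[str]] = field(default_factory=dict)
    negative: dict[Block, list[str]] = field(default_factory=dict)
    indirect: dict[Block, list[str]] = field(default_factory=dict)
    discordant: dict[Block, list[str]] = field(default_factory=dict)

    def side(self, block: Block, sign: int) -> list[str]:
        bucket = self.positive if sign > 0 else self.negative
        return bucket.get(block, [])


def sign_partition(assignment: CommunityAssignment,
                   anchor_id: str | Sequence[str]) -> SignPartition:
    """Split an anchor's community members by anchor-association sign.

    ``anchor_id`` may be a single anchor or an anchor group; with a group,
    a member's signs against every group anchor it touches must agree,
    otherwise it is flagged discordant rather than silently assigned.
    Functional-block nodes (the anchors' own block) are not partitioned.
    """
    anchors = (anchor_id,) if isinstance(anchor_id, str) else tuple(anchor_id)
    for a in anchors:
        if a not in assignment.membership:
            raise KeyError(f"anchor {a!r} not present in the assignment")
    cid = assignment.membership[anchors[0]]
    if any(assignment.membership[a] != cid for a in anchors[1:]):
        raise ValueError(f"anchor group {anchors} spans multiple communities")

    part = SignPartition(anchor_ids=anchors, community=cid)
    for node, node_cid in assignment.membership.items():
        if node_cid != cid or node in anchors:
            continue
        block = assignment.node_block[node]
        if block is Block.FUNCTIONAL:
            continue
        signs = {assignment.signs[(node, a)] for a in anchors
                 if (node, a) in assignment.signs}
        if not signs:
            part.indirect.setdefault(block, []).append(node)
        elif len(signs) > 1:
            part.discordant.setdefault(block, []).append(node)
        elif signs == {1}:
            part.positive.setdefault(block, []).append(node)
        else:
            part.negative.setdefault(block, []).append(node)
    for bucket in (part.positive, part.negative, part.indirect, part.discordant):
        for members in bucket.values():
            members.sort()
    return part


def _anchor_r(graph: nx.Graph, node: str, anchors: tuple[str, ...]) -> float:
    """Strongest direct node-anchor association r across the group."""
    best = 0.0
    for a in anchors:
        if graph.has_edge(node, a):
            r = graph.edges[node, a]["r"]
            if abs(r) > abs(best):
                best = r
    return best


def antagonistic_pairs(graph: nx.Graph, assignment: CommunityAssignment,
                       anchor_id: str | Sequence[str],
                       top_k: int | None = None) -> list[AntagonisticPair]:
    """Ranked opposite-sign (gene, metabolite) pairs for one anchor.

    The candidate set is the cross product of opposite-direction
    transcriptome and metabolome members of the anchor's community; pairs
    are ranked by min(|gene_r|, |metabolite_r|) descending (ties broken
    lexicographically) and the direct gene-metabolite association is
    attached when such an edge survived thresholding. Returns the top_k
    pairs, or all pairs when top_k is None. Empty sides yield an empty
    list.
    """
    part = sign_partition(assignment, anchor_id)
    anchors = part.anchor_ids
    pairs: list[AntagonisticPair] = []
    for gene_sign, met_sign in ((1, -1), (-1, 1)):
        genes = part.side(Block.TRANSCRIPTOME, gene_sign)
        mets = part.side(Block.METABOLOME, met_sign)
        for gene in genes:
            for met in mets:
                pair_r = (float(graph.edges[gene, met]["r"])
                          if graph.has_edge(gene, met) else None)
                pairs.append(AntagonisticPair(
                    gene_id=gene, metabolite_id=met, anchor_id="+".join(anchors),
                    gene_sign=gene_sign, metabolite_sign=met_sign,
                    gene_r=_anchor_r(graph, gene, anchors),
                    metabolite_r=_anchor_r(graph, met, anchors),
                    pair_r=pair_r))
    pairs.sort(key=lambda p: (-p.rank_score, p.gene_id, p.metabolite_id))
    return pairs if top_k is None else pairs[:top_k]


def pairs_to_frame(pairs: Sequence[AntagonisticPair]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": p.gene_id, "metabolite_id": p.metabolite_id,
            "anchor_id": p.anchor_id,
            "gene_sign": p.gene_sign, "metabolite_sign": p.metabolite_sign,
            "gene_r": p.gene_r, "metabolite_r": p.metabolite_r,
            "pair_r": p.pair_r if p.pair_r is not None else float("nan"),
            "rank_score": p.rank_score,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=[
        "gene_id", "metabolite_id", "anchor_id", "gene_sign",
        "metabolite_sign", "gene_r", "metabolite_r", "pair_r", "rank_score"])


def biotype_summary(assignment: CommunityAssignment,
                    biotypes: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-community transcript counts by biotype.

    ``biotypes`` maps gene id -> biotype; unmapped genes count as
    ``unknown``. The per-community total equals the community's gene
    count.
    """
    biotypes = biotypes or {}
    counts: dict[tuple[int, str], int] = {}
    for node, cid in assignment.membership.items():
        if assignment.node_block[node] is not Block.TRANSCRIPTOME:
            continue
        bt = biotypes.get(node, "unknown")
        counts[(cid, bt)] = counts.get((cid, bt), 0) + 1
    rows = [{"community": cid, "biotype": bt, "count": n}
            for (cid, bt), n in sorted(counts.items())]
    return pd.DataFrame(rows, columns=["community", "biotype", "count"])
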
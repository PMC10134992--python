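#!/usr/bin/env python
"""Pairwise PLS integration of the three preprocessed blocks.

Fits deterministic NIPALS PLS (3 components — one per functional anchor
program) for functional~metabolome, functional~transcriptome and
metabolome~transcriptome, scores every cross-block feature pair on the
correlation scale and keeps edges with |r| > 0.8 and p < 0.05 (t-test,
n - 2 df, n = 6 dose conditions). Writes edge tables under
results/analysis/edges/.
"""

from pathlib import Path

from tmwas import io as tio
from tmwas import pls
from tmwas.types import Block

PROC = Path("results/analysis/proc")
OUT = Path("results/analysis/edges")

PAIRS = ((Block.FUNCTIONAL, Block.METABOLOME),
         (Block.FUNCTIONAL, Block.TRANSCRIPTOME),
         (Block.METABOLOME, Block.TRANSCRIPTOME))


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    blocks = {bid: tio.read_feature_table(PROC / f"{bid.value}.tsv", bid)
              for bid in Block}
    n_comp = min(blocks[Block.FUNCTIONAL].shape[0],
                 len(blocks[Block.FUNCTIONAL].sample_ids) - 1)
    for a, b in PAIRS:
        _, edges = pls.integrate(blocks[a], blocks[b], n_components=n_comp,
                                 r_threshold=0.8, p_threshold=0.05)
        tio.write_edges(edges, OUT / f"{a.value}_{b.value}.tsv")
        strongest = edges[0] if edges else None
        print(f"{a.value}~{b.value}: {len(edges)} edges pass |r|>0.8, p<0.05"
              + (f"; strongest {strongest.source_id}~{strongest.target_id} "
                 f"r={strongest.r:+.3f}" if strongest else ""))


if __name__ == "__main__":
    main()
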
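#!/usr/bin/env python
"""Preprocess the three blocks to per-dose profiles.

Metabolome: 80% presence filter -> quantile normalization -> log2 ->
per-dose median collapse. Transcriptome (taken as already
variance-stabilized) and the functional parameters: median collapse only.
Writes the collapsed 6-condition matrices under results/analysis/proc/.
"""

from pathlib import Path

from tmwas import io as tio
from tmwas import preprocess
from tmwas.types import Block

DATA = Path("results/analysis/data")
OUT = Path("results/analysis/proc")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    design = tio.read_design(DATA / "design.tsv")
    for bid in Block:
        block = tio.read_feature_table(DATA / f"{bid.value}.tsv", bid)
        done = preprocess.preprocess_block(block, design)
        tio.write_feature_table(done, OUT / f"{bid.value}.tsv")
        print(f"{bid.value}: {block.shape} -> {done.shape} "
              f"(columns now per-dose medians)")


if __name__ == "__main__":
    main()
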
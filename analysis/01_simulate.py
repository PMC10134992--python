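#!/usr/bin/env python
"""Generate the synthetic dose-response study.

Three anchors (cellular Mn: increasing; thiols: decreasing; basal OCR:
biphasic/hormetic) over a control + 5 log-spaced Mn doses with 3
replicates; 40 planted metabolome and 40 transcriptome features per
anchor (half coupled positively, half negatively), 200 noise features per
omics block, replicate noise sd 0.15 on the log-intensity scale.

Writes the replicate-level blocks, the dose design and the planted truth
under results/analysis/data/.
"""

from pathlib import Path

from tmwas import io as tio
from tmwas import synth
from tmwas.types import Block

OUT = Path("results/analysis/data")
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scenario = synth.default_scenario()
    blocks, design, truth = synth.generate(scenario, seed=SEED)

    tio.write_design(design, OUT / "design.tsv")
    for bid, block in blocks.items():
        tio.write_feature_table(block, OUT / f"{bid.value}.tsv")
    tio.write_annotation_table(blocks[Block.TRANSCRIPTOME],
                               OUT / "biotype_annotation.tsv")
    truth.to_frame().to_csv(OUT / "truth.tsv", sep="\t", index=False)

    print(f"design: {design.n_conditions} conditions, "
          f"{len(design.replicate_columns)} replicate columns")
    for bid, block in blocks.items():
        print(f"{bid.value}: {block.shape[0]} features x "
              f"{block.shape[1]} replicate columns")
    n_planted = len(truth.planted_features())
    print(f"planted features: {n_planted} "
          f"({n_planted // 2} per omics block), noise: 400")


if __name__ == "__main__":
    main()
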
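#!/usr/bin/env python
"""Annotate metabolome m/z values and test pathway enrichment per community.

Features are matched to the packaged metabolite library through positive-
mode adducts (M+H, M+Na, M+H-H2O) at 10 ppm; each anchored community's
metabolome members are then tested for pathway over-representation by
permutation (1000 draws), counting distinct pathway metabolites hit, and
pathways with overlap > 3 are retained.

Writes annotations.tsv and enrichment_<anchor>.tsv under
results/analysis/enrichment/.
"""

import dataclasses
from pathlib import Path

import pandas as pd

from tmwas import enrich
from tmwas import io as tio
from tmwas.types import Block

PROC = Path("results/analysis/proc")
NET = Path("results/analysis/network")
OUT = Path("results/analysis/enrichment")
SEED = 7


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    met = tio.read_feature_table(PROC / "metabolome.tsv", Block.METABOLOME)
    db = tio.read_gmt(tio.default_fixture_path("pathways.gmt"))
    masses = tio.read_metabolite_masses(
        tio.default_fixture_path("metabolite_masses.tsv"))
    adducts = tio.read_adducts(tio.default_fixture_path("adducts.tsv"))

    annotations = enrich.annotate_mz(met.feature_meta, masses, adducts,
                                     tolerance_ppm=10, ion_mode="positive")
    pd.DataFrame([dataclasses.asdict(a) for a in annotations]).to_csv(
        OUT / "annotations.tsv", sep="\t", index=False, float_format="%.8g")
    annotated = len({a.feature_id for a in annotations})
    print(f"annotation: {annotated}/{met.shape[0]} features matched "
          f"({len(annotations)} candidate records)")

    communities = pd.read_csv(NET / "communities.tsv", sep="\t")
    mets = communities[communities["block"] == "metabolome"]
    universe = met.feature_ids
    for label, group in mets.groupby("label"):
        if label == "unanchored":
            continue
        significant = sorted(set(group["node"]) & set(universe))
        results = enrich.pathway_permutation_test(
            significant, universe, annotations, db, n_perm=1000, seed=SEED)
        kept = enrich.filter_pathways(results, min_overlap=3)
        enrich.results_to_frame(results).to_csv(
            OUT / f"enrichment_{label}.tsv", sep="\t", index=False,
            float_format="%.6g")
        top = sorted(kept, key=lambda r: r.p_perm)[:2]
        summary = ", ".join(f"{r.name} (overlap {r.overlap}, "
                            f"p_perm={r.p_perm:.3g})" for r in top) or "none"
        print(f"community [{label}]: {len(significant)} metabolome members; "
              f"{len(kept)}/{len(results)} pathways pass overlap>3; "
              f"top: {summary}")


if __name__ == "__main__":
    main()
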
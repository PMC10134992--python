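"""End-to-end driver: data -> preprocessing -> three pairwise PLS
integrations -> signed network -> communities -> antagonistic pairs ->
pathway enrichment, with a reproducible run manifest.

Inputs are either the three on-disk feature tables plus a dose-design TSV,
or a synthetic scenario. All randomness flows from a single seed; rerunning
with the same configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import antagonism as ant
from . import enrich as enr
from . import io as tio
from . import netcomm, pls, preprocess, synth
from .types import Block, CommunityAssignment, OmicsBlock

log = logging.getLogger("tmwas")

PAIRS = (
    (Block.FUNCTIONAL, Block.METABOLOME),
    (Block.FUNCTIONAL, Block.TRANSCRIPTOME),
    (Block.METABOLOME, Block.TRANSCRIPTOME),
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    When the three ``*_path`` entries are unset the packaged synthetic
    scenario generates the inputs. ``n_components="auto"`` resolves to
    min(#functional features, n_conditions - 1): the latent space must be
    able to span one axis per functional anchor program.
    """

    functional_path: str | None = None
    metabolome_path: str | None = None
    transcriptome_path: str | None = None
    design_path: str | None = None
    annotation_path: str | None = None

    r_threshold: float = 0.8
    p_threshold: float = 0.05
    stringency: list[float] = field(default_factory=lambda: [0.8, 0.9])
    n_components: int | str = "auto"
    resolution: float = 1.0
    split_multi_anchor: bool = True
    min_fraction: float = 0.8
    pseudocount: float = 1.0
    top_k_pairs: int = 50

    ppm_tolerance: float = 10.0
    ion_mode: str = "positive"
    n_perm: int = 1000
    min_overlap: int = 3
    pathways_path: str | None = None   # default: packaged fixture
    masses_path: str | None = None
    adducts_path: str | None = None

    seed: int = 7

    def __post_init__(self) -> None:
        for t in (self.r_threshold, self.p_threshold):
            if not 0 < t < 1:
                raise ValueError("thresholds must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _load_inputs(config: RunConfig):
    paths = (config.functional_path, config.metabolome_path,
             config.transcriptome_path)
    if any(paths):
        if not all(paths) or config.design_path is None:
            raise ValueError("file input requires all three block paths and a design")
        design = tio.read_design(config.design_path)
        blocks = {
            Block.FUNCTIONAL: tio.read_feature_table(
                config.functional_path, Block.FUNCTIONAL),
            Block.METABOLOME: tio.read_feature_table(
                config.metabolome_path, Block.METABOLOME),
            Block.TRANSCRIPTOME: tio.read_feature_table(
                config.transcriptome_path, Block.TRANSCRIPTOME,
                annotation=config.annotation_path),
        }
        truth = None
    else:
        scenario = synth.default_scenario()
        blocks, design, truth = synth.generate(scenario, seed=config.seed)
    return blocks, design, truth


def _resolve_components(config: RunConfig, functional: OmicsBlock,
                        n_conditions: int) -> int:
    if config.n_components == "auto":
        return max(1, min(functional.shape[0], n_conditions - 1))
    return int(config.n_components)


def _check_alignment(blocks: dict[Block, OmicsBlock]) -> dict[Block, OmicsBlock]:
    ref = blocks[Block.FUNCTIONAL].sample_ids
    out = {}
    for bid, block in blocks.items():
        if set(block.sample_ids) != set(ref):
            raise ValueError(
                f"sample ids of {bid.value} do not match the functional block: "
                f"{sorted(set(block.sample_ids) ^ set(ref))}")
        out[bid] = block.reindex_samples(ref)
    return out


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis; returns the run directory.

    Writes, under ``out_dir``: the (possibly synthetic) input tables, the
    per-pair edge lists, the GraphML network with its community table, the
    stringency nesting report, per-anchor sign partitions and antagonistic
    pair tables, metabolite pathway enrichment, the biotype summary, the
    per-community report, and ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    blocks, design, truth = _load_inputs(config)
    blocks = _check_alignment(blocks)
    log.info("loaded blocks: %s",
             {b.value: blk.shape for b, blk in blocks.items()})

    tio.write_design(design, out / "design.tsv")
    for bid, block in blocks.items():
        tio.write_feature_table(block, out / f"input_{bid.value}.tsv")
    if truth is not None:
        truth.to_frame().to_csv(out / "truth.tsv", sep="\t", index=False)

    proc = {bid: preprocess.preprocess_block(
        block, design, config.min_fraction, config.pseudocount)
        for bid, block in blocks.items()}
    for bid, block in proc.items():
        log.info("preprocessed %s: %s -> %s", bid.value,
                 blocks[bid].shape, block.shape)

    n_cond = design.n_conditions
    n_comp = _resolve_components(config, proc[Block.FUNCTIONAL], n_cond)

    edge_lists = []
    for a, b in PAIRS:
        r_matrix, edges = pls.integrate(
            proc[a], proc[b], n_components=n_comp,
            r_threshold=config.r_threshold, p_threshold=config.p_threshold)
        edge_lists.append(edges)
        tio.write_edges(edges, out / f"edges_{a.value}_{b.value}.tsv")
        log.info("integration %s~%s: %d edges", a.value, b.value, len(edges))

    graph = netcomm.build_graph(edge_lists)
    assignment = netcomm.detect_communities(
        graph, resolution=config.resolution, seed=config.seed)
    if config.split_multi_anchor:
        assignment = netcomm.split_multi_anchor_communities(
            graph, assignment, resolution=config.resolution, seed=config.seed)
    log.info("communities: %d (Q=%.3f) labels=%s",
             len(set(assignment.membership.values())),
             assignment.modularity, assignment.labels)
    assignment.to_frame().to_csv(out / "communities.tsv", sep="\t", index=False)
    tio.write_network(_all_edges(edge_lists), assignment, out / "network.graphml")

    all_edges = _all_edges(edge_lists)
    stringency = netcomm.stringency_compare(
        all_edges, config.stringency, config.resolution, config.seed)
    pd.DataFrame(stringency).to_csv(out / "stringency.tsv", sep="\t",
                                    index=False, float_format="%.12g")

    anchors_present = sorted(
        {a for anchors in assignment.anchor_map.values() for a in anchors})
    partition_rows = []
    for anchor in anchors_present:
        part = ant.sign_partition(assignment, anchor)
        for bucket_name, bucket in (("positive", part.positive),
                                    ("negative", part.negative),
                                    ("indirect", part.indirect),
                                    ("discordant", part.discordant)):
            for block, members in sorted(bucket.items()):
                for member in members:
                    partition_rows.append({
                        "anchor": anchor, "direction": bucket_name,
                        "block": block.value, "feature_id": member})
        pairs = ant.antagonistic_pairs(graph, assignment, anchor,
                                       top_k=config.top_k_pairs)
        ant.pairs_to_frame(pairs).to_csv(
            out / f"pairs_{anchor}.tsv", sep="\t", index=False,
            float_format="%.12g")
    pd.DataFrame(partition_rows,
                 columns=["anchor", "direction", "block", "feature_id"]
                 ).to_csv(out / "sign_partitions.tsv", sep="\t", index=False)

    _run_enrichment(config, blocks[Block.METABOLOME], proc[Block.METABOLOME],
                    edge_lists[0], assignment, out)

    biotypes = {}
    meta = blocks[Block.TRANSCRIPTOME].feature_meta
    if meta is not None and "biotype" in meta:
        biotypes = meta["biotype"].to_dict()
    ant.biotype_summary(assignment, biotypes).to_csv(
        out / "biotypes.tsv", sep="\t", index=False)

    community_report(assignment).to_csv(out / "report.tsv", sep="\t",
                                        index=False)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "seed": config.seed,
        "n_components": n_comp,
        "versions": _versions(),
        "outputs": _checksums(out),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out


def _all_edges(edge_lists):
    merged = [e for edges in edge_lists for e in edges]
    merged.sort(key=lambda e: (-abs(e.r), e.source_id, e.target_id))
    return merged


def _run_enrichment(config: RunConfig, met_raw: OmicsBlock,
                    met_proc: OmicsBlock, func_met_edges,
                    assignment: CommunityAssignment, out: Path) -> None:
    if met_raw.feature_meta is None or "mz" not in met_raw.feature_meta:
        log.info("metabolome has no m/z metadata; skipping enrichment")
        return
    db = tio.read_gmt(config.pathways_path or
                      tio.default_fixture_path("pathways.gmt"))
    masses = tio.read_metabolite_masses(
        config.masses_path or tio.default_fixture_path("metabolite_masses.tsv"))
    adducts = tio.read_adducts(config.adducts_path or
                               tio.default_fixture_path("adducts.tsv"))

    universe = met_proc.feature_ids
    meta = met_raw.feature_meta.loc[universe]
    annotations = enr.annotate_mz(meta, masses, adducts,
                                  config.ppm_tolerance, config.ion_mode)
    pd.DataFrame([dataclasses.asdict(a) for a in annotations]).to_csv(
        out / "annotations.tsv", sep="\t", index=False, float_format="%.8g")

    def run_one(significant: list[str], tag: str) -> None:
        results = enr.pathway_permutation_test(
            significant, universe, annotations, db,
            n_perm=config.n_perm, seed=config.seed)
        enr.results_to_frame(results).to_csv(
            out / f"enrichment_{tag}.tsv", sep="\t", index=False,
            float_format="%.12g")
        kept = enr.filter_pathways(results, config.min_overlap)
        enr.results_to_frame(kept).to_csv(
            out / f"enrichment_{tag}_filtered.tsv", sep="\t", index=False,
            float_format="%.12g")
        log.info("enrichment[%s]: %d significant features, %d/%d pathways "
                 "pass the overlap filter", tag, len(significant),
                 len(kept), len(results))

    # global: metabolome features passing the functional-block thresholds
    universe_set = set(universe)
    significant = sorted(
        {e.target_id for e in func_met_edges
         if e.target_block is Block.METABOLOME}
        | {e.source_id for e in func_met_edges
           if e.source_block is Block.METABOLOME})
    run_one([f for f in significant if f in universe_set], "all")

    # per anchored community: its metabolome members
    for cid, anchors in sorted(assignment.anchor_map.items()):
        members = sorted(
            n for n, c in assignment.membership.items()
            if c == cid and assignment.node_block[n] is Block.METABOLOME
            and n in universe_set)
        run_one(members, assignment.labels.get(cid, str(cid)))


def community_report(assignment: CommunityAssignment) -> pd.DataFrame:
    """Per-(community, anchor) counts of genes/metabolites split by sign."""
    rows = []
    for cid in sorted(set(assignment.membership.values())):
        anchors = assignment.anchor_map.get(cid, [])
        members = [n for n, c in assignment.membership.items() if c == cid]
        base = {
            "community": cid,
            "label": assignment.labels.get(cid, ""),
            "n_nodes": len(members),
            "n_genes": sum(assignment.node_block[n] is Block.TRANSCRIPTOME
                           for n in members),
            "n_metabolites": sum(assignment.node_block[n] is Block.METABOLOME
                                 for n in members),
        }
        if not anchors:
            rows.append({**base, "anchor": "", "genes_pos": 0, "genes_neg": 0,
                         "mets_pos": 0, "mets_neg": 0})
            continue
        for anchor in anchors:
            part = ant.sign_partition(assignment, anchor)
            rows.append({
                **base, "anchor": anchor,
                "genes_pos": len(part.positive.get(Block.TRANSCRIPTOME, [])),
                "genes_neg": len(part.negative.get(Block.TRANSCRIPTOME, [])),
                "mets_pos": len(part.positive.get(Block.METABOLOME, [])),
                "mets_neg": len(part.negative.get(Block.METABOLOME, [])),
            })
    return pd.DataFrame(rows, columns=[
        "community", "label", "anchor", "n_nodes", "n_genes", "n_metabolites",
        "genes_pos", "genes_neg", "mets_pos", "mets_neg"])


def _versions() -> dict[str, str]:
    import igraph
    import networkx
    import numpy
    import pandas as pd_mod
    import scipy
    import sklearn

    from . import __version__
    return {
        "tmwas": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "pandas": pd_mod.__version__,
        "networkx": networkx.__version__,
        "igraph": igraph.__version__,
        "sklearn": sklearn.__version__,
    }


def _checksums(out: Path) -> dict[str, str]:
    sums = {}
    for path in sorted(out.glob("*")):
        if path.name == "manifest.json" or path.is_dir():
            continue
        sums[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    return sums
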
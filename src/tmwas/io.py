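"""Readers and writers for feature tables, fixtures and network outputs.

Feature tables are tab-separated text with a header row and the feature id
in the first column; metabolome tables carry ``mz`` and ``time`` columns
(apLCMS-style) ahead of the sample intensities. Networks are written as
GraphML with a companion flat edge TSV. Pathways use GMT-style lines and
adduct/mass fixtures are plain TSV.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    Adduct,
    AdductTable,
    AssociationEdge,
    Block,
    CommunityAssignment,
    DoseDesign,
    OmicsBlock,
    PathwayDB,
)

METABOLOME_META_COLUMNS = ("mz", "time")


def read_feature_table(path: str | Path, block_id: Block | str,
                       annotation: str | Path | None = None) -> OmicsBlock:
    """Read a delimited feature table into an :class:`OmicsBlock`.

    Metabolome tables must carry ``mz`` and ``time`` as their first two
    data columns; these become feature metadata (``mz`` in Da, ``rt`` in
    seconds). For transcriptome blocks an optional two-column
    ``annotation`` TSV (feature_id, biotype) attaches biotypes; features
    without an annotation get ``"unknown"``.

    Zero intensities are preserved as zeros, not treated as missing.
    Duplicated feature ids or non-numeric cells are hard errors.
    """
    block_id = Block(block_id)
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    if not df.index.is_unique:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated feature ids {dups}")

    meta = None
    if block_id is Block.METABOLOME:
        missing = [c for c in METABOLOME_META_COLUMNS if c not in df.columns[:2]]
        if missing:
            raise ValueError(
                f"{path}: metabolome table must start with columns "
                f"{METABOLOME_META_COLUMNS}, missing {missing}")
        meta = df.loc[:, list(METABOLOME_META_COLUMNS)].astype(float)
        meta = meta.rename(columns={"time": "rt"})
        df = df.drop(columns=list(METABOLOME_META_COLUMNS))

    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = df.index[bad | df[col].isna()][0]
            raise ValueError(f"{path}: non-numeric or missing cell at "
                             f"feature {row!r}, column {col!r}")
        df[col] = coerced.astype(float)

    if block_id is Block.TRANSCRIPTOME:
        biotype = pd.Series("unknown", index=df.index, name="biotype")
        if annotation is not None:
            ann = pd.read_csv(annotation, sep="\t", header=None,
                              names=["feature_id", "biotype"], dtype=str)
            ann = ann.set_index("feature_id")["biotype"]
            known = ann.index.intersection(df.index)
            biotype.loc[known] = ann.loc[known]
        meta = biotype.to_frame()

    return OmicsBlock(block_id, df, meta)


def write_feature_table(block: OmicsBlock, path: str | Path) -> Path:
    """Write an :class:`OmicsBlock` in the dialect :func:`read_feature_table` reads."""
    path = Path(path)
    out = block.values.copy()
    if block.block_id is Block.METABOLOME:
        if block.feature_meta is None or "mz" not in block.feature_meta:
            raise ValueError("metabolome block requires mz/rt metadata to serialize")
        meta = block.feature_meta.loc[:, ["mz", "rt"]].rename(columns={"rt": "time"})
        out = pd.concat([meta, out], axis=1)
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t", float_format="%.12g")
    return path


def write_annotation_table(block: OmicsBlock, path: str | Path) -> Path:
    """Write a transcriptome biotype annotation TSV (feature_id, biotype)."""
    if block.feature_meta is None or "biotype" not in block.feature_meta:
        raise ValueError("block has no biotype metadata")
    block.feature_meta["biotype"].to_csv(path, sep="\t", header=False)
    return Path(path)


def write_design(design: DoseDesign, path: str | Path) -> Path:
    """Write the dose design as TSV (condition, dose, comma-joined replicates)."""
    rows = [
        {"condition": lab, "dose": dose,
         "replicates": ",".join(design.replicate_map.get(lab, []))}
        for lab, dose in zip(design.condition_labels, design.dose_values)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")
    return Path(path)


def read_design(path: str | Path) -> DoseDesign:
    df = pd.read_csv(path, sep="\t", dtype={"condition": str, "replicates": str})
    replicate_map = {
        str(r["condition"]): ([] if pd.isna(r["replicates"]) or not r["replicates"]
                              else str(r["replicates"]).split(","))
        for _, r in df.iterrows()
    }
    return DoseDesign(
        condition_labels=[str(c) for c in df["condition"]],
        dose_values=[float(d) for d in df["dose"]],
        replicate_map=replicate_map)


def read_gmt(path: str | Path) -> PathwayDB:
    """Read GMT-style pathway definitions (id, name, tab-separated members).

    The reference universe is the union of all pathway members.
    """
    pathways: list[tuple[str, str, frozenset[str]]] = []
    universe: set[str] = set()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed GMT line {line!r}")
        pid, name, members = parts[0], parts[1], frozenset(parts[2:])
        pathways.append((pid, name, members))
        universe |= members
    return PathwayDB(pathways, frozenset(universe))


def write_gmt(db: PathwayDB, path: str | Path) -> Path:
    lines = ["\t".join([pid, name, *sorted(members)])
             for pid, name, members in db.pathways]
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def read_adducts(path: str | Path) -> AdductTable:
    """Read an adduct TSV with columns name, mass_shift, charge, mode."""
    df = pd.read_csv(path, sep="\t")
    rows = [
        Adduct(str(r["name"]), float(r["mass_shift"]), int(r["charge"]), str(r["mode"]))
        for _, r in df.iterrows()
    ]
    return AdductTable(rows)


def read_metabolite_masses(path: str | Path) -> pd.DataFrame:
    """Read metabolite monoisotopic masses (metabolite_id, name, formula, mass)."""
    df = pd.read_csv(path, sep="\t", dtype={"metabolite_id": str})
    return df.set_index("metabolite_id")


def default_fixture_path(name: str) -> Path:
    """Path of a packaged text fixture (pathways.gmt, adducts.tsv, ...)."""
    return Path(str(importlib.resources.files("tmwas").joinpath("data", name)))


def edges_to_frame(edges: Iterable[AssociationEdge]) -> pd.DataFrame:
    rows = [
        {
            "source_id": e.source_id,
            "target_id": e.target_id,
            "source_block": e.source_block.value,
            "target_block": e.target_block.value,
            "r": e.r,
            "p": e.p,
            "n": e.n,
        }
        for e in edges
    ]
    return pd.DataFrame(
        rows, columns=["source_id", "target_id", "source_block",
                       "target_block", "r", "p", "n"])


def write_edges(edges: Iterable[AssociationEdge], path: str | Path) -> Path:
    edges_to_frame(edges).to_csv(path, sep="\t", index=False, float_format="%.12g")
    return Path(path)


def read_edges(path: str | Path) -> list[AssociationEdge]:
    df = pd.read_csv(path, sep="\t", dtype={"source_id": str, "target_id": str})
    return [
        AssociationEdge(
            source_id=r["source_id"],
            target_id=r["target_id"],
            source_block=Block(r["source_block"]),
            target_block=Block(r["target_block"]),
            r=float(r["r"]),
            p=float(r["p"]),
            n=int(r["n"]),
        )
        for _, r in df.iterrows()
    ]


def write_network(edges: list[AssociationEdge],
                  communities: CommunityAssignment,
                  path: str | Path) -> tuple[Path, Path]:
    """Serialize the association network as GraphML plus a flat edge TSV.

    Node attributes: block, community, label; edge attributes: r, p, sign,
    weight (|r|). Edges naming a node absent from ``communities`` are a
    hard error. Returns (graphml_path, edge_tsv_path).
    """
    path = Path(path)
    graph = nx.Graph()
    for node in sorted(communities.membership):
        graph.add_node(
            node,
            block=communities.node_block[node].value,
            community=int(communities.membership[node]),
            label=communities.labels.get(communities.membership[node], ""),
        )
    for e in edges:
        for node in (e.source_id, e.target_id):
            if node not in graph:
                raise ValueError(f"edge references unknown node {node!r}")
        graph.add_edge(e.source_id, e.target_id, r=float(e.r), p=float(e.p),
                       sign=e.sign, weight=abs(float(e.r)))
    graph.graph["modularity"] = float(communities.modularity)
    nx.write_graphml(graph, path)
    tsv_path = path.with_suffix(".edges.tsv")
    write_edges(edges, tsv_path)
    return path, tsv_path


def read_network(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
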
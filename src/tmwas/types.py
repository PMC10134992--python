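"""Core domain types for dose-series multi-omics association analysis.

Three data blocks enter the analysis: a small matrix of functional
(mitochondrial/cellular) parameters, a metabolome feature table and a
transcriptome expression matrix, all measured over the same ordered dose
conditions. Every type here is a thin, validated container; computation
lives in the sibling modules.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


class Block(str, enum.Enum):
    """Identity of a data block in the integration."""

    FUNCTIONAL = "functional"
    METABOLOME = "metabolome"
    TRANSCRIPTOME = "transcriptome"


BIOTYPES = ("mRNA", "lncRNA", "miRNA", "sncRNA", "unknown")


@dataclass
class OmicsBlock:
    """One features x samples matrix with per-feature metadata.

    ``values`` is a pandas DataFrame indexed by feature id with sample ids
    as columns; ``feature_meta`` (optional) is indexed identically and may
    carry ``mz``/``rt`` columns for metabolome blocks or a ``biotype``
    column for transcriptome blocks.
    """

    block_id: Block
    values: pd.DataFrame
    feature_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.block_id = Block(self.block_id)
        if not self.values.index.is_unique:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated feature ids: {dups}")
        non_numeric = [c for c in self.values.columns
                       if not np.issubdtype(self.values[c].dtype, np.number)]
        if non_numeric:
            raise ValueError(f"non-numeric sample columns: {non_numeric}")
        if self.feature_meta is not None and not self.feature_meta.index.equals(self.values.index):
            self.feature_meta = self.feature_meta.reindex(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return [str(i) for i in self.values.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.values.columns]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def matrix(self) -> np.ndarray:
        """Feature x sample values as a float array."""
        return self.values.to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame) -> "OmicsBlock":
        """New block sharing metadata, restricted to ``values``' features."""
        meta = None
        if self.feature_meta is not None:
            meta = self.feature_meta.reindex(values.index)
        return OmicsBlock(self.block_id, values, meta)

    def reindex_samples(self, sample_ids: Sequence[str]) -> "OmicsBlock":
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValueError(f"block {self.block_id.value} lacks samples {missing}")
        return self.with_values(self.values.loc[:, list(sample_ids)])


@dataclass
class DoseDesign:
    """Ordered dose conditions (control first) and their replicate columns.

    ``replicate_map`` maps each condition label to the replicate-level
    column names belonging to it; it is only meaningful before the
    per-dose median collapse.
    """

    condition_labels: list[str]
    dose_values: list[float]
    replicate_map: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.condition_labels) != len(self.dose_values):
            raise ValueError("condition_labels and dose_values length mismatch")
        if not self.dose_values or self.dose_values[0] != 0.0:
            raise ValueError("control (dose 0) must be present and first")
        diffs = np.diff(self.dose_values)
        if np.any(diffs <= 0):
            raise ValueError("doses must be strictly increasing in label order")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    @property
    def replicate_columns(self) -> list[str]:
        cols: list[str] = []
        for label in self.condition_labels:
            cols.extend(self.replicate_map.get(label, []))
        return cols


@dataclass
class PathwayDB:
    """Named metabolite sets over a reference universe of metabolite ids."""

    pathways: list[tuple[str, str, frozenset[str]]]
    reference_metabolites: frozenset[str]

    def __post_init__(self) -> None:
        for pid, _name, members in self.pathways:
            if len(members) < 1:
                raise ValueError(f"pathway {pid} is empty")
            stray = members - self.reference_metabolites
            if stray:
                raise ValueError(f"pathway {pid} members outside universe: {sorted(stray)}")

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class Adduct:
    name: str
    mass_shift: float  # Da
    charge: int
    ion_mode: str  # "positive" | "negative"

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be nonzero")
        if self.ion_mode not in ("positive", "negative"):
            raise ValueError(f"unknown ion mode {self.ion_mode!r}")


@dataclass
class AdductTable:
    rows: list[Adduct]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for row in self.rows:
            key = (row.name, row.ion_mode)
            if key in seen:
                raise ValueError(f"duplicate adduct {key}")
            seen.add(key)

    def for_mode(self, ion_mode: str) -> list[Adduct]:
        return [r for r in self.rows if r.ion_mode == ion_mode]


@dataclass(frozen=True)
class AssociationEdge:
    """A scored, signed cross-block feature pair.

    ``r`` is the PLS-derived association score on the correlation scale;
    ``p`` its two-sided p-value under the correlation t-test at ``n``
    conditions.
    """

    source_id: str
    target_id: str
    source_block: Block
    target_block: Block
    r: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-9:
            raise ValueError(f"|r|={abs(self.r)} exceeds 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"p={self.p} outside [0,1]")
        if self.source_block == self.target_block:
            raise ValueError("association edges are cross-block only")

    @property
    def sign(self) -> int:
        return 1 if self.r >= 0 else -1


@dataclass
class CommunityAssignment:
    """Node -> community partition with anchor labels and signs.

    ``signs`` maps (node, anchor) to +1/-1 from the r of the node's direct
    edge to that anchor; absent when no direct edge exists.
    """

    membership: dict[str, int]
    node_block: dict[str, Block]
    signs: dict[tuple[str, str], int]
    anchor_map: dict[int, list[str]]
    modularity: float
    labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not -0.5 - 1e-9 <= self.modularity <= 1.0 + 1e-9:
            raise ValueError(f"modularity {self.modularity} outside [-0.5, 1]")

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, []).append(node)
        for members in out.values():
            members.sort()
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "node": node,
                "community": cid,
                "block": self.node_block[node].value,
                "label": self.labels.get(cid, ""),
            }
            for node, cid in sorted(self.membership.items())
        ]
        return pd.DataFrame(rows, columns=["node", "community", "block", "label"])


@dataclass(frozen=True)
class AntagonisticPair:
    """A gene-metabolite pair with opposing direction relative to an anchor."""

    gene_id: str
    metabolite_id: str
    anchor_id: str
    gene_sign: int
    metabolite_sign: int
    gene_r: float
    metabolite_r: float
    pair_r: float | None = None

    def __post_init__(self) -> None:
        if self.gene_sign == self.metabolite_sign:
            raise ValueError("antagonistic pair requires opposite signs")

    @property
    def rank_score(self) -> float:
        return min(abs(self.gene_r), abs(self.metabolite_r))


@dataclass(frozen=True)
class AnnotationRecord:
    """One m/z -> candidate metabolite match via an adduct."""

    feature_id: str
    mz: float
    metabolite_id: str
    adduct_name: str
    theoretical_mz: float
    ppm_error: float


@dataclass(frozen=True)
class PathwayResult:
    """Over-representation result for one pathway / gene set."""

    pathway_id: str
    name: str
    overlap: int
    pathway_size: int
    p_perm: float | None
    p_fisher: float
    q_value: float | None = None

    def __post_init__(self) -> None:
        if self.overlap > self.pathway_size:
            raise ValueError("overlap exceeds pathway size")


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted by the synthetic generator.

    ``anchor_assignment`` maps each feature id to its anchor parameter id,
    or ``"noise"``; planted features additionally carry a coupling sign and
    effect size. ``response_shape`` records each anchor's dose-response
    form.
    """

    anchor_assignment: dict[str, str]
    sign: dict[str, int]
    response_shape: dict[str, str]
    coupling: dict[str, float]
    noise_sd: dict[str, float]
    seed: int

    def __post_init__(self) -> None:
        for feat, anchor in self.anchor_assignment.items():
            planted = anchor != "noise"
            if planted and feat not in self.sign:
                raise ValueError(f"planted feature {feat} has no sign")
            if not planted and feat in self.sign:
                raise ValueError(f"noise feature {feat} must not have a sign")

    def planted_features(self) -> list[str]:
        return sorted(f for f, a in self.anchor_assignment.items() if a != "noise")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for feat in sorted(self.anchor_assignment):
            anchor = self.anchor_assignment[feat]
            rows.append(
                {
                    "feature_id": feat,
                    "anchor": anchor,
                    "sign": self.sign.get(feat, 0),
                    "coupling": self.coupling.get(feat, 0.0),
                }
            )
        return pd.DataFrame(rows, columns=["feature_id", "anchor", "sign", "coupling"])
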
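"""Feature filtering, normalization and per-dose median collapse.

The metabolome recipe, applied at replicate level and in this order:
presence filter (a feature must have a nonzero intensity in at least a
fraction of samples) -> quantile normalization -> log2 transform ->
per-dose median collapse. Transcriptome input is assumed already
variance-stabilized and, like the functional block, receives only the
median collapse.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import Block, DoseDesign, OmicsBlock


def presence_filter(block: OmicsBlock, min_fraction: float = 0.8) -> OmicsBlock:
    """Keep features with a nonzero intensity in >= ``min_fraction`` of samples.

    "Has an intensity" means strictly positive; zeros are absences.
    Feature order is preserved. An empty result warns rather than errors.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    values = block.matrix()
    frac_present = (values > 0).mean(axis=1)
    keep = frac_present >= min_fraction
    if not keep.any():
        warnings.warn("presence filter removed every feature", stacklevel=2)
    return block.with_values(block.values.loc[keep])


def quantile_normalize(block: OmicsBlock) -> OmicsBlock:
    """Force every sample column onto the common reference distribution.

    The reference is the row-wise mean of the column-sorted matrix; each
    column's values are replaced by the reference value at their rank.
    Ties within a column receive the mean of the reference values at the
    ranks they occupy, so the operation is idempotent and permutation
    equivariant.
    """
    values = block.matrix()
    if np.any(values < 0):
        raise ValueError("quantile normalization expects nonnegative intensities")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values, dtype=float)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = reference.copy()
        # average reference values over runs of tied input values
        sorted_col = col[order]
        start = 0
        for end in range(1, len(col) + 1):
            if end == len(col) or sorted_col[end] != sorted_col[start]:
                ranked[start:end] = reference[start:end].mean()
                start = end
        out[order, j] = ranked
    return block.with_values(
        pd.DataFrame(out, index=block.values.index, columns=block.values.columns))


def log2_transform(block: OmicsBlock, pseudocount: float = 1.0) -> OmicsBlock:
    """Elementwise ``log2(value + pseudocount)``; nonpositive arguments error."""
    values = block.matrix() + pseudocount
    if np.any(values <= 0):
        raise ValueError("log2 transform requires value + pseudocount > 0")
    return block.with_values(
        pd.DataFrame(np.log2(values), index=block.values.index,
                     columns=block.values.columns))


def median_collapse(block: OmicsBlock, design: DoseDesign) -> OmicsBlock:
    """Collapse replicate columns to one median column per dose condition."""
    cols = set(block.sample_ids)
    collapsed = {}
    for label in design.condition_labels:
        reps = design.replicate_map.get(label, [])
        if not reps:
            raise ValueError(f"condition {label!r} has no replicate columns")
        missing = [r for r in reps if r not in cols]
        if missing:
            raise ValueError(f"replicate columns {missing} absent from block")
        collapsed[label] = block.values.loc[:, reps].median(axis=1)
    return block.with_values(pd.DataFrame(collapsed, index=block.values.index))


def preprocess_block(block: OmicsBlock, design: DoseDesign,
                     min_fraction: float = 0.8,
                     pseudocount: float = 1.0) -> OmicsBlock:
    """Route a replicate-level block through its block-specific recipe."""
    if block.block_id is Block.METABOLOME:
        block = presence_filter(block, min_fraction)
        block = quantile_normalize(block)
        block = log2_transform(block, pseudocount)
    return median_collapse(block, design)
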
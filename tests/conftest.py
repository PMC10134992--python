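"""Shared fixtures: toy blocks and one full default-scenario run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tmwas import netcomm, pls, preprocess, synth
from tmwas.types import Block, OmicsBlock

RECOVERY_SEED = 7  # the package's default run seed


def make_block(values, block_id=Block.METABOLOME, feature_ids=None,
               sample_ids=None, meta=None) -> OmicsBlock:
    values = np.asarray(values, dtype=float)
    feature_ids = feature_ids or [f"f{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=feature_ids, columns=sample_ids)
    return OmicsBlock(block_id, df, meta)


@pytest.fixture(scope="session")
def default_run():
    """Default synthetic scenario pushed through integration + communities.

    Session-scoped: several tests interrogate different aspects of the
    same run (recovery, signs, antagonism, stringency).
    """
    scenario = synth.default_scenario()
    blocks, design, truth = synth.generate(scenario, seed=RECOVERY_SEED)
    proc = {b: preprocess.preprocess_block(blk, design)
            for b, blk in blocks.items()}
    n_comp = min(proc[Block.FUNCTIONAL].shape[0], design.n_conditions - 1)
    edge_lists = []
    for a, b in ((Block.FUNCTIONAL, Block.METABOLOME),
                 (Block.FUNCTIONAL, Block.TRANSCRIPTOME),
                 (Block.METABOLOME, Block.TRANSCRIPTOME)):
        _, edges = pls.integrate(proc[a], proc[b], n_components=n_comp)
        edge_lists.append(edges)
    graph = netcomm.build_graph(edge_lists)
    assignment = netcomm.detect_communities(graph)
    assignment = netcomm.split_multi_anchor_communities(graph, assignment)
    return {
        "scenario": scenario, "blocks": blocks, "design": design,
        "truth": truth, "proc": proc, "edge_lists": edge_lists,
        "graph": graph, "assignment": assignment,
    }


@pytest.fixture(scope="session")
def zero_noise_run():
    """Noise-free small scenario: recovery must be exact.

    All blocks enter as already-normalized log intensities and receive
    only the median collapse. Rank-based quantile normalization is
    deliberately not applied here: with zero noise, planted features form
    exact within-column tie blocks whose ranks carry no information, so
    QN would replace magnitudes with arbitrary reference quantiles. QN
    behavior has its own tests on continuous data.
    """
    scenario = synth.Scenario(
        n_planted_met=6, n_planted_tx=6, n_noise_met=4, n_noise_tx=4,
        noise_sd={Block.FUNCTIONAL: 0.0, Block.METABOLOME: 0.0,
                  Block.TRANSCRIPTOME: 0.0})
    blocks, design, truth = synth.generate(scenario, seed=1)
    proc = {b: preprocess.median_collapse(blk, design)
            for b, blk in blocks.items()}
    edge_lists = []
    for a, b in ((Block.FUNCTIONAL, Block.METABOLOME),
                 (Block.FUNCTIONAL, Block.TRANSCRIPTOME),
                 (Block.METABOLOME, Block.TRANSCRIPTOME)):
        _, edges = pls.integrate(proc[a], proc[b], n_components=3)
        edge_lists.append(edges)
    graph = netcomm.build_graph(edge_lists)
    assignment = netcomm.detect_communities(graph)
    assignment = netcomm.split_multi_anchor_communities(graph, assignment)
    return {"blocks": blocks, "design": design, "truth": truth, "proc": proc,
            "edge_lists": edge_lists, "graph": graph, "assignment": assignment}
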
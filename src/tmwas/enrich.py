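"""m/z annotation and permutation-based pathway over-representation.

Untargeted metabolomics features are annotated by matching their observed
m/z against theoretical adduct m/z values of reference metabolites within
a ppm tolerance; a feature may annotate several metabolites (ambiguity is
expected and is the reason enrichment uses permutation rather than a
straight Fisher test). Pathway enrichment then asks whether the
significant features hit more distinct pathway metabolites than random
same-size feature draws would. A hypergeometric tail p is attached as a
cross-check, and plain hypergeometric over-representation with BH
correction is provided for gene sets.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AdductTable, AnnotationRecord, PathwayDB, PathwayResult


def annotate_mz(features: pd.DataFrame, masses: pd.DataFrame,
                adducts: AdductTable, tolerance_ppm: float = 10.0,
                ion_mode: str = "positive") -> list[AnnotationRecord]:
    """Match observed feature m/z to metabolite adduct m/z at ppm tolerance.

    ``features`` is indexed by feature id with an ``mz`` column (Da);
    ``masses`` is indexed by metabolite id with a monoisotopic ``mass``
    column. The theoretical m/z of metabolite M under adduct A is
    ``(mass_M + shift_A) / |charge_A|``; a feature matches when
    ``|observed - theoretical| / theoretical * 1e6 <= tolerance_ppm``.
    All candidates are returned; uniqueness is never forced.
    """
    if tolerance_ppm < 0:
        raise ValueError("tolerance must be nonnegative")
    mode_adducts = adducts.for_mode(ion_mode)
    if not mode_adducts:
        raise ValueError(f"no adducts defined for ion mode {ion_mode!r}")
    records: list[AnnotationRecord] = []
    met_ids = masses.index.to_numpy()
    met_mass = masses["mass"].to_numpy(dtype=float)
    for fid, row in features.iterrows():
        observed = float(row["mz"])
        for adduct in mode_adducts:
            theoretical = (met_mass + adduct.mass_shift) / abs(adduct.charge)
            ppm = (observed - theoretical) / theoretical * 1e6
            hits = np.abs(ppm) <= tolerance_ppm
            for mid, theo, err in zip(met_ids[hits], theoretical[hits], ppm[hits]):
                records.append(AnnotationRecord(
                    feature_id=str(fid), mz=observed, metabolite_id=str(mid),
                    adduct_name=adduct.name, theoretical_mz=float(theo),
                    ppm_error=float(err)))
    return records


def _annotation_map(annotations: Iterable[AnnotationRecord]) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    for rec in annotations:
        out.setdefault(rec.feature_id, set()).add(rec.metabolite_id)
    return {k: frozenset(v) for k, v in out.items()}


def pathway_permutation_test(significant: Sequence[str], universe: Sequence[str],
                             annotations: Iterable[AnnotationRecord],
                             db: PathwayDB, n_perm: int = 1000,
                             seed: int = 0) -> list[PathwayResult]:
    """Permutation over-representation of pathways among significant features.

    The observed statistic per pathway is the number of *distinct* pathway
    metabolites annotated by any significant feature (so several features
    resolving to one metabolite count once). The null draws ``n_perm``
    random subsets of ``|significant|`` features from the universe without
    replacement; ``p_perm = (1 + #{null >= observed}) / (1 + n_perm)``
    (add-one, so p is never zero). A hypergeometric tail p on
    feature-hit counts is attached as ``p_fisher`` for cross-checking.
    """
    significant = sorted(set(significant))
    universe = sorted(set(universe))
    if not set(significant) <= set(universe):
        raise ValueError("significant features must be a subset of the universe")
    if len(significant) > len(universe):
        raise ValueError("more significant features than universe members")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")

    feat_mets = _annotation_map(annotations)
    rng = np.random.default_rng(seed)
    n_universe, n_sig = len(universe), len(significant)
    feat_index = {f: i for i, f in enumerate(universe)}
    sig_idx = [feat_index[f] for f in significant]

    results = []
    draws = None
    if n_sig > 0:
        # row-wise random subsets without replacement, vectorized
        draws = np.argsort(rng.random((n_perm, n_universe)), axis=1)[:, :n_sig]
    for pid, name, members in db.pathways:
        member_list = sorted(members)
        col = {m: j for j, m in enumerate(member_list)}
        hit_matrix = np.zeros((n_universe, len(member_list)), dtype=bool)
        for i, feat in enumerate(universe):
            for met in feat_mets.get(feat, ()):
                if met in col:
                    hit_matrix[i, col[met]] = True

        observed = int(hit_matrix[sig_idx].any(axis=0).sum()) if sig_idx else 0

        if n_sig == 0:
            p_perm = 1.0
        else:
            null = hit_matrix[draws].any(axis=1).sum(axis=1)
            p_perm = float((1 + int((null >= observed).sum())) / (1 + n_perm))

        feature_hits_universe = int(hit_matrix.any(axis=1).sum())
        feature_hits_sig = int(hit_matrix[sig_idx].any(axis=1).sum()) if sig_idx else 0
        p_fisher = float(stats.hypergeom.sf(
            feature_hits_sig - 1, n_universe, feature_hits_universe, n_sig)) \
            if n_sig else 1.0

        results.append(PathwayResult(
            pathway_id=pid, name=name, overlap=observed,
            pathway_size=len(member_list), p_perm=p_perm, p_fisher=p_fisher))
    return results


def filter_pathways(results: Sequence[PathwayResult],
                    min_overlap: int = 3) -> list[PathwayResult]:
    """Keep pathways whose overlap strictly exceeds ``min_overlap``."""
    return [r for r in results if r.overlap > min_overlap]


def gene_overrepresentation(significant: Sequence[str], universe: Sequence[str],
                            gene_sets: Mapping[str, Sequence[str]] |
                            Sequence[tuple[str, str, frozenset[str]]],
                            ) -> list[PathwayResult]:
    """Hypergeometric over-representation of gene sets, BH-corrected.

    ``gene_sets`` is either a mapping set_id -> members or GMT-style
    (id, name, members) triples. Genes outside the universe are ignored.
    """
    significant = set(significant)
    universe_set = set(universe)
    if not significant <= universe_set:
        raise ValueError("significant genes must be a subset of the universe")
    if isinstance(gene_sets, Mapping):
        triples = [(sid, sid, frozenset(m)) for sid, m in gene_sets.items()]
    else:
        triples = [(sid, name, frozenset(m)) for sid, name, m in gene_sets]

    n_universe, n_sig = len(universe_set), len(significant)
    raw = []
    for sid, name, members in triples:
        in_universe = members & universe_set
        overlap = len(in_universe & significant)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe,
                                     len(in_universe), n_sig)) \
            if n_sig else 1.0
        raw.append((sid, name, overlap, len(in_universe), p))
    if not raw:
        return []
    qvals = multipletests([r[4] for r in raw], method="fdr_bh")[1]
    return [PathwayResult(pathway_id=sid, name=name, overlap=overlap,
                          pathway_size=size, p_perm=None, p_fisher=p,
                          q_value=float(q))
            for (sid, name, overlap, size, p), q in zip(raw, qvals)]


def results_to_frame(results: Sequence[PathwayResult]) -> pd.DataFrame:
    rows = [
        {
            "pathway_id": r.pathway_id, "name": r.name, "overlap": r.overlap,
            "pathway_size": r.pathway_size,
            "p_perm": r.p_perm if r.p_perm is not None else float("nan"),
            "p_fisher": r.p_fisher,
            "q_value": r.q_value if r.q_value is not None else float("nan"),
        }
        for r in results
    ]
    return pd.DataFrame(rows, columns=["pathway_id", "name", "overlap",
                                       "pathway_size", "p_perm", "p_fisher",
                                       "q_value"])
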
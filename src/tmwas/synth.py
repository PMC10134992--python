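"""Synthetic dose-series multi-omics with planted, signed anchor structure.

The generator emulates the statistical shape the downstream analysis
assumes: a handful of functional parameters ("anchors") respond to an
increasing dose series with monotone or biphasic (hormetic) profiles, and
planted metabolome/transcriptome features track one anchor each, linearly
on the log-intensity scale, with a planted coupling sign and i.i.d.
Gaussian replicate noise. Everything else is pure baseline noise. The
planted memberships and signs are returned as ground truth for recovery
tests.

Dose-response shapes
--------------------
increasing   saturating Hill curve, 0 at control, 1 at the top dose
decreasing   one minus the increasing curve
biphasic     inverted-U ``(d/p) * exp(1 - d/p)``, 0 at control, peak 1 at p

The default recovery scenario plants three anchors with one shape each,
giving each anchor distinct kinetics so that the anchor profiles are
mutually weakly correlated over the default log-spaced dose grid
(pairwise |r| < 0.6, asserted at generation time); without that
separation the |r|-weighted community structure would not be identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as tio
from .types import Block, DoseDesign, OmicsBlock, SyntheticTruth

#: log-intensity baselines per block (arbitrary units, configurable)
BASELINES = {Block.FUNCTIONAL: 1.0, Block.METABOLOME: 15.0, Block.TRANSCRIPTOME: 8.0}

#: maximum tolerated |Pearson r| between noiseless anchor profiles
ANCHOR_SEPARATION_LIMIT = 0.6


def make_design(n_doses: int, dose_max: float, n_replicates: int) -> DoseDesign:
    """Control plus ``n_doses`` log-spaced doses spanning two decades.

    Conditions are labeled ``dose0`` (control, 0 uM) through
    ``dose<n_doses>``; replicate columns are ``<label>_r<j>``.
    """
    if n_doses < 2:
        raise ValueError("need at least 2 doses beyond control")
    if dose_max <= 0:
        raise ValueError("dose_max must be positive")
    doses = np.logspace(math.log10(dose_max) - 2, math.log10(dose_max), n_doses)
    dose_values = [0.0, *[float(d) for d in doses]]
    labels = [f"dose{i}" for i in range(len(dose_values))]
    replicate_map = {
        lab: [f"{lab}_r{j + 1}" for j in range(n_replicates)] for lab in labels
    }
    return DoseDesign(labels, dose_values, replicate_map)


def anchor_response(shape: str, dose: float, dose_max: float,
                    k: float | None = None, hill: float = 2.0) -> float:
    """Noiseless anchor dose-response, a unitless value in [0, 1].

    ``k`` is the half-saturation constant for the monotone shapes (default
    ``dose_max / 4``) or the peak dose for the biphasic shape (same
    default). The increasing curve is normalized to hit exactly 1 at
    ``dose_max``; the decreasing curve is its complement and so starts at
    1 for the control.
    """
    if not 0 <= dose <= dose_max:
        raise ValueError(f"dose {dose} outside [0, {dose_max}]")
    if k is None:
        k = dose_max / 4.0
    if shape == "increasing":
        h = dose ** hill / (dose ** hill + k ** hill)
        top = dose_max ** hill / (dose_max ** hill + k ** hill)
        return h / top
    if shape == "decreasing":
        return 1.0 - anchor_response("increasing", dose, dose_max, k=k, hill=hill)
    if shape == "biphasic":
        if dose == 0:
            return 0.0
        x = dose / k
        return x * math.exp(1.0 - x)
    raise ValueError(f"unknown response shape {shape!r}")


@dataclass(frozen=True)
class AnchorSpec:
    """One functional parameter: its shape and kinetic constants."""

    anchor_id: str
    shape: str
    k: float | None = None  # uM; None -> dose_max / 4
    hill: float = 2.0

    def profile(self, design: DoseDesign, dose_max: float) -> np.ndarray:
        return np.array([
            anchor_response(self.shape, d, dose_max, k=self.k, hill=self.hill)
            for d in design.dose_values
        ])


@dataclass
class Scenario:
    """Generator configuration for one synthetic study.

    Defaults are the package's standard recovery scenario: three anchors
    (increasing / decreasing / biphasic), 40 planted metabolome and 40
    planted transcriptome features per anchor with alternating coupling
    signs, 200 noise features per omics block, coupling 1.0 and replicate
    noise sd 0.15 on the log-intensity scale.
    """

    n_doses: int = 5
    dose_max: float = 100.0
    n_replicates: int = 3
    anchors: list[AnchorSpec] = field(default_factory=lambda: [
        AnchorSpec("Mn", "increasing", k=5.0, hill=2.0),
        AnchorSpec("thiols", "decreasing", k=100.0, hill=4.0),
        AnchorSpec("bOCR", "biphasic", k=5.0),
    ])
    n_planted_met: int = 40
    n_planted_tx: int = 40
    n_noise_met: int = 200
    n_noise_tx: int = 200
    coupling: float = 1.0
    annotation_rate: float = 0.5
    noise_sd: dict[Block, float] = field(default_factory=lambda: {
        Block.FUNCTIONAL: 0.15,
        Block.METABOLOME: 0.15,
        Block.TRANSCRIPTOME: 0.15,
    })

    def design(self) -> DoseDesign:
        return make_design(self.n_doses, self.dose_max, self.n_replicates)


def default_scenario() -> Scenario:
    return Scenario()


def _check_anchor_separation(scenario: Scenario, design: DoseDesign) -> None:
    profiles = {a.anchor_id: a.profile(design, scenario.dose_max)
                for a in scenario.anchors}
    ids = list(profiles)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            r = np.corrcoef(profiles[a], profiles[b])[0, 1]
            if abs(r) >= ANCHOR_SEPARATION_LIMIT:
                raise ValueError(
                    f"anchor profiles {a!r} and {b!r} correlate at |r|="
                    f"{abs(r):.3f} >= {ANCHOR_SEPARATION_LIMIT}; communities "
                    "would not be separable — adjust anchor kinetics")


def make_truth(scenario: Scenario, seed: int) -> SyntheticTruth:
    """Assign planted features to anchors with alternating coupling signs.

    Half of each anchor's planted features couple positively, half
    negatively (odd counts give the extra feature to the positive side),
    providing the opposite-sign subgroups the antagonism readout needs.
    """
    anchor_assignment: dict[str, str] = {}
    sign: dict[str, int] = {}
    coupling: dict[str, float] = {}

    def plant(prefix: str, n_per_anchor: int, n_noise: int) -> None:
        idx = 0
        for spec in scenario.anchors:
            for j in range(n_per_anchor):
                fid = f"{prefix}_{idx:04d}"
                idx += 1
                anchor_assignment[fid] = spec.anchor_id
                sign[fid] = 1 if j < (n_per_anchor + 1) // 2 else -1
                coupling[fid] = scenario.coupling
        for _ in range(n_noise):
            fid = f"{prefix}_{idx:04d}"
            idx += 1
            anchor_assignment[fid] = "noise"

    plant("met", scenario.n_planted_met, scenario.n_noise_met)
    plant("tx", scenario.n_planted_tx, scenario.n_noise_tx)

    return SyntheticTruth(
        anchor_assignment=anchor_assignment,
        sign=sign,
        response_shape={a.anchor_id: a.shape for a in scenario.anchors},
        coupling=coupling,
        noise_sd={b.value: s for b, s in scenario.noise_sd.items()},
        seed=seed,
    )


def generate(scenario: Scenario, seed: int,
             truth: SyntheticTruth | None = None,
             ) -> tuple[dict[Block, OmicsBlock], DoseDesign, SyntheticTruth]:
    """Generate the three replicate-level blocks plus ground truth.

    Each planted feature's replicate value is
    ``baseline + sign * coupling * anchor_response(dose) + Normal(0, sd)``;
    the functional block holds the anchors' own noisy responses; noise
    features are Gaussian around the block baseline. Deterministic given
    ``seed``.
    """
    design = scenario.design()
    _check_anchor_separation(scenario, design)
    if truth is None:
        truth = make_truth(scenario, seed)
    rng = np.random.default_rng(seed)

    profiles = {a.anchor_id: a.profile(design, scenario.dose_max)
                for a in scenario.anchors}
    rep_cols = design.replicate_columns
    # replicate-level anchor response, one entry per replicate column
    rep_profile = {
        aid: np.repeat(prof, [len(design.replicate_map[lab])
                              for lab in design.condition_labels])
        for aid, prof in profiles.items()
    }
    n_rep = len(rep_cols)

    def build(prefix: str, block: Block) -> OmicsBlock:
        fids = sorted(f for f in truth.anchor_assignment if f.startswith(prefix + "_"))
        base = BASELINES[block]
        sd = scenario.noise_sd[block]
        rows = np.empty((len(fids), n_rep))
        for i, fid in enumerate(fids):
            anchor = truth.anchor_assignment[fid]
            signal = 0.0
            if anchor != "noise":
                signal = truth.sign[fid] * truth.coupling[fid] * rep_profile[anchor]
            rows[i] = base + signal + rng.normal(0.0, sd, n_rep)
        return OmicsBlock(block, pd.DataFrame(rows, index=fids, columns=rep_cols))

    met = build("met", Block.METABOLOME)
    tx = build("tx", Block.TRANSCRIPTOME)

    # functional block: the anchors themselves, noisy
    func_rows = np.empty((len(scenario.anchors), n_rep))
    for i, spec in enumerate(scenario.anchors):
        func_rows[i] = (BASELINES[Block.FUNCTIONAL] + scenario.coupling *
                        rep_profile[spec.anchor_id] +
                        rng.normal(0.0, scenario.noise_sd[Block.FUNCTIONAL], n_rep))
    func = OmicsBlock(
        Block.FUNCTIONAL,
        pd.DataFrame(func_rows, index=[a.anchor_id for a in scenario.anchors],
                     columns=rep_cols))

    met = _attach_mz(met, rng, truth, [a.anchor_id for a in scenario.anchors],
                     scenario.annotation_rate)
    tx = _attach_biotypes(tx, rng)

    blocks = {Block.FUNCTIONAL: func, Block.METABOLOME: met, Block.TRANSCRIPTOME: tx}
    return blocks, design, truth


def _attach_mz(block: OmicsBlock, rng: np.random.Generator,
               truth: SyntheticTruth, anchor_order: list[str],
               annotation_rate: float = 0.5) -> OmicsBlock:
    """Give metabolome features m/z and retention-time metadata.

    The fixture metabolite list is split into one contiguous pool per
    anchor; each planted feature is assigned, round-robin within its
    anchor's pool, the protonated (M+H) m/z of a pool metabolite with a
    small (<5 ppm) mass jitter — so each anchor community resolves to its
    own pathway neighborhood through the packaged annotation fixtures.
    Only ``annotation_rate`` of planted features receive a library m/z
    (untargeted features frequently have no database match); the rest,
    and all noise features, get uniform m/z in 85-800 Da (mostly
    unannotatable). Retention times are uniform in 30-300 s.
    """
    masses = tio.read_metabolite_masses(tio.default_fixture_path("metabolite_masses.tsv"))
    proton = 1.00727646
    theo = masses["mass"].to_numpy() + proton  # singly protonated
    pools = np.array_split(np.arange(len(theo)), max(len(anchor_order), 1))
    pool_of = {aid: pools[i % len(pools)] for i, aid in enumerate(anchor_order)}
    counters = {aid: 0 for aid in anchor_order}

    mz = np.empty(block.shape[0])
    for i, fid in enumerate(block.values.index):
        anchor = truth.anchor_assignment.get(str(fid), "noise")
        annotatable = rng.random() < annotation_rate
        if anchor == "noise" or anchor not in pool_of or not annotatable:
            mz[i] = rng.uniform(85.0, 800.0)
        else:
            pool = pool_of[anchor]
            met_idx = pool[counters[anchor] % len(pool)]
            counters[anchor] += 1
            mz[i] = theo[met_idx] * (1.0 + rng.uniform(-5.0, 5.0) * 1e-6)
    meta = pd.DataFrame(
        {"mz": mz, "rt": rng.uniform(30.0, 300.0, block.shape[0])},
        index=block.values.index)
    return OmicsBlock(block.block_id, block.values, meta)


def _attach_biotypes(block: OmicsBlock, rng: np.random.Generator) -> OmicsBlock:
    """Assign transcript biotypes with an mRNA-dominated mixture."""
    biotypes = np.array(["mRNA", "lncRNA", "miRNA", "sncRNA"])
    probs = np.array([0.79, 0.14, 0.06, 0.01])
    draw = rng.choice(biotypes, size=block.shape[0], p=probs)
    meta = pd.DataFrame({"biotype": draw}, index=block.values.index)
    return OmicsBlock(block.block_id, block.values, meta)
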
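# Methods

## Overview

`tmwas` implements a functional-anchored transcriptome–metabolome-wide
association analysis for dose-response designs. Three sample-aligned
blocks enter the analysis: a small matrix of measured functional
parameters (e.g. cellular Mn concentration, total thiols, mitochondrial
ROS/H2O2, SOD2 activity, basal and proton-leak oxygen consumption), an
untargeted metabolomics feature table, and a transcriptome expression
matrix, all observed over a control plus an increasing dose series.
The pipeline scores every cross-block feature pair on a correlation
scale via partial least squares (PLS), assembles the significant pairs
into a signed network, partitions it into communities anchored by the
functional parameters, extracts opposite-direction ("antagonistic")
gene–metabolite pairs within each community, and tests the metabolome
members of each community for pathway over-representation.

## Preprocessing

Metabolome feature tables (replicate-level intensities) pass through:

1. **Presence filter** — keep features with a strictly positive
   intensity in ≥ 80% of replicate columns (zeros are absences).
2. **Quantile normalization** — the standard sorted-means construction:
   the reference distribution is the row-wise mean of the column-sorted
   matrix and each column's values are replaced by the reference value
   at their rank. Ties within a column receive the mean of the reference
   values over the ranks they occupy, which makes the operation
   idempotent (to 1e-12) and permutation-equivariant.
3. **log2(x + 1)** — the pseudocount of 1 maps zeros to zero.
4. **Per-dose median collapse** — one column per condition, the median
   over that condition's replicates.

The transcriptome is taken as already variance-stabilized and, like the
functional block, receives only the median collapse. This routing is a
deliberate asymmetry: variance stabilization of counts is a separate,
upstream concern, and the functional parameters are already on
interpretable scales.

A caveat worth knowing: rank-based quantile normalization assumes
continuously distributed intensities. On degenerate inputs where many
features are exactly (or almost exactly) tied within a column —
e.g. noise-free simulations — ranks carry no information and QN replaces
magnitudes with arbitrary reference quantiles, destroying correlation
structure. The exactness tests therefore feed already-normalized data
to the integration (median collapse only); QN has its own tests on
continuous data. Real intensity data are effectively tie-free.

## PLS association scoring

For each ordered block pair (X, Y) with n aligned conditions, features
are standardized and a deterministic NIPALS PLS in regression mode
extracts H latent components. Each component's Y-weight iteration starts
from the maximal-variance Y column (no random initialization), X is
deflated by its score-loading outer product and Y by the regression of Y
on the X score; successive X scores are exactly orthogonal. Optional
sparsity soft-thresholds the weight vectors to a per-component budget of
retained features (`keep_x` / `keep_y`; default: no sparsity).

The association score between feature x_i and y_j is

    r_ij = Σ_{h=1..H} cor(x_i, ξ_h) · cor(y_j, ξ_h),

with ξ_h the h-th X latent score — the latent-component similarity used
by the mixOmics/xMWAS family for network construction in regression
mode, clipped to [−1, 1]. Both blocks are projected onto the X scores;
this makes the score collapse *exactly* to the Pearson correlation when
either block is univariate, which is the property that justifies pairing
an |r| cutoff with a correlation t-test. (Correlating Y against the
averaged scores (ξ_h + ω_h)/2 instead — available as
`score_mode="average"` — yields sign(r)(1+|r|)/2 in the univariate limit
and is not used by default.)

**Number of components.** The default is `"auto"` =
min(#functional features, n − 1). The association matrix is a rank-H
object: H must be at least the number of distinct anchor response
programs or cross-block associations are computed in a projection that
cannot separate them. On the default synthetic scenario (three anchors),
H = 2 inflates cross-anchor associations enough to merge two planted
communities, while H = 3 recovers all three cleanly; the same logic
applies to real designs, where the functional block's dimension is the
natural upper bound on meaningful latent structure.

**Significance.** p = two-sided t-test on r with n − 2 degrees of
freedom. With n = 6 conditions, |r| > 0.8 roughly coincides with
p < 0.05, so the paired default thresholds (|r| > 0.8 AND p < 0.05,
both strict) act as a consistent pair. The t-test is exactly calibrated
when the score is a genuine correlation (univariate blocks; verified
empirically at n = 20: 5% ± 2pp rejections under the null). For
multivariate blocks the latent-score product has *smaller* null
dispersion than a Pearson correlation, so the test is conservative —
a screening property, not an inferential guarantee.

## Network and communities

Edges from the three pairwise integrations are merged into one
undirected graph weighted by |r|; the association sign is an edge
attribute (rendered as edge color downstream) and does not enter the
objective. Duplicated pairs keep the larger |r|.

Communities are found by multilevel (Louvain) modularity optimization
(python-igraph) at resolution 1.0. Two determinism measures: igraph's
internal RNG is pinned from the run seed, and the sweep is restarted on
8 seeded vertex-order permutations keeping the best-modularity partition
— the multilevel heuristic is order-dependent, and without restarts it
misses the global optimum on roughly one in ten random ≤10-node graphs.
A community containing two or more anchors is re-clustered on its
induced subgraph (sub-community bifurcation), which reproduces the
anchor-group splits that a single global pass can merge. Communities are
labeled by the sorted anchors they contain, or "unanchored".

## Antagonistic pairs

Within an anchored community, each member's direction is the sign of its
direct edge to the anchor ([+]/[−]); members without a direct anchor
edge are reported as "indirect", and under anchor groups a member whose
signs disagree across the group's anchors is flagged "discordant" rather
than silently assigned. Antagonistic pairs are the cross product of
opposite-direction (gene, metabolite) members, ranked by
min(|gene_r|, |metabolite_r|) descending (lexicographic tie-break); the
direct gene–metabolite edge, when present, is attached as `pair_r` but
is not required — pairing is anchored, not pairwise-thresholded.

## Annotation and enrichment

Observed m/z values are matched against a metabolite library through an
adduct table: theoretical m/z = (monoisotopic mass + adduct shift) /
|charge|, matching within 10 ppm by default. All candidates are kept;
ambiguity is expected, and is the reason enrichment uses permutation.
The packaged defaults are positive-mode M+H, M+Na, M+H−H2O and
negative-mode M−H, M+Cl; both the adduct table and the mass library are
plain TSV and user-replaceable. The packaged pathway file is a small
synthetic GMT fixture shaped like a metabolic pathway database, not a
snapshot of any real one.

Pathway over-representation: the observed statistic is the number of
*distinct* pathway metabolites annotated by any significant feature
(multiple features resolving to one metabolite count once). The null is
n_perm random draws of |significant| features from the universe without
replacement; p_perm = (1 + #{null ≥ observed}) / (1 + n_perm) — add-one,
so p is never zero at finite n_perm. A hypergeometric tail p on
feature-hit counts is attached as a cross-check; on one-to-one
annotation toys the two coincide within Monte-Carlo error. Pathways with
overlap strictly greater than 3 are retained. Because the overlap
statistic is discrete, permutation p-values are mildly superuniform
(conservative) between attainable values; uniformity holds to the
resolution of the statistic, which is what the calibration tests check.
Gene-set over-representation is a plain hypergeometric test with
Benjamini–Hochberg correction.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not raw mass-spectrometry or sequencing data:

- **Design**: control + 5 doses log-spaced over two decades up to
  100 µM, 3 replicates (18 replicate columns).
- **Anchors** (defaults): `Mn`, increasing saturating Hill
  (K = dose_max/20, Hill 2); `thiols`, decreasing (K = dose_max,
  Hill 4); `bOCR`, biphasic (d/p)·exp(1 − d/p) peaking at dose_max/20.
  Kinetic constants deliberately differ per anchor so the noiseless
  profiles correlate pairwise at |r| < 0.6 over the dose grid — the
  generator asserts this and errors otherwise. (An increasing curve and
  its exact complement are perfectly anti-correlated and would merge
  under |r|-weighted modularity: shape alone does not separate
  communities, kinetics do.)
- **Planted features**: 40 metabolome + 40 transcriptome features per
  anchor; replicate value = baseline + sign·coupling·response(dose) +
  N(0, σ), with baselines 15 (metabolome), 8 (transcriptome), 1
  (functional) on the log-intensity scale, coupling 1.0 and σ = 0.15.
  Half of each anchor's features couple positively, half negatively,
  providing the opposite-sign subgroups the antagonism readout needs.
- **Noise features**: 200 per omics block, baseline + N(0, σ).
- **Metadata**: planted metabolome features receive the M+H m/z of a
  library metabolite from their anchor's slice of the library (±5 ppm
  jitter); only half are annotatable (a realistic untargeted annotation
  rate) and noise features get uniform m/z in 85–800 Da. Transcripts get
  biotypes from an mRNA-dominated mixture (79% mRNA, 14% lncRNA, 6%
  miRNA, 1% sncRNA).

What it does **not** emulate: intensity-dependent or batch missingness,
retention-time drift, count-distribution (negative-binomial) sampling,
correlated feature blocks beyond the planted structure, isotope
patterns. Passing recovery tests therefore demonstrates that the
pipeline's inference chain is correct under its own model assumptions —
linear log-scale coupling, i.i.d. Gaussian replicate noise, separable
anchor programs — not that it is robust to every artifact of real
acquisitions.

Under the default scenario the pipeline at |r| > 0.8, p < 0.05 recovers
planted communities with ARI ≥ 0.9 and planted coupling signs with
≥ 95% agreement (observed: ARI ≈ 0.90–0.97 and 100% sign agreement
across seeds).

## Numerical and reproducibility choices

- NIPALS convergence: weight-change tolerance 1e-12, ≤ 1000 iterations;
  zero-variance features dropped with a warning before fitting.
- Scores/weights have deterministic initialization; no randomness in the
  fit.
- Edge sorting: |r| descending, ties by (source_id, target_id); all
  boundary comparisons strict.
- Every source of randomness (generator, permutation test, community
  restarts) flows from explicit seeds; a full `tmwas run` is
  byte-identical across reruns of the same configuration, and the run
  manifest records the config hash, seed, resolved component count,
  library versions and output checksums.
- Floats are serialized with %.12g, enough to round-trip the analysis
  losslessly for the tolerances used.

## Problem sizes

The shipped scenario (3 anchors, 640 omics features, 6 conditions) runs
the full pipeline in a few seconds on one core; the acceptance script's
exhaustive-modularity comparison enumerates all partitions of random 5–8
node graphs, and the permutation calibrations use 20,000 draws (against
the closed-form hypergeometric) and 200 replicates of 199 draws (for
null uniformity). These sizes were chosen to make every check exact or
tightly calibrated while staying interactive.

## Known limitations

- With n = 6 conditions, individual edge p-values are screening
  devices; no multiplicity correction is applied at the edge level (the
  |r| cutoff is the operative filter, as in the tool family).
- The association score inherits PLS's rank-H structure: H must cover
  the functional programs (see above), and anchors whose response
  profiles are strongly collinear over the dose grid cannot be separated
  by any method operating on |r| weights.
- Annotation confidence is ppm error only; co-elution and
  isotope-pattern evidence are out of scope.
- The multilevel restarts make small-graph detection near-optimal but
  modularity optimization remains a heuristic on large graphs.
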
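# Methods

This note documents the models and procedures the package implements, the
choices that were genuinely open, and what the synthetic data do and do not
establish.

## The analysis

The pipeline contrasts two tumor cohorts measured on two different
expression platforms — the setting of a serrated vs. conventional
colorectal-carcinoma comparison built from two public microarray cohorts —
and proceeds in six stages:

1. **Probe collapse.** Probes annotated to two or more gene ids are
   discarded outright; probes sharing a gene id are summarised by their
   per-sample median (even counts: mean of the two central values). The
   pipeline starts from probe- or gene-level expression matrices on the
   log2 scale; array background correction and probe-level summarisation
   are upstream of its scope.
2. **Quantile normalization.** Within each dataset, every array is mapped
   onto the common reference distribution (row-wise means of the
   column-sorted matrix) by rank. Ties receive the mean of the reference
   values at their tied ranks, which makes the map deterministic. With
   continuous intensities the operation is idempotent and equalises the
   column value multisets exactly.
3. **Cross-platform normalization (XPN).** See below.
4. **Differential expression.** Per-gene two-sided pooled-variance Student
   t-test (Welch behind a flag), Benjamini-Hochberg step-up adjustment, fold
   change as the linear-scale ratio of group means (`2^Δ` on log2 data), and
   a direction call (up/down) for genes significant at the BH threshold.
   Three thresholds appear in the workflow and are all explicit parameters:
   raw p < 0.05 and BH p < 0.05 for the main DEG call, BH p < 0.1 for
   selecting the PPI gene list. Up/down proportions between two contrasts
   are compared with the two-sided Fisher exact test (point-probability
   rule, summing hypergeometric probabilities ≤ the observed table's).
5. **Over-representation (EASE score).** For a DEG list against a gene-set
   collection, the EASE score is the one-tailed Fisher upper-tail p computed
   after decrementing the overlap by one, so single-gene overlaps carry no
   evidence (p = 1). The background universe is the cross-platform common
   gene universe, passed explicitly. BH adjustment runs over every tested
   set, including zero-overlap sets (which are counted in the family but not
   reported), so the family size never depends on the observed overlaps.
6. **Networks and crosstalk.** The PPI subnetwork around a DEG list keeps
   every interaction with at least one DEG endpoint; nodes are the DEGs plus
   their direct non-DEG interactors. Hubs are the highest-degree nodes
   (lexicographic tie-break, ties flagged), restricted by default to DEGs.
   Pathway crosstalk is assessed per unordered pathway pair on DEG-touching
   interaction edges: with N such edges in the whole network, M touching
   pathway 1, n touching pathway 2 and k spanning both, the pair's p-value
   is the upper hypergeometric tail P(X ≥ k), X ~ Hypergeometric(N, M, n);
   pairs below the threshold form the pathway interaction network. An empty
   network is a valid, explicitly reported outcome ("no interactions").

## The XPN block model

Platforms differ by systematic structure that swamps biology when cohorts
are pooled. XPN models each platform's matrix as

    x_ij = A[α(i), β(j)] · b_i + c_i + σ_i · ε_ij

with K gene blocks α, L sample blocks β, a K×L block-amplitude matrix A per
platform, and per-gene sensitivity b, offset c and noise scale σ. Blocks
are found by k-means (seeded restarts, best inertia kept) on row-
standardized data pooled across platforms, so platform offsets do not drive
the clustering and sample blocks are comparable across platforms. Per
platform, A and (b, c) are alternated in closed-form least squares until
the fitted matrix stabilises; identifiability is fixed by scaling b to mean
1 within each gene block. The platform parameters are then replaced by
their sample-count-weighted cross-platform averages and each observation is
rebuilt as the averaged systematic part plus its own standardised residual.

Numerical choices:

* The per-gene regression of x on the block-amplitude profile is
  ridge-shrunk toward b = 1 with a prior weight equal to the mean profile
  variance across genes. Genes whose amplitude profile is nearly flat carry
  no information about b, and the unregularised slope diverges on noise;
  the shrinkage leaves informative genes essentially unpenalised.
* Defaults K = 25, L = 5 degrade automatically on small data
  (K ≤ n_genes/10, L ≤ n_samples/3 per platform, both ≥ 1).
* σ is floored at 1e-8; degenerate block denominators yield A = 0 rather
  than dividing by ~0.
* The two inputs are ordered canonically (by platform id and sample ids)
  before fitting, so swapping the argument order is exactly a no-op.

Exact idempotence is not attainable for this class of method: a second
pass re-estimates all parameters from finite noisy samples, and the
platform-to-platform sampling noise of those estimates is redistributed by
the averaging step. On the scales used here the re-application perturbation
is about two orders of magnitude below the platform effect removed, and the
suite pins it below 10% of the pre-normalization discrepancy.

## Crosstalk statistic: reading and conventions

* The cumulative formulation `p = 1 − Σ_{k=0}^{m−1} C(M,k)C(N−M,n−k)/C(N,n)`
  is evaluated as the upper tail P(X ≥ k_obs); an observed count of zero
  gives exactly p = 1 (empty sum).
* N is computed once per network + DEG list, not per pair.
* Membership is a predicate, not a partition: an edge inside the overlap of
  both pathways counts toward M, n and k simultaneously.
* Two conventional thresholds circulate for this statistic (0.05 and 0.1);
  the threshold is a required explicit parameter, defaulting to 0.05.
* No multiple-testing correction is applied over pathway pairs by default;
  a BH option exists.
* Tails are summed in log space from log-gamma binomial coefficients
  (summing the shorter tail), exact to double precision for all counts the
  pipeline produces; the test suite cross-checks against integer-exact
  enumeration, library distributions and Monte-Carlo frequencies.

## Synthetic data

The generator emulates the structure of the two-cohort study at
configurable scale: two platforms over overlapping gene universes, each
with a tumor and a normal group; per-gene log2 baselines uniform on
[6, 10] (post-normalization intensity scale); planted DEGs (default 10% of
genes) shifted by ±effect·noise_sd in the tumor group with recorded
directions; a gene-wise affine platform effect (default shift 3, scale 1.5)
plus independent Gaussian noise (sd 1) on platform B — the minimal
structure XPN is designed to remove; probe maps with a planted
multi-mapping fraction; one "signal" pathway drawing 80% of its members
from planted DEGs among uniform decoy sets; and interaction edges whose
endpoints attach to DEGs with a configurable weight (default 3× neutral).
Default cohort sizes (15 per group per platform) sit in the range of the
motivating cohorts (7–32 samples per arm); analysis-grade checks use
10 per group, 2,000 genes, and the FDR/power study runs 200 replicates —
sizes at which every property under test is already stable.

What the simulation does **not** model: probe-level physics and
hybridisation, correlated gene-gene expression structure (genes are
independent given group), heavy-tailed or intensity-dependent noise,
confounded batch/biology designs, and annotation errors. Passing tests
therefore demonstrate correctness of the procedures and their statistical
calibration under clean assumptions, not robustness to the full messiness
of real array data — in particular, empirical FDR control here reflects
independent genes; correlated expression would widen the FDR's variance.

## Degenerate inputs and tie-breaks

* t-test: two zero-variance groups with equal means → t = 0, p = 1; zero
  pooled variance with unequal means → p = 0 with a warning.
* Fold change of an equal-means gene is exactly 1 and its direction "none".
* Hub ties at equal degree are broken lexicographically and flagged.
* Duplicate edges and self-loops are dropped at network construction,
  before any degree computation.
* Empty crosstalk and empty enrichment results are returned as empty
  tables, not errors; an all-zero 2×2 table is rejected.

## Known limitations

* XPN supports exactly two platforms; other batch methods (ComBat, DWD) are
  out of scope.
* Probe collapse assumes the probe→gene map is complete for the matrix at
  hand and errors otherwise (naming the probe).
* The enrichment universe must be supplied; there is no genome default.
* Sample-block discovery is unsupervised; with very small cohorts (< 3
  samples per platform) L collapses to 1 and XPN reduces to a gene-wise
  affine alignment.
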
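# crosspath

Cross-platform expression integration and pathway crosstalk analysis.

`crosspath` re-implements, as a tested and reusable pipeline, a classic
two-subtype tumor contrast workflow: two expression cohorts measured on
different microarray platforms are integrated over their common genes,
differentially expressed genes (DEGs) are called per contrast, gene sets
are tested for over-representation, and protein–protein interaction (PPI)
evidence is used both to find hub genes and to declare *pathway crosstalk* —
pathway pairs joined by significantly many interactions. It is written for
computational biologists who want each stage available as a plain library
function (or CLI command) with explicit thresholds, and who want the whole
pipeline runnable on synthetic data with planted ground truth.

## What it computes

* **Preprocessing** — probes mapping to ≥ 2 gene ids are removed, probes
  sharing a gene are collapsed by per-sample median, and each dataset is
  quantile-normalized.
* **Cross-platform normalization (XPN)** — a block model
  `x_ij = A[α(i), β(j)]·b_i + c_i + σ_i·ε_ij` (K gene blocks, L sample
  blocks, per-gene sensitivity/offset/noise) is fitted per platform on a
  shared block structure; platform parameters are replaced by their
  cross-platform weighted averages, removing platform structure while
  preserving the biological contrast.
* **Differential expression** — per-gene pooled-variance Student t-tests,
  Benjamini-Hochberg (BH) step-up adjustment, linear-scale fold changes,
  up/down calls; Fisher's exact test for comparing up/down proportions.
* **Over-representation** — the EASE score, a conservative one-tailed
  Fisher exact test computed after decrementing the query/set overlap by
  one, with BH adjustment over the collection.
* **PPI networks** — the subnetwork of interactions touching a DEG list,
  node degrees, and hubs (highest-degree DEGs).
* **Pathway crosstalk** — for pathways P₁, P₂ on a PPI network with N
  DEG-touching interactions, M touching P₁, n touching P₂ and k spanning
  both, the pair's p-value is the hypergeometric upper tail

  p = P(X ≥ k) = 1 − Σ_{j<k} C(M,j)·C(N−M,n−j) / C(N,n),  X ~ Hypergeom(N, M, n);

  pairs below threshold form the pathway interaction network ("no
  interactions" is a valid, reported outcome).
* **Synthetic data** — a seeded generator for two-platform datasets with
  planted DEGs, affine platform effects, probe maps, pathway collections
  and PPI edge lists, with full ground truth for every downstream stage.

## Worked example

```python
from crosspath import (SimulationConfig, XpnConfig, generate_two_platform_dataset,
                       generate_pathways_and_ppi, quantile_normalize,
                       intersect_gene_universe, xpn_normalize,
                       cross_platform_discrepancy, call_differential, enrich,
                       build_ppi_subnetwork, top_hubs, build_pathway_network)

config = SimulationConfig(n_genes=1000, n_samples_per_group_per_platform=10,
                          de_fraction=0.1, effect_size=2.0, seed=7)
mat_a, mat_b, annotation, truth = generate_two_platform_dataset(config)
gene_sets, ppi = generate_pathways_and_ppi(config, truth)

qa, qb = quantile_normalize(mat_a), quantile_normalize(mat_b)
ia, ib = intersect_gene_universe(qa, qb)
_, before = cross_platform_discrepancy(ia, ib)
xa, xb, _ = xpn_normalize(ia, ib, XpnConfig(seed=7))
_, after = cross_platform_discrepancy(xa, xb)
print(f"platform discrepancy: {before:.3f} -> {after:.3f}")

de = call_differential(xa, annotation[annotation.platform == "A"])
called = set(de.loc[de.significant_bh, "gene"])
print(f"DEGs at BH<0.05: {len(called)} "
      f"(true positives: {len(called & set(truth.de_genes))})")

result = enrich(set(de.loc[de.significant_raw, "gene"]), gene_sets,
                set(xa.gene_ids))
top = result.iloc[0]
print(f"top pathway: {top.set_name} (overlap {top.overlap}, BH p {top.p_bh:.2e})")

sub = build_ppi_subnetwork(ppi, called)
hub = top_hubs(sub, 1, de_table=de)[0]
print(f"PPI subnetwork: {sub.n_nodes} nodes / {sub.n_edges} edges; "
      f"hub {hub.gene} (degree {hub.degree}, {hub.direction})")

talk = build_pathway_network(ppi, set(de.loc[de.significant_raw, "gene"]),
                             gene_sets, threshold=0.05)
print(f"pathway crosstalk: {talk.describe()}")
```

Output:

```
platform discrepancy: 6.971 -> 0.037
DEGs at BH<0.05: 100 (true positives: 99)
top pathway: pathway_01 (overlap 14, BH p 1.19e-07)
PPI subnetwork: 579 nodes / 866 edges; hub g0004 (degree 16, down)
pathway crosstalk: no interactions
```

The planted platform effect (shift 3, scale 1.5) is reduced ~200-fold; the
BH-0.05 DEG call recovers 99 of the 100 planted DEGs with one false
positive; the planted "signal" pathway ranks first; and — with only one
truly enriched pathway among random decoys — the crosstalk stage correctly
reports that no pathway pair interacts beyond chance.

The same analysis runs from the shell:

```bash
crosspath simulate --n-genes 1000 --seed 7 --out-dir data/
crosspath run-all --seed 7 --out-dir results/
```

`run-all` writes every stage artifact (normalized matrices, DE tables,
enrichment tables, SIF/GraphML networks, hub and crosstalk pair tables) plus
a machine-readable `summary.json` that is byte-identical across reruns with
the same seed.

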
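"""Synthetic two-platform expression data with planted ground truth.

The generator emulates the structure of a two-cohort microarray study of two
colorectal-carcinoma subtypes: two platforms measuring overlapping gene
universes, each with a tumor and a normal group, a planted fraction of
differentially expressed genes (DEGs) with known directions, an affine
platform effect (shift + scale) on the second platform, multi-mapping probes,
and pathway / protein-interaction annotations correlated with the planted
DEGs. Every generator is fully determined by the seed in
:class:`SimulationConfig`, and the complete ground truth is returned (and
serialisable) so that every downstream stage can be scored against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    InteractionNetwork,
    ProbeMap,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "generate_two_platform_dataset",
    "generate_probe_map",
    "generate_pathways_and_ppi",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-platform study.

    Defaults describe a desk-scale analogue of a two-cohort tumor/normal
    microarray comparison: 2,000 genes, 15 samples per group per platform,
    10% planted DEGs with a 2-SD mean shift, and an affine platform effect
    (shift 3, scale 1.5) on platform B of the kind cross-platform
    normalization is designed to remove.

    Attributes
    ----------
    n_genes
        Size of the full gene universe.
    n_samples_per_group_per_platform
        Samples in each of the tumor and normal groups, on each platform.
    de_fraction
        Fraction of genes planted as differentially expressed, in (0, 1).
    effect_size
        Tumor-vs-normal mean shift at DE genes, in units of ``noise_sd``.
    platform_shift, platform_scale
        Affine transform applied to platform B signal before noise.
    noise_sd
        Standard deviation of the per-measurement Gaussian noise (log2 scale).
    baseline_range
        Range of per-gene baseline log2 means.
    shared_gene_fraction
        Fraction of the universe measured by both platforms; the remainder is
        split between platform-private gene sets.
    n_pathways, pathway_size_range
        Number and size range of generated gene sets; the first set is the
        "signal" pathway enriched for DE genes.
    signal_pathway_de_fraction
        Fraction of the signal pathway drawn from planted DE genes.
    ppi_edge_count
        Number of undirected interaction edges to generate.
    de_ppi_enrichment
        Sampling weight (≥ 1) of DE genes relative to non-DE genes when
        drawing edge endpoints; 1 means neutral attachment.
    probes_per_gene
        Probes generated per gene by :func:`generate_probe_map`.
    seed
        Seed determining every random draw.
    """

    n_genes: int = 2000
    n_samples_per_group_per_platform: int = 15
    de_fraction: float = 0.1
    effect_size: float = 2.0
    platform_shift: float = 3.0
    platform_scale: float = 1.5
    noise_sd: float = 1.0
    baseline_range: tuple[float, float] = (6.0, 10.0)
    shared_gene_fraction: float = 1.0
    n_pathways: int = 10
    pathway_size_range: tuple[int, int] = (15, 40)
    signal_pathway_de_fraction: float = 0.8
    ppi_edge_count: int = 2000
    de_ppi_enrichment: float = 3.0
    probes_per_gene: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_samples_per_group_per_platform < 1:
            raise ValueError("n_samples_per_group_per_platform must be positive")
        if not 0.0 < self.de_fraction < 1.0:
            raise ValueError("de_fraction must lie in (0, 1)")
        if self.de_fraction * self.n_genes < 1:
            raise ValueError("de_fraction * n_genes must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.shared_gene_fraction <= 1.0:
            raise ValueError("shared_gene_fraction must lie in (0, 1]")
        lo, hi = self.pathway_size_range
        if not (1 <= lo <= hi):
            raise ValueError("pathway_size_range must satisfy 1 <= min <= max")
        if hi > self.n_genes:
            raise ValueError("pathway sizes cannot exceed the gene universe")
        if self.ppi_edge_count < 0:
            raise ValueError("ppi_edge_count must be non-negative")
        if self.de_ppi_enrichment < 1.0:
            raise ValueError("de_ppi_enrichment must be >= 1")
        if self.probes_per_gene < 1:
            raise ValueError("probes_per_gene must be positive")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated dataset.

    ``de_genes`` maps each planted DE gene to its direction ("up"/"down" in
    tumor relative to normal); ``de_effects`` holds the signed mean shift
    actually applied (in log2 units). Pathway membership and interaction
    edges are filled in by :func:`generate_pathways_and_ppi`.
    """

    gene_ids: list[str]
    de_genes: dict[str, str]
    de_effects: dict[str, float]
    platform_shift: float
    platform_scale: float
    pathway_membership: dict[str, list[str]] = field(default_factory=dict)
    ppi_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        if not set(self.de_genes) <= universe:
            raise ValueError("de_genes must be a subset of the gene universe")
        bad = {d for d in self.de_genes.values() if d not in ("up", "down")}
        if bad:
            raise ValueError(f"invalid DE directions: {bad}")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "de_genes": self.de_genes,
            "de_effects": self.de_effects,
            "platform_shift": self.platform_shift,
            "platform_scale": self.platform_scale,
            "pathway_membership": self.pathway_membership,
            "ppi_edges": [list(e) for e in self.ppi_edges],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["ppi_edges"] = [tuple(e) for e in payload["ppi_edges"]]
        return cls(**payload)


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def generate_two_platform_dataset(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Simulate expression matrices for two platforms with planted DEGs.

    Returns ``(matrix_a, matrix_b, annotation, truth)``. Both platforms share
    ``shared_gene_fraction`` of the universe (plus disjoint private halves of
    the remainder). Tumor samples differ from normal by
    ``effect_size * noise_sd`` (signed per gene) at planted DE genes on both
    platforms; platform B values are ``platform_scale * signal +
    platform_shift`` before independent Gaussian noise. The annotation table
    has columns sample_id, group ("tumor"/"normal") and platform.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array(_gene_ids(config.n_genes))
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    signs = rng.choice([1.0, -1.0], size=n_de)
    effect = config.effect_size * config.noise_sd

    baseline = rng.uniform(*config.baseline_range, size=config.n_genes)
    delta = np.zeros(config.n_genes)
    delta[de_idx] = signs * effect

    de_genes = {
        genes[i]: ("up" if s > 0 else "down") for i, s in zip(de_idx, signs)
    }
    de_effects = {genes[i]: float(s * effect) for i, s in zip(de_idx, signs)}

    # split the universe into shared and platform-private subsets
    n_shared = int(round(config.shared_gene_fraction * config.n_genes))
    n_shared = max(1, n_shared)
    perm = rng.permutation(config.n_genes)
    shared = perm[:n_shared]
    rest = perm[n_shared:]
    half = len(rest) // 2
    idx_a = np.sort(np.concatenate([shared, rest[:half]]))
    idx_b = np.sort(np.concatenate([shared, rest[half:]]))

    n = config.n_samples_per_group_per_platform

    def _platform(idx: np.ndarray, tag: str, affine: bool) -> pd.DataFrame:
        mu = baseline[idx]
        shift = delta[idx]
        # columns: tumor block then normal block
        signal = np.empty((len(idx), 2 * n))
        signal[:, :n] = (mu + shift)[:, None]
        signal[:, n:] = mu[:, None]
        if affine:
            signal = config.platform_scale * signal + config.platform_shift
        noise = rng.normal(0.0, config.noise_sd, size=signal.shape)
        cols = [f"{tag}_tumor_{j + 1}" for j in range(n)] + [
            f"{tag}_normal_{j + 1}" for j in range(n)
        ]
        return pd.DataFrame(signal + noise, index=genes[idx], columns=cols)

    df_a = _platform(idx_a, "A", affine=False)
    df_b = _platform(idx_b, "B", affine=True)

    annotation = pd.DataFrame(
        {
            "sample_id": list(df_a.columns) + list(df_b.columns),
            "group": (["tumor"] * n + ["normal"] * n) * 2,
            "platform": ["A"] * 2 * n + ["B"] * 2 * n,
        }
    )

    truth = SyntheticTruth(
        gene_ids=list(genes),
        de_genes=de_genes,
        de_effects=de_effects,
        platform_shift=config.platform_shift,
        platform_scale=config.platform_scale,
    )
    return (
        ExpressionMatrix(df_a, platform_id="A"),
        ExpressionMatrix(df_b, platform_id="B"),
        annotation,
        truth,
    )


def generate_probe_map(
    config: SimulationConfig, multi_map_fraction: float
) -> ProbeMap:
    """Generate a probe → gene map with a planted multi-mapping fraction.

    Each gene receives ``config.probes_per_gene`` probes, so every gene is
    covered. Exactly ``round(multi_map_fraction * n_probes)`` probes are then
    assigned one or two additional target genes, making them multi-mapping.
    Deterministic under ``config.seed``.
    """
    if not 0.0 <= multi_map_fraction < 1.0:
        raise ValueError("multi_map_fraction must lie in [0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genes = _gene_ids(config.n_genes)
    mapping: dict[str, set[str]] = {}
    probes: list[str] = []
    for gi, gene in enumerate(genes):
        for k in range(config.probes_per_gene):
            probe = f"p{gi * config.probes_per_gene + k + 1:06d}"
            mapping[probe] = {gene}
            probes.append(probe)
    n_multi = int(round(multi_map_fraction * len(probes)))
    if n_multi > 0 and config.n_genes < 2:
        raise ValueError("multi-mapping probes require at least 2 genes")
    chosen = rng.choice(len(probes), size=n_multi, replace=False)
    for pi in chosen:
        probe = probes[pi]
        n_extra = int(rng.integers(1, 3))  # 1 or 2 extra targets
        pool = rng.choice(config.n_genes,
                          size=min(n_extra + 2, config.n_genes), replace=False)
        added = 0
        for g in pool:
            if genes[g] not in mapping[probe]:
                mapping[probe].add(genes[g])
                added += 1
            if added == n_extra:
                break
    return ProbeMap(mapping)


def generate_pathways_and_ppi(
    config: SimulationConfig, truth: SyntheticTruth
) -> tuple[GeneSetCollection, InteractionNetwork]:
    """Generate gene sets and a PPI edge list correlated with planted DEGs.

    The first gene set (``pathway_01``, description ``signal``) draws
    ``signal_pathway_de_fraction`` of its members from planted DE genes; the
    others are uniform draws from the universe. PPI edge endpoints are
    sampled with weight ``de_ppi_enrichment`` on DE genes and 1 elsewhere;
    self-loops and duplicate undirected edges are rejected and redrawn. The
    generated sets and edges are recorded on ``truth``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    genes = np.array(truth.gene_ids)
    universe = set(truth.gene_ids)
    if not set(truth.de_genes) <= universe:
        raise ValueError("truth inconsistent: DE genes outside universe")
    lo, hi = config.pathway_size_range
    if hi > len(genes):
        raise ValueError("requested pathway sizes exceed the gene universe")

    de_list = np.array(sorted(truth.de_genes))
    non_de = np.array(sorted(universe - set(truth.de_genes)))

    sets: list[GeneSet] = []
    width = max(2, len(str(config.n_pathways)))
    for p in range(config.n_pathways):
        size = int(rng.integers(lo, hi + 1))
        name = f"pathway_{p + 1:0{width}d}"
        if p == 0 and len(de_list) > 0:
            n_sig = min(int(round(config.signal_pathway_de_fraction * size)),
                        len(de_list))
            sig = rng.choice(de_list, size=n_sig, replace=False)
            n_bg = min(size - n_sig, len(non_de))
            bg = rng.choice(non_de, size=n_bg, replace=False)
            members = frozenset(sig) | frozenset(bg)
            sets.append(GeneSet(name, "signal", members))
        else:
            members = frozenset(rng.choice(genes, size=size, replace=False))
            sets.append(GeneSet(name, "background", members))
    collection = GeneSetCollection(sets)

    weights = np.ones(len(genes))
    de_mask = np.isin(genes, de_list)
    weights[de_mask] = config.de_ppi_enrichment
    weights = weights / weights.sum()

    edges: set[tuple[str, str]] = set()
    max_edges = len(genes) * (len(genes) - 1) // 2
    if config.ppi_edge_count > max_edges:
        raise ValueError("ppi_edge_count exceeds the number of possible edges")
    while len(edges) < config.ppi_edge_count:
        need = config.ppi_edge_count - len(edges)
        # oversample to amortise rejections
        draws = rng.choice(len(genes), size=(2 * need + 8, 2), p=weights)
        for u, v in draws:
            if u == v:
                continue
            a, b = genes[u], genes[v]
            edges.add((a, b) if a < b else (b, a))
            if len(edges) == config.ppi_edge_count:
                break
    network = InteractionNetwork(sorted(edges))

    truth.pathway_membership = {s.name: sorted(s.members) for s in collection}
    truth.ppi_edges = network.edges()
    return collection, network
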
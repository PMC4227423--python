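"""Probe-to-gene collapse and within-dataset normalization.

The preprocessing contract, from the expression level onward: probes mapping
to more than one gene id are removed outright; probes sharing a gene id are
summarised by their per-sample median; each dataset is quantile-normalized so
all arrays share one intensity distribution; and the two platforms are
restricted to their common gene universe before any cross-platform work.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ProbeMap

__all__ = [
    "collapse_probes",
    "quantile_normalize",
    "intersect_gene_universe",
]


def collapse_probes(probe_matrix: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to a gene-level matrix.

    Probes mapping to two or more gene ids are discarded; each output gene
    row is the per-sample median over its surviving probes (the median of an
    even number of probes being the mean of the two central values). Genes
    with no surviving probe are absent from the output. Output rows are
    sorted by gene id.

    Raises
    ------
    KeyError
        If a probe row is absent from ``probe_map`` (the probe is named).
    """
    missing = [p for p in probe_matrix.values.index if p not in probe_map]
    if missing:
        raise KeyError(f"probe(s) not in map: {missing[:5]}")

    gene_for_probe = {}
    for probe in probe_matrix.values.index:
        targets = probe_map[probe]
        if len(targets) == 1:
            gene_for_probe[probe] = next(iter(targets))

    surviving = probe_matrix.values.loc[list(gene_for_probe)]
    if surviving.empty:
        collapsed = surviving.copy()
        collapsed.index = pd.Index([], dtype=object)
    else:
        genes = pd.Index([gene_for_probe[p] for p in surviving.index])
        collapsed = surviving.groupby(genes).median().sort_index()
        collapsed.index.name = None
    return ExpressionMatrix(collapsed, platform_id=probe_matrix.platform_id)


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize all samples to a common intensity distribution.

    Each column is replaced by the reference distribution — the vector of
    row-wise means of the column-sorted values — assigned by within-column
    rank, so every column ends up with the identical multiset of values and
    each column's rank order is preserved. Ties receive the mean of the
    reference values at their tied ranks (the standard mid-rank convention),
    which makes the operation deterministic and idempotent.

    Raises
    ------
    ValueError
        If the matrix has fewer than two samples.
    """
    values = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = values.shape
    if n_samples < 2:
        raise ValueError("quantile normalization requires at least 2 samples")

    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_samples):
        order = np.argsort(values[:, j], kind="stable")
        sorted_vals = values[order, j]
        # tie groups share the mean of the reference values at their ranks
        grp = np.concatenate(([0], np.cumsum(sorted_vals[1:] != sorted_vals[:-1])))
        group_mean = np.bincount(grp, weights=reference) / np.bincount(grp)
        out[order, j] = group_mean[grp]
    result = pd.DataFrame(out, index=matrix.values.index,
                          columns=matrix.values.columns)
    return ExpressionMatrix(result, platform_id=matrix.platform_id)


def intersect_gene_universe(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two matrices to their common gene ids, in identical row order.

    Raises
    ------
    ValueError
        If the two gene universes are disjoint.
    """
    common = sorted(set(a.gene_ids) & set(b.gene_ids))
    if not common:
        raise ValueError("gene universes are disjoint: no common genes")
    return (
        ExpressionMatrix(a.values.loc[common].copy(), platform_id=a.platform_id),
        ExpressionMatrix(b.values.loc[common].copy(), platform_id=b.platform_id),
    )
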
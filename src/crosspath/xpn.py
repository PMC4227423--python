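"""Cross-platform normalization (XPN) of two expression cohorts.

Two platforms measuring the same genes differ by systematic, platform-wide
structure (probe affinity, scanner gain, labelling chemistry) that swamps
biological contrasts when cohorts are pooled. XPN removes it with a block
model: genes are clustered into K row blocks and samples into L column
blocks, and each platform's data are modelled as

    x_ij = A[alpha(i), beta(j)] * b_i + c_i + sigma_i * eps_ij

where ``A`` is a K×L block-amplitude matrix, ``b_i`` and ``c_i`` are
per-gene sensitivity and offset, and ``sigma_i`` a per-gene noise scale.
The model is fitted separately per platform on the common block structure;
the platform-specific parameters are then replaced by their cross-platform
averages (weighted by sample counts), and each observation is rebuilt from
the averaged systematic part plus its own standardised residual. Biological
signal, which lives in the sample-block amplitudes shared by both cohorts
and in the residuals, survives; platform-specific offsets and gains do not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .containers import ExpressionMatrix

__all__ = ["XpnConfig", "XpnModel", "xpn_normalize", "cross_platform_discrepancy"]

_EPS = 1e-12


@dataclass
class XpnConfig:
    """Tuning parameters of the XPN fit.

    ``n_gene_blocks`` (K) and ``n_sample_blocks`` (L) are upper bounds,
    scaled down automatically on small data (K ≤ n_genes/10, L ≤
    n_samples/3 per platform, both at least 1) so the defaults degrade
    gracefully at desk scale. All randomness (k-means restarts) is funnelled
    through ``seed``.
    """

    n_gene_blocks: int = 25
    n_sample_blocks: int = 5
    n_clustering_restarts: int = 10
    max_iterations: int = 50
    convergence_tolerance: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gene_blocks < 1 or self.n_sample_blocks < 1:
            raise ValueError("block counts must be >= 1")
        if self.n_clustering_restarts < 1:
            raise ValueError("n_clustering_restarts must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.convergence_tolerance <= 0:
            raise ValueError("convergence_tolerance must be positive")


@dataclass
class XpnModel:
    """Fitted XPN block structure and parameters, for audit.

    ``gene_block_assignment`` maps gene id → row-block index;
    ``sample_block_assignment`` maps sample id → column-block index (samples
    of both platforms share one block labelling). Per-platform parameter
    dictionaries are keyed by platform id; ``A`` is K×L.
    """

    gene_block_assignment: dict[str, int]
    sample_block_assignment: dict[str, int]
    A: dict[str, np.ndarray]
    b: dict[str, pd.Series]
    c: dict[str, pd.Series]
    sigma: dict[str, pd.Series]
    n_gene_blocks: int
    n_sample_blocks: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_gene_blocks": self.n_gene_blocks,
            "n_sample_blocks": self.n_sample_blocks,
            "gene_block_assignment": self.gene_block_assignment,
            "sample_block_assignment": self.sample_block_assignment,
            "A": {p: a.tolist() for p, a in self.A.items()},
            "b": {p: s.round(10).to_dict() for p, s in self.b.items()},
            "c": {p: s.round(10).to_dict() for p, s in self.c.items()},
            "sigma": {p: s.round(10).to_dict() for p, s in self.sigma.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / np.maximum(sd, _EPS)


def _fit_platform(
    x: np.ndarray,
    row_block: np.ndarray,
    col_block: np.ndarray,
    n_row_blocks: int,
    n_col_blocks: int,
    max_iterations: int,
    tolerance: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Least-squares fit of A, b, c for one platform by block coordinate descent."""
    n_genes, n_samples = x.shape
    b = np.ones(n_genes)
    c = x.mean(axis=1)
    col_sizes = np.bincount(col_block, minlength=n_col_blocks).astype(float)
    fitted_prev: np.ndarray | None = None
    fitted = np.zeros_like(x)
    for _ in range(max_iterations):
        # A-step: per-block weighted least squares given b, c
        r = (x - c[:, None]) * b[:, None]
        row_sums = np.zeros((n_row_blocks, n_samples))
        np.add.at(row_sums, row_block, r)
        s = np.zeros((n_col_blocks, n_row_blocks))
        np.add.at(s, col_block, row_sums.T)
        b_sq = np.bincount(row_block, weights=b * b, minlength=n_row_blocks)
        denom = np.outer(b_sq, col_sizes)
        a = np.divide(s.T, denom, out=np.zeros_like(s.T), where=denom > _EPS)

        # b,c-step: per-gene regression of x on the block amplitude profile,
        # ridge-shrunk toward sensitivity 1: genes whose amplitude profile is
        # nearly flat carry no information about b, and the unregularised
        # slope explodes on noise there
        a_cells = a[row_block][:, col_block]
        a_mean = a_cells.mean(axis=1)
        x_mean = x.mean(axis=1)
        a_centered = a_cells - a_mean[:, None]
        cov = (a_centered * (x - x_mean[:, None])).mean(axis=1)
        var = (a_centered**2).mean(axis=1)
        prior = max(var.mean(), _EPS)
        b = (cov + prior) / (var + prior)
        c = x_mean - b * a_mean

        # identifiability: mean sensitivity 1 within each gene block
        block_n = np.maximum(np.bincount(row_block, minlength=n_row_blocks), 1)
        b_mean = np.bincount(row_block, weights=b, minlength=n_row_blocks) / block_n
        scale = np.where(np.abs(b_mean) > 1e-8, b_mean, 1.0)
        b = b / scale[row_block]
        a = a * scale[:, None]

        fitted = a[row_block][:, col_block] * b[:, None] + c[:, None]
        if fitted_prev is not None and np.max(np.abs(fitted - fitted_prev)) < tolerance:
            break
        fitted_prev = fitted
    resid = x - fitted
    ddof = 1 if n_samples > 1 else 0
    sigma = np.maximum(resid.std(axis=1, ddof=ddof), 1e-8)
    return a, b, c, sigma, fitted


def xpn_normalize(
    a: ExpressionMatrix, b: ExpressionMatrix, config: XpnConfig | None = None
) -> tuple[ExpressionMatrix, ExpressionMatrix, XpnModel]:
    """Normalize two platforms over their common genes with the XPN block model.

    Both matrices must carry the identical gene universe in identical row
    order (use :func:`crosspath.preprocess.intersect_gene_universe` first).
    Returns the two normalized matrices (same shapes, same labels) and the
    fitted :class:`XpnModel`. Deterministic given ``config.seed``.
    """
    if config is None:
        config = XpnConfig()
    if a.gene_ids != b.gene_ids:
        raise ValueError("gene universes differ or are ordered differently; "
                         "run intersect_gene_universe first")

    # canonical internal order => swapping the arguments is a no-op
    key_a = (a.platform_id, tuple(a.sample_ids))
    key_b = (b.platform_id, tuple(b.sample_ids))
    swapped = key_b < key_a
    first, second = (b, a) if swapped else (a, b)

    x1 = first.values.to_numpy(dtype=float)
    x2 = second.values.to_numpy(dtype=float)
    n_genes = x1.shape[0]
    n1, n2 = x1.shape[1], x2.shape[1]

    n_row_blocks = max(1, min(config.n_gene_blocks, n_genes // 10 or 1))
    n_col_blocks = max(1, min(config.n_sample_blocks, min(n1, n2) // 3 or 1))
    if n_row_blocks > n_genes:
        raise ValueError("more gene blocks than genes")
    if n_col_blocks > min(n1, n2):
        raise ValueError("more sample blocks than samples on a platform")

    # cluster on within-platform standardized data so platform offsets do not
    # drive the block structure
    z = np.hstack([_standardize_rows(x1), _standardize_rows(x2)])
    if n_row_blocks == 1:
        row_block = np.zeros(n_genes, dtype=int)
    else:
        km = KMeans(n_clusters=n_row_blocks, n_init=config.n_clustering_restarts,
                    random_state=config.seed % (2**31))
        row_block = km.fit_predict(z)
    if n_col_blocks == 1:
        col_block_all = np.zeros(n1 + n2, dtype=int)
    else:
        km = KMeans(n_clusters=n_col_blocks, n_init=config.n_clustering_restarts,
                    random_state=(config.seed + 1) % (2**31))
        col_block_all = km.fit_predict(z.T)
    col1, col2 = col_block_all[:n1], col_block_all[n1:]

    fit1 = _fit_platform(x1, row_block, col1, n_row_blocks, n_col_blocks,
                         config.max_iterations, config.convergence_tolerance)
    fit2 = _fit_platform(x2, row_block, col2, n_row_blocks, n_col_blocks,
                         config.max_iterations, config.convergence_tolerance)
    a1, b1, c1, s1, fitted1 = fit1
    a2, b2, c2, s2, fitted2 = fit2

    # cross-platform averages weighted by cohort size
    w1, w2 = n1 / (n1 + n2), n2 / (n1 + n2)
    a_star = w1 * a1 + w2 * a2
    b_star = w1 * b1 + w2 * b2
    c_star = w1 * c1 + w2 * c2
    s_star = np.sqrt(w1 * s1**2 + w2 * s2**2)

    def _transform(x, fitted, sigma, colb):
        systematic = a_star[row_block][:, colb] * b_star[:, None] + c_star[:, None]
        return systematic + s_star[:, None] * (x - fitted) / sigma[:, None]

    y1 = _transform(x1, fitted1, s1, col1)
    y2 = _transform(x2, fitted2, s2, col2)

    out_first = ExpressionMatrix(
        pd.DataFrame(y1, index=first.values.index, columns=first.values.columns),
        platform_id=first.platform_id,
    )
    out_second = ExpressionMatrix(
        pd.DataFrame(y2, index=second.values.index, columns=second.values.columns),
        platform_id=second.platform_id,
    )

    genes = first.gene_ids
    p1 = first.platform_id or "platform_1"
    p2 = second.platform_id or "platform_2"
    if p1 == p2:
        p1, p2 = f"{p1}_1", f"{p2}_2"
    model = XpnModel(
        gene_block_assignment={g: int(k) for g, k in zip(genes, row_block)},
        sample_block_assignment={
            **{s: int(k) for s, k in zip(first.sample_ids, col1)},
            **{s: int(k) for s, k in zip(second.sample_ids, col2)},
        },
        A={p1: a1, p2: a2},
        b={p1: pd.Series(b1, index=genes), p2: pd.Series(b2, index=genes)},
        c={p1: pd.Series(c1, index=genes), p2: pd.Series(c2, index=genes)},
        sigma={p1: pd.Series(s1, index=genes), p2: pd.Series(s2, index=genes)},
        n_gene_blocks=n_row_blocks,
        n_sample_blocks=n_col_blocks,
    )
    if swapped:
        return out_second, out_first, model
    return out_first, out_second, model


def cross_platform_discrepancy(
    a: ExpressionMatrix, b: ExpressionMatrix
) -> tuple[pd.Series, float]:
    """Per-gene absolute difference of platform means, and its global mean.

    A diagnostic for the XPN stage: large values before normalization and
    small values after indicate removed platform structure.
    """
    if a.gene_ids != b.gene_ids:
        raise ValueError("gene universes differ or are ordered differently")
    diff = (a.values.mean(axis=1) - b.values.mean(axis=1)).abs()
    return diff, float(diff.mean())
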
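"""Two-group differential expression with BH correction and direction calls.

Statistics used throughout the pipeline: the classic pooled-variance
two-sided Student t-test per gene (Welch available behind a flag),
Benjamini-Hochberg step-up adjustment of the raw p-values, linear-scale fold
changes (expression is log2, so the ratio of un-logged group means), and the
two-sided Fisher exact test for 2×2 contingency tables such as the
up-vs-down proportion comparison between two tumor subtypes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ExpressionMatrix

__all__ = [
    "t_test_two_sample",
    "bh_adjust",
    "call_differential",
    "fisher_exact_2x2",
    "DE_RESULT_COLUMNS",
]

DE_RESULT_COLUMNS = ["gene", "t", "p", "p_bh", "fc", "direction",
                     "significant_raw", "significant_bh"]


def _pooled_t(x: np.ndarray, y: np.ndarray, axis: int = -1,
              welch: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided t-test along ``axis``; handles zero-variance groups."""
    nx, ny = x.shape[axis], y.shape[axis]
    mx, my = x.mean(axis=axis), y.mean(axis=axis)
    vx, vy = x.var(axis=axis, ddof=1), y.var(axis=axis, ddof=1)
    diff = mx - my
    if welch:
        se_sq = vx / nx + vy / ny
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se_sq**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
        df = np.where(np.isfinite(df), df, nx + ny - 2)
    else:
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se_sq = pooled * (1.0 / nx + 1.0 / ny)
        df = np.full(np.shape(diff), float(nx + ny - 2))
    se = np.sqrt(se_sq)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero pooled variance: equal means -> t=0 (p=1); unequal -> +-inf (p=0)
    degenerate = se == 0
    t = np.where(degenerate & (diff == 0), 0.0, t)
    t = np.where(degenerate & (diff != 0), np.where(diff > 0, np.inf, -np.inf), t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def t_test_two_sample(
    x, y, welch: bool = False
) -> tuple[float, float]:
    """Two-sided two-sample Student t-test with pooled variance.

    Returns ``(t_statistic, p_value)`` with ``df = n_x + n_y - 2`` (pooled)
    or the Welch-Satterthwaite df when ``welch=True``. Degenerate inputs are
    defined rather than propagated as NaN: two zero-variance groups with
    equal means give ``t=0, p=1``; zero pooled variance with unequal means
    gives ``p=0`` and emits a warning.

    Raises
    ------
    ValueError
        If either group has fewer than two observations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("inputs must be one-dimensional sample vectors")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    t, p = _pooled_t(x, y, welch=welch)
    if np.isinf(t):
        warnings.warn("zero pooled variance with unequal means: p set to 0",
                      RuntimeWarning, stacklevel=2)
    return float(t), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order.

    Sort ascending, take ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1,
    and undo the sort. Output is elementwise >= input and monotone in it.

    Raises
    ------
    ValueError
        If any entry lies outside [0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_differential(
    matrix: ExpressionMatrix,
    annotation: pd.DataFrame,
    raw_threshold: float = 0.05,
    bh_threshold: float = 0.05,
    group_column: str = "group",
    case: str = "tumor",
    control: str = "normal",
    welch: bool = False,
) -> pd.DataFrame:
    """Per-gene differential expression between two sample groups.

    For every gene: pooled t-statistic and raw p for case vs. control,
    BH-adjusted p over all genes, fold change as the ratio of linear-scale
    group means (values are log2, so ``fc = 2^mean(case) / 2^mean(control)``
    computed stably as ``2^(mean difference)``), and a direction call —
    "up"/"down" from the sign of the mean difference among genes significant
    at ``bh_threshold``, "none" otherwise. Flags at both the raw and the BH
    threshold are reported.

    Returns a DataFrame with columns
    ``gene, t, p, p_bh, fc, direction, significant_raw, significant_bh``.
    """
    ann = annotation.set_index("sample_id")
    samples = [s for s in matrix.sample_ids if s in ann.index]
    groups = ann.loc[samples, group_column]
    case_samples = [s for s in samples if groups[s] == case]
    control_samples = [s for s in samples if groups[s] == control]
    if len(case_samples) < 2 or len(control_samples) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(case_samples)} {case!r} "
            f"and {len(control_samples)} {control!r}"
        )

    x = matrix.values[case_samples].to_numpy(dtype=float)
    y = matrix.values[control_samples].to_numpy(dtype=float)
    t, p = _pooled_t(x, y, axis=1, welch=welch)
    p_bh = bh_adjust(p)
    mean_diff = x.mean(axis=1) - y.mean(axis=1)
    fc = np.exp2(mean_diff)
    sig_bh = p_bh < bh_threshold
    direction = np.where(
        sig_bh & (mean_diff > 0), "up", np.where(sig_bh & (mean_diff < 0), "down", "none")
    )
    return pd.DataFrame(
        {
            "gene": matrix.gene_ids,
            "t": t,
            "p": p,
            "p_bh": p_bh,
            "fc": fc,
            "direction": direction,
            "significant_raw": p < raw_threshold,
            "significant_bh": sig_bh,
        }
    )


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact test p-value for a 2×2 contingency table.

    The two-sided p sums the hypergeometric point probabilities of every
    table with the observed margins whose probability does not exceed that
    of the observed table (the point-probability rule).

    Raises
    ------
    ValueError
        For negative cells or an all-zero table.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("cells must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("cells must be integers")
        t = np.round(t).astype(int)
    if t.sum() == 0:
        raise ValueError("table must have at least one positive margin")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
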
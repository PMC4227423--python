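"""Gene-set over-representation analysis with the EASE score.

The EASE score is the conservative variant of the one-tailed Fisher exact
test used by the DAVID annotation tool: before computing the upper-tail
hypergeometric probability of the query/set overlap, the overlap count is
decremented by one. A single-gene overlap therefore never scores better
than p = 1, which damps spurious enrichment of tiny sets. Raw EASE p-values
are BH-adjusted across the whole collection; sets with zero overlap are
never reported but still count toward the adjustment family, so the family
size does not depend on the observed overlaps.

The background universe is an explicit argument — in this pipeline, the
common gene universe shared by both expression platforms.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from .containers import GeneSetCollection
from .diffexpr import bh_adjust
from .hyperstats import hypergeom_upper_tail

__all__ = ["ease_score", "enrich"]


def ease_score(overlap: int, query_size: int, set_size: int,
               universe_size: int) -> float:
    """EASE p-value: one-tailed Fisher with the overlap decremented by one.

    ``P(X >= overlap - 1)`` for ``X ~ Hypergeometric(universe_size,
    set_size, query_size)``; an overlap of 0 or 1 returns exactly 1.

    Raises
    ------
    ValueError
        If the counts are inconsistent (overlap larger than query or set,
        or set/query larger than the universe).
    """
    for name, value in (("overlap", overlap), ("query_size", query_size),
                        ("set_size", set_size), ("universe_size", universe_size)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    if overlap > min(query_size, set_size):
        raise ValueError("overlap exceeds query or set size")
    if max(query_size, set_size) > universe_size:
        raise ValueError("query or set larger than the universe")
    return hypergeom_upper_tail(max(overlap - 1, 0), universe_size,
                                set_size, query_size)


def enrich(
    query_genes: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    threshold: float = 0.1,
    significance_column: str = "p",
) -> pd.DataFrame:
    """Test a gene list against every set of a collection.

    Sets are intersected with the universe before testing, and the query
    must be a subset of the universe. One output row per set with overlap
    ≥ 1, sorted ascending by EASE p (ties by set name); BH adjustment runs
    over *all* tested sets, including those with zero overlap. Significance
    is flagged at ``threshold`` on ``significance_column`` ("p" for raw
    EASE p, "p_bh" for the adjusted value).

    Returns a DataFrame with columns
    ``set_name, overlap, set_size, p, p_bh, significant``.
    """
    query = set(query_genes)
    universe = set(universe)
    if not query:
        raise ValueError("query gene list is empty")
    if not universe:
        raise ValueError("universe is empty")
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe: {extra}")
    if significance_column not in ("p", "p_bh"):
        raise ValueError("significance_column must be 'p' or 'p_bh'")

    rows = []
    for gene_set in collection:
        members = gene_set.members & universe
        if not members:
            continue
        overlap = len(members & query)
        p = ease_score(overlap, len(query), len(members), len(universe))
        rows.append((gene_set.name, overlap, len(members), p))
    if not rows:
        return pd.DataFrame(
            columns=["set_name", "overlap", "set_size", "p", "p_bh", "significant"]
        )
    table = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size", "p"])
    table["p_bh"] = bh_adjust(table["p"].to_numpy())
    table = table[table["overlap"] >= 1]
    table = table.sort_values(["p", "set_name"], kind="stable").reset_index(drop=True)
    table["significant"] = table[significance_column] < threshold
    return table
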
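"""PPI subnetworks, degrees, hubs and DE-overlay networks.

The subnetwork around a list of differentially expressed genes (DEGs) keeps
every interaction touching at least one DEG, so its nodes are the DEGs plus
their direct non-DEG interactors. A hub is simply the node with the most
interactions; by default hub ranking is restricted to DEGs, since the
non-DEG neighbours carry no differential-expression evidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .containers import InteractionNetwork

__all__ = [
    "build_ppi_subnetwork",
    "node_degrees",
    "top_hubs",
    "HubRecord",
    "overlay_expression",
]


@dataclass(frozen=True)
class HubRecord:
    gene: str
    degree: int
    direction: str
    p_bh: float | None
    tied: bool = False


def build_ppi_subnetwork(
    edges: InteractionNetwork, deg_list: Iterable[str]
) -> InteractionNetwork:
    """Subnetwork of every interaction with at least one endpoint in ``deg_list``.

    Nodes of the result are the retained endpoints: the DEGs present in the
    network plus their direct non-DEG interactors. Self-loops and duplicate
    undirected edges never survive (the container drops them). Idempotent.

    Raises
    ------
    ValueError
        If ``deg_list`` is empty.
    """
    degs = set(deg_list)
    if not degs:
        raise ValueError("deg_list is empty")
    kept = [(u, v) for u, v in edges.edges() if u in degs or v in degs]
    sub = InteractionNetwork(kept)
    for node, data in edges.graph.nodes(data=True):
        if node in sub.graph:
            sub.graph.nodes[node].update(data)
    return sub


def node_degrees(network: InteractionNetwork) -> dict[str, int]:
    """Degree of every node: the number of distinct incident undirected edges."""
    return network.degrees()


def top_hubs(
    network: InteractionNetwork,
    k: int,
    de_table: pd.DataFrame | None = None,
    restrict_to_degs: bool = True,
) -> list[HubRecord]:
    """The ``k`` highest-degree nodes, annotated from a DE result table.

    Ties at equal degree are broken by lexicographic node id and flagged on
    the records involved. When ``de_table`` is given (columns ``gene``,
    ``direction``, ``p_bh``) and ``restrict_to_degs`` is true, only nodes
    with an entry in the table are eligible — non-DEG interactors are never
    called hubs. If ``k`` exceeds the number of eligible nodes, the list is
    truncated with a warning.

    Raises
    ------
    ValueError
        If ``k < 1``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    degrees = network.degrees()
    info: dict[str, tuple[str, float | None]] = {}
    if de_table is not None:
        for row in de_table.itertuples(index=False):
            info[row.gene] = (row.direction, float(row.p_bh))
        if restrict_to_degs:
            degrees = {g: d for g, d in degrees.items() if g in info}

    ranked = sorted(degrees.items(), key=lambda item: (-item[1], item[0]))
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds the {len(ranked)} eligible nodes; truncating",
            RuntimeWarning, stacklevel=2,
        )
        k = len(ranked)
    selected = ranked[:k]
    degree_counts: dict[int, int] = {}
    for _, d in ranked:
        degree_counts[d] = degree_counts.get(d, 0) + 1
    records = []
    for gene, degree in selected:
        direction, p_bh = info.get(gene, ("non-DEG", None))
        records.append(
            HubRecord(gene=gene, degree=degree, direction=direction,
                      p_bh=p_bh, tied=degree_counts[degree] > 1)
        )
    return records


def overlay_expression(
    network: InteractionNetwork,
    de_a: pd.DataFrame,
    de_b: pd.DataFrame,
    label_a: str = "subtype_a",
    label_b: str = "subtype_b",
) -> tuple[InteractionNetwork, pd.DataFrame]:
    """Label network nodes with per-subtype direction calls and summarise.

    Each node receives two attributes (``direction_<label>``), "up"/"down"
    from the corresponding DE table's direction column, "none" for a tested
    but non-significant gene, "non-DEG" for nodes absent from a table. The
    summary counts up/down per subtype and the genes changing in the same
    direction in both, split by direction — the concordance a side-by-side
    overlay of the two subtype networks displays.
    """
    dir_a = dict(zip(de_a["gene"], de_a["direction"]))
    dir_b = dict(zip(de_b["gene"], de_b["direction"]))
    annotated = InteractionNetwork(network.edges())
    for node in annotated.graph.nodes:
        annotated.graph.nodes[node][f"direction_{label_a}"] = dir_a.get(node, "non-DEG")
        annotated.graph.nodes[node][f"direction_{label_b}"] = dir_b.get(node, "non-DEG")

    nodes = annotated.nodes()
    a_calls = {n: dir_a.get(n, "non-DEG") for n in nodes}
    b_calls = {n: dir_b.get(n, "non-DEG") for n in nodes}

    def _count(calls: dict[str, str], wanted: str) -> int:
        return sum(1 for v in calls.values() if v == wanted)

    same_up = sum(1 for n in nodes if a_calls[n] == "up" and b_calls[n] == "up")
    same_down = sum(1 for n in nodes if a_calls[n] == "down" and b_calls[n] == "down")
    summary = pd.DataFrame(
        [
            (f"up_{label_a}", _count(a_calls, "up")),
            (f"down_{label_a}", _count(a_calls, "down")),
            (f"up_{label_b}", _count(b_calls, "up")),
            (f"down_{label_b}", _count(b_calls, "down")),
            ("same_direction_up", same_up),
            ("same_direction_down", same_down),
            ("same_direction_total", same_up + same_down),
        ],
        columns=["quantity", "count"],
    )
    return annotated, summary
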
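"""Pathway-pathway interaction (crosstalk) on protein-interaction edges.

Two pathways "talk" when the protein-interaction edges spanning them are
more numerous than chance allows. The unit of counting is the interaction
edge, restricted throughout to edges involving at least one differentially
expressed gene (DEG):

* ``N`` — interactions in the whole network with >= 1 DEG endpoint;
* ``M`` — those with >= 1 endpoint in pathway 1;
* ``n`` — those with >= 1 endpoint in pathway 2;
* ``k_obs`` — those with one endpoint in pathway 1 and the other in
  pathway 2.

Under the null that pathway 2's ``n`` interactions are an unbiased draw
from the ``N``, the count falling in pathway 1's ``M`` is hypergeometric;
the crosstalk p-value is the upper tail

    p = 1 - sum_{k=0}^{k_obs - 1} C(M, k) C(N-M, n-k) / C(N, n)
      = P(X >= k_obs),   X ~ Hypergeometric(N, M, n),

with p = 1 when ``k_obs = 0``. ``N`` is fixed globally per network + DEG
list, not recomputed per pair. A pathway pair is declared interacting when
p falls below the threshold (default 0.05; 0.1 is the other threshold in
circulation for this statistic — it is a required, explicit parameter).
Membership is a predicate, not a partition: an edge inside the overlap of
two pathways counts toward ``M``, ``n`` and ``k_obs`` simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import pandas as pd

from .containers import GeneSetCollection, InteractionNetwork
from .diffexpr import bh_adjust
from .hyperstats import hypergeom_upper_tail

__all__ = [
    "PathwayPairStats",
    "PathwayNetwork",
    "count_pair_interactions",
    "pathway_interaction_p",
    "build_pathway_network",
]


@dataclass(frozen=True)
class PathwayPairStats:
    """Edge counts and crosstalk p for one unordered pathway pair."""

    pathway_1: str
    pathway_2: str
    N: int
    M: int
    n: int
    k_obs: int
    p: float

    def __post_init__(self) -> None:
        if not (self.k_obs <= min(self.M, self.n) and max(self.M, self.n) <= self.N):
            raise ValueError("inconsistent pair counts")


@dataclass
class PathwayNetwork:
    """Pathway interaction network: enriched pathways joined by crosstalk edges.

    ``pairs`` holds the full audit table (one row per tested pair with N, M,
    n, k and p); ``network`` has one node per tested pathway and an edge per
    pair passing the threshold. An empty edge set is a valid outcome,
    reported as "no interactions".
    """

    network: InteractionNetwork
    pairs: pd.DataFrame
    threshold: float

    @property
    def has_interactions(self) -> bool:
        return self.network.n_edges > 0

    def degrees(self) -> dict[str, int]:
        return self.network.degrees()

    def describe(self) -> str:
        if not self.has_interactions:
            return "no interactions"
        return f"{self.network.n_edges} interacting pathway pair(s)"


def count_pair_interactions(
    network: InteractionNetwork,
    deg_list: Iterable[str],
    set_1: Iterable[str],
    set_2: Iterable[str],
) -> tuple[int, int, int, int]:
    """Count DEG-touching interactions globally, per pathway and between.

    Returns ``(N, M, n, k_obs)`` as defined in the module docstring.

    Raises
    ------
    ValueError
        If the network has no edges.
    """
    if network.n_edges == 0:
        raise ValueError("network has no edges")
    degs = set(deg_list)
    s1, s2 = set(set_1), set(set_2)
    N = M = n = k_obs = 0
    for u, v in network.edges():
        if u not in degs and v not in degs:
            continue
        N += 1
        in_1 = u in s1 or v in s1
        in_2 = u in s2 or v in s2
        if in_1:
            M += 1
        if in_2:
            n += 1
        if (u in s1 and v in s2) or (u in s2 and v in s1):
            k_obs += 1
    return N, M, n, k_obs


def pathway_interaction_p(N: int, M: int, n: int, k_obs: int) -> float:
    """Upper-tail hypergeometric crosstalk p-value, P(X >= k_obs).

    ``X ~ Hypergeometric(N, M, n)``; ``k_obs = 0`` gives exactly 1 (the
    cumulative sum below it is empty).

    Raises
    ------
    ValueError
        Naming the offending count when ``k_obs > min(M, n)``, ``M > N`` or
        ``n > N`` (or any count is negative).
    """
    for name, value in (("N", N), ("M", M), ("n", n), ("k_obs", k_obs)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    if M > N:
        raise ValueError(f"M={M} exceeds N={N}")
    if n > N:
        raise ValueError(f"n={n} exceeds N={N}")
    if k_obs > min(M, n):
        raise ValueError(f"k_obs={k_obs} exceeds min(M, n)={min(M, n)}")
    return hypergeom_upper_tail(k_obs, N, M, n)


def build_pathway_network(
    network: InteractionNetwork,
    deg_list: Iterable[str],
    enriched_sets: GeneSetCollection,
    threshold: float = 0.05,
    bh_correct: bool = False,
) -> PathwayNetwork:
    """Test every unordered pair of enriched pathways for crosstalk.

    Edges join pairs with p below ``threshold`` (on the BH-adjusted p when
    ``bh_correct`` is set; the default applies no correction over pairs).
    The pairs table carries N, M, n, k and p for every tested pair, sorted
    by p then pair name, for audit.

    Raises
    ------
    ValueError
        If fewer than two sets are supplied.
    """
    if len(enriched_sets) < 2:
        raise ValueError("need at least 2 enriched sets")
    degs = set(deg_list)
    names = enriched_sets.names()
    rows = []
    for name_1, name_2 in combinations(names, 2):
        s1 = enriched_sets[name_1].members
        s2 = enriched_sets[name_2].members
        N, M, n, k_obs = count_pair_interactions(network, degs, s1, s2)
        p = pathway_interaction_p(N, M, n, k_obs)
        rows.append((name_1, name_2, N, M, n, k_obs, p))
    pairs = pd.DataFrame(
        rows, columns=["pathway_1", "pathway_2", "N", "M", "n", "k", "p"]
    )
    p_col = "p"
    if bh_correct:
        pairs["p_bh"] = bh_adjust(pairs["p"].to_numpy())
        p_col = "p_bh"
    pairs["significant"] = pairs[p_col] < threshold
    pairs = pairs.sort_values(
        [p_col, "pathway_1", "pathway_2"], kind="stable"
    ).reset_index(drop=True)

    result = InteractionNetwork(
        (r.pathway_1, r.pathway_2)
        for r in pairs.itertuples(index=False)
        if r.significant
    )
    result.graph.add_nodes_from(names)
    return PathwayNetwork(network=result, pairs=pairs, threshold=threshold)
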
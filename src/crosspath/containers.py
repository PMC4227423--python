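"""Core in-memory containers and their tab-separated on-disk formats.

Everything downstream operates on a small set of shared structures:

* :class:`ExpressionMatrix` — genes × samples log2 intensities for one platform;
* :class:`ProbeMap` — probe → gene-id mapping, possibly multi-mapping;
* :class:`GeneSetCollection` — named gene sets (pathway stand-ins), GMT-backed;
* :class:`InteractionNetwork` — an undirected protein-interaction graph.

All on-disk formats are plain tab-separated text so that fixtures, audits and
external viewers (Cytoscape-compatible SIF/GraphML) can consume them directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ProbeMap",
    "GeneSet",
    "GeneSetCollection",
    "InteractionNetwork",
    "read_sample_annotation",
    "write_sample_annotation",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples matrix of log2 intensities with a platform label.

    Parameters
    ----------
    values
        DataFrame indexed by gene (or probe) id with sample ids as columns.
        All values must be finite; gene and sample ids must be unique.
    platform_id
        Free-text label identifying the measurement platform.
    """

    values: pd.DataFrame
    platform_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a pandas DataFrame")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes[:5])}")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        self.values = self.values.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.platform_id)

    def to_tsv(self, path: str | Path) -> None:
        """Write as tab-separated text: first column gene id, header of sample ids."""
        out = self.values.copy()
        out.index.name = "gene"
        out.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, platform_id: str = "") -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.index.name = None
        return cls(df, platform_id=platform_id)


class ProbeMap:
    """Mapping from probe id to the set of gene ids it interrogates.

    Probes mapping to more than one gene are allowed here; the preprocessing
    step is responsible for discarding them.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset[str]] = {}
        for probe, genes in mapping.items():
            targets = frozenset(str(g) for g in genes)
            if not targets:
                raise ValueError(f"probe {probe!r} has an empty target set")
            self._map[str(probe)] = targets

    def __getitem__(self, probe: str) -> frozenset[str]:
        return self._map[probe]

    def __contains__(self, probe: str) -> bool:
        return probe in self._map

    def __len__(self) -> int:
        return len(self._map)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ProbeMap) and self._map == other._map

    def items(self):
        return self._map.items()

    def probes(self) -> list[str]:
        return list(self._map)

    def genes(self) -> set[str]:
        out: set[str] = set()
        for targets in self._map.values():
            out |= targets
        return out

    def multi_mapping_probes(self) -> set[str]:
        """Probes assigned to two or more genes."""
        return {p for p, g in self._map.items() if len(g) > 1}

    def to_tsv(self, path: str | Path) -> None:
        """One row per probe-gene pair: ``probe<TAB>gene``."""
        with open(path, "w") as fh:
            fh.write("probe\tgene\n")
            for probe in sorted(self._map):
                for gene in sorted(self._map[probe]):
                    fh.write(f"{probe}\t{gene}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        mapping: dict[str, set[str]] = {}
        for probe, gene in zip(df["probe"], df["gene"]):
            mapping.setdefault(probe, set()).add(gene)
        return cls(mapping)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")


class GeneSetCollection:
    """Ordered collection of uniquely named gene sets, GMT-serialisable."""

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: list[GeneSet] = list(sets)
        names = [s.name for s in self._sets]
        if len(names) != len(set(names)):
            seen: set[str] = set()
            dupes = [n for n in names if n in seen or seen.add(n)]
            raise ValueError(f"duplicate set names: {dupes}")

    def __iter__(self):
        return iter(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self._sets:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(s.name == name for s in self._sets)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSetCollection) and self._sets == other._sets

    def names(self) -> list[str]:
        return [s.name for s in self._sets]

    def subset(self, names: Iterable[str]) -> "GeneSetCollection":
        wanted = set(names)
        return GeneSetCollection([s for s in self._sets if s.name in wanted])

    def to_gmt(self, path: str | Path) -> None:
        """Write GMT: ``name<TAB>description<TAB>member...`` one set per line."""
        with open(path, "w") as fh:
            for s in self._sets:
                members = "\t".join(sorted(s.members))
                fh.write(f"{s.name}\t{s.description}\t{members}\n")

    @classmethod
    def from_gmt(cls, path: str | Path) -> "GeneSetCollection":
        sets = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line!r}")
                sets.append(GeneSet(parts[0], parts[1], frozenset(parts[2:])))
        return cls(sets)


class InteractionNetwork:
    """Undirected interaction graph with no self-loops or duplicate edges.

    Wraps a :class:`networkx.Graph`; construction silently collapses duplicate
    undirected edges and drops self-loops, as flat interaction files routinely
    contain both.
    """

    def __init__(self, edges: Iterable[tuple[str, str]] = ()):
        g = nx.Graph()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                continue
            g.add_edge(u, v)
        self.graph = g

    @classmethod
    def from_graph(cls, graph: nx.Graph) -> "InteractionNetwork":
        net = cls()
        net.graph = nx.Graph()
        net.graph.add_nodes_from(graph.nodes(data=True))
        net.graph.add_edges_from(
            (u, v, d) for u, v, d in graph.edges(data=True) if u != v
        )
        return net

    # -- queries ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        """Edges as lexicographically ordered pairs, sorted."""
        return sorted(tuple(sorted((u, v))) for u, v in self.graph.edges)

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree)

    def has_edge(self, u: str, v: str) -> bool:
        return self.graph.has_edge(u, v)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, InteractionNetwork) and self.edges() == other.edges()

    # -- node attributes -------------------------------------------------

    def set_node_attribute(self, name: str, values: Mapping[str, object],
                           default: object = None) -> None:
        for node in self.graph.nodes:
            self.graph.nodes[node][name] = values.get(node, default)

    # -- serialisation ---------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("node_a\tnode_b\n")
            for u, v in self.edges():
                fh.write(f"{u}\t{v}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "InteractionNetwork":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(zip(df.iloc[:, 0], df.iloc[:, 1]))

    def to_sif(self, path: str | Path, relation: str = "pp") -> None:
        """Simple-interaction format: ``node_a<TAB>relation<TAB>node_b``."""
        with open(path, "w") as fh:
            isolated = sorted(n for n in self.graph.nodes
                              if self.graph.degree[n] == 0)
            for u, v in self.edges():
                fh.write(f"{u}\t{relation}\t{v}\n")
            for n in isolated:
                fh.write(f"{n}\n")

    def to_graphml(self, path: str | Path) -> None:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.graph.nodes))
        for n, data in self.graph.nodes(data=True):
            g.nodes[n].update({k: v for k, v in data.items() if v is not None})
        g.add_edges_from(self.edges())
        nx.write_graphml(g, path)


# -- sample annotation ----------------------------------------------------

_ANNOT_COLUMNS = ["sample_id", "group", "platform"]


def write_sample_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    """Write sample annotation (sample_id, group, platform) as TSV."""
    missing = [c for c in _ANNOT_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    annotation[_ANNOT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_sample_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation missing columns: {missing}")
    return df
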
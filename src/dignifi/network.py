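"""PPI network container and edge-list I/O.

The network is an undirected, weighted graph over gene symbols. Curated
binary interactions carry weight 1.0; a weighted edge list may supply
arbitrary non-negative weights. Cleaning at read time removes self-loops
and duplicate edges (the maximum weight wins) and drops degree-0 nodes so
that every random-walk transition row is well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "CooccurrenceTable",
    "read_network",
    "write_network",
    "read_cooccurrence",
    "enrich_with_cooccurrence",
]


class NetworkError(ValueError):
    """Raised for malformed or degenerate network inputs."""


class Network:
    """An undirected weighted gene-interaction graph.

    Nodes are opaque, case-sensitive gene symbols. ``K(v)`` is the node
    strength (sum of incident edge weights), ``M`` the number of edges.
    Instances are treated as immutable after construction; derived
    quantities (node ordering, strength vector, transition matrix, walk
    vectors) are cached on the instance.
    """

    def __init__(self, graph: nx.Graph):
        cleaned = nx.Graph()
        for u, v, data in graph.edges(data=True):
            if u == v:
                continue
            w = float(data.get("weight", 1.0))
            if w < 0:
                raise NetworkError(f"negative edge weight {w} on ({u}, {v})")
            prev = cleaned.get_edge_data(u, v)
            if prev is None or prev["weight"] < w:
                cleaned.add_edge(u, v, weight=w)
        if cleaned.number_of_edges() == 0:
            raise NetworkError("network is empty after cleaning")
        self._graph = cleaned
        self._nodes: tuple[str, ...] = tuple(sorted(cleaned.nodes))
        self._index: dict[str, int] = {g: i for i, g in enumerate(self._nodes)}
        self._strengths = np.array(
            [cleaned.degree(g, weight="weight") for g in self._nodes], dtype=float
        )
        self._cache: dict = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        """All gene symbols, in the canonical (sorted) order."""
        return self._nodes

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        """M, the number of edges (links) in the network."""
        return self._graph.number_of_edges()

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def index(self, gene: str) -> int:
        try:
            return self._index[gene]
        except KeyError:
            raise KeyError(f"gene {gene!r} is not in the network") from None

    def strength(self, gene: str) -> float:
        """K(v): total weight of edges incident to ``gene``."""
        return float(self._strengths[self.index(gene)])

    @property
    def strengths(self) -> np.ndarray:
        """Strength vector aligned with :attr:`nodes`."""
        return self._strengths

    def has_edge(self, u: str, v: str) -> bool:
        return self._graph.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        data = self._graph.get_edge_data(u, v)
        return 0.0 if data is None else float(data["weight"])

    def neighbors(self, gene: str) -> Iterator[str]:
        if gene not in self._index:
            raise KeyError(f"gene {gene!r} is not in the network")
        return iter(self._graph[gene])

    def edges(self) -> Iterator[tuple[str, str, float]]:
        """Edges as lexicographically oriented (u, v, weight) triples."""
        for u, v, data in self._graph.edges(data=True):
            a, b = (u, v) if u <= v else (v, u)
            yield a, b, float(data["weight"])

    # -- matrices ----------------------------------------------------------

    def adjacency(self) -> sparse.csr_matrix:
        """Weighted adjacency matrix in canonical node order (CSR)."""
        key = "adjacency"
        if key not in self._cache:
            self._cache[key] = nx.to_scipy_sparse_array(
                self._graph, nodelist=self._nodes, weight="weight", format="csr"
            ).astype(float)
        return self._cache[key]

    def transition_matrix(self) -> sparse.csr_matrix:
        """Row-stochastic transition matrix P with P[i, j] = w(i, j) / K(i)."""
        key = "transition"
        if key not in self._cache:
            adj = self.adjacency()
            inv_k = sparse.diags_array(1.0 / self._strengths)
            self._cache[key] = (inv_k @ adj).tocsr()
        return self._cache[key]


@dataclass(frozen=True)
class CooccurrenceTable:
    """Unordered gene pairs with PubMed co-mention article counts."""

    records: tuple[tuple[str, str, int], ...]

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int]]) -> "CooccurrenceTable":
        seen: dict[frozenset, int] = {}
        for a, b, count in records:
            if a == b:
                raise NetworkError(f"self-pair ({a}, {b}) in co-occurrence table")
            count = int(count)
            if count < 0:
                raise NetworkError(f"negative article count for ({a}, {b})")
            key = frozenset((a, b))
            seen[key] = max(seen.get(key, 0), count)
        rows = tuple(
            (*sorted(pair), count) for pair, count in sorted(seen.items(), key=lambda kv: sorted(kv[0]))
        )
        return cls(rows)

    def __len__(self) -> int:
        return len(self.records)


def read_network(path: str | Path, weighted: bool = False) -> Network:
    """Read an edge-list TSV (``geneA geneB [weight]``; ``#`` comments).

    Duplicates collapse to the maximum weight, self-loops are dropped, and
    the result must be non-empty. Malformed lines raise with their line
    number.
    """
    graph = nx.Graph()
    n_self = n_dup = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise NetworkError(f"{path}:{lineno}: expected at least two columns, got {line!r}")
            a, b = parts[0], parts[1]
            if weighted and len(parts) >= 3:
                try:
                    w = float(parts[2])
                except ValueError:
                    raise NetworkError(f"{path}:{lineno}: non-numeric weight {parts[2]!r}") from None
            else:
                w = 1.0
            if w < 0:
                raise NetworkError(f"{path}:{lineno}: negative weight {w}")
            if a == b:
                n_self += 1
                continue
            prev = graph.get_edge_data(a, b)
            if prev is not None:
                n_dup += 1
                if prev["weight"] >= w:
                    continue
            graph.add_edge(a, b, weight=w)
    if graph.number_of_edges() == 0:
        raise NetworkError(f"{path}: network is empty after cleaning")
    net = Network(graph)
    logger.info(
        "read %s: %d genes, %d interactions (%d self-loops and %d duplicates removed)",
        path, net.n_nodes, net.n_edges, n_self, n_dup,
    )
    return net


def write_network(net: Network, path: str | Path) -> None:
    """Write the network as a 3-column TSV; read_network round-trips it."""
    with open(path, "w") as fh:
        for u, v, w in sorted(net.edges()):
            fh.write(f"{u}\t{v}\t{w!r}\n")


def read_cooccurrence(path: str | Path) -> CooccurrenceTable:
    """Read a ``geneA geneB count`` TSV of literature co-mention pairs."""
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise NetworkError(f"{path}:{lineno}: expected three columns, got {line!r}")
            try:
                count = int(parts[2])
            except ValueError:
                raise NetworkError(f"{path}:{lineno}: non-integer count {parts[2]!r}") from None
            records.append((parts[0], parts[1], count))
    return CooccurrenceTable.from_records(records)


def enrich_with_cooccurrence(
    net: Network, co: CooccurrenceTable, min_articles: int = 30
) -> Network:
    """Add literature co-mention pairs with >= ``min_articles`` as new edges.

    Pairs already present as interactions are left untouched; added edges
    get weight 1.0 (literature edges are treated as ordinary binary
    interactions). Returns a new Network.
    """
    if min_articles < 1:
        raise ValueError("min_articles must be >= 1")
    graph = net.graph.copy()
    added = overlap = 0
    for a, b, count in co.records:
        if count < min_articles:
            continue
        if graph.has_edge(a, b):
            overlap += 1
        else:
            graph.add_edge(a, b, weight=1.0)
            added += 1
    logger.info(
        "co-occurrence enrichment: %d pairs passed the >=%d-article threshold "
        "(%d overlapped existing interactions, %d added)",
        added + overlap, min_articles, overlap, added,
    )
    if added == 0:
        return Network(net.graph)
    return Network(graph)
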
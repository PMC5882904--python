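"""Ground-truth random directed networks.

Synthetic benchmarks need directed graphs drawn uniformly from the set of all
simple digraphs with a fixed number of nodes ``N`` and directed edges ``n_e``
(no self-loops; antiparallel pairs i->j and j->i are allowed and count as two
edges).  Network density is ``d_n = n_e / (N * (N - 1))``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "DirectedNetwork",
    "sample_uniform_digraph",
    "edge_schedule",
    "average_degree",
    "EDGE_SCHEDULE_20",
]

#: Edge-count sweep for 20-node benchmark networks: 23 levels whose densities
#: are approximately log-equidistant between 0.005 and 1.
EDGE_SCHEDULE_20: tuple[int, ...] = (
    2, 3, 4, 5, 6, 8, 10, 12, 15, 19, 24, 30, 38, 48, 60,
    76, 95, 120, 151, 190, 240, 302, 380,
)


@dataclass(frozen=True)
class DirectedNetwork:
    """A simple directed graph with an exact edge count.

    Parameters
    ----------
    n_nodes
        Number of nodes ``N``; nodes are labelled ``0 .. N-1``.
    edges
        Ordered pairs ``(source, target)`` with ``source != target``.
    seed
        Record of the RNG seed used to draw the graph (``None`` when the
        graph was constructed explicitly).
    """

    n_nodes: int
    edges: frozenset[tuple[int, int]]
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be positive")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-edge {i}->{j} not allowed")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge {i}->{j} outside [0, {self.n_nodes})")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        """``n_e / (N * (N - 1))``."""
        return self.n_edges / (self.n_nodes * (self.n_nodes - 1))

    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix ``A[i, j] = True`` iff edge ``i -> j``."""
        a = np.zeros((self.n_nodes, self.n_nodes), dtype=bool)
        for i, j in self.edges:
            a[i, j] = True
        return a

    def sorted_edges(self) -> list[tuple[int, int]]:
        return sorted(self.edges)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(self.sorted_edges())
        return g

    @classmethod
    def from_adjacency(cls, a: np.ndarray, seed: int | None = None) -> "DirectedNetwork":
        a = np.asarray(a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        edges = frozenset((int(i), int(j)) for i, j in zip(*np.nonzero(a)) if i != j)
        return cls(n_nodes=a.shape[0], edges=edges, seed=seed)

    # -- serialization ----------------------------------------------------

    def to_edgelist_tsv(self, path: str | Path) -> None:
        """Write one ``source<TAB>target`` row per directed edge (0-based ids)."""
        path = Path(path)
        lines = ["source\ttarget"]
        lines += [f"{i}\t{j}" for i, j in self.sorted_edges()]
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_edgelist_tsv(cls, path: str | Path, n_nodes: int | None = None) -> "DirectedNetwork":
        rows = Path(path).read_text().strip().splitlines()
        body = rows[1:] if rows and not rows[0].split("\t")[0].lstrip("-").isdigit() else rows
        edges = set()
        for line in body:
            if not line.strip():
                continue
            i, j = (int(tok) for tok in line.split("\t")[:2])
            edges.add((i, j))
        if n_nodes is None:
            n_nodes = 1 + max((max(i, j) for i, j in edges), default=-1)
        return cls(n_nodes=n_nodes, edges=frozenset(edges))

    def to_graphml(self, path: str | Path) -> None:
        nx.write_graphml(self.to_networkx(), str(path))


def sample_uniform_digraph(
    n_nodes: int, n_edges: int, rng: np.random.Generator
) -> DirectedNetwork:
    """Draw a digraph uniformly from all simple digraphs with ``n_edges`` edges.

    Sampling is rejection-free: ``n_edges`` ordered pairs are chosen without
    replacement from the ``N * (N - 1)`` admissible pairs, which is exactly the
    uniform distribution over edge sets of the requested size.  Antiparallel
    pairs may co-occur; self-loops never.
    """
    n_possible = n_nodes * (n_nodes - 1)
    if not 0 <= n_edges <= n_possible:
        raise ValueError(
            f"n_edges={n_edges} outside [0, {n_possible}] for n_nodes={n_nodes}"
        )
    # enumerate ordered non-diagonal pairs: index k -> (i, j)
    picks = rng.choice(n_possible, size=n_edges, replace=False)
    edges = set()
    for k in picks:
        i, rem = divmod(int(k), n_nodes - 1)
        j = rem if rem < i else rem + 1
        edges.add((i, j))
    return DirectedNetwork(n_nodes=n_nodes, edges=frozenset(edges))


def edge_schedule(n_nodes: int = 20) -> list[int]:
    """Edge-count sweep whose densities are ~log-equidistant in [0.005, 1].

    For the 20-node benchmark family the canonical 23-entry list is returned
    verbatim; for other sizes an analogous schedule is built by rounding
    log-spaced densities to integer edge counts and deduplicating.
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if n_nodes == 20:
        return list(EDGE_SCHEDULE_20)
    n_possible = n_nodes * (n_nodes - 1)
    dens = np.logspace(np.log10(0.005), 0.0, 23)
    counts = sorted({max(1, int(round(d * n_possible))) for d in dens})
    return counts


def average_degree(network: DirectedNetwork) -> float:
    """Mean number of incident edges (in + out) per node: ``2 n_e / N``."""
    return 2.0 * network.n_edges / network.n_nodes


def schedule_to_json(path: str | Path, n_nodes: int = 20) -> None:
    counts = edge_schedule(n_nodes)
    n_possible = n_nodes * (n_nodes - 1)
    payload = {
        "n_nodes": n_nodes,
        "edge_counts": counts,
        "densities": [c / n_possible for c in counts],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def sample_network_family(
    n_nodes: int,
    n_edges: int,
    count: int,
    rng: np.random.Generator,
) -> list[DirectedNetwork]:
    """Independent draws at one density (e.g. the 32 networks per sweep point)."""
    return [sample_uniform_digraph(n_nodes, n_edges, rng) for _ in range(count)]
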
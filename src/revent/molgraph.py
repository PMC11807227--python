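"""Molecular graphs, reverse degrees and reverse-degree edge partitions.

A molecular graph here is the hydrogen-suppressed heavy-atom graph of a
compound: vertices are atoms, edges are bonds, bond orders and charges are
ignored, and the graph must be simple and connected. The *reverse degree* of a
vertex v is

    upsilon(v) = Delta - d(v) + 1,

where Delta is the maximum degree of the graph itself and d(v) the ordinary
degree, so upsilon(v) >= 1 always, with equality exactly at maximum-degree
vertices. Note that Delta is recomputed for every input graph: embedding a
graph in a larger one changes every reverse degree.

The edge partition groups edges by the sorted pair of endpoint reverse
degrees; it is a sufficient statistic for every index and entropy measure in
this package.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    AdjacencyMatrixError,
    DisconnectedGraphError,
    DuplicateEdgeError,
    EmptyInputError,
    MultiFragmentError,
    PartitionError,
    SelfLoopError,
    SmilesAdapterUnavailableError,
    SmilesError,
)

__all__ = [
    "MolecularGraph",
    "ReverseDegreeProfile",
    "EdgePartition",
    "graph_from_edge_list",
    "graph_from_adjacency",
    "graph_from_smiles",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency_csv",
    "write_adjacency_csv",
    "reverse_degrees",
    "edge_partition",
    "random_connected_graph",
]


@dataclass(frozen=True)
class MolecularGraph:
    """A finite, simple, connected, undirected graph with opaque string labels.

    Iteration order over vertices and edges is canonical (sorted), so every
    derived quantity is independent of input order.
    """

    vertices: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]

    def __init__(self, edges: Iterable[tuple[str, str]]):
        canon = []
        seen = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise SelfLoopError(f"self-loop at vertex {u!r}")
            key = (u, v) if u < v else (v, u)
            if key in seen:
                raise DuplicateEdgeError(f"duplicate edge {key!r}")
            seen.add(key)
            canon.append(key)
        if not canon:
            raise EmptyInputError("graph needs at least one edge")
        canon.sort()
        verts = tuple(sorted({x for e in canon for x in e}))
        g = nx.Graph(canon)
        if not nx.is_connected(g):
            n_comp = nx.number_connected_components(g)
            raise DisconnectedGraphError(
                f"graph has {n_comp} components; expected a single one"
            )
        object.__setattr__(self, "vertices", verts)
        object.__setattr__(self, "edges", tuple(canon))

    @property
    def p(self) -> int:
        """Vertex count (order)."""
        return len(self.vertices)

    @property
    def q(self) -> int:
        """Edge count (size)."""
        return len(self.edges)

    def degrees(self) -> dict[str, int]:
        d = dict.fromkeys(self.vertices, 0)
        for u, v in self.edges:
            d[u] += 1
            d[v] += 1
        return d

    @property
    def max_degree(self) -> int:
        return max(self.degrees().values())

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def adjacency(self) -> pd.DataFrame:
        """Dense 0/1 adjacency matrix with sorted vertex labels."""
        idx = list(self.vertices)
        a = pd.DataFrame(0, index=idx, columns=idx, dtype=int)
        for u, v in self.edges:
            a.loc[u, v] = a.loc[v, u] = 1
        return a

    def __repr__(self) -> str:
        return f"MolecularGraph(p={self.p}, q={self.q})"


@dataclass(frozen=True)
class ReverseDegreeProfile:
    """Reverse degrees upsilon(v) = Delta - d(v) + 1 for one graph."""

    max_degree: int
    upsilon: Mapping[str, int]

    def on_edge(self, u: str, v: str) -> tuple[int, int]:
        a, b = self.upsilon[u], self.upsilon[v]
        return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class EdgePartition:
    """Multiset of reverse-degree pairs (a, b), a <= b, with edge counts.

    ``context`` carries (p, q) of the originating graph for the
    context-dependent Balaban weight.
    """

    classes: Mapping[tuple[int, int], int]
    context: tuple[int, int] | None = None

    def __post_init__(self):
        classes = dict(self.classes)
        for (a, b), n in classes.items():
            if not (isinstance(a, int) and isinstance(b, int)) or a < 1 or b < a:
                raise PartitionError(f"invalid class pair {(a, b)!r}")
            if n < 0:
                raise PartitionError(f"negative count {n} for class {(a, b)}")
        object.__setattr__(self, "classes", classes)

    @property
    def q(self) -> int:
        return sum(self.classes.values())

    def items(self):
        return sorted(self.classes.items())

    def __repr__(self) -> str:
        body = ", ".join(f"{k}: {n}" for k, n in self.items())
        return f"EdgePartition({{{body}}}, q={self.q})"


# ---------------------------------------------------------------------------
# constructors


def graph_from_edge_list(records: Iterable) -> MolecularGraph:
    """Build a graph from two-token records.

    Each record is either a pair of labels or a whitespace-separated string;
    blank lines and ``#`` comments are skipped.
    """
    edges = []
    for rec in records:
        if isinstance(rec, str):
            line = rec.split("#", 1)[0].strip()
            if not line:
                continue
            toks = line.split()
        else:
            toks = [str(t) for t in rec]
        if len(toks) != 2:
            raise EmptyInputError(
                f"edge record must have exactly two tokens, got {toks!r}"
            )
        edges.append((toks[0], toks[1]))
    if not edges:
        raise EmptyInputError("no edges in input")
    return MolecularGraph(edges)


def read_edge_list(path) -> MolecularGraph:
    with open(path, "r", encoding="utf-8") as fh:
        return graph_from_edge_list(fh)


def write_edge_list(graph: MolecularGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in graph.edges:
            fh.write(f"{u} {v}\n")


def graph_from_adjacency(matrix, labels: Sequence[str] | None = None) -> MolecularGraph:
    """Build a graph from a square, symmetric, hollow 0/1 matrix."""
    if isinstance(matrix, pd.DataFrame):
        if labels is None:
            labels = [str(c) for c in matrix.columns]
        matrix = matrix.to_numpy()
    a = np.asarray(matrix)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise AdjacencyMatrixError(f"matrix must be square, got shape {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise AdjacencyMatrixError("matrix entries must be 0 or 1")
    if np.diag(a).any():
        raise AdjacencyMatrixError("matrix diagonal must be zero (no self-loops)")
    if not (a == a.T).all():
        raise AdjacencyMatrixError("matrix must be symmetric")
    n = a.shape[0]
    if labels is None:
        labels = [f"v{i}" for i in range(n)]
    elif len(labels) != n:
        raise AdjacencyMatrixError("label count does not match matrix size")
    ii, jj = np.nonzero(np.triu(a, 1))
    if len(ii) == 0:
        raise EmptyInputError("adjacency matrix has no edges")
    return MolecularGraph((labels[i], labels[j]) for i, j in zip(ii, jj))


def read_adjacency_csv(path) -> MolecularGraph:
    """Read a CSV adjacency matrix; a non-numeric first row/column is taken
    as labels."""
    raw = pd.read_csv(path, header=None, comment="#")
    first = raw.iloc[0, 0]
    labelled = (first is None or (isinstance(first, float) and np.isnan(first))
                or (isinstance(first, str)
                    and not str(first).strip().lstrip("-").isdigit()))
    if labelled:
        df = pd.read_csv(path, index_col=0, comment="#")
        return graph_from_adjacency(df.to_numpy(), [str(c) for c in df.columns])
    return graph_from_adjacency(raw.to_numpy())


def write_adjacency_csv(graph: MolecularGraph, path) -> None:
    graph.adjacency().to_csv(path)


def graph_from_smiles(smiles: str) -> MolecularGraph:
    """Hydrogen-suppressed heavy-atom graph of a single-fragment SMILES.

    Bond orders are ignored (an aromatic or double bond contributes one
    edge). Requires the optional ``rdkit`` dependency.
    """
    try:
        from rdkit import Chem
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise SmilesAdapterUnavailableError(
            "RDKit is not installed; install the 'smiles' extra or supply an "
            "edge-list / adjacency file instead"
        ) from exc
    mol = Chem.MolFromSmiles(smiles, sanitize=True)
    if mol is None:
        raise SmilesError(f"unparsable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise MultiFragmentError(
            f"SMILES encodes {len(frags)} fragments; supply a single fragment"
        )
    if mol.GetNumBonds() == 0:
        raise EmptyInputError("molecule has no bonds between heavy atoms")
    return MolecularGraph(
        (f"a{b.GetBeginAtomIdx()}", f"a{b.GetEndAtomIdx()}") for b in mol.GetBonds()
    )


# ---------------------------------------------------------------------------
# reverse degrees and partitions


def reverse_degrees(graph: MolecularGraph) -> ReverseDegreeProfile:
    """upsilon(v) = Delta - d(v) + 1, with Delta the graph's own maximum degree."""
    deg = graph.degrees()
    delta = max(deg.values())
    ups = {v: delta - d + 1 for v, d in deg.items()}
    return ReverseDegreeProfile(max_degree=delta, upsilon=ups)


def edge_partition(graph: MolecularGraph) -> EdgePartition:
    """Partition edges by the sorted endpoint reverse-degree pair."""
    prof = reverse_degrees(graph)
    counts = Counter(prof.on_edge(u, v) for u, v in graph.edges)
    return EdgePartition(dict(counts), context=(graph.p, graph.q))


# ---------------------------------------------------------------------------
# synthetic graphs


def random_connected_graph(n: int, extra_edges: int = 0, seed: int = 0) -> MolecularGraph:
    """Uniform random labeled spanning tree on n vertices plus ``extra_edges``
    distinct non-tree edges. Deterministic for a fixed seed."""
    if n < 2:
        raise ValueError("need n >= 2 vertices")
    max_extra = n * (n - 1) // 2 - (n - 1)
    if extra_edges < 0 or extra_edges > max_extra:
        raise ValueError(
            f"extra_edges must be in [0, {max_extra}] for n={n}, got {extra_edges}"
        )
    tree = nx.random_labeled_tree(n, seed=int(seed))
    label = {i: f"v{i:03d}" for i in range(n)}
    edges = {tuple(sorted((label[u], label[v]))) for u, v in tree.edges}
    if extra_edges:
        rng = np.random.default_rng(int(seed))
        non_edges = [
            (label[i], label[j])
            for i, j in itertools.combinations(range(n), 2)
            if (label[i], label[j]) not in edges
        ]
        pick = rng.choice(len(non_edges), size=extra_edges, replace=False)
        edges.update(non_edges[k] for k in sorted(pick))
    return MolecularGraph(sorted(edges))
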
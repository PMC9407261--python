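"""Network containers, edge-list I/O, matrix views and synthetic generators.

Networks are undirected, unweighted simple graphs: no self-loops, no
duplicate edges.  Nodes carry opaque string labels; internally every node is
a contiguous 0-based index and all matrices are indexed accordingly.
Isolated nodes are legal (they can appear as endpoints of sampled
non-edges); random-walk machinery treats them as absorbing with no mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "MatrixViews",
    "SyntheticSpec",
    "read_edge_list",
    "write_edge_list",
    "read_adjacency_matrix",
    "matrix_views",
    "generate_synthetic",
]


def _canon(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


@dataclass
class Network:
    """An undirected simple graph with string node labels.

    Edges are stored once as index pairs ``(i, j)`` with ``i < j``.
    ``blocks`` records a planted partition when the network came from a
    stochastic block model generator.
    """

    node_ids: list[str]
    edges: set[tuple[int, int]]
    blocks: list[int] | None = None
    _views: "MatrixViews | None" = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.node_ids)
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-loop on node index {i}")
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"edge ({i},{j}) outside node range 0..{n - 1}")
            if i > j:
                raise ValueError(f"edge ({i},{j}) not stored with i<j")
        if len(set(self.node_ids)) != n:
            raise ValueError("duplicate node labels")

    @property
    def N(self) -> int:
        return len(self.node_ids)

    @property
    def M(self) -> int:
        return len(self.edges)

    def has_edge(self, i: int, j: int) -> bool:
        return _canon(i, j) in self.edges

    def degrees(self) -> np.ndarray:
        k = np.zeros(self.N, dtype=np.int64)
        for i, j in self.edges:
            k[i] += 1
            k[j] += 1
        return k

    def neighbors(self, i: int) -> set[int]:
        out = set()
        for a, b in self.edges:
            if a == i:
                out.add(b)
            elif b == i:
                out.add(a)
        return out

    def adjacency_sets(self) -> list[set[int]]:
        """Neighbor set per node; one pass over the edge list."""
        adj: list[set[int]] = [set() for _ in range(self.N)]
        for i, j in self.edges:
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def views(self) -> "MatrixViews":
        """Matrix views, cached on the network (the graph is immutable by use)."""
        if self._views is None:
            self._views = matrix_views(self)
        return self._views

    def without_edges(self, remove: Iterable[tuple[int, int]]) -> "Network":
        """Copy with the given edges removed; node roster (and blocks) kept."""
        drop = {_canon(i, j) for i, j in remove}
        return Network(list(self.node_ids), set(self.edges) - drop, blocks=self.blocks)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.N))
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], extra_nodes: Sequence[str] = ()
    ) -> "Network":
        """Build from labeled pairs; labels are indexed in first-appearance order.

        Self-loops are dropped and reciprocal/duplicate pairs collapsed, with a
        logged warning reporting how many lines were coerced.
        """
        index: dict[str, int] = {}
        for lab in extra_nodes:
            index.setdefault(str(lab), len(index))
        edges: set[tuple[int, int]] = set()
        n_self = n_dup = 0
        for a, b in pairs:
            ia = index.setdefault(str(a), len(index))
            ib = index.setdefault(str(b), len(index))
            if ia == ib:
                n_self += 1
                continue
            e = _canon(ia, ib)
            if e in edges:
                n_dup += 1
            else:
                edges.add(e)
        if n_self or n_dup:
            logger.warning(
                "coerced input: dropped %d self-loop(s), collapsed %d duplicate/reciprocal pair(s)",
                n_self,
                n_dup,
            )
        labels = [None] * len(index)
        for lab, i in index.items():
            labels[i] = lab
        return cls(labels, edges)  # type: ignore[arg-type]


@dataclass
class MatrixViews:
    """Dense matrix views of a network.

    ``laplacian_pinv`` is computed lazily (it is O(N^3) and only the global
    similarity indices need it).
    """

    adjacency: np.ndarray
    degree_vector: np.ndarray
    laplacian: np.ndarray
    transition: np.ndarray
    _laplacian_pinv: np.ndarray | None = field(default=None, repr=False)

    @property
    def laplacian_pinv(self) -> np.ndarray:
        if self._laplacian_pinv is None:
            self._laplacian_pinv = np.linalg.pinv(self.laplacian, hermitian=True)
        return self._laplacian_pinv


def matrix_views(net: Network) -> MatrixViews:
    """Adjacency, degrees, Laplacian L = D - A and row-stochastic transition P.

    Rows of P for isolated nodes are all zero (absorbing with no mass).
    """
    n = net.N
    a = np.zeros((n, n), dtype=float)
    for i, j in net.edges:
        a[i, j] = 1.0
        a[j, i] = 1.0
    k = a.sum(axis=1)
    lap = np.diag(k) - a
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(k[:, None] > 0, a / np.where(k[:, None] > 0, k[:, None], 1.0), 0.0)
    return MatrixViews(adjacency=a, degree_vector=k, laplacian=lap, transition=p)


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

_NODES_HEADER = "#nodes:"


class EdgeListParseError(ValueError):
    pass


def read_edge_list(path: str | Path) -> Network:
    """Read a whitespace-delimited edge list.

    Lines starting with ``#`` are comments, except a ``#nodes:`` header which
    declares the node roster (used to preserve isolated nodes across a
    write/read round trip).  Each data line needs at least two tokens; extra
    tokens (e.g. weights) are ignored.  Directed/reciprocal duplicates are
    symmetrized and collapsed; self-loops dropped with a warning.
    """
    path = Path(path)
    roster: list[str] = []
    pairs: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith(_NODES_HEADER):
                    roster.extend(line[len(_NODES_HEADER):].split())
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            pairs.append((tokens[0], tokens[1]))
    return Network.from_pairs(pairs, extra_nodes=roster)


def write_edge_list(net: Network, path: str | Path) -> Path:
    """Write ``net`` so that ``read_edge_list`` round-trips it exactly.

    A ``#nodes:`` header preserves the label order and any isolated nodes;
    each edge is one ``label_i label_j`` line with i < j in index order.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_NODES_HEADER + " " + " ".join(net.node_ids) + "\n")
        for i, j in sorted(net.edges):
            fh.write(f"{net.node_ids[i]} {net.node_ids[j]}\n")
    return path


def read_adjacency_matrix(path: str | Path) -> Network:
    """Read a square 0/1 adjacency matrix from whitespace-delimited text."""
    a = np.loadtxt(path)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise EdgeListParseError(f"{path}: not a square matrix (shape {a.shape})")
    if not np.allclose(a, a.T):
        logger.warning("adjacency matrix not symmetric; symmetrizing")
        a = np.maximum(a, a.T)
    n = a.shape[0]
    edges = {(i, j) for i in range(n) for j in range(i + 1, n) if a[i, j] != 0}
    return Network([str(i) for i in range(n)], edges)


# ---------------------------------------------------------------------------
# Synthetic networks
# ---------------------------------------------------------------------------

_MODELS = ("erdos_renyi", "barabasi_albert", "watts_strogatz", "stochastic_block")


@dataclass
class SyntheticSpec:
    """Recipe for a reproducible synthetic network.

    model_params by model:
      erdos_renyi:       p (edge probability)
      barabasi_albert:   m (edges per new node)
      watts_strogatz:    k (ring neighbors, even), p (rewiring probability)
      stochastic_block:  sizes (list of block sizes), p_in, p_out
                         (or an explicit ``p_matrix``)
    """

    model: str
    n_nodes: int
    model_params: dict
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        for key in ("p", "p_in", "p_out"):
            if key in self.model_params:
                v = self.model_params[key]
                if not (0.0 <= v <= 1.0):
                    raise ValueError(f"{key}={v} outside [0, 1]")


def generate_synthetic(spec: SyntheticSpec) -> Network:
    """Generate a network from a :class:`SyntheticSpec`; seeded and reproducible."""
    n, params, seed = spec.n_nodes, spec.model_params, spec.seed
    blocks: list[int] | None = None
    if spec.model == "erdos_renyi":
        g = nx.gnp_random_graph(n, params["p"], seed=seed)
    elif spec.model == "barabasi_albert":
        g = nx.barabasi_albert_graph(n, params["m"], seed=seed)
    elif spec.model == "watts_strogatz":
        g = nx.watts_strogatz_graph(n, params["k"], params["p"], seed=seed)
    else:  # stochastic_block
        sizes = list(params["sizes"])
        if sum(sizes) != n:
            raise ValueError(f"block sizes {sizes} do not sum to n_nodes={n}")
        if "p_matrix" in params:
            pm = [list(row) for row in params["p_matrix"]]
        else:
            p_in, p_out = params["p_in"], params["p_out"]
            b = len(sizes)
            pm = [[p_in if r == c else p_out for c in range(b)] for r in range(b)]
        g = nx.stochastic_block_model(sizes, pm, seed=seed)
        blocks = []
        for bi, size in enumerate(sizes):
            blocks.extend([bi] * size)
    edges = {_canon(i, j) for i, j in g.edges() if i != j}
    net = Network([str(i) for i in range(n)], edges, blocks=blocks)
    return net
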
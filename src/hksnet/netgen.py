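"""Layer and multiplex topology construction.

A two-layer multiplex is described by the intra-layer Laplacian
``L^B = blockdiag(B1, B2)`` and the inter-layer Laplacian

    L^A = [[D1, -A], [-A^T, D2]],

where ``A`` is the (layer1 x layer2) inter-adjacency and ``D1``, ``D2`` its
row/column degree matrices.  The coupled shift-map dynamics are governed by
the supra-Laplacian ``L = eps * L^B + gamma * alpha * L^A`` with
``alpha = l12 / N1`` the inter-connection density.

All graphs are undirected and unweighted within a layer.  Node indices are
0-based in memory; edge-list files on disk are 1-based (stated in their
header comment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "LayerGraph",
    "MultiplexGraph",
    "SupraLaplacian",
    "circulant_layer",
    "small_world_layer",
    "complete_layer",
    "erdos_renyi_layer",
    "mirror_multiplex",
    "build_multiplex",
    "supra_laplacian",
    "read_edgelist",
    "write_edgelist",
    "read_multiplex",
    "write_multiplex",
]


@dataclass
class LayerGraph:
    """One layer: adjacency, Laplacian ``B = D - A`` and its spectrum.

    ``omega`` holds the Laplacian eigenvalues in ascending order; the trace
    identity ``sum(omega) == sum(degrees) == degree_sum`` (S) links spectrum
    and topology and is relied on throughout the scaling analysis.
    """

    n_nodes: int
    adjacency: np.ndarray
    degrees: np.ndarray
    laplacian: np.ndarray
    omega: np.ndarray
    degree_sum: int
    mean_degree: float
    label: str = ""

    @classmethod
    def from_adjacency(cls, adjacency: np.ndarray, label: str = "") -> "LayerGraph":
        adj = np.asarray(adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric (undirected graph)")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency must have a zero diagonal (no self-loops)")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1 (unweighted graph)")
        adj = adj.astype(np.int64)
        n = adj.shape[0]
        degrees = adj.sum(axis=1)
        lap = np.diag(degrees).astype(float) - adj
        omega = np.linalg.eigvalsh(lap)
        omega[np.abs(omega) < 1e-12] = np.abs(omega[np.abs(omega) < 1e-12])
        s = int(degrees.sum())
        return cls(
            n_nodes=n,
            adjacency=adj,
            degrees=degrees,
            laplacian=lap,
            omega=omega,
            degree_sum=s,
            mean_degree=s / n,
            label=label,
        )

    @property
    def omega_max(self) -> float:
        """Largest Laplacian eigenvalue omega_{N1}."""
        return float(self.omega[-1])

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass
class MultiplexGraph:
    """Two layers plus inter-layer connections.

    ``inter_adjacency`` is an integer (N1 x N2) matrix; mirror multiplexes
    may carry multiplicities > 1 (each node m-fold linked to its mirror),
    which is why the matrix, not an edge list, is the source of truth.
    """

    layer1: LayerGraph
    layer2: LayerGraph
    inter_adjacency: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.inter_adjacency, dtype=np.int64)
        if a.shape != (self.layer1.n_nodes, self.layer2.n_nodes):
            raise ValueError("inter_adjacency shape must be (N1, N2)")
        if np.any(a < 0):
            raise ValueError("inter_adjacency entries must be non-negative")
        self.inter_adjacency = a
        if self.l12 > self.layer1.n_nodes ** 2:
            raise ValueError("l12 exceeds the N1^2 upper bound on inter-connections")

    @property
    def n_nodes(self) -> int:
        return self.layer1.n_nodes + self.layer2.n_nodes

    @property
    def l12(self) -> int:
        """Number of undirected inter-connections."""
        return int(self.inter_adjacency.sum())

    @property
    def alpha(self) -> float:
        """Inter-connection density alpha = l12 / N1."""
        return self.l12 / self.layer1.n_nodes

    @property
    def inter_edges(self) -> list[tuple[int, int]]:
        """Inter-edge pairs (i, j), repeated according to multiplicity."""
        pairs: list[tuple[int, int]] = []
        for i, j in zip(*np.nonzero(self.inter_adjacency)):
            pairs.extend([(int(i), int(j))] * int(self.inter_adjacency[i, j]))
        return pairs

    @property
    def laplacian_B(self) -> np.ndarray:
        """Block-diagonal intra Laplacian blockdiag(B1, B2)."""
        n1, n2 = self.layer1.n_nodes, self.layer2.n_nodes
        lb = np.zeros((n1 + n2, n1 + n2))
        lb[:n1, :n1] = self.layer1.laplacian
        lb[n1:, n1:] = self.layer2.laplacian
        return lb

    @property
    def laplacian_A(self) -> np.ndarray:
        """Inter Laplacian [[D1, -A], [-A^T, D2]] with D1 = diag(A 1),
        D2 = diag(A^T 1), built from the binary inter-connection pattern.

        Edge multiplicity (mirror multiplexes with l12 = m*N1) enters the
        supra-Laplacian globally through the alpha = l12/N1 prefactor, not
        through A; this is what makes the eigenvalue pairing
        mu = {eps*omega_i, eps*omega_i + 2*gamma*alpha} exact.
        """
        a = (self.inter_adjacency > 0).astype(float)
        n1, n2 = a.shape
        la = np.zeros((n1 + n2, n1 + n2))
        la[:n1, :n1] = np.diag(a.sum(axis=1))
        la[n1:, n1:] = np.diag(a.sum(axis=0))
        la[:n1, n1:] = -a
        la[n1:, :n1] = -a.T
        return la

    def with_inter_edge(self, i: int, j: int) -> "MultiplexGraph":
        """New multiplex with inter-edge (i, j) added (layers shared)."""
        a = self.inter_adjacency.copy()
        a[i, j] += 1
        return MultiplexGraph(self.layer1, self.layer2, a, label=self.label)


@dataclass
class SupraLaplacian:
    """L = eps * L^B + gamma * alpha * L^A with its ascending spectrum mu."""

    matrix: np.ndarray
    epsilon: float
    gamma: float
    mu: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mu is None:
            self.mu = np.linalg.eigvalsh(self.matrix)

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def _layer_from_nx(g: nx.Graph, label: str) -> LayerGraph:
    adj = nx.to_numpy_array(g, nodelist=sorted(g.nodes()), dtype=np.int64)
    return LayerGraph.from_adjacency(adj, label=label)


def circulant_layer(n: int, k: int) -> LayerGraph:
    """Circulant (ring-lattice) graph: every node linked to k/2 neighbours
    per side, total intra-degree k, so S = k*n."""
    if n < 3:
        raise ValueError("circulant layer needs n >= 3")
    if k <= 0 or k >= n:
        raise ValueError(f"need 0 < k < n, got k={k}, n={n}")
    if k % 2 != 0:
        raise ValueError(f"k must be even (k/2 neighbours per side), got k={k}")
    g = nx.circulant_graph(n, list(range(1, k // 2 + 1)))
    return _layer_from_nx(g, label=f"circulant(n={n},k={k})")


def small_world_layer(n: int, k: int, p_rewire: float, seed: int, max_attempts: int = 100) -> LayerGraph:
    """Watts-Strogatz small-world layer.

    Rewiring preserves the edge count, so S = k*n for every seed.  If the
    rewired graph is disconnected the construction is retried with the seed
    incremented, up to ``max_attempts`` times.
    """
    if k % 2 != 0 or k >= n:
        raise ValueError(f"need even k < n, got k={k}, n={n}")
    if not 0.0 <= p_rewire <= 1.0:
        raise ValueError(f"rewiring probability must be in [0, 1], got {p_rewire}")
    for attempt in range(max_attempts):
        g = nx.watts_strogatz_graph(n, k, p_rewire, seed=seed + attempt)
        if nx.is_connected(g):
            return _layer_from_nx(g, label=f"small_world(n={n},k={k},p={p_rewire},seed={seed})")
    raise RuntimeError(f"no connected Watts-Strogatz graph in {max_attempts} attempts")


def complete_layer(n: int) -> LayerGraph:
    """All-to-all graph K_n: omega = (0, n, ..., n), S = n(n-1)."""
    if n < 2:
        raise ValueError("complete layer needs n >= 2")
    return _layer_from_nx(nx.complete_graph(n), label=f"complete(n={n})")


def erdos_renyi_layer(n: int, p: float, seed: int, max_attempts: int = 100) -> LayerGraph:
    """Erdos-Renyi G(n, p) layer, regenerated until connected."""
    if not 0.0 < p <= 1.0:
        raise ValueError(f"edge probability must be in (0, 1], got {p}")
    for attempt in range(max_attempts):
        g = nx.gnp_random_graph(n, p, seed=seed + attempt)
        if nx.is_connected(g):
            return _layer_from_nx(g, label=f"erdos_renyi(n={n},p={p},seed={seed})")
    raise RuntimeError(f"no connected G(n,p) graph in {max_attempts} attempts")


def mirror_multiplex(layer: LayerGraph, l12: int) -> MultiplexGraph:
    """Two identical copies of ``layer``, each node linked l12/N1 times to
    its mirror node; requires l12 to be a multiple of N1 so the eigenvalue
    pairing mu = {eps*omega_i, eps*omega_i + 2*gamma*alpha} holds exactly."""
    n1 = layer.n_nodes
    if l12 % n1 != 0:
        raise ValueError(
            f"mirror multiplex needs l12 to be a multiple of N1={n1}, got l12={l12}; "
            "use build_multiplex for arbitrary inter-edge sets"
        )
    m = l12 // n1
    a = m * np.eye(n1, dtype=np.int64)
    return MultiplexGraph(layer, layer, a, label=f"mirror({layer.label},l12={l12})")


def build_multiplex(
    layer1: LayerGraph, layer2: LayerGraph, inter_edges: list[tuple[int, int]]
) -> MultiplexGraph:
    """General two-layer multiplex from an explicit list of inter-edges
    (i in layer1, j in layer2); duplicates and out-of-range indices rejected."""
    n1, n2 = layer1.n_nodes, layer2.n_nodes
    seen = set()
    a = np.zeros((n1, n2), dtype=np.int64)
    for i, j in inter_edges:
        if not (0 <= i < n1 and 0 <= j < n2):
            raise ValueError(f"inter-edge ({i}, {j}) out of range for layers of size {n1}, {n2}")
        if (i, j) in seen:
            raise ValueError(f"duplicate inter-edge ({i}, {j})")
        seen.add((i, j))
        a[i, j] = 1
    return MultiplexGraph(layer1, layer2, a)


def supra_laplacian(g: MultiplexGraph, epsilon: float, gamma: float) -> SupraLaplacian:
    """Assemble L = eps * L^B + gamma * alpha * L^A and its spectrum."""
    if epsilon < 0 or gamma < 0:
        raise ValueError("coupling strengths must be non-negative")
    mat = epsilon * g.laplacian_B + gamma * g.alpha * g.laplacian_A
    return SupraLaplacian(matrix=mat, epsilon=epsilon, gamma=gamma)


# ---------------------------------------------------------------------------
# File I/O: TSV edge lists (1-based on disk) and a JSON multiplex descriptor.

def write_edgelist(path, edges: list[tuple[int, int]], comment: str = "") -> None:
    lines = ["# 1-based node indices, one undirected edge per line (u<TAB>v)"]
    if comment:
        lines.append(f"# {comment}")
    lines += [f"{u + 1}\t{v + 1}" for u, v in edges]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path) -> list[tuple[int, int]]:
    edges = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        u, v = line.split("\t")
        edges.append((int(u) - 1, int(v) - 1))
    return edges


def layer_edges(layer: LayerGraph) -> list[tuple[int, int]]:
    iu, ju = np.nonzero(np.triu(layer.adjacency))
    return [(int(i), int(j)) for i, j in zip(iu, ju)]


def write_layer(path, layer: LayerGraph) -> None:
    write_edgelist(path, layer_edges(layer), comment=layer.label)


def read_layer(path, n_nodes: int | None = None) -> LayerGraph:
    edges = read_edgelist(path)
    n = n_nodes if n_nodes is not None else (max(max(e) for e in edges) + 1)
    adj = np.zeros((n, n), dtype=np.int64)
    for u, v in edges:
        adj[u, v] = adj[v, u] = 1
    return LayerGraph.from_adjacency(adj, label=str(path))


def write_multiplex(descriptor_path, g: MultiplexGraph, epsilon: float, gamma: float) -> None:
    """Write layer/inter edge-list files next to a JSON descriptor bundling
    them with l12, epsilon and gamma."""
    base = Path(descriptor_path)
    stem = base.with_suffix("")
    paths = {
        "layer1": f"{stem}.layer1.tsv",
        "layer2": f"{stem}.layer2.tsv",
        "inter": f"{stem}.inter.tsv",
    }
    write_layer(paths["layer1"], g.layer1)
    write_layer(paths["layer2"], g.layer2)
    write_edgelist(paths["inter"], g.inter_edges, comment="inter-edges: u in layer1, v in layer2")
    desc = {
        "layer1": paths["layer1"],
        "layer2": paths["layer2"],
        "inter": paths["inter"],
        "n1": g.layer1.n_nodes,
        "n2": g.layer2.n_nodes,
        "l12": g.l12,
        "epsilon": epsilon,
        "gamma": gamma,
    }
    base.write_text(json.dumps(desc, indent=2) + "\n")


def read_multiplex(descriptor_path) -> tuple[MultiplexGraph, float, float]:
    desc = json.loads(Path(descriptor_path).read_text())
    l1 = read_layer(desc["layer1"], n_nodes=desc["n1"])
    l2 = read_layer(desc["layer2"], n_nodes=desc["n2"])
    inter = read_edgelist(desc["inter"])
    a = np.zeros((l1.n_nodes, l2.n_nodes), dtype=np.int64)
    for i, j in inter:
        a[i, j] += 1
    g = MultiplexGraph(l1, l2, a)
    return g, float(desc["epsilon"]), float(desc["gamma"])
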
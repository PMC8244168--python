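"""Areal contiguity graphs and the BYM2 spatial model.

This module holds the graph algebra behind the spatial random effect:
the intrinsic conditional autoregressive (ICAR) structure matrix of a
contiguity graph, the scaling factor that standardises the ICAR so its
generalised marginal variances have geometric mean one, and the BYM2
combination of a scaled-ICAR (spatially structured) component ``u`` and
an iid (overdispersion) component ``v``,

    b_i = sigma_b * ( sqrt(phi) * u_i + sqrt(1 - phi) * v_i ),

so that ``sigma_b`` is the marginal standard deviation of the field and
``phi`` in [0, 1] is the fraction of its variance carried by the
spatially structured part.

Graphs are undirected, without self-loops; disconnected graphs are
supported with per-component conventions (see :func:`scaling_factor`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SpatialGraph",
    "make_lattice_graph",
    "icar_precision",
    "scaling_factor",
    "scaled_icar_precision",
    "sample_scaled_icar",
    "bym2_field",
]

#: relative eigenvalue tolerance below which an eigenvalue counts as zero
ZERO_EIG_RTOL = 1e-8


@dataclass(frozen=True)
class SpatialGraph:
    """Areal contiguity structure.

    Parameters
    ----------
    node_ids
        Ordered area identifiers; the ordering fixes the row/column
        order of every matrix built from the graph.
    edges
        Unordered neighbour pairs, stored as sorted tuples of node ids.
    """

    node_ids: tuple
    edges: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        ids = tuple(self.node_ids)
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        known = set(ids)
        canon = set()
        for e in self.edges:
            a, b = e
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if a not in known or b not in known:
                raise ValueError(f"edge {e!r} references unknown node")
            canon.add((a, b) if str(a) <= str(b) else (b, a))
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def n(self) -> int:
        return len(self.node_ids)

    @property
    def index(self) -> dict:
        return {v: i for i, v in enumerate(self.node_ids)}

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.edges)
        return g

    def components(self) -> list[np.ndarray]:
        """Connected components as arrays of node *indices*, each sorted,
        ordered by their smallest member."""
        idx = self.index
        comps = [
            np.array(sorted(idx[v] for v in comp))
            for comp in nx.connected_components(self.to_networkx())
        ]
        return sorted(comps, key=lambda c: c[0])

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n, dtype=int)
        idx = self.index
        for a, b in self.edges:
            deg[idx[a]] += 1
            deg[idx[b]] += 1
        return deg


def make_lattice_graph(n_rows: int, n_cols: int) -> SpatialGraph:
    """Rook-adjacency rectangular lattice with ``n_rows * n_cols`` areas.

    Stands in for a real municipality contiguity map: reproducible and
    parameterisable in size, always connected. Node ids are strings
    ``"r{i}c{j}"`` ordered row-major.
    """
    if n_rows < 1 or n_cols < 1:
        raise ValueError("lattice dimensions must be >= 1")
    nodes = [f"r{i}c{j}" for i in range(n_rows) for j in range(n_cols)]
    edges = set()
    for i in range(n_rows):
        for j in range(n_cols):
            if i + 1 < n_rows:
                edges.add((f"r{i}c{j}", f"r{i + 1}c{j}"))
            if j + 1 < n_cols:
                edges.add((f"r{i}c{j}", f"r{i}c{j + 1}"))
    return SpatialGraph(tuple(nodes), frozenset(edges))


def icar_precision(graph: SpatialGraph) -> np.ndarray:
    """ICAR structure matrix: Q_ii = degree(i), Q_ij = -1 for neighbours.

    Symmetric positive semidefinite with zero row sums; its null space is
    spanned by the indicator vectors of the connected components, so
    rank(Q) = n - (number of components).
    """
    if graph.n == 0:
        raise ValueError("empty graph")
    q = np.diag(graph.degrees().astype(float))
    idx = graph.index
    for a, b in graph.edges:
        i, j = idx[a], idx[b]
        q[i, j] = q[j, i] = -1.0
    return q


def _component_pinv_diag(q_comp: np.ndarray) -> np.ndarray:
    """Diagonal of the sum-to-zero constrained generalised inverse of a
    connected component's ICAR structure matrix (eigen pseudo-inverse)."""
    w, v = np.linalg.eigh(q_comp)
    tol = ZERO_EIG_RTOL * w.max()
    nz = w > tol
    inv = np.zeros_like(w)
    inv[nz] = 1.0 / w[nz]
    return np.einsum("ij,j,ij->i", v, inv, v)


def scaling_factor(graph: SpatialGraph) -> dict:
    """Per-component ICAR scaling factors.

    For each connected component with >= 2 nodes, returns the geometric
    mean ``s`` of the diagonal of the constrained generalised inverse of
    the component's structure matrix; ``s * Q`` then has generalised
    marginal variances with geometric mean exactly 1. Singleton
    components (islands) get ``None``: scaling is undefined there and the
    structured component is fixed at zero (the iid part carries all
    variation).

    Returns
    -------
    dict mapping the component's smallest node index to its factor.
    """
    q = icar_precision(graph)
    out = {}
    for comp in graph.components():
        if len(comp) < 2:
            out[int(comp[0])] = None
            continue
        diag = _component_pinv_diag(q[np.ix_(comp, comp)])
        out[int(comp[0])] = float(np.exp(np.mean(np.log(diag))))
    return out


def scaled_icar_precision(graph: SpatialGraph) -> np.ndarray:
    """Structure matrix with each component block multiplied by its
    scaling factor; island rows/columns are left zero (their structured
    effect is pinned to zero by convention)."""
    q = icar_precision(graph)
    for comp, s in zip(graph.components(), scaling_factor(graph).values()):
        if s is not None:
            q[np.ix_(comp, comp)] *= s
    return q


def sample_scaled_icar(
    graph: SpatialGraph, rng: np.random.Generator, size: int | None = None
) -> np.ndarray:
    """Draw ``u`` from the scaled ICAR with exact per-component
    sum-to-zero: eigen-decompose each component's scaled structure matrix
    and sample along the non-null eigendirections with variance 1/eig.
    Islands get u = 0. Returns shape (n,) or (size, n)."""
    squeeze = size is None
    m = 1 if squeeze else size
    u = np.zeros((m, graph.n))
    q = icar_precision(graph)
    for comp, s in zip(graph.components(), scaling_factor(graph).values()):
        if s is None:
            continue
        w, v = np.linalg.eigh(s * q[np.ix_(comp, comp)])
        nz = w > ZERO_EIG_RTOL * w.max()
        z = rng.standard_normal((m, nz.sum())) / np.sqrt(w[nz])
        u[:, comp] = z @ v[:, nz].T
    return u[0] if squeeze else u


def bym2_field(
    u: np.ndarray, v: np.ndarray, sigma_b: float, phi: float
) -> np.ndarray:
    """Combine standardised components into the BYM2 field
    ``b = sigma_b * (sqrt(phi) u + sqrt(1-phi) v)``.

    ``u`` must be a scaled-ICAR draw (unit generalised variance, zero sum
    per component) and ``v`` iid standard normal, so the marginal
    variance of ``b`` is ``sigma_b**2`` regardless of ``phi``.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    if u.shape != v.shape:
        raise ValueError("u and v must have matching shapes")
    if not 0.0 <= phi <= 1.0:
        raise ValueError("phi must lie in [0, 1]")
    if sigma_b < 0:
        raise ValueError("sigma_b must be >= 0")
    return sigma_b * (np.sqrt(phi) * u + np.sqrt(1.0 - phi) * v)
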
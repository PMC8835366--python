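"""Areal adjacency graphs and the intrinsic CAR (ICAR) structure.

The spatial layer of the model is a set of administrative areas (e.g. the
36 Nigerian states plus the FCT) with a symmetric neighbourhood relation.
The ICAR prior on an area-level field ``x`` has improper density

    p(x | tau) ∝ tau^((n-k)/2) * exp(-tau/2 * x' Q x),      Q = D - W,

where ``W`` is the 0/1 adjacency matrix, ``D`` the diagonal of neighbour
counts, and ``k`` the number of connected components (Q's rank deficiency).
The density is invariant to per-component level shifts, hence fields are
identified by a sum-to-zero constraint within each component.

Adjacency files use a GAL-style plain-text neighbour list: a header line
with the number of areas, then one line per area with ``id n_neighbours
id1 id2 ...`` (ids 1-based in files, 0-based in memory).  Lines starting
with ``#`` are comments.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "StateGraph",
    "IcarStructure",
    "read_adjacency",
    "write_adjacency",
    "lattice_graph",
    "icar_precision",
    "sample_icar",
]


class AdjacencyParseError(ValueError):
    """Raised when a neighbour-list file cannot be parsed."""


@dataclass(frozen=True)
class StateGraph:
    """Symmetric areal adjacency with connected-component labels.

    Attributes
    ----------
    n_areas
        Number of areas, indexed ``0 .. n_areas-1``.
    neighbors
        Tuple of tuples; ``neighbors[i]`` lists the areas adjacent to ``i``
        in ascending order.  Symmetric, no self-neighbours.
    component_labels
        ``component_labels[i]`` is the id of the connected component of
        area ``i`` (0-based, ordered by smallest member).
    """

    n_areas: int
    neighbors: tuple[tuple[int, ...], ...]
    component_labels: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_areas <= 0:
            raise ValueError("n_areas must be positive")
        if len(self.neighbors) != self.n_areas:
            raise ValueError("neighbors must have one entry per area")
        for i, nbrs in enumerate(self.neighbors):
            for j in nbrs:
                if not 0 <= j < self.n_areas:
                    raise ValueError(f"neighbour id {j} of area {i} out of range")
                if j == i:
                    raise ValueError(f"area {i} lists itself as a neighbour")
                if i not in self.neighbors[j]:
                    raise ValueError(f"adjacency not symmetric: {i}->{j}")
        if not self.component_labels:
            object.__setattr__(
                self, "component_labels", tuple(self._compute_components())
            )
        elif len(self.component_labels) != self.n_areas:
            raise ValueError("component_labels must have one entry per area")

    def _compute_components(self) -> list[int]:
        g = self.to_networkx()
        labels = [-1] * self.n_areas
        comps = sorted(nx.connected_components(g), key=min)
        for cid, comp in enumerate(comps):
            for i in comp:
                labels[i] = cid
        return labels

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_areas))
        for i, nbrs in enumerate(self.neighbors):
            g.add_edges_from((i, j) for j in nbrs if j > i)
        return g

    @property
    def n_components(self) -> int:
        return max(self.component_labels) + 1

    @property
    def degrees(self) -> np.ndarray:
        return np.array([len(n) for n in self.neighbors], dtype=int)

    @classmethod
    def from_edges(cls, n_areas: int, edges) -> "StateGraph":
        nbrs: list[set[int]] = [set() for _ in range(n_areas)]
        for i, j in edges:
            if i == j:
                raise ValueError("self-edges are not allowed")
            nbrs[i].add(j)
            nbrs[j].add(i)
        return cls(n_areas, tuple(tuple(sorted(s)) for s in nbrs))


@dataclass(frozen=True)
class IcarStructure:
    """Precision structure matrix Q = D - W of an ICAR field.

    ``rank_deficiency`` equals the number of connected components of the
    underlying graph; Q is symmetric positive semidefinite with zero row
    sums and rank ``n_areas - rank_deficiency``.
    """

    precision_pattern: np.ndarray
    rank_deficiency: int
    component_labels: tuple[int, ...]

    @property
    def n_areas(self) -> int:
        return self.precision_pattern.shape[0]


def read_adjacency(path, dialect: str = "neighbor_list") -> StateGraph:
    """Read a GAL-style neighbour-list adjacency file.

    Asymmetric entries (i lists j but not vice versa) are symmetrized with
    a warning.  Malformed lines and out-of-range ids raise errors naming
    the offending line.
    """
    if dialect != "neighbor_list":
        raise ValueError(f"unknown adjacency dialect: {dialect!r}")
    lines = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            text = raw.strip()
            if not text or text.startswith("#"):
                continue
            lines.append((lineno, text))
    if not lines:
        raise AdjacencyParseError(f"{path}: empty adjacency file")
    header_lineno, header = lines[0]
    try:
        n_areas = int(header.split()[0])
    except ValueError as exc:
        raise AdjacencyParseError(
            f"{path}:{header_lineno}: header must give the number of areas"
        ) from exc
    if n_areas <= 0:
        raise AdjacencyParseError(f"{path}:{header_lineno}: n_areas must be positive")

    nbrs: list[set[int]] = [set() for _ in range(n_areas)]
    seen: set[int] = set()
    for lineno, text in lines[1:]:
        parts = text.split()
        if len(parts) < 2:
            raise AdjacencyParseError(
                f"{path}:{lineno}: expected 'id n_neighbours id...'"
            )
        try:
            area = int(parts[0]) - 1
            count = int(parts[1])
            ids = [int(p) - 1 for p in parts[2:]]
        except ValueError as exc:
            raise AdjacencyParseError(f"{path}:{lineno}: non-integer token") from exc
        if not 0 <= area < n_areas:
            raise AdjacencyParseError(
                f"{path}:{lineno}: area id {area + 1} out of range 1..{n_areas}"
            )
        if len(ids) != count:
            raise AdjacencyParseError(
                f"{path}:{lineno}: declared {count} neighbours, found {len(ids)}"
            )
        for j in ids:
            if not 0 <= j < n_areas:
                raise AdjacencyParseError(
                    f"{path}:{lineno}: neighbour id {j + 1} out of range 1..{n_areas}"
                )
            if j == area:
                raise AdjacencyParseError(
                    f"{path}:{lineno}: area {area + 1} lists itself as neighbour"
                )
        seen.add(area)
        nbrs[area].update(ids)

    # symmetrize, warning on repairs
    repaired = False
    for i in range(n_areas):
        for j in list(nbrs[i]):
            if i not in nbrs[j]:
                nbrs[j].add(i)
                repaired = True
    if repaired:
        warnings.warn(
            f"{path}: asymmetric adjacency entries were symmetrized", stacklevel=2
        )
    return StateGraph(n_areas, tuple(tuple(sorted(s)) for s in nbrs))


def write_adjacency(graph: StateGraph, path) -> None:
    """Write a StateGraph as a GAL-style neighbour-list file (1-based ids)."""
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(f"{graph.n_areas}\n")
        for i, nbrs in enumerate(graph.neighbors):
            ids = " ".join(str(j + 1) for j in nbrs)
            fh.write(f"{i + 1} {len(nbrs)}{' ' if ids else ''}{ids}\n")


def lattice_graph(rows: int, cols: int, extra: int = 0) -> StateGraph:
    """Rook-adjacency lattice plus ``extra`` pendant areas.

    A connected synthetic stand-in for an administrative map; ``(6, 6, 1)``
    yields 37 areas, the size of Nigeria's state layer (36 states + FCT).
    Each pendant area is attached to one boundary cell of the lattice,
    cycling along the boundary.
    """
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be positive")
    if extra < 0:
        raise ValueError("extra must be non-negative")
    n = rows * cols
    edges = []
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            if c + 1 < cols:
                edges.append((i, i + 1))
            if r + 1 < rows:
                edges.append((i, i + cols))
    boundary = [
        r * cols + c
        for r in range(rows)
        for c in range(cols)
        if r in (0, rows - 1) or c in (0, cols - 1)
    ]
    for e in range(extra):
        edges.append((n + e, boundary[e % len(boundary)]))
    return StateGraph.from_edges(n + extra, edges)


def icar_precision(graph: StateGraph) -> IcarStructure:
    """Build the ICAR structure matrix Q = D - W from an adjacency graph."""
    n = graph.n_areas
    q = np.zeros((n, n))
    for i, nbrs in enumerate(graph.neighbors):
        q[i, i] = len(nbrs)
        for j in nbrs:
            q[i, j] = -1.0
    return IcarStructure(
        precision_pattern=q,
        rank_deficiency=graph.n_components,
        component_labels=graph.component_labels,
    )


def sample_icar(
    structure: IcarStructure,
    precision_scalar: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw one ICAR field restricted to the span of Q's non-null eigenvectors.

    The improper ICAR density is proper on the orthogonal complement of the
    per-component constant vectors; sampling uses the eigendecomposition of
    Q with independent N(0, 1/(tau * lambda_k)) coefficients on each
    positive-eigenvalue direction.  The draw sums to zero within every
    connected component; isolated areas (their own component) are fixed at 0.
    """
    if not np.isfinite(precision_scalar) or precision_scalar <= 0:
        raise ValueError("precision_scalar must be positive and finite")
    rng = np.random.default_rng(seed) if isinstance(seed, (int, np.integer)) else seed
    q = structure.precision_pattern
    n = q.shape[0]
    eigval, eigvec = np.linalg.eigh(q)
    # null space has dimension = number of components; tolerance relative to n
    tol = eigval.max() * n * np.finfo(float).eps if eigval.max() > 0 else 1e-12
    positive = eigval > tol
    if positive.sum() != n - structure.rank_deficiency:
        raise RuntimeError("eigenvalue null-space dimension mismatch")
    coef = rng.standard_normal(positive.sum()) / np.sqrt(
        precision_scalar * eigval[positive]
    )
    return eigvec[:, positive] @ coef


def icar_pseudo_covariance(structure: IcarStructure, precision_scalar: float = 1.0):
    """Moore–Penrose pseudoinverse of tau*Q — the ICAR covariance on the
    constrained subspace.  Used as an independent distributional oracle."""
    return np.linalg.pinv(structure.precision_pattern) / precision_scalar
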
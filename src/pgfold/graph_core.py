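"""Undirected weighted graphs, their Laplacians and spectral decompositions.

Every descriptor in this package is a function of the spectrum of the graph
Laplacian ``L = D - A`` (degree matrix minus adjacency matrix).  The graph is
required to be simple (zero diagonal), undirected (symmetric weights) and,
for all thermostatistical descriptors, connected: the zero Laplacian
eigenvalue is then simple, and the remaining eigenvalues are the squared
vibrational frequencies of the harmonic linear chain equivalent to the graph.

Vertices are documented 1-based (vertex ``i = 1..n``) to match the structural
biology convention of residue numbering; arrays are 0-based internally and the
mapping is fixed at construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.linalg
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "GraphError",
    "DisconnectedGraphError",
    "Graph",
    "SpectralDecomposition",
    "laplacian",
    "spectral_decomposition",
    "laplacian_pseudoinverse",
    "is_connected",
]

#: Relative tolerance below which a Laplacian eigenvalue is treated as zero.
#: Scale-free (relative to the largest eigenvalue), robust up to a few
#: thousand vertices with a dense symmetric eigensolver.
ZERO_EIGENVALUE_RTOL = 1e-9


class GraphError(ValueError):
    """Raised for structurally invalid graphs (asymmetry, negative weights...)."""


class DisconnectedGraphError(GraphError):
    """Raised when a descriptor requiring a connected graph meets one that is not.

    All force constants involve sums of ``1/lambda_l`` over nonzero Laplacian
    eigenvalues; a disconnected graph has ``lambda_2 = 0`` and the descriptors
    are undefined.
    """


@dataclass(frozen=True)
class Graph:
    """Simple undirected weighted graph on ``n`` ordered vertices.

    Parameters
    ----------
    weights
        Symmetric ``(n, n)`` matrix of nonnegative edge weights with zero
        diagonal.  For protein graphs all nonzero weights are 1.
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise GraphError(f"weight matrix must be square, got shape {w.shape}")
        if w.shape[0] < 2:
            raise GraphError("a graph needs at least 2 vertices")
        if not np.all(np.isfinite(w)):
            raise GraphError("weights must be finite")
        if np.any(w < 0):
            raise GraphError("negative edge weights are not allowed")
        if np.any(np.diagonal(w) != 0):
            raise GraphError("diagonal must be zero (simple graph, no loops)")
        if not np.array_equal(w, w.T):
            raise GraphError("weight matrix must be symmetric (undirected graph)")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]

    @property
    def adjacency(self) -> np.ndarray:
        return self.weights

    @property
    def degrees(self) -> np.ndarray:
        """Vertex degrees ``d_i = sum_j w_ij`` (weighted degree)."""
        return self.weights.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights)))

    @classmethod
    def from_edges(
        cls, n: int, edges: Iterable[tuple[int, int] | tuple[int, int, float]]
    ) -> "Graph":
        """Build a graph from 1-based edge pairs, optionally with weights."""
        w = np.zeros((n, n))
        for edge in edges:
            i, j = int(edge[0]), int(edge[1])
            weight = float(edge[2]) if len(edge) > 2 else 1.0
            if not (1 <= i <= n and 1 <= j <= n):
                raise GraphError(f"edge ({i},{j}) out of range 1..{n}")
            if i == j:
                raise GraphError(f"self-loop on vertex {i} not allowed")
            w[i - 1, j - 1] = w[j - 1, i - 1] = weight
        return cls(w)

    def edges(self) -> list[tuple[int, int, float]]:
        """Edge list as 1-based ``(i, j, weight)`` with ``i < j``."""
        ii, jj = np.nonzero(np.triu(self.weights))
        return [(int(i) + 1, int(j) + 1, float(self.weights[i, j])) for i, j in zip(ii, jj)]

    # -- serialization ------------------------------------------------------

    def to_edgelist(self, path: str | Path) -> None:
        """Write a plain-text edge list: ``i j weight`` per line, 1-based."""
        lines = [f"{self.n}"]
        lines += [f"{i} {j} {w!r}" for i, j, w in self.edges()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_edgelist(cls, path: str | Path) -> "Graph":
        raw = Path(path).read_text().split("\n")
        n = int(raw[0])
        edges = []
        for line in raw[1:]:
            if not line.strip():
                continue
            i, j, w = line.split()
            edges.append((int(i), int(j), float(w)))
        return cls.from_edges(n, edges)

    def to_json(self) -> str:
        return json.dumps({"n": self.n, "edges": [[i, j, w] for i, j, w in self.edges()]})

    @classmethod
    def from_json(cls, text: str) -> "Graph":
        obj = json.loads(text)
        return cls.from_edges(obj["n"], [tuple(e) for e in obj["edges"]])


@dataclass(frozen=True)
class SpectralDecomposition:
    """Sorted Laplacian eigenvalues and orthonormal eigenvectors.

    ``eigenvalues[l]`` is the (dimensionless) eigenvalue ``lambda_{l+1}`` in
    ascending order, ``eigenvectors[:, l]`` the matching orthonormal
    eigenvector; ``eigenvectors[i, l]`` is the component of mode ``l+1`` on
    vertex ``i+1``.  ``lambda_1`` is clamped to exactly 0; for a connected
    graph ``lambda_2 > 0`` (the algebraic connectivity, whose eigenvector is
    the Fiedler vector).
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    zero_tol: float = field(default=0.0, compare=False)

    @property
    def n(self) -> int:
        return self.eigenvalues.shape[0]

    @property
    def algebraic_connectivity(self) -> float:
        return float(self.eigenvalues[1])

    @property
    def fiedler_vector(self) -> np.ndarray:
        return self.eigenvectors[:, 1]

    @property
    def is_connected(self) -> bool:
        return self.eigenvalues[1] > self.zero_tol

    def require_connected(self) -> None:
        if not self.is_connected:
            raise DisconnectedGraphError(
                "graph is disconnected (lambda_2 = "
                f"{self.eigenvalues[1]:.3e} <= tolerance {self.zero_tol:.3e}); "
                "force constants are undefined"
            )


def laplacian(graph: Graph) -> np.ndarray:
    """Graph Laplacian ``L_ij = -A_ij`` off-diagonal, ``L_ii = d_i``.

    Row sums vanish identically — the graph analogue of the translational
    sum rule of a force-constant matrix.
    """
    return np.diag(graph.degrees) - graph.adjacency


def spectral_decomposition(lap: np.ndarray, *, check: bool = True) -> SpectralDecomposition:
    """Diagonalize a graph Laplacian.

    Parameters
    ----------
    lap
        Symmetric matrix with zero row sums (as produced by :func:`laplacian`).
    check
        Validate symmetry and row sums before diagonalizing.

    Returns
    -------
    SpectralDecomposition
        Ascending eigenvalues with near-zero values clamped to exactly 0,
        and orthonormal eigenvectors (columns).
    """
    lap = np.asarray(lap, dtype=float)
    n = lap.shape[0]
    if check:
        if not np.allclose(lap, lap.T, atol=1e-12):
            raise GraphError("Laplacian must be symmetric")
        if np.max(np.abs(lap.sum(axis=1))) > 1e-9 * max(1.0, np.abs(lap).max()):
            raise GraphError("Laplacian row sums must vanish")
    try:
        eigenvalues, eigenvectors = scipy.linalg.eigh(lap)
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover - eigh on sym is robust
        raise ArithmeticError(
            f"eigensolver failure on {n}x{n} Laplacian "
            f"(cond={np.linalg.cond(lap):.3e})"
        ) from exc
    tol = ZERO_EIGENVALUE_RTOL * max(eigenvalues.max(), 1.0)
    eigenvalues = eigenvalues.copy()
    eigenvalues[np.abs(eigenvalues) < tol] = 0.0
    return SpectralDecomposition(eigenvalues=eigenvalues, eigenvectors=eigenvectors, zero_tol=tol)


def laplacian_pseudoinverse(lap: np.ndarray) -> np.ndarray:
    """Moore–Penrose pseudoinverse of a connected graph's Laplacian.

    Computed from the spectral sum ``L+_ij = sum_{l>=2} e_l(i) e_l(j) / lambda_l``,
    which shares the null space (the constant vector) with ``L`` itself.  The
    diagonal of ``L+`` gives the inverse local force constants and its trace
    the Kirchhoff index.
    """
    spec = spectral_decomposition(lap)
    spec.require_connected()
    nonzero = spec.eigenvalues > spec.zero_tol
    vecs = spec.eigenvectors[:, nonzero]
    pinv = (vecs / spec.eigenvalues[nonzero]) @ vecs.T
    return (pinv + pinv.T) / 2.0  # exact symmetry (kills last-ulp asymmetry)


def is_connected(graph: Graph) -> bool:
    """Connectivity by breadth-first traversal of the adjacency structure.

    Agrees with the spectral criterion ``lambda_2 > 0``; protein graphs are
    always connected because the peptide-bond backbone edges form a spanning
    path.
    """
    n_components, _ = connected_components(
        csr_matrix(graph.adjacency), directed=False
    )
    return int(n_components) == 1
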
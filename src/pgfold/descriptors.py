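"""Thermostatistical and topological descriptors of a connected graph.

A connected, simple, undirected graph is mechanically equivalent to a linear
chain of atoms coupled by identical harmonic springs according to the
adjacency matrix.  In thermal equilibrium the mean-square fluctuations of the
chain define three dimensionless effective force constants, all functions of
the Laplacian spectrum ``{lambda_l, e_l}``:

* local,    ``1/k_i   = sum_{l>=2} e_l(i)^2 / lambda_l``  — stiffness felt by
  vertex ``i`` alone (the diagonal of the Laplacian pseudoinverse, inverted);
* nonlocal, ``1/K_ij  = sum_{l>=2} (e_l(i)-e_l(j))^2 / lambda_l`` — stiffness
  of the relative fluctuation of a vertex pair, whose inverse is exactly the
  Randic (effective electrical) resistance ``Omega_ij``;
* global,   ``1/K     = sum_{l>=2} 1 / lambda_l`` — whole-graph rigidity,
  whose inverse is the Kirchhoff index ``Kf``.

They obey three sum rules (ordered-pair convention, ``<.>`` over ``j != i``)::

    1/K   = (1/2n) sum_i sum_{j!=i} 1/K_ij
    1/K   = sum_i 1/k_i
    1/k_i = (1/n) (sum_j 1/K_ij - 1/K)

The module also provides shortest-path statistics: the Wiener index (double
sum of shortest path lengths over ordered pairs) and its normalized mean
``<l0> = Wiener / (n(n-1))``.

Note on the mean-resistance form of the Kirchhoff index: eliminating the
double sum with the ordered-pair mean resistance ``<Omega>`` turns the first
sum rule into ``Kf = (n-1)<Omega>/2`` (see docs/methods.md); the exact double
sum above is what is implemented and tested.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .graph_core import (
    DisconnectedGraphError,
    Graph,
    SpectralDecomposition,
    laplacian,
    laplacian_pseudoinverse,
    spectral_decomposition,
)

__all__ = [
    "DescriptorSet",
    "local_force_constants",
    "global_force_constant",
    "nonlocal_force_constants",
    "randic_resistance",
    "shortest_path_stats",
    "shortest_path_matrix",
    "compute_descriptor_set",
]


def _nonzero_modes(spec: SpectralDecomposition) -> tuple[np.ndarray, np.ndarray]:
    spec.require_connected()
    mask = spec.eigenvalues > spec.zero_tol
    return spec.eigenvalues[mask], spec.eigenvectors[:, mask]


def local_force_constants(spec: SpectralDecomposition) -> np.ndarray:
    """Local force constants ``k_i``, the inverse diagonal of ``L+``.

    A small ``k_i`` marks a floppy vertex (typically low degree, e.g. chain
    termini held by the backbone only); such vertices dominate the entropy of
    the graph and depress the global force constant.
    """
    lam, vecs = _nonzero_modes(spec)
    inv_k = (vecs**2 / lam).sum(axis=1)
    return 1.0 / inv_k


def global_force_constant(spec: SpectralDecomposition) -> float:
    """Global force constant ``K = 1 / sum_{l>=2} 1/lambda_l = 1/Kf``."""
    lam, _ = _nonzero_modes(spec)
    return float(1.0 / np.sum(1.0 / lam))


def nonlocal_force_constants(spec: SpectralDecomposition) -> np.ndarray:
    """Nonlocal force constants ``K_ij`` (pairwise stiffness matrix).

    The diagonal is formally ``1/K_ii = 0``; it is reported as ``+inf`` and
    must be excluded from sums.
    """
    lam, vecs = _nonzero_modes(spec)
    # 1/K_ij = L+_ii + L+_jj - 2 L+_ij, evaluated through the spectral sum
    pinv = (vecs / lam) @ vecs.T
    inv_K = np.add.outer(np.diagonal(pinv), np.diagonal(pinv)) - 2.0 * pinv
    np.fill_diagonal(inv_K, 0.0)
    with np.errstate(divide="ignore"):
        K = 1.0 / inv_K
    np.fill_diagonal(K, np.inf)
    return K


def randic_resistance(pinv: np.ndarray) -> np.ndarray:
    """Randic (effective) resistance ``Omega_ij = L+_ii + L+_jj - 2 L+_ij``.

    With unit-resistor edges this is the two-point effective electrical
    resistance; it equals ``1/K_ij`` and, on a tree, the shortest-path
    distance (unit resistances in series).
    """
    pinv = np.asarray(pinv, dtype=float)
    diag = np.diagonal(pinv)
    omega = np.add.outer(diag, diag) - 2.0 * pinv
    np.fill_diagonal(omega, 0.0)
    return omega


def shortest_path_matrix(graph: Graph) -> np.ndarray:
    """All-pairs shortest path lengths.

    Unweighted (binary) graphs use breadth-first search per source; weighted
    graphs fall back to Dijkstra with the edge weights as lengths.  Protein
    graphs are binary, so lengths are edge counts.
    """
    adj = csr_matrix(graph.adjacency)
    unweighted = bool(np.all(np.isin(graph.weights, (0.0, 1.0))))
    dist = _csgraph_shortest_path(
        adj, method="D", directed=False, unweighted=unweighted
    )
    if np.isinf(dist).any():
        raise DisconnectedGraphError("shortest paths undefined: graph is disconnected")
    return dist


def shortest_path_stats(graph: Graph) -> tuple[float, float]:
    """Wiener index and mean shortest path length ``<l0>``.

    Returns
    -------
    (wiener, l0_mean)
        ``wiener`` is the double sum of shortest path lengths over ordered
        pairs (an even integer for unweighted graphs); ``l0_mean`` is
        ``wiener / (n (n-1))``.
    """
    dist = shortest_path_matrix(graph)
    n = graph.n
    wiener = float(dist.sum())
    return wiener, wiener / (n * (n - 1))


@dataclass(frozen=True)
class DescriptorSet:
    """Per-conformation bundle of all graph descriptors."""

    n: int
    degrees: np.ndarray          # d_i
    k_local: np.ndarray          # k_i
    K_nonlocal: np.ndarray       # K_ij, +inf diagonal
    K_global: float              # K
    kirchhoff: float             # Kf = 1/K
    randic: np.ndarray           # Omega_ij = 1/K_ij, zero diagonal
    wiener: float
    l0_mean: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n,
                "K_global": self.K_global,
                "kirchhoff": self.kirchhoff,
                "wiener": self.wiener,
                "l0_mean": self.l0_mean,
                "degrees": self.degrees.tolist(),
                "k_local": self.k_local.tolist(),
                "randic": self.randic.tolist(),
            }
        )

    def to_csv(self, path: str | Path, *, matrices: bool = False) -> None:
        """Write scalars as a header block and per-vertex rows ``i, d_i, k_i``.

        With ``matrices=True`` the dense ``Omega_ij`` matrix is appended as
        CSV rows after a separator line (``K_ij`` is its elementwise inverse).
        """
        lines = [
            f"# n,{self.n}",
            f"# K_global,{self.K_global!r}",
            f"# kirchhoff,{self.kirchhoff!r}",
            f"# wiener,{self.wiener!r}",
            f"# l0_mean,{self.l0_mean!r}",
            "vertex,degree,k_local",
        ]
        lines += [
            f"{i + 1},{self.degrees[i]!r},{self.k_local[i]!r}" for i in range(self.n)
        ]
        if matrices:
            lines.append("# randic_resistance_matrix")
            lines += [",".join(repr(v) for v in row) for row in self.randic]
        Path(path).write_text("\n".join(lines) + "\n")


def compute_descriptor_set(graph: Graph) -> DescriptorSet:
    """Compute every descriptor of a connected graph in one coherent record."""
    lap = laplacian(graph)
    spec = spectral_decomposition(lap)
    spec.require_connected()
    pinv = laplacian_pseudoinverse(lap)
    omega = randic_resistance(pinv)
    with np.errstate(divide="ignore"):
        K_nonlocal = 1.0 / omega
    np.fill_diagonal(K_nonlocal, np.inf)
    K = global_force_constant(spec)
    wiener, l0_mean = shortest_path_stats(graph)
    return DescriptorSet(
        n=graph.n,
        degrees=graph.degrees,
        k_local=local_force_constants(spec),
        K_nonlocal=K_nonlocal,
        K_global=K,
        kirchhoff=1.0 / K,
        randic=omega,
        wiener=wiener,
        l0_mean=l0_mean,
    )
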
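"""Closed-form results for linear chains and complete graphs.

The protein graph of a fully extended chain is the path graph ``P_n``
(backbone edges only, the minimum ``n-1`` edges).  Its Laplacian spectrum is
known in closed form, which yields exact expressions for the extreme values
of the global force constant ``K`` and the mean shortest path length
``<l0>`` over all protein graphs with ``n`` vertices:

* path graph (softest, longest paths):  ``1/K = (n^2-1)/6``, ``<l0> = (n+1)/3``
* complete graph (hypothetical stiffest): ``1/K = 1 - 1/n``, ``<l0> = 1``

Eliminating ``n`` between the two path-graph formulas gives the curve
``1/K = l0 (3 l0 - 2) / 2``, which bounds the (K, <l0>) scatter of real
conformations from above in K.  The ``(n, j)`` model chains — backbone plus
contacts at a single sequence stride ``j`` — populate that upper boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_core import Graph

__all__ = [
    "ModelChainSpec",
    "path_chain_eigenvalues",
    "unfolded_chain_K",
    "unfolded_chain_l0",
    "K_from_l0",
    "complete_graph_K",
    "model_chain_graph",
    "path_graph",
    "complete_graph",
]


def _require_n(n: int) -> int:
    n = int(n)
    if n < 2:
        raise ValueError(f"chain length must be >= 2, got {n}")
    return n


@dataclass(frozen=True)
class ModelChainSpec:
    """Regular model chain ``(n, j)``: backbone plus contacts at stride ``j``.

    ``j=None`` denotes the bare path graph.
    """

    n: int
    j: int | None = None

    def __post_init__(self) -> None:
        _require_n(self.n)
        if self.j is not None and not (2 <= self.j < self.n):
            raise ValueError(f"contact stride must satisfy 2 <= j < n, got j={self.j}, n={self.n}")


def path_graph(n: int) -> Graph:
    """Path graph ``P_n``: unit-weight edges (i, i+1)."""
    n = _require_n(n)
    return Graph.from_edges(n, [(i, i + 1) for i in range(1, n)])


def complete_graph(n: int) -> Graph:
    """Complete graph ``K_n`` with unit weights."""
    n = _require_n(n)
    w = np.ones((n, n)) - np.eye(n)
    return Graph(w)


def path_chain_eigenvalues(n: int) -> np.ndarray:
    """Laplacian eigenvalues of the path graph: ``4 sin^2((l-1) pi / 2n)``.

    These are the squared vibrational frequencies (in units of ``c/m``) of a
    free linear chain of ``n`` identical atoms with nearest-neighbor springs.
    Returned ascending, ``l = 1..n``, first value exactly 0.
    """
    n = _require_n(n)
    l = np.arange(n)
    return 4.0 * np.sin(l * np.pi / (2 * n)) ** 2


def unfolded_chain_K(n: int) -> float:
    """Global force constant of the path graph: ``K = 6 / (n^2 - 1)``.

    The smallest possible ``K`` among all protein graphs on ``n`` vertices:
    adding any contact can only stiffen the chain.
    """
    n = _require_n(n)
    return 6.0 / (n**2 - 1)


def unfolded_chain_l0(n: int) -> float:
    """Mean shortest path length of the path graph: ``<l0> = (n+1)/3``.

    The largest possible ``<l0>`` among protein graphs on ``n`` vertices:
    any contact edge can only shorten paths.
    """
    n = _require_n(n)
    return (n + 1) / 3.0


def K_from_l0(l0: float) -> float:
    """Global force constant predicted from ``<l0>`` for an unfolded chain.

    Eliminating ``n`` between ``<l0> = (n+1)/3`` and ``1/K = (n^2-1)/6``
    gives ``1/K = l0 (3 l0 - 2) / 2``.  Applied to arbitrary conformations
    the curve is an upper bound on ``K`` at given ``<l0>``.
    """
    l0 = float(l0)
    if l0 < 1.0:
        raise ValueError(f"mean shortest path length must be >= 1, got {l0}")
    return 2.0 / (l0 * (3.0 * l0 - 2.0))


def complete_graph_K(n: int) -> float:
    """Global force constant of the complete graph: ``K = n / (n - 1)``.

    The stiffest (hypothetical) graph; ``K`` tends to its mathematical
    minimum of 1 from above as ``n`` grows.
    """
    n = _require_n(n)
    return n / (n - 1.0)


def model_chain_graph(spec: ModelChainSpec | None = None, *, n: int | None = None,
                      j: int | None = None) -> Graph:
    """Graph of the ``(n, j)`` model chain.

    Edges are exactly the backbone pairs ``(i, i+1)`` plus the single-stride
    contacts ``(i, i+j)``, all with unit weight — intermediate strides are
    not included.  A ``(n, j)`` chain mimics a completely unfolded chain of
    roughly ``n/j`` residues, which is why its ``(K, <l0>)`` point falls on
    the :func:`K_from_l0` curve.
    """
    if spec is None:
        spec = ModelChainSpec(n=n, j=j)
    edges = [(i, i + 1) for i in range(1, spec.n)]
    if spec.j is not None:
        edges += [(i, i + spec.j) for i in range(1, spec.n - spec.j + 1)]
    return Graph.from_edges(spec.n, edges)
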
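"""Einstein-model thermodynamics of a graph.

Each vertex of a connected graph is treated as an independent harmonic
oscillator whose frequency derives from its local force constant (an
Einstein crystal with per-site frequencies).  With the reduced frequency
``z = hbar*omega / kB*T``, the per-vertex quantum internal energy (above the
ground-state offset, in units of ``kB*T``) and entropy (units of ``kB``) are

    u(z) = (z/2) coth(z/2)            ->  1        as z -> 0
    s(z) = z/(e^z - 1) - ln(1 - e^-z) ->  1 - ln z as z -> 0

In the classical (high-temperature) limit the free-energy difference between
two conformations of the same chain reduces to a parameter-free entropic
term built from force-constant (or eigenvalue) ratios plus an enthalpic term
proportional to the change in vertex degrees, scaled by a single unknown
dimensionless parameter ``epsilon < 0`` (energy per contact; each edge is
split between its two vertices).  Four variants are defined, differing in
which force constant carries the entropy:

    local       (1/2) sum_i       ln(k_i / k_i0)
    nonlocal    (1/4) sum_{i != j} ln(K_ij / K_ij0)
    global      (1/2) ln(K / K0)
    collective  (1/2) sum_{l>=2}  ln(lambda_l / lambda_l0)

all sharing the enthalpic term ``(epsilon/2) sum_i (d_i - d_i0)``.  The
entropic term as reported here is the entropic *free energy* (``-T dS`` in
``kB*T`` units): positive when the conformation is stiffer than the
reference, e.g. in folded stretches of a trajectory referenced to the
native structure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .descriptors import DescriptorSet
from .graph_core import SpectralDecomposition

__all__ = [
    "FreeEnergyRecord",
    "einstein_internal_energy",
    "einstein_entropy",
    "delta_f_local",
    "delta_f_nonlocal",
    "delta_f_global",
    "delta_f_collective",
    "FREE_ENERGY_MODELS",
]

FREE_ENERGY_MODELS = ("local", "nonlocal", "global", "collective")


def einstein_internal_energy(z: float) -> float:
    """Thermal internal energy ``(z/2) coth(z/2)`` of one oscillator.

    Units of ``kB*T``, ground-state offset excluded.  Tends to 1 in the
    classical limit ``z << 1`` (equipartition) and to the zero-point value
    ``z/2`` for ``z >> 1``.
    """
    z = float(z)
    if z <= 0:
        raise ValueError(f"reduced frequency must be positive, got {z}")
    return (z / 2.0) / math.tanh(z / 2.0)


def einstein_entropy(z: float) -> float:
    """Oscillator entropy ``z/(e^z - 1) - ln(1 - e^-z)`` in units of ``kB``.

    Positive and decreasing in ``z``; approaches ``1 - ln z`` classically
    and 0 for a frozen (``z >> 1``) oscillator.
    """
    z = float(z)
    if z <= 0:
        raise ValueError(f"reduced frequency must be positive, got {z}")
    if z > 700.0:  # e^z overflows; entropy is 0 to double precision anyway
        return 0.0
    return z / math.expm1(z) - math.log(-math.expm1(-z))


@dataclass(frozen=True)
class FreeEnergyRecord:
    """Free-energy difference of a graph vs a reference graph (kB*T units).

    ``total = enthalpic + entropic`` exactly; the entropic term is
    independent of ``epsilon`` and the enthalpic term is linear in it.
    """

    model: str
    enthalpic: float
    entropic: float
    epsilon: float
    reference_id: str | None = None

    @property
    def total(self) -> float:
        return self.enthalpic + self.entropic


def _check_n(target_n: int, reference_n: int) -> None:
    if target_n != reference_n:
        raise ValueError(
            f"target and reference must have the same size, got {target_n} != {reference_n}"
        )


def _enthalpic(
    target_degrees: np.ndarray, reference_degrees: np.ndarray, epsilon: float
) -> float:
    return 0.5 * float(epsilon) * float(np.sum(target_degrees - reference_degrees))


def delta_f_local(
    target: DescriptorSet,
    reference: DescriptorSet,
    epsilon: float = 0.0,
    reference_id: str | None = None,
) -> FreeEnergyRecord:
    """Free-energy difference from per-vertex local force constants."""
    _check_n(target.n, reference.n)
    entropic = 0.5 * float(np.sum(np.log(target.k_local / reference.k_local)))
    return FreeEnergyRecord(
        model="local",
        enthalpic=_enthalpic(target.degrees, reference.degrees, epsilon),
        entropic=entropic,
        epsilon=float(epsilon),
        reference_id=reference_id,
    )


def delta_f_nonlocal(
    target: DescriptorSet,
    reference: DescriptorSet,
    epsilon: float = 0.0,
    reference_id: str | None = None,
) -> FreeEnergyRecord:
    """Free-energy difference from pairwise nonlocal force constants.

    The double product runs over ordered pairs, hence the extra 1/2 (1/4 in
    total) so that the record vanishes at identity and matches the
    sum-rule structure of the descriptors.
    """
    _check_n(target.n, reference.n)
    off = ~np.eye(target.n, dtype=bool)
    # ln(K_ij / K_ij0) = ln(Omega_ij0 / Omega_ij): resistances are finite
    ratio = reference.randic[off] / target.randic[off]
    entropic = 0.25 * float(np.sum(np.log(ratio)))
    return FreeEnergyRecord(
        model="nonlocal",
        enthalpic=_enthalpic(target.degrees, reference.degrees, epsilon),
        entropic=entropic,
        epsilon=float(epsilon),
        reference_id=reference_id,
    )


def delta_f_global(
    target: DescriptorSet,
    reference: DescriptorSet,
    epsilon: float = 0.0,
    reference_id: str | None = None,
) -> FreeEnergyRecord:
    """Coarse-grained free-energy difference from the global force constant."""
    _check_n(target.n, reference.n)
    entropic = 0.5 * math.log(target.K_global / reference.K_global)
    return FreeEnergyRecord(
        model="global",
        enthalpic=_enthalpic(target.degrees, reference.degrees, epsilon),
        entropic=entropic,
        epsilon=float(epsilon),
        reference_id=reference_id,
    )


def delta_f_collective(
    target_spectrum: SpectralDecomposition,
    reference_spectrum: SpectralDecomposition,
    target_degrees: np.ndarray,
    reference_degrees: np.ndarray,
    epsilon: float = 0.0,
    reference_id: str | None = None,
) -> FreeEnergyRecord:
    """Free-energy difference from the collective (normal-mode) spectrum.

    At equal degree terms, the conformation with the smaller product of
    nonzero Laplacian eigenvalues has the lower free energy.
    """
    _check_n(target_spectrum.n, reference_spectrum.n)
    target_spectrum.require_connected()
    reference_spectrum.require_connected()
    lam_t = target_spectrum.eigenvalues[1:]
    lam_r = reference_spectrum.eigenvalues[1:]
    entropic = 0.5 * float(np.sum(np.log(lam_t / lam_r)))
    return FreeEnergyRecord(
        model="collective",
        enthalpic=_enthalpic(np.asarray(target_degrees), np.asarray(reference_degrees), epsilon),
        entropic=entropic,
        epsilon=float(epsilon),
        reference_id=reference_id,
    )
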
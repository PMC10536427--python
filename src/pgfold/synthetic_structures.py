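"""Synthetic C-alpha coordinate generators with controllable contact topology.

These fixtures let every pipeline stage run without downloading structures
or molecular-dynamics data: extended chains (whose protein graph is exactly
the path graph), regular helices (folded-like, rigid), seeded self-avoiding
coils (disordered-like), linearly interpolated folding/unfolding pseudo-
trajectories, and 3D realizations of the ``(n, j)`` model chains.

All geometry is in nm.  The default virtual bond length 0.38 nm is the
canonical C-alpha–C-alpha distance of a trans peptide.  The default helix
parameters (rise 0.14 nm, radius 0.28 nm, twist 100 degrees per residue)
are an idealized, slightly compressed alpha-helix C-alpha geometry tuned
so that exactly the classic helical neighbor offsets — sequence strides 3
and 4 — fall under the 0.6 nm contact cutoff (a real alpha helix puts the
stride-4 pair at about 0.62 nm, just outside it, and the stride-2 pair just
inside).  These generators emulate contact topology only — not dihedral
statistics, excluded-volume physics beyond a hard minimum separation, or
solvent.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .analytic_models import ModelChainSpec, model_chain_graph
from .graph_core import Graph
from .protein_graph_io import (
    DEFAULT_CUTOFF_NM,
    Structure,
    build_protein_graph,
    write_pdb,
)

__all__ = [
    "FixtureSpec",
    "CA_BOND_NM",
    "extended_chain",
    "helix",
    "self_avoiding_coil",
    "interpolated_folding_trajectory",
    "model_chain_3d",
    "zipper_unfolding_trajectory",
    "make_fixture",
    "write_fixture",
]

#: Canonical C-alpha virtual bond length (trans peptide), nm.
CA_BOND_NM = 0.38

HELIX_RISE_NM = 0.14
HELIX_RADIUS_NM = 0.28
HELIX_TWIST_DEG = 100.0


@dataclass(frozen=True)
class FixtureSpec:
    """Declarative fixture request (used by the CLI and JSON sidecars)."""

    kind: str
    n: int
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        valid = {"extended", "helix", "coil", "interpolated_folding", "model_chain_3d"}
        if self.kind not in valid:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {sorted(valid)}")
        if self.n < 2:
            raise ValueError(f"need n >= 2 residues, got {self.n}")


def extended_chain(n: int, bond_length: float = CA_BOND_NM) -> Structure:
    """Straight chain along x: the completely unfolded conformation.

    Its protein graph is the path graph P_n (second neighbors sit at
    ``2 * bond_length`` = 0.76 nm by default, outside the contact cutoff).
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if bond_length <= 0:
        raise ValueError("bond length must be positive")
    coords = np.zeros((n, 3))
    coords[:, 0] = bond_length * np.arange(n)
    return Structure(coords=coords)


def helix(
    n: int,
    rise: float = HELIX_RISE_NM,
    radius: float = HELIX_RADIUS_NM,
    twist_deg: float = HELIX_TWIST_DEG,
) -> Structure:
    """Regular helix; the default (idealized alpha-helical) geometry puts
    all sequence strides 3 and 4 — and only those — under the contact
    cutoff, giving a rigid, folded-like graph."""
    if n < 4:
        raise ValueError(f"need n >= 4 for a helix, got {n}")
    if rise < 0 or radius < 0 or rise + radius <= 0:
        raise ValueError("degenerate helix geometry: rise and radius cannot both vanish")
    theta = np.deg2rad(twist_deg) * np.arange(n)
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)]
    )
    return Structure(coords=coords)


def self_avoiding_coil(
    n: int,
    seed: int,
    bond_length: float = CA_BOND_NM,
    min_separation: float = 0.4,
    max_restarts: int = 200,
    max_tries: int = 200,
) -> Structure:
    """Seeded self-avoiding random walk with fixed bond length.

    Successive residues sit exactly ``bond_length`` apart in a uniformly
    random direction; any non-bonded pair must be at least ``min_separation``
    apart.  Growth is retried per step and the whole chain is restarted on
    dead ends; reproducible for a given seed.
    """
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    for _ in range(max_restarts):
        coords = np.zeros((n, 3))
        failed = False
        for i in range(1, n):
            for _ in range(max_tries):
                step = rng.normal(size=3)
                step *= bond_length / np.linalg.norm(step)
                candidate = coords[i - 1] + step
                if i >= 2:
                    dists = np.linalg.norm(coords[: i - 1] - candidate, axis=1)
                    if dists.min() < min_separation:
                        continue
                coords[i] = candidate
                break
            else:
                failed = True
                break
        if not failed:
            return Structure(coords=coords)
    raise RuntimeError(
        f"could not place a self-avoiding coil of n={n} after {max_restarts} "
        f"restarts; relax min_separation (currently {min_separation} nm)"
    )


def interpolated_folding_trajectory(
    start: Structure,
    end: Structure,
    steps: int,
    seed: int = 0,
    noise_nm: float = 0.0,
) -> list[Structure]:
    """Linear interpolation from ``start`` to ``end`` with seeded jitter.

    Frame 0 is exactly ``start`` (so the native-contact fraction relative to
    ``start`` is 1 at t=0); later frames get isotropic Gaussian jitter of
    standard deviation ``noise_nm`` per coordinate.  Contact counts drift
    monotonically up to that noise.
    """
    if start.n != end.n:
        raise ValueError(f"start and end sizes differ: {start.n} != {end.n}")
    if steps < 2:
        raise ValueError(f"need steps >= 2, got {steps}")
    rng = np.random.default_rng(seed)
    frames = []
    for k in range(steps):
        t = k / (steps - 1)
        coords = (1.0 - t) * start.coords + t * end.coords
        if k > 0 and noise_nm > 0:
            coords = coords + rng.normal(scale=noise_nm, size=coords.shape)
        frames.append(Structure(coords=coords, labels=start.labels, model_id=k + 1))
    return frames


def model_chain_3d(n: int, j: int, cutoff: float = DEFAULT_CUTOFF_NM) -> Structure:
    """3D realization of the ``(n, j)`` model chain.

    Residues are placed on a helix with exactly ``j`` residues per turn
    (twist ``2*pi/j``) and a rise tuned so that only the stride-``j`` pairs
    (vertically stacked, distance ``j * rise``) fall under the contact
    cutoff; the radius pushes every other stride outside it.  The resulting
    protein graph is verified against the abstract ``(n, j)`` graph and a
    mismatch is an error.
    """
    spec = ModelChainSpec(n=n, j=j)
    rise, radius = _model_chain_geometry(j, cutoff)
    theta = (2.0 * np.pi / j) * np.arange(n)
    coords = np.column_stack(
        [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)]
    )
    structure = Structure(coords=coords)
    expected = model_chain_graph(spec)
    built = build_protein_graph(structure, cutoff)
    if not np.array_equal(built.weights, expected.weights):
        raise RuntimeError(
            f"geometry search failed for (n={n}, j={j}): realized protein graph "
            "does not match the model chain graph"
        )
    return structure


def _model_chain_geometry(j: int, cutoff: float) -> tuple[float, float]:
    """(rise, radius) of the model-chain helix: stride-j pairs stack
    vertically at ``j*rise`` inside the cutoff, every other stride is pushed
    outside it by the in-plane chord ``2 r sin(pi/j) = 1.2 * cutoff``."""
    rise = 0.75 * cutoff / j
    radius = 1.2 * np.sqrt(cutoff**2 / (2.0 * (1.0 - np.cos(2.0 * np.pi / j))))
    return rise, radius


def zipper_unfolding_trajectory(
    n: int, j: int, cutoff: float = DEFAULT_CUTOFF_NM
) -> list[Structure]:
    """Progressive end-unwinding of the ``(n, j)`` model chain.

    Frame ``t`` keeps residues ``1..n-t`` wound on the model-chain helix and
    extends the remaining tail straight along the helix axis — unfolding
    nucleating at the C-terminus, one residue per frame, from the fully
    wound chain (native-contact fraction 1) down to the fully extended one
    (0).  Every frame's protein graph is exactly the backbone plus the
    stride-``j`` contacts surviving in the wound segment — the truncated
    boundary-family graphs whose (K, <l0>) points track the unfolded-chain
    envelope from below.  Each frame is verified against that graph.
    """
    spec = ModelChainSpec(n=n, j=j)
    rise, radius = _model_chain_geometry(j, cutoff)
    theta = (2.0 * np.pi / j) * np.arange(n)
    frames: list[Structure] = []
    for t in range(n + 1):
        m = n - t  # residues still wound
        coords = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), rise * np.arange(n)]
        )
        if m < n:
            anchor = coords[max(m - 1, 0)]
            for i in range(max(m, 1), n):
                coords[i] = anchor + np.array(
                    [0.0, 0.0, CA_BOND_NM * (i - max(m - 1, 0))]
                )
        structure = Structure(coords=coords, model_id=t + 1)
        expected_edges = [(i, i + 1) for i in range(1, n)]
        expected_edges += [(i, i + j) for i in range(1, m - j + 1)]
        expected = Graph.from_edges(n, expected_edges)
        built = build_protein_graph(structure, cutoff)
        if not np.array_equal(built.weights, expected.weights):
            raise RuntimeError(
                f"zipper frame t={t} for (n={n}, j={j}): realized protein graph "
                "does not match the partial model chain"
            )
        frames.append(structure)
    return frames


def make_fixture(spec: FixtureSpec) -> Structure | list[Structure]:
    """Dispatch a :class:`FixtureSpec` to the matching generator."""
    p = dict(spec.params)
    if spec.kind == "extended":
        return extended_chain(spec.n, **p)
    if spec.kind == "helix":
        return helix(spec.n, **p)
    if spec.kind == "coil":
        if spec.seed is None:
            raise ValueError("coil fixtures require a seed")
        return self_avoiding_coil(spec.n, seed=spec.seed, **p)
    if spec.kind == "model_chain_3d":
        return model_chain_3d(spec.n, **p)
    # interpolated_folding: helix -> extended by default
    steps = int(p.pop("steps", 100))
    noise = float(p.pop("noise_nm", 0.0))
    start = helix(spec.n)
    end = extended_chain(spec.n)
    return interpolated_folding_trajectory(
        start, end, steps=steps, seed=spec.seed or 0, noise_nm=noise
    )


def write_fixture(
    spec: FixtureSpec, pdb_path: str | Path, sidecar: bool = True
) -> Structure | list[Structure]:
    """Generate a fixture, write it as a minimal PDB plus a JSON sidecar
    recording the spec (kind, n, seed, params) for reproducibility."""
    result = make_fixture(spec)
    write_pdb(result, pdb_path)
    if sidecar:
        Path(pdb_path).with_suffix(".json").write_text(json.dumps(asdict(spec), indent=1))
    return result
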
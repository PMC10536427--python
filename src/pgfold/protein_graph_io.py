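"""Protein structures, contact sets and protein-graph construction.

A protein conformation is coarse-grained to the ordered positions of its
C-alpha atoms (one per residue, internal unit nm).  The protein graph (PG)
has one vertex per residue and unit-weight edges of two kinds:

* backbone edges ``(i, i+1)`` representing the peptide bonds — always
  present, so a PG is always connected;
* contact edges between residues nonadjacent in sequence (``|i-j| >= 2``)
  whose C-alpha distance is strictly below a cutoff radius (default 0.6 nm).

The fraction of native contacts ``xi = |contacts(t) ∩ native| / |native|``
is the classic folded/unfolded order parameter; backbone edges never count.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .graph_core import Graph

__all__ = [
    "StructureError",
    "Structure",
    "ContactSet",
    "DEFAULT_CUTOFF_NM",
    "contacts",
    "build_protein_graph",
    "contacts_from_graph",
    "native_contact_fraction",
    "read_pdb_models",
    "write_pdb",
    "Frame",
    "iterate_frames",
]

logger = logging.getLogger(__name__)

#: Contact cutoff radius in nm; captures the first-neighbor peak of C-alpha
#: pair distances in folded structures.
DEFAULT_CUTOFF_NM = 0.6

ANGSTROM_PER_NM = 10.0


class StructureError(ValueError):
    """Raised for invalid structures or unreadable structure files."""


@dataclass(frozen=True)
class Structure:
    """Ordered C-alpha coordinates (nm) of one conformation.

    ``labels`` are residue tags like ``"ASN1"`` (name + 1-based sequence
    index); ``model_id`` tags the source model/frame when known.
    """

    coords: np.ndarray
    labels: tuple[str, ...] = ()
    model_id: int | None = None

    def __post_init__(self) -> None:
        xyz = np.asarray(self.coords, dtype=float)
        if xyz.ndim != 2 or xyz.shape[1] != 3:
            raise StructureError(f"coords must be (n, 3), got {xyz.shape}")
        if xyz.shape[0] < 2:
            raise StructureError("a structure needs at least 2 residues")
        if not np.all(np.isfinite(xyz)):
            raise StructureError("coordinates must be finite")
        object.__setattr__(self, "coords", xyz)
        if self.labels and len(self.labels) != xyz.shape[0]:
            raise StructureError("labels length must match residue count")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"GLY{i + 1}" for i in range(xyz.shape[0]))
            )

    @property
    def n(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class ContactSet:
    """Unordered residue pairs ``(i, j)``, 1-based, with ``|i - j| >= 2``."""

    pairs: frozenset[tuple[int, int]]
    n: int | None = None

    def __post_init__(self) -> None:
        normed = set()
        for i, j in self.pairs:
            i, j = int(min(i, j)), int(max(i, j))
            if j - i < 2:
                raise StructureError(
                    f"({i},{j}) is not a contact: sequence-adjacent or identical"
                )
            if i < 1 or (self.n is not None and j > self.n):
                raise StructureError(f"contact ({i},{j}) out of range 1..{self.n}")
            normed.add((i, j))
        object.__setattr__(self, "pairs", frozenset(normed))

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs

    def to_csv(self, path: str | Path) -> None:
        lines = ["i,j"] + [f"{i},{j}" for i, j in sorted(self.pairs)]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path, n: int | None = None) -> "ContactSet":
        rows = Path(path).read_text().strip().split("\n")[1:]
        pairs = frozenset(tuple(int(x) for x in row.split(",")) for row in rows)
        return cls(pairs=pairs, n=n)


def contacts(structure: Structure, cutoff: float = DEFAULT_CUTOFF_NM) -> ContactSet:
    """Contact set of a conformation: ``|i-j| >= 2`` and distance < cutoff.

    The inequality is strict ("below" the cutoff radius).
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    dist = squareform(pdist(structure.coords))
    n = structure.n
    pairs = {
        (i + 1, j + 1)
        for i in range(n)
        for j in range(i + 2, n)
        if dist[i, j] < cutoff
    }
    return ContactSet(pairs=frozenset(pairs), n=n)


def build_protein_graph(
    structure: Structure, cutoff: float = DEFAULT_CUTOFF_NM
) -> Graph:
    """Protein graph: backbone edges plus contact edges, all unit weight.

    The edge count is ``(n - 1) + |contacts|``; with no contact the PG is the
    path graph, the softest conformation possible at this chain length.
    """
    n = structure.n
    edges: list[tuple[int, int]] = [(i, i + 1) for i in range(1, n)]
    edges += sorted(contacts(structure, cutoff).pairs)
    return Graph.from_edges(n, edges)


def contacts_from_graph(graph: Graph) -> ContactSet:
    """Recover the contact set of a PG (its edges minus the backbone)."""
    pairs = frozenset(
        (i, j) for i, j, _ in graph.edges() if j - i >= 2
    )
    return ContactSet(pairs=pairs, n=graph.n)


def native_contact_fraction(snapshot: ContactSet, native: ContactSet) -> float:
    """Fraction of native contacts ``xi`` of a snapshot.

    Counts the snapshot contacts that are present in the native reference,
    normalized by the native contact count; non-native contacts never raise
    ``xi``, so ``xi`` is in ``[0, 1]`` and equals 1 for the reference itself.
    """
    if len(native) == 0:
        raise ValueError("native contact set is empty: xi is undefined")
    return len(snapshot.pairs & native.pairs) / len(native)


# -- PDB reading/writing ----------------------------------------------------


def read_pdb_models(
    path: str | Path, chain: str | None = None
) -> list[Structure]:
    """Read the C-alpha trace of every model in a (multi-model) PDB file.

    One :class:`Structure` per MODEL record (a single one if the file has no
    MODEL records).  Coordinates are converted from Angstrom to nm.  For
    disordered atoms the first alternate location wins (with a warning); a
    multi-chain model requires an explicit ``chain`` selection; a residue
    without a C-alpha atom is an error naming the residue.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    path = Path(path)
    if not path.is_file():
        raise StructureError(f"no such PDB file: {path}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        pdb = parser.get_structure(path.stem, str(path))

    structures: list[Structure] = []
    for model in pdb:
        chains = [c for c in model if any(r.id[0] == " " for r in c)]
        if not chains:
            continue
        if chain is None:
            if len(chains) > 1:
                raise StructureError(
                    f"model {model.id + 1} has {len(chains)} chains "
                    f"({', '.join(c.id for c in chains)}); select one with chain="
                )
            selected = chains[0]
        else:
            matches = [c for c in chains if c.id == chain]
            if not matches:
                raise StructureError(f"chain {chain!r} not found in model {model.id + 1}")
            selected = matches[0]

        coords, labels = [], []
        seen: set[tuple[str, int]] = set()
        for residue in selected:
            if residue.id[0] != " ":
                continue  # heteroatoms / waters
            key = (residue.resname, residue.id[1])
            if key in seen:
                logger.warning("duplicate residue %s%d: first occurrence kept", *key)
                continue
            seen.add(key)
            if "CA" not in residue:
                raise StructureError(
                    f"residue {residue.resname}{residue.id[1]} in model "
                    f"{model.id + 1} has no C-alpha atom"
                )
            atom = residue["CA"]
            if atom.is_disordered():
                logger.warning(
                    "altloc on %s%d: first alternate location kept", *key
                )
                atom = atom.disordered_get_list()[0]
            coords.append(atom.coord / ANGSTROM_PER_NM)
            labels.append(f"{residue.resname}{residue.id[1]}")
        if len(coords) < 2:
            continue
        structures.append(
            Structure(
                coords=np.array(coords), labels=tuple(labels), model_id=model.id + 1
            )
        )
    if not structures:
        raise StructureError(f"no C-alpha coordinates found in {path}")
    return structures


_RES3 = {name for name in (
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL"
).split()}


def _split_label(label: str) -> tuple[str, int]:
    name = label[:3] if label[:3] in _RES3 else "GLY"
    digits = "".join(ch for ch in label if ch.isdigit())
    return name, int(digits) if digits else 0


def write_pdb(structures: Structure | Sequence[Structure], path: str | Path) -> None:
    """Write C-alpha-only structures as a minimal (multi-model) PDB file."""
    if isinstance(structures, Structure):
        structures = [structures]
    multi = len(structures) > 1
    lines: list[str] = []
    for m, structure in enumerate(structures, start=1):
        if multi:
            lines.append(f"MODEL     {m:4d}")
        for i in range(structure.n):
            resname, resseq = _split_label(structure.labels[i])
            resseq = resseq or i + 1
            x, y, z = structure.coords[i] * ANGSTROM_PER_NM
            lines.append(
                f"ATOM  {i + 1:5d}  CA  {resname:>3s} A{resseq:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class Frame:
    """One trajectory frame: index, timestamp (ps) and structure."""

    index: int
    time_ps: float
    structure: Structure


def iterate_frames(
    source: str | Path | Iterable[Structure],
    *,
    dt_ps: float = 1.0,
    chain: str | None = None,
) -> Iterator[Frame]:
    """Iterate trajectory frames as :class:`Frame` objects in time order.

    ``source`` may be a multi-model PDB path or any iterable of
    :class:`Structure` (the adapter contract: anything yielding per-frame
    C-alpha coordinate sets — e.g. structures built from an mdtraj or
    MDAnalysis trajectory).  Timestamps are ``index * dt_ps``.
    """
    if isinstance(source, (str, Path)):
        structures: Iterable[Structure] = read_pdb_models(source, chain=chain)
    else:
        structures = source
    n_ref: int | None = None
    for index, structure in enumerate(structures):
        if not isinstance(structure, Structure):
            raise StructureError(
                f"frame {index}: expected Structure, got {type(structure).__name__}"
            )
        if n_ref is None:
            n_ref = structure.n
        elif structure.n != n_ref:
            raise StructureError(
                f"frame {index}: residue count {structure.n} != {n_ref} of frame 0"
            )
        yield Frame(index=index, time_ps=index * dt_ps, structure=structure)
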
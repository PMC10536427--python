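"""Per-frame trajectory analysis: descriptors, order parameters, statistics.

For every frame of a trajectory the pipeline builds the protein graph,
computes the descriptor set (global force constant ``K``, mean shortest
path ``<l0>``, local force constants), the fraction of native contacts
``xi`` relative to a native reference structure, and the four graph
free-energy differences vs the native reference at each requested
``epsilon``.  Frames are then partitioned into folded (``xi >= threshold``,
default 0.6) and unfolded states; state means and Pearson correlations are
computed from the raw per-frame values, never from smoothed series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.stats

from .descriptors import DescriptorSet, compute_descriptor_set
from .einstein_free_energy import (
    FreeEnergyRecord,
    delta_f_collective,
    delta_f_global,
    delta_f_local,
    delta_f_nonlocal,
)
from .graph_core import laplacian, spectral_decomposition
from .protein_graph_io import (
    DEFAULT_CUTOFF_NM,
    ContactSet,
    Frame,
    Structure,
    build_protein_graph,
    contacts,
    native_contact_fraction,
)

__all__ = [
    "AnalysisConfig",
    "FrameRecord",
    "StateSummary",
    "analyze_trajectory",
    "partition_states",
    "moving_mean",
    "pdf2d",
    "pearson",
    "records_to_dataframe",
    "klocal_dataframe",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the trajectory pipeline.

    ``cutoff_nm``: contact radius; ``xi_threshold``: folded/unfolded split
    on the native-contact fraction; ``epsilons``: enthalpic energy scales
    for the free-energy models (0 = purely entropic); ``bins``: grid size of
    2D probability densities; ``window``: moving-mean window in frames
    (convert from time with the trajectory timestep); ``reference_model``:
    1-based model index of the native reference in a multi-model file.
    """

    cutoff_nm: float = DEFAULT_CUTOFF_NM
    xi_threshold: float = 0.6
    epsilons: tuple[float, ...] = (0.0,)
    bins: int = 25
    window: int = 1
    reference_model: int = 1
    chain: str | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")
        if not 0.0 <= self.xi_threshold <= 1.0:
            raise ValueError("xi threshold must be in [0, 1]")
        if self.bins < 2:
            raise ValueError("need at least 2 bins")
        if self.window < 1:
            raise ValueError("window must be >= 1 frame")


@dataclass(frozen=True)
class FrameRecord:
    """Descriptors and free energies of one trajectory frame."""

    frame: int
    time_ps: float
    xi: float
    K: float
    l0_mean: float
    degree_sum: float
    k_local: np.ndarray
    free_energy: dict[tuple[str, float], FreeEnergyRecord] = field(default_factory=dict)

    def total(self, model: str, epsilon: float) -> float:
        return self.free_energy[(model, epsilon)].total


@dataclass(frozen=True)
class StateSummary:
    """Folded/unfolded state means and descriptor correlations.

    Means of an empty state are ``None`` (flagged missing, never zero).
    Correlations are over all frames, from raw values.
    """

    threshold: float
    n_frames: int
    n_folded: int
    n_unfolded: int
    K_folded: float | None
    K_unfolded: float | None
    l0_folded: float | None
    l0_unfolded: float | None
    corr_xi_K: float
    corr_xi_l0: float
    corr_K_l0: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _as_frames(frames: Iterable[Structure | Frame]) -> Iterable[Frame]:
    for index, item in enumerate(frames):
        if isinstance(item, Frame):
            yield item
        else:
            yield Frame(index=index, time_ps=float(index), structure=item)


def analyze_trajectory(
    frames: Iterable[Structure | Frame],
    native: Structure,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[FrameRecord]:
    """Analyze a trajectory against a native reference structure.

    Deterministic: identical inputs give identical records.  Raises on the
    first frame whose residue count differs from the native structure.
    """
    native_contacts = contacts(native, config.cutoff_nm)
    native_graph = build_protein_graph(native, config.cutoff_nm)
    native_desc = compute_descriptor_set(native_graph)
    native_spec = spectral_decomposition(laplacian(native_graph))

    records: list[FrameRecord] = []
    for frame in _as_frames(frames):
        structure = frame.structure
        if structure.n != native.n:
            raise ValueError(
                f"frame {frame.index}: residue count {structure.n} != native {native.n}"
            )
        snapshot_contacts = contacts(structure, config.cutoff_nm)
        graph = build_protein_graph(structure, config.cutoff_nm)
        desc = compute_descriptor_set(graph)
        spec = spectral_decomposition(laplacian(graph))
        xi = native_contact_fraction(snapshot_contacts, native_contacts)

        free_energy: dict[tuple[str, float], FreeEnergyRecord] = {}
        for eps in config.epsilons:
            free_energy[("local", eps)] = delta_f_local(desc, native_desc, eps)
            free_energy[("nonlocal", eps)] = delta_f_nonlocal(desc, native_desc, eps)
            free_energy[("global", eps)] = delta_f_global(desc, native_desc, eps)
            free_energy[("collective", eps)] = delta_f_collective(
                spec, native_spec, desc.degrees, native_desc.degrees, eps
            )
        records.append(
            FrameRecord(
                frame=frame.index,
                time_ps=frame.time_ps,
                xi=xi,
                K=desc.K_global,
                l0_mean=desc.l0_mean,
                degree_sum=float(desc.degrees.sum()),
                k_local=desc.k_local,
                free_energy=free_energy,
            )
        )
        if (frame.index + 1) % 100 == 0:
            logger.info("analyzed %d frames", frame.index + 1)
    return records


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance series")
    return float(scipy.stats.pearsonr(x, y).statistic)


def partition_states(
    records: Sequence[FrameRecord], threshold: float = 0.6
) -> StateSummary:
    """Split frames into folded (``xi >= threshold``) and unfolded states.

    State means use raw per-frame values.  Folded conformations are expected
    to be stiffer (larger mean ``K``) with shorter paths (smaller ``<l0>``)
    than unfolded ones.
    """
    if not records:
        raise ValueError("no frames to partition")
    xi = np.array([r.xi for r in records])
    K = np.array([r.K for r in records])
    l0 = np.array([r.l0_mean for r in records])
    folded = xi >= threshold

    def _mean(values: np.ndarray, mask: np.ndarray) -> float | None:
        return float(values[mask].mean()) if mask.any() else None

    def _corr(a: np.ndarray, b: np.ndarray) -> float:
        try:
            return pearson(a, b)
        except ValueError:
            return float("nan")

    return StateSummary(
        threshold=threshold,
        n_frames=len(records),
        n_folded=int(folded.sum()),
        n_unfolded=int((~folded).sum()),
        K_folded=_mean(K, folded),
        K_unfolded=_mean(K, ~folded),
        l0_folded=_mean(l0, folded),
        l0_unfolded=_mean(l0, ~folded),
        corr_xi_K=_corr(xi, K),
        corr_xi_l0=_corr(xi, l0),
        corr_K_l0=_corr(K, l0),
    )


def moving_mean(series: Sequence[float], window: int) -> np.ndarray:
    """Centered moving mean, truncated at the edges; output length = input.

    Smoothing is for display only — state statistics are always computed
    from the raw series.
    """
    x = np.asarray(series, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > x.size:
        raise ValueError(f"window {window} exceeds series length {x.size}")
    return (
        pd.Series(x).rolling(window=window, center=True, min_periods=1).mean().to_numpy()
    )


def pdf2d(
    x: Sequence[float], y: Sequence[float], bins: int = 25
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """2D probability density on a ``bins x bins`` grid spanning the data.

    Returns ``(counts, density, x_edges, y_edges)``; the density integrates
    to 1 (sum times cell area).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    density, _, _ = np.histogram2d(x, y, bins=(xe, ye), density=True)
    return counts, density, xe, ye


# -- tabular output ---------------------------------------------------------


def records_to_dataframe(records: Sequence[FrameRecord]) -> pd.DataFrame:
    """Main rectangular table: one row per frame, free-energy totals as
    ``dF_<model>_eps<val>`` columns."""
    rows = []
    for r in records:
        row: dict = {
            "frame": r.frame,
            "time_ps": r.time_ps,
            "xi": r.xi,
            "K": r.K,
            "l0_mean": r.l0_mean,
            "degree_sum": r.degree_sum,
        }
        for (model, eps), rec in r.free_energy.items():
            row[f"dF_{model}_eps{eps:g}"] = rec.total
        rows.append(row)
    return pd.DataFrame(rows)


def klocal_dataframe(records: Sequence[FrameRecord]) -> pd.DataFrame:
    """Wide per-residue table of local force constants (one column per
    residue), kept separate to preserve the main table's shape."""
    data = np.array([r.k_local for r in records])
    columns = [f"k{i + 1}" for i in range(data.shape[1])]
    df = pd.DataFrame(data, columns=columns)
    df.insert(0, "frame", [r.frame for r in records])
    return df
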
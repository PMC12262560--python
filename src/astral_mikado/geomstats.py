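"""Dangling-end and productive-segment geometry of astral networks.

A filament portion is *productive* when it is bounded at both ends by a
connection — either the astral center (for asters with ``a_n >= 2``,
whose filament ends are crosslinked to each other precisely at the
center) or an inter-aster crosslink.  Everything else is a *dangling
end* and carries no net force under deformation.  A filament with no
connections at all counts as a single dangling end of length ``ell``
(not two half-ends); this convention is what produces the accumulation
point at ``ell`` in dangling-length histograms.

The use-fraction of a network is

    1 - (total dangling length) / (total filament length).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .netgen import AstralNetwork, _crosslink_arrays

__all__ = [
    "FilamentPartition",
    "DanglingStats",
    "SegmentsPerNode",
    "partition_filament",
    "network_partitions",
    "use_fraction",
    "dangling_length_distribution",
    "segments_per_node",
    "geometry_summary",
]

_EPS = 1e-12


@dataclass
class FilamentPartition:
    """Partition of one filament into productive and dangling intervals.

    Intervals are ``(lo, hi)`` arc coordinates measured from the center
    end; productive + dangling lengths sum to the filament length.
    """

    productive: list[tuple[float, float]]
    dangling: list[tuple[float, float]]
    length: float

    @property
    def productive_length(self) -> float:
        return sum(hi - lo for lo, hi in self.productive)

    @property
    def dangling_lengths(self) -> list[float]:
        return [hi - lo for lo, hi in self.dangling]

    @property
    def dangling_length(self) -> float:
        return sum(self.dangling_lengths)


def partition_filament(
    connections: Sequence[float], ell: float, has_center_attachment: bool
) -> FilamentPartition:
    """Partition a filament given its connection arc-coordinates.

    With a center attachment, arc 0 is always a connection.  Consecutive
    connections bound productive segments; the interval past the last
    connection (and, without a center attachment, the one before the
    first) is a dangling end.  No connections at all: one dangling end of
    length ``ell``.
    """
    conn = np.sort(np.asarray(list(connections), dtype=float))
    if conn.size and (conn[0] < -_EPS or conn[-1] > ell + _EPS):
        raise ValueError(f"connection arc outside [0, {ell}]: {conn}")
    conn = np.clip(conn, 0.0, ell)
    if has_center_attachment:
        conn = np.concatenate([[0.0], conn])
    if conn.size == 0:
        return FilamentPartition(productive=[], dangling=[(0.0, ell)], length=ell)
    # drop duplicate coordinates (two crosslinks at the same point)
    conn = conn[np.concatenate([[True], np.diff(conn) > _EPS])]
    productive = [(float(a), float(b)) for a, b in zip(conn[:-1], conn[1:])]
    dangling = []
    if not has_center_attachment and conn[0] > _EPS:
        dangling.append((0.0, float(conn[0])))
    if conn[-1] < ell - _EPS:
        dangling.append((float(conn[-1]), ell))
    return FilamentPartition(productive=productive, dangling=dangling, length=ell)


def _arcs_by_filament(net: AstralNetwork, crosslinks: Optional[dict] = None):
    """Per-filament lists of inter-aster crosslink arc coordinates."""
    if crosslinks is None:
        crosslinks = _crosslink_arrays(net)
    F = net.n_filaments
    arcs: list[list[float]] = [[] for _ in range(F)]
    for fil, arc in (
        (crosslinks["fil_i"], crosslinks["arc_i"]),
        (crosslinks["fil_j"], crosslinks["arc_j"]),
    ):
        for f, a in zip(fil, arc):
            arcs[f].append(float(a))
    return arcs, crosslinks


def network_partitions(
    net: AstralNetwork, crosslinks: Optional[dict] = None
) -> list[FilamentPartition]:
    """Per-filament partitions for a whole network.

    Astral centers count as connections only for ``a_n >= 2``; in
    non-astral networks both filament ends are free.
    """
    arcs, _ = _arcs_by_filament(net, crosslinks)
    ell = net.params.filament_length
    has_center = net.params.astral_number >= 2
    return [partition_filament(a, ell, has_center) for a in arcs]


def use_fraction(net: AstralNetwork, crosslinks: Optional[dict] = None) -> float:
    """1 - total dangling length / total filament length, in [0, 1]."""
    if net.n_filaments == 0:
        raise ValueError("empty network")
    parts = network_partitions(net, crosslinks)
    dangling = sum(p.dangling_length for p in parts)
    return 1.0 - dangling / net.total_filament_length


@dataclass
class DanglingStats:
    """Pooled dangling-end lengths with overall and sub-ell means."""

    lengths: np.ndarray
    ell: float
    mean: float
    mean_sub_ell: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray

    @property
    def n_full_length(self) -> int:
        """Number of dangling ends at the accumulation point (length ell)."""
        return int(np.sum(self.lengths >= self.ell - 1e-9))


def dangling_length_distribution(
    nets: Iterable[AstralNetwork], bins: int = 50
) -> DanglingStats:
    """Pool dangling-end lengths over networks.

    Reports the overall mean and the mean restricted to lengths strictly
    below ``ell`` (the sub-ell, exponential-body part).
    """
    nets = list(nets)
    if not nets:
        raise ValueError("need at least one network")
    ell = nets[0].params.filament_length
    lengths: list[float] = []
    for net in nets:
        for p in network_partitions(net):
            lengths.extend(p.dangling_lengths)
    arr = np.asarray(lengths, dtype=float)
    sub = arr[arr < ell - 1e-9]
    counts, edges = np.histogram(arr, bins=bins, range=(0.0, ell))
    return DanglingStats(
        lengths=arr,
        ell=ell,
        mean=float(arr.mean()) if arr.size else np.nan,
        mean_sub_ell=float(sub.mean()) if sub.size else np.nan,
        hist_counts=counts,
        hist_edges=edges,
    )


@dataclass
class SegmentsPerNode:
    """Incident productive-segment counts per mechanical node.

    Nodes are astral centers (for ``a_n >= 2``) and inter-aster
    crosslinks; nodes with zero incident productive segments (e.g. an
    isolated aster center) are excluded from the mean.
    """

    crosslink_counts: np.ndarray
    center_counts: np.ndarray
    mean: float


def segments_per_node(
    net: AstralNetwork, crosslinks: Optional[dict] = None
) -> SegmentsPerNode:
    """Count productive segments incident to every node.

    A crosslink touches two filaments and up to four local half-segments;
    a half-segment counts when its far end is bounded by another
    connection (crosslink or astral center).  An astral center counts one
    productive segment per filament that carries at least one crosslink.
    """
    arcs, crosslinks = _arcs_by_filament(net, crosslinks)
    a_n = net.params.astral_number
    has_center = a_n >= 2
    sorted_arcs = [np.sort(np.asarray(a)) for a in arcs]

    def half_counts(fil: int, arc: float) -> int:
        sa = sorted_arcs[fil]
        below = has_center or bool(np.any(sa < arc - _EPS))
        above = bool(np.any(sa > arc + _EPS))
        return int(below) + int(above)

    m = crosslinks["fil_i"].size
    cl_counts = np.fromiter(
        (
            half_counts(int(crosslinks["fil_i"][k]), float(crosslinks["arc_i"][k]))
            + half_counts(int(crosslinks["fil_j"][k]), float(crosslinks["arc_j"][k]))
            for k in range(m)
        ),
        dtype=int,
        count=m,
    )
    if has_center:
        n_links = np.array([len(a) for a in arcs]).reshape(-1, a_n)
        center_counts = (n_links > 0).sum(axis=1)
    else:
        center_counts = np.empty(0, dtype=int)
    pooled = np.concatenate([cl_counts, center_counts])
    pooled = pooled[pooled > 0]
    mean = float(pooled.mean()) if pooled.size else np.nan
    return SegmentsPerNode(
        crosslink_counts=cl_counts, center_counts=center_counts, mean=mean
    )


def mean_segments_per_node(nets: Iterable[AstralNetwork]) -> float:
    """Node counts pooled over an ensemble of networks, then averaged."""
    pooled: list[np.ndarray] = []
    for net in nets:
        spn = segments_per_node(net)
        pooled.append(spn.crosslink_counts[spn.crosslink_counts > 0])
        pooled.append(spn.center_counts[spn.center_counts > 0])
    allc = np.concatenate(pooled)
    if allc.size == 0:
        raise ValueError("no nodes with incident productive segments")
    return float(allc.mean())


def geometry_summary(net: AstralNetwork) -> dict:
    """Per-network geometry summary row (CSV-ready)."""
    crosslinks = _crosslink_arrays(net)
    parts = network_partitions(net, crosslinks)
    dl = np.asarray([x for p in parts for x in p.dangling_lengths])
    ell = net.params.filament_length
    sub = dl[dl < ell - 1e-9]
    spn = segments_per_node(net, crosslinks)
    return {
        "a_n": net.params.astral_number,
        "rho_per_um": net.params.density,
        "seed": net.params.seed,
        "n_crosslinks": int(crosslinks["fil_i"].size),
        "mean_dangle_um": float(dl.mean()) if dl.size else np.nan,
        "mean_dangle_sub_l_um": float(sub.mean()) if sub.size else np.nan,
        "use_fraction": use_fraction(net, crosslinks),
        "mean_segments_per_node": spn.mean,
    }
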
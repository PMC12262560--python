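"""Random astral network generation and derived geometry.

An astral network is a collection of *asters*: radial assemblies of
``a_n`` straight filaments of common length ``ell`` emanating from a
central node.  Aster centers are placed uniformly at random in a square
domain of side ``s`` and filament orientations are uniform on
``[0, 2*pi)``.  With ``a_n = 1`` the model reduces to the classical
Mikado network of randomly thrown sticks.

Network density ``rho`` is the average filament length per unit area,

    rho = a_n * N_n * ell / s**2

where ``N_n`` is the number of asters.  Crosslinks are placed wherever
filaments from *distinct* asters intersect; two horizontal boundary
lines at ``y = 0`` and ``y = s`` stand in for the boundary filaments of
the mechanical model and their crossings are used by the spanning test.

All lengths are in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "ON_SEGMENT_TOL",
    "NetworkParams",
    "Aster",
    "AstralNetwork",
    "Crosslink",
    "density",
    "n_asters_for_density",
    "sample_network",
    "segment_intersection",
    "all_crosslinks",
    "crosslink_table",
]

#: tolerance for point-on-segment tests, in micrometres
ON_SEGMENT_TOL = 1e-9


def density(a_n: int, n_asters: int, ell: float, s: float) -> float:
    """Average filament length per unit area, ``a_n * N_n * ell / s**2``.

    ``n_asters = 0`` is allowed (empty network); all other arguments must
    be positive.
    """
    if a_n <= 0 or ell <= 0 or s <= 0 or n_asters < 0:
        raise ValueError(
            "a_n, ell, s must be positive and n_asters non-negative; got "
            f"a_n={a_n}, n_asters={n_asters}, ell={ell}, s={s}"
        )
    return a_n * n_asters * ell / s**2


def n_asters_for_density(rho: float, a_n: int, ell: float, s: float) -> int:
    """Number of asters whose realized density is closest to ``rho``.

    Nearest-integer rounding of ``rho * s**2 / (a_n * ell)``.
    """
    if rho < 0:
        raise ValueError(f"rho must be non-negative, got {rho}")
    if a_n <= 0 or ell <= 0 or s <= 0:
        raise ValueError("a_n, ell and s must be positive")
    return int(round(rho * s**2 / (a_n * ell)))


@dataclass(frozen=True)
class NetworkParams:
    """Parameters of a random astral network.

    Exactly one of ``density`` / ``n_asters`` may be given; the other is
    derived (``n_asters`` by nearest-integer rounding, after which the
    realized density is recomputed and stored in ``density``).
    """

    astral_number: int
    filament_length: float = 1.0
    domain_size: float = 10.0
    density: Optional[float] = None
    n_asters: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.astral_number < 1:
            raise ValueError(f"astral_number must be >= 1, got {self.astral_number}")
        if self.filament_length <= 0 or self.domain_size <= 0:
            raise ValueError("filament_length and domain_size must be positive")
        if (self.density is None) == (self.n_asters is None):
            raise ValueError("specify exactly one of density / n_asters")
        if self.n_asters is None:
            n = n_asters_for_density(
                self.density, self.astral_number, self.filament_length, self.domain_size
            )
            object.__setattr__(self, "n_asters", n)
        elif self.n_asters < 0:
            raise ValueError(f"n_asters must be non-negative, got {self.n_asters}")
        rho = density(
            self.astral_number, self.n_asters, self.filament_length, self.domain_size
        )
        object.__setattr__(self, "density", rho)

    @property
    def n_filaments(self) -> int:
        return self.astral_number * self.n_asters

    def to_dict(self) -> dict:
        return {
            "astral_number": self.astral_number,
            "filament_length": self.filament_length,
            "domain_size": self.domain_size,
            "n_asters": self.n_asters,
            "density": self.density,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(
            astral_number=d["astral_number"],
            filament_length=d["filament_length"],
            domain_size=d["domain_size"],
            n_asters=d["n_asters"],
            seed=d.get("seed", 0),
        )


@dataclass(frozen=True)
class Aster:
    """One aster: a center point and ``a_n`` filament orientations (rad)."""

    center: np.ndarray
    orientations: np.ndarray

    @property
    def astral_number(self) -> int:
        return len(self.orientations)


@dataclass
class AstralNetwork:
    """A sampled astral network.

    ``centers`` has shape ``(N_n, 2)`` and ``orientations`` shape
    ``(N_n, a_n)``.  Filaments are indexed globally by
    ``f = aster_index * a_n + k`` and run from the aster center to
    ``center + ell * (cos th, sin th)``; they may protrude beyond the
    (open, non-periodic) domain ``[0, s]**2``.
    """

    params: NetworkParams
    centers: np.ndarray
    orientations: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, 2)
        self.orientations = np.asarray(self.orientations, dtype=float)
        if self.orientations.ndim == 1:
            self.orientations = self.orientations.reshape(-1, 1)
        if self.centers.shape[0] != self.params.n_asters:
            raise ValueError("centers inconsistent with params.n_asters")
        if self.orientations.shape != (self.params.n_asters, self.params.astral_number):
            raise ValueError("orientations must have shape (n_asters, astral_number)")

    # -- derived geometry -------------------------------------------------
    @property
    def n_filaments(self) -> int:
        return self.params.n_filaments

    @property
    def asters(self) -> list[Aster]:
        return [
            Aster(center=self.centers[i].copy(), orientations=self.orientations[i].copy())
            for i in range(self.params.n_asters)
        ]

    @property
    def filament_aster(self) -> np.ndarray:
        """Aster index of each global filament, shape ``(F,)``."""
        return np.repeat(np.arange(self.params.n_asters), self.params.astral_number)

    @property
    def segment_starts(self) -> np.ndarray:
        """Filament center-ends, shape ``(F, 2)``."""
        return np.repeat(self.centers, self.params.astral_number, axis=0)

    @property
    def segment_ends(self) -> np.ndarray:
        th = self.orientations.ravel()
        ell = self.params.filament_length
        return self.segment_starts + ell * np.column_stack([np.cos(th), np.sin(th)])

    @property
    def total_filament_length(self) -> float:
        return self.params.n_filaments * self.params.filament_length

    def boundary_crossings(self) -> pd.DataFrame:
        """Crossings of filaments with the boundary lines y=0 and y=s.

        Geometric mode: the boundaries are the full lines, not segments.
        Returns a DataFrame with columns (boundary, filament, aster, x, y,
        arc) where ``arc`` is the distance from the filament's center end.
        """
        starts, ends = self.segment_starts, self.segment_ends
        ell = self.params.filament_length
        rows = []
        for tag, yb in (("bottom", 0.0), ("top", self.params.domain_size)):
            y0, y1 = starts[:, 1], ends[:, 1]
            dy = y1 - y0
            with np.errstate(divide="ignore", invalid="ignore"):
                t = (yb - y0) / dy
            mask = (np.abs(dy) > 0) & (t >= 0.0) & (t <= 1.0)
            idx = np.nonzero(mask)[0]
            x = starts[idx, 0] + t[idx] * (ends[idx, 0] - starts[idx, 0])
            rows.append(
                pd.DataFrame(
                    {
                        "boundary": tag,
                        "filament": idx,
                        "aster": self.filament_aster[idx],
                        "x": x,
                        "y": yb,
                        "arc": t[idx] * ell,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "params": self.params.to_dict(),
                "centers": self.centers.tolist(),
                "orientations": self.orientations.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "AstralNetwork":
        d = json.loads(text)
        return cls(
            params=NetworkParams.from_dict(d["params"]),
            centers=np.asarray(d["centers"], dtype=float),
            orientations=np.asarray(d["orientations"], dtype=float),
        )


@dataclass(frozen=True)
class Crosslink:
    """An intersection point of two filaments from distinct asters.

    ``members`` holds two ``(aster, filament)`` pairs, or one pair and a
    boundary tag (``"bottom"``/``"top"``) for boundary-line crossings.
    ``arc_coords`` are distances of the point from each filament's center
    end (a single value for boundary crossings).
    """

    position: tuple[float, float]
    members: tuple
    arc_coords: tuple


def sample_network(
    params: NetworkParams, rng: Optional[np.random.Generator] = None
) -> AstralNetwork:
    """Draw a random astral network: centers i.i.d. uniform on the domain,
    orientations i.i.d. uniform on ``[0, 2*pi)``.  Deterministic for a
    fixed ``params.seed`` (unless an explicit ``rng`` is passed).
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    s = params.domain_size
    centers = rng.uniform(0.0, s, size=(params.n_asters, 2))
    orientations = rng.uniform(0.0, 2.0 * np.pi, size=(params.n_asters, params.astral_number))
    return AstralNetwork(params=params, centers=centers, orientations=orientations)


def segment_intersection(a0, a1, b0, b1, tol: float = ON_SEGMENT_TOL):
    """Intersection point of segments a0-a1 and b0-b1, or ``None``.

    Returns the unique interior/endpoint intersection; parallel and
    collinear-overlapping segments return ``None`` (overlap has measure
    zero under continuous sampling).  Zero-length segments raise.
    """
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    b0 = np.asarray(b0, dtype=float)
    b1 = np.asarray(b1, dtype=float)
    da, db = a1 - a0, b1 - b0
    la, lb = np.hypot(*da), np.hypot(*db)
    if la == 0.0 or lb == 0.0:
        raise ValueError("degenerate zero-length segment")
    denom = da[0] * db[1] - da[1] * db[0]
    if abs(denom) <= 1e-14 * la * lb:  # parallel or collinear
        return None
    d = b0 - a0
    t = (d[0] * db[1] - d[1] * db[0]) / denom
    u = (d[0] * da[1] - d[1] * da[0]) / denom
    ta, tb = tol / la, tol / lb
    if -ta <= t <= 1.0 + ta and -tb <= u <= 1.0 + tb:
        return a0 + t * da
    return None


def _crosslink_arrays(net: AstralNetwork, tol: float = ON_SEGMENT_TOL) -> dict:
    """All pairwise filament intersections between distinct asters.

    Vectorized over filament pairs; returns a dict of flat arrays:
    points (M,2), aster_i/j, fil_i/j (global filament indices, i < j),
    arc_i/j (distance from each filament's center end).
    """
    starts = net.segment_starts
    F = starts.shape[0]
    empty = dict(
        points=np.empty((0, 2)),
        aster_i=np.empty(0, dtype=int),
        aster_j=np.empty(0, dtype=int),
        fil_i=np.empty(0, dtype=int),
        fil_j=np.empty(0, dtype=int),
        arc_i=np.empty(0),
        arc_j=np.empty(0),
    )
    if F < 2:
        return empty
    ends = net.segment_ends
    d = ends - starts
    ell = net.params.filament_length
    aster = net.filament_aster
    t_tol = tol / ell

    # candidate pairs: midpoints of two intersecting length-ell segments
    # are at most ell apart, so a KD-tree radius query is exact pruning
    mid = 0.5 * (starts + ends)
    tree = cKDTree(mid)
    cand = tree.query_pairs(r=ell + tol, output_type="ndarray")
    if cand.size == 0:
        return empty
    fi0, fj0 = cand[:, 0], cand[:, 1]
    keep = aster[fi0] != aster[fj0]
    fi0, fj0 = fi0[keep], fj0[keep]

    di, dj = d[fi0], d[fj0]
    denom = di[:, 0] * dj[:, 1] - di[:, 1] * dj[:, 0]
    dd = starts[fj0] - starts[fi0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (dd[:, 0] * dj[:, 1] - dd[:, 1] * dj[:, 0]) / denom
        u = (dd[:, 0] * di[:, 1] - dd[:, 1] * di[:, 0]) / denom
    hit = (
        (np.abs(denom) > 1e-15)
        & (t >= -t_tol)
        & (t <= 1.0 + t_tol)
        & (u >= -t_tol)
        & (u <= 1.0 + t_tol)
    )
    fi, fj = fi0[hit], fj0[hit]
    ti = np.clip(t[hit], 0.0, 1.0)
    tj = np.clip(u[hit], 0.0, 1.0)
    if fi.size == 0:
        return empty
    pts = starts[fi] + ti[:, None] * d[fi]
    return dict(
        points=pts,
        aster_i=aster[fi],
        aster_j=aster[fj],
        fil_i=fi,
        fil_j=fj,
        arc_i=ti * ell,
        arc_j=tj * ell,
    )


def all_crosslinks(net: AstralNetwork, include_boundaries: bool = False) -> list[Crosslink]:
    """One :class:`Crosslink` per intersecting filament pair from distinct
    asters (filaments of the same aster meet only at the center and never
    contribute).  With ``include_boundaries``, filament crossings of the
    boundary lines y=0 and y=s are appended with a boundary tag.
    """
    arr = _crosslink_arrays(net)
    a_n = net.params.astral_number
    links = [
        Crosslink(
            position=(float(arr["points"][m, 0]), float(arr["points"][m, 1])),
            members=(
                (int(arr["aster_i"][m]), int(arr["fil_i"][m] % a_n)),
                (int(arr["aster_j"][m]), int(arr["fil_j"][m] % a_n)),
            ),
            arc_coords=(float(arr["arc_i"][m]), float(arr["arc_j"][m])),
        )
        for m in range(arr["fil_i"].size)
    ]
    if include_boundaries:
        bc = net.boundary_crossings()
        for row in bc.itertuples(index=False):
            links.append(
                Crosslink(
                    position=(float(row.x), float(row.y)),
                    members=((int(row.aster), int(row.filament) % a_n), row.boundary),
                    arc_coords=(float(row.arc),),
                )
            )
    return links


def crosslink_table(net: AstralNetwork) -> pd.DataFrame:
    """Inter-aster crosslinks as a DataFrame (CSV-ready)."""
    arr = _crosslink_arrays(net)
    a_n = net.params.astral_number
    return pd.DataFrame(
        {
            "x_um": arr["points"][:, 0],
            "y_um": arr["points"][:, 1],
            "aster_i": arr["aster_i"],
            "fil_i": arr["fil_i"] % a_n,
            "aster_j": arr["aster_j"],
            "fil_j": arr["fil_j"] % a_n,
            "arc_i_um": arr["arc_i"],
            "arc_j_um": arr["arc_j"],
        }
    )
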
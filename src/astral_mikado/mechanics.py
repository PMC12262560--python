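"""Overdamped mechanics of crosslinked astral networks.

Filaments are inextensible chains of vertices (segmentation 0.2 um)
with discrete bending elasticity, asters tie their
filaments to a rigid central body by two springs, crosslinkers diffuse,
bind irreversibly and become zero-rest-length Hookean springs, and two
stiff horizontal boundary filaments transmit/resist the applied load.

The update is semi-implicit: all Hookean link forces and bending forces
are treated implicitly (backward Euler on the linear part), aster-body
rotation and crosslinker binding are explicit, and filament
inextensibility is restored after each step by iterative length
projection.  Because every implicit term is isotropic, the system matrix
factors into one scalar sparse matrix applied to the x and y coordinate
columns; the factorization is cached and reused until the topology
(bindings, anchors) changes.

Units: um, pN, s throughout.

The experiment protocol has two phases: a crosslinking phase (default
5 s) with both boundary filaments anchored and no external force, and a
force phase (default 40 s) with the top anchors removed and a constant
force applied to the top boundary filament (rightward at its right end
for shear; upward, split between both ends, for tension).  The network
center-of-mass displacement between the ends of the two phases is the
measured response; boundary filaments are excluded from it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import factorized
from scipy.spatial import cKDTree

from .netgen import AstralNetwork

__all__ = [
    "MechParams",
    "Protocol",
    "MechState",
    "ExperimentResult",
    "discretize",
    "step",
    "relax",
    "simulate_crosslinking",
    "prepare_state",
    "run_force_phase",
    "run_experiment",
    "make_chain_state",
]


@dataclass(frozen=True)
class MechParams:
    """Biophysical and numerical parameters of the mechanical model.

    Defaults are the model's reference parameter set (stiffnesses in
    pN/um, rigidities in pN um^2, viscosity in pN s/um^2).
    """

    k_bend: float = 20.0                     # filament bending rigidity
    aster_center_stiffness: float = 1000.0   # spring #1: filament end -> center
    aster_rot_stiffness: float = 500.0       # spring #2: resists rotation
    aster_rot_arm: float = 0.3               # spring #2 acts this far from center
    crosslink_stiffness: float = 100.0
    binding_rate: float = 10.0               # 1/s
    binding_range: float = 0.01              # um
    crosslink_diffusivity: float = 10.0      # um^2/s
    boundary_rigidity_shear: float = 1e3
    boundary_rigidity_tensile: float = 1e6
    anchor_stiffness: float = 1e3
    anchor_spacing: float = 1.0
    viscosity: float = 0.01
    dt: float = 0.01
    segmentation: float = 0.2
    boundary_segmentation: float = 0.5
    crosslinkers_per_filament: int = 30
    boundary_linker_density: float = 10.0    # particles per um of boundary
    kT: float = 0.0042                       # pN um, used only when thermal noise is on
    thermal: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in (
            "k_bend",
            "aster_center_stiffness",
            "aster_rot_stiffness",
            "crosslink_stiffness",
            "anchor_stiffness",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_yaml(self, path) -> None:
        import dataclasses

        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "MechParams":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class Protocol:
    """Loading protocol: mode, force magnitude and phase durations.

    Shear: the full force ``F`` acts rightward on the right-hand end
    vertex of the top boundary filament.  Tensile: ``F/2`` acts upward on
    each end vertex of the top boundary filament.
    """

    mode: str  # {"shear", "tensile"}
    force: float  # pN
    t_crosslink: float = 5.0
    t_force: float = 40.0

    def __post_init__(self) -> None:
        if self.mode not in ("shear", "tensile"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class _Chains:
    """A group of equal-length vertex chains (contiguous in the state)."""

    start: int          # first vertex index
    n_chains: int
    n_vertices: int     # per chain
    h: float            # segment length
    kappa: float        # bending rigidity

    @property
    def stop(self) -> int:
        return self.start + self.n_chains * self.n_vertices

    def view(self, xy: np.ndarray) -> np.ndarray:
        return xy[self.start : self.stop].reshape(self.n_chains, self.n_vertices, 2)


@dataclass
class MechState:
    """Discretized mechanical state of one network experiment."""

    xy: np.ndarray                 # (V, 2) vertex coordinates
    gamma: np.ndarray              # (V,) per-vertex drag, pN s/um
    groups: list                   # list[_Chains]; [0] = network filaments
    # aster bodies
    aster_centers: np.ndarray      # (A, 2)
    aster_angles: np.ndarray       # (A,) body rotation from reference frame
    aster_ref_angles: np.ndarray   # (A, a_n) reference filament orientations
    gamma_center: float
    # crosslink springs: attachment p = (1-w) xy[i] + w xy[i+1]
    spring_i: np.ndarray           # (S,) base vertex index, filament a
    spring_wi: np.ndarray
    spring_j: np.ndarray
    spring_wj: np.ndarray
    # anchors (Hookean pins)
    anchor_idx: np.ndarray
    anchor_pos: np.ndarray
    anchor_k: np.ndarray
    # applied constant forces
    force_idx: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    force_vec: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    # crosslinker particles (populated by discretize, consumed by binding)
    linker_free: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    linker_single: list = field(default_factory=list)  # (fil, arc, t_double, partners)
    t: float = 0.0
    pinned: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    topology_version: int = 0
    _ops: dict = field(default_factory=dict, repr=False)

    # -- bookkeeping ------------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return self.xy.shape[0]

    @property
    def n_asters(self) -> int:
        return self.aster_centers.shape[0]

    @property
    def network_group(self) -> _Chains:
        return self.groups[0]

    def filament_point(self, fil: int, arc: float) -> tuple[int, float]:
        """(base vertex index, interpolation weight) for an arc position
        on network filament ``fil``."""
        g = self.network_group
        k = min(int(arc / g.h), g.n_vertices - 2)
        w = arc / g.h - k
        return g.start + fil * g.n_vertices + k, float(np.clip(w, 0.0, 1.0))

    def copy(self) -> "MechState":
        new = copy.copy(self)
        for name in (
            "xy",
            "aster_centers",
            "aster_angles",
            "force_idx",
            "force_vec",
            "anchor_idx",
            "anchor_pos",
            "anchor_k",
        ):
            setattr(new, name, getattr(self, name).copy())
        new._ops = self._ops  # factorizations are immutable; share
        return new

    def invalidate(self) -> None:
        self.topology_version += 1

    # -- energies (diagnostics) ------------------------------------------
    def bending_energy(self) -> float:
        e = 0.0
        for g in self.groups:
            p = g.view(self.xy)
            if g.n_vertices < 3:
                continue
            d2 = p[:, 2:] - 2.0 * p[:, 1:-1] + p[:, :-2]
            e += 0.5 * g.kappa / g.h**3 * float(np.sum(d2**2))
        return e

    def spring_energy(self, k_crosslink: float) -> float:
        pa = (1 - self.spring_wi)[:, None] * self.xy[self.spring_i] + self.spring_wi[
            :, None
        ] * self.xy[self.spring_i + 1]
        pb = (1 - self.spring_wj)[:, None] * self.xy[self.spring_j] + self.spring_wj[
            :, None
        ] * self.xy[self.spring_j + 1]
        return 0.5 * k_crosslink * float(np.sum((pa - pb) ** 2))

    def anchor_energy(self) -> float:
        d = self.xy[self.anchor_idx] - self.anchor_pos
        return 0.5 * float(np.sum(self.anchor_k[:, None] * d**2))

    def aster_energy(self, mech: "MechParams") -> float:
        e = 0.0
        if self.n_asters == 0:
            return e
        g = self.network_group
        a_n = self.aster_ref_angles.shape[1]
        first = g.start + np.arange(self.n_asters * a_n) * g.n_vertices
        ends = self.xy[first].reshape(self.n_asters, a_n, 2)
        e += 0.5 * mech.aster_center_stiffness * float(
            np.sum((ends - self.aster_centers[:, None, :]) ** 2)
        )
        if mech.aster_rot_stiffness > 0:
            r = mech.aster_rot_arm
            ib, wb = self._rot_attach(g, r)
            p = (1 - wb) * self.xy[ib] + wb * self.xy[ib + 1]
            p = p.reshape(self.n_asters, a_n, 2)
            th = self.aster_ref_angles + self.aster_angles[:, None]
            anchors = self.aster_centers[:, None, :] + r * np.stack(
                [np.cos(th), np.sin(th)], axis=-1
            )
            e += 0.5 * mech.aster_rot_stiffness * float(np.sum((p - anchors) ** 2))
        return e

    def _rot_attach(self, g: _Chains, r: float):
        nf = self.n_asters * self.aster_ref_angles.shape[1]
        k = min(int(r / g.h), g.n_vertices - 2)
        w = r / g.h - k
        ib = g.start + np.arange(nf) * g.n_vertices + k
        return ib[:, None], w

    def total_energy(self, mech: "MechParams") -> float:
        """Elastic energy minus work of the applied forces (potential)."""
        work = float(np.sum(self.force_vec * self.xy[self.force_idx]))
        return (
            self.bending_energy()
            + self.spring_energy(mech.crosslink_stiffness)
            + self.anchor_energy()
            + self.aster_energy(mech)
            - work
        )


# ---------------------------------------------------------------------------
# construction


def discretize(
    net: AstralNetwork,
    mech: MechParams,
    mode: str = "shear",
    rng: Optional[np.random.Generator] = None,
) -> MechState:
    """Discretize a sampled network into a mechanical state.

    Network filaments become straight chains at ``mech.segmentation``;
    two boundary filaments (chains at ``mech.boundary_segmentation``,
    rigidity by ``mode``) are appended at y=0 and y=s, with anchors every
    ``anchor_spacing`` along both.  Crosslinker particles are seeded
    uniformly: ``crosslinkers_per_filament x n_filaments`` in the bulk
    plus ``boundary_linker_density x s`` near each boundary filament.
    """
    if rng is None:
        rng = np.random.default_rng(net.params.seed)
    ell, s = net.params.filament_length, net.params.domain_size
    nseg = int(round(ell / mech.segmentation))
    if abs(nseg * mech.segmentation - ell) > 1e-9:
        raise ValueError("segmentation must divide the filament length")
    h = ell / nseg
    nf = net.n_filaments
    nv = nseg + 1

    starts = net.segment_starts
    th = net.orientations.ravel()
    u = np.column_stack([np.cos(th), np.sin(th)])
    arc = np.arange(nv) * h
    fil_xy = (starts[:, None, :] + arc[None, :, None] * u[:, None, :]).reshape(nf * nv, 2)

    nbseg = int(round(s / mech.boundary_segmentation))
    hb = s / nbseg
    nbv = nbseg + 1
    xb = np.arange(nbv) * hb
    bot = np.column_stack([xb, np.zeros(nbv)])
    top = np.column_stack([xb, np.full(nbv, s)])

    xy = np.vstack([fil_xy, bot, top])
    kb = (
        mech.boundary_rigidity_shear if mode == "shear" else mech.boundary_rigidity_tensile
    )
    groups = [
        _Chains(start=0, n_chains=nf, n_vertices=nv, h=h, kappa=mech.k_bend),
        _Chains(start=nf * nv, n_chains=2, n_vertices=nbv, h=hb, kappa=kb),
    ]

    # drag: filament drag nu per unit length, end vertices carry half shares
    def chain_gamma(n, hseg):
        g = np.full(n, mech.viscosity * hseg)
        g[[0, -1]] = mech.viscosity * hseg / 2.0
        return g

    gamma = np.concatenate(
        [np.tile(chain_gamma(nv, h), nf), np.tile(chain_gamma(nbv, hb), 2)]
    )

    # anchors on both boundary filaments (top ones removed at force onset)
    every = max(1, int(round(mech.anchor_spacing / hb)))
    rel = np.arange(0, nbv, every)
    bstart = nf * nv
    anchor_idx = np.concatenate([bstart + rel, bstart + nbv + rel])
    anchor_pos = xy[anchor_idx].copy()
    anchor_k = np.full(anchor_idx.size, mech.anchor_stiffness)

    # crosslinker particles
    n_bulk = mech.crosslinkers_per_filament * nf
    bulk = rng.uniform(0.0, s, size=(n_bulk, 2))
    n_b = int(round(mech.boundary_linker_density * s))
    near = []
    for yb in (0.0, s):
        pts = np.column_stack(
            [rng.uniform(0.0, s, n_b), yb + rng.uniform(-0.05, 0.05, n_b)]
        )
        near.append(pts)
    linker_free = np.vstack([bulk] + near)

    state = MechState(
        xy=xy,
        gamma=gamma,
        groups=groups,
        aster_centers=net.centers.copy(),
        aster_angles=np.zeros(net.params.n_asters),
        aster_ref_angles=net.orientations.copy(),
        gamma_center=mech.viscosity * 0.1,
        spring_i=np.empty(0, dtype=int),
        spring_wi=np.empty(0),
        spring_j=np.empty(0, dtype=int),
        spring_wj=np.empty(0),
        anchor_idx=anchor_idx,
        anchor_pos=anchor_pos,
        anchor_k=anchor_k,
        linker_free=linker_free,
    )
    return state


def make_chain_state(
    points: np.ndarray,
    mech: MechParams,
    kappa: Optional[float] = None,
    pinned: Optional[list] = None,
) -> MechState:
    """Build a bare state from explicit chains (testing/oracle helper).

    ``points`` has shape (n_chains, n_vertices, 2) with equal segment
    lengths; ``pinned`` vertices are clamped (immobile).
    """
    points = np.asarray(points, dtype=float)
    nc, nv, _ = points.shape
    seg = np.linalg.norm(np.diff(points, axis=1), axis=2)
    h = float(seg.flat[0])
    if not np.allclose(seg, h, atol=1e-9):
        raise ValueError("chains must have uniform segment length")
    gamma = np.tile(
        np.concatenate([[0.5], np.ones(nv - 2), [0.5]]) * mech.viscosity * h, nc
    )
    state = MechState(
        xy=points.reshape(nc * nv, 2).copy(),
        gamma=gamma,
        groups=[_Chains(0, nc, nv, h, kappa if kappa is not None else mech.k_bend)],
        aster_centers=np.empty((0, 2)),
        aster_angles=np.empty(0),
        aster_ref_angles=np.empty((0, 1)),
        gamma_center=mech.viscosity * 0.1,
        spring_i=np.empty(0, dtype=int),
        spring_wi=np.empty(0),
        spring_j=np.empty(0, dtype=int),
        spring_wj=np.empty(0),
        anchor_idx=np.empty(0, dtype=int),
        anchor_pos=np.empty((0, 2)),
        anchor_k=np.empty(0),
    )
    if pinned:
        state.pinned = np.asarray(pinned, dtype=int)
        state.gamma = state.gamma.copy()
        state.gamma[state.pinned] = 1e12  # effectively immobile
    return state


# ---------------------------------------------------------------------------
# implicit operator


def _assemble(state: MechState, mech: MechParams, dt: float):
    """Scalar system matrix A = diag(gamma)/dt + K and its factorization.

    K collects every isotropic quadratic term: bending, crosslink
    springs, anchors and the aster springs; the same scalar matrix acts
    on the x and y coordinate columns.
    """
    V = state.n_vertices
    A = state.n_asters
    n = V + A
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(np.asarray(i).ravel())
        cols.append(np.asarray(j).ravel())
        vals.append(np.asarray(v).ravel())

    # bending: (kappa/h^3) D2^T D2 per chain
    for g in state.groups:
        if g.n_vertices < 3 or g.kappa == 0:
            continue
        nvv = g.n_vertices
        base = g.start + np.arange(g.n_chains)[:, None] * nvv
        idx = base + np.arange(nvv)[None, :]  # (C, nv)
        c = g.kappa / g.h**3
        # D2 rows: vertices (k, k+1, k+2) with stencil (1, -2, 1)
        k = np.arange(nvv - 2)
        trip = np.stack([idx[:, k], idx[:, k + 1], idx[:, k + 2]], axis=-1)  # (C,R,3)
        st = np.array([1.0, -2.0, 1.0])
        for a in range(3):
            for b in range(3):
                add(trip[..., a], trip[..., b], np.full(trip.shape[:2], c * st[a] * st[b]))

    # generalized springs: k * u u^T with sparse weight vector u
    def add_spring_rows(idxs, wts, k):
        # idxs, wts: (S, m) arrays; energy k/2 (sum w x)^2
        S, m = idxs.shape
        for a in range(m):
            for b in range(m):
                add(idxs[:, a], idxs[:, b], k * wts[:, a] * wts[:, b])

    if state.spring_i.size:
        idxs = np.column_stack(
            [state.spring_i, state.spring_i + 1, state.spring_j, state.spring_j + 1]
        )
        wts = np.column_stack(
            [1 - state.spring_wi, state.spring_wi, -(1 - state.spring_wj), -state.spring_wj]
        )
        add_spring_rows(idxs, wts, mech.crosslink_stiffness)

    if state.anchor_idx.size:
        add(state.anchor_idx, state.anchor_idx, state.anchor_k)

    if A:
        g = state.network_group
        a_n = state.aster_ref_angles.shape[1]
        nf = A * a_n
        first = g.start + np.arange(nf) * g.n_vertices
        centers = V + np.repeat(np.arange(A), a_n)
        # spring #1: filament first vertex <-> center
        idxs = np.column_stack([first, centers])
        wts = np.tile(np.array([1.0, -1.0]), (nf, 1))
        add_spring_rows(idxs, wts, mech.aster_center_stiffness)
        # spring #2: filament point at the rotation arm <-> body anchor
        if mech.aster_rot_stiffness > 0:
            ib, w = state._rot_attach(g, mech.aster_rot_arm)
            idxs = np.column_stack([ib.ravel(), ib.ravel() + 1, centers])
            wts = np.tile(np.array([1.0 - w, w, -1.0]), (nf, 1))
            add_spring_rows(idxs, wts, mech.aster_rot_stiffness)

    gam = np.concatenate([state.gamma, np.full(A, state.gamma_center)])
    add(np.arange(n), np.arange(n), gam / dt)
    K = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsc()
    return factorized(K), gam


def _get_ops(state: MechState, mech: MechParams, dt: float):
    fp = (
        mech.k_bend,
        mech.crosslink_stiffness,
        mech.aster_center_stiffness,
        mech.aster_rot_stiffness,
        mech.anchor_stiffness,
    )
    key = (round(dt, 12), state.topology_version, state.anchor_idx.size, fp)
    ops = state._ops.get("solver")
    if ops is None or ops[0] != key:
        solver, gam = _assemble(state, mech, dt)
        state._ops["solver"] = (key, solver, gam)
    return state._ops["solver"][1], state._ops["solver"][2]


# ---------------------------------------------------------------------------
# stepping


def _tridiag_solve(lower, diag, upper, rhs):
    """Thomas algorithm, vectorized over leading (chain) axis."""
    n = diag.shape[1]
    cp = np.empty_like(diag)
    dp = np.empty_like(rhs)
    cp[:, 0] = upper[:, 0] / diag[:, 0]
    dp[:, 0] = rhs[:, 0] / diag[:, 0]
    for j in range(1, n):
        m = diag[:, j] - lower[:, j] * cp[:, j - 1]
        cp[:, j] = upper[:, j] / m if j < n - 1 else 0.0
        dp[:, j] = (rhs[:, j] - lower[:, j] * dp[:, j - 1]) / m
    x = np.empty_like(rhs)
    x[:, -1] = dp[:, -1]
    for j in range(n - 2, -1, -1):
        x[:, j] = dp[:, j] - cp[:, j] * x[:, j + 1]
    return x


def _project_inextensible(state: MechState, tol: float = 1e-9, max_iter: int = 50) -> None:
    """Restore segment lengths by drag-weighted constraint projection.

    Newton iteration on the length constraints; each iteration solves the
    tridiagonal system J W J^T lambda = -c per chain (W = inverse drag)
    and applies the correction W J^T lambda, vectorized across chains.
    """
    for g in state.groups:
        if g.n_vertices < 2:
            continue
        p = g.view(state.xy)
        gam = state.gamma[g.start : g.stop].reshape(g.n_chains, g.n_vertices)
        w = np.where(gam >= 1e11, 0.0, 1.0 / gam)  # pinned vertices immobile
        m = g.n_vertices - 1
        frozen = (w[:, :-1] == 0.0) & (w[:, 1:] == 0.0)
        for it in range(max_iter):
            d = p[:, 1:] - p[:, :-1]
            L = np.linalg.norm(d, axis=2)
            c = np.where(frozen, 0.0, L - g.h)
            if float(np.max(np.abs(c), initial=0.0)) < tol:
                break
            n_hat = d / np.maximum(L, 1e-12)[:, :, None]
            diag = np.where(frozen, 1.0, w[:, :-1] + w[:, 1:])
            dots = np.einsum("cjk,cjk->cj", n_hat[:, :-1], n_hat[:, 1:])
            lower = np.zeros_like(diag)
            upper = np.zeros_like(diag)
            if m > 1:
                off = -w[:, 1:-1] * dots
                upper[:, :-1] = off
                lower[:, 1:] = off
            lam = _tridiag_solve(lower, diag, upper, -c)
            imp = lam[:, :, None] * n_hat  # impulse on each segment
            p[:, :-1] -= w[:, :-1, None] * imp
            p[:, 1:] += w[:, 1:, None] * imp
        else:
            d = np.linalg.norm(np.diff(p, axis=1), axis=2) - g.h
            raise RuntimeError(
                f"inextensibility projection did not converge in {max_iter} "
                f"iterations (max violation {np.max(np.abs(d)):.3g} um)"
            )
        state.xy[g.start : g.stop] = p.reshape(-1, 2)


def step(
    state: MechState,
    mech: MechParams,
    dt: Optional[float] = None,
    thermal: Optional[bool] = None,
    rng: Optional[np.random.Generator] = None,
    bind: bool = True,
) -> MechState:
    """Advance the state by one semi-implicit overdamped step (in place).

    Implicit in bending and all Hookean links; explicit in applied and
    Brownian forces, aster-body rotation and crosslinker binding.
    Returns ``state`` for chaining.
    """
    if dt is None:
        dt = mech.dt
    if thermal is None:
        thermal = mech.thermal
    if (thermal or bind) and rng is None:
        rng = np.random.default_rng(0)
    solver, gam = _get_ops(state, mech, dt)

    V, A = state.n_vertices, state.n_asters
    b = np.zeros((V + A, 2))
    if state.anchor_idx.size:
        b[state.anchor_idx] += state.anchor_k[:, None] * state.anchor_pos
    if state.force_idx.size:
        np.add.at(b, state.force_idx, state.force_vec)
    if A and mech.aster_rot_stiffness > 0:
        g = state.network_group
        a_n = state.aster_ref_angles.shape[1]
        th = (state.aster_ref_angles + state.aster_angles[:, None]).ravel()
        off = mech.aster_rot_arm * np.column_stack([np.cos(th), np.sin(th)])
        ib, w = state._rot_attach(g, mech.aster_rot_arm)
        ib = ib.ravel()
        centers = V + np.repeat(np.arange(A), a_n)
        k2 = mech.aster_rot_stiffness
        np.add.at(b, ib, (1.0 - w) * k2 * off)
        np.add.at(b, ib + 1, w * k2 * off)
        np.add.at(b, centers, -k2 * off)
    if thermal and mech.kT > 0:
        b += np.sqrt(2.0 * mech.kT * gam[:, None] / dt) * rng.standard_normal((V + A, 2))

    X = np.concatenate([state.xy, state.aster_centers]) if A else state.xy
    rhs = (gam / dt)[:, None] * X + b
    Xn = np.column_stack([solver(rhs[:, 0]), solver(rhs[:, 1])])
    state.xy = Xn[:V]
    if A:
        state.aster_centers = Xn[V:]

    _project_inextensible(state)

    # aster-body rotation: quasi-static torque balance (the body angle has
    # no inertia and relaxes far faster than filament positions do).  The
    # zero-torque angle maximizes sum_f u_f(phi) . (p_f - c), giving a
    # closed form via the rotated-reference projections.
    if A and mech.aster_rot_stiffness > 0:
        g = state.network_group
        a_n = state.aster_ref_angles.shape[1]
        ib, w = state._rot_attach(g, mech.aster_rot_arm)
        p = ((1 - w) * state.xy[ib.ravel()] + w * state.xy[ib.ravel() + 1]).reshape(
            A, a_n, 2
        )
        d = p - state.aster_centers[:, None, :]
        ct = np.cos(state.aster_ref_angles)
        stn = np.sin(state.aster_ref_angles)
        C = np.sum(ct * d[..., 0] + stn * d[..., 1], axis=1)
        S = np.sum(ct * d[..., 1] - stn * d[..., 0], axis=1)
        state.aster_angles = np.arctan2(S, C)

    if bind:
        _update_linkers(state, mech, dt, rng)
    state.t += dt
    return state


# ---------------------------------------------------------------------------
# crosslinker binding


def _segment_distance_arc(p, a0, u, ell):
    """Distance from point(s) p to segment a0 + t*u (|u|=1, t in [0, ell])
    and the clamped arc coordinate."""
    d = p - a0
    t = np.clip(d @ u, 0.0, ell)
    foot = a0 + t[..., None] * u
    return np.linalg.norm(p - foot, axis=-1), t


def _update_linkers(state, mech, dt, rng):
    """Diffuse free crosslinkers and perform irreversible binding.

    Particles bind the nearest filament within the binding range at rate
    ``binding_rate`` (first one filament, then a second distinct one at
    the projection of the attachment point).  Geometry is taken from the
    cached straight-filament description built at seeding time; once a
    particle is doubly bound it becomes a Hookean spring.
    """
    geo = state._ops.get("linker_geo")
    if geo is None:
        return
    starts, units, ell, tree, pts_fil, box = geo

    p_bind = 1.0 - np.exp(-mech.binding_rate * dt)

    # second binding: scheduled exponential waiting times (geometry static)
    if state.linker_single:
        remaining = []
        for fil, arc, t_double, partners in state.linker_single:
            if not partners:
                continue
            if state.t >= t_double:
                fb, arcb = partners[0]
                state.add_spring_any(fil, arc, fb, arcb)
            else:
                remaining.append((fil, arc, t_double, partners))
        state.linker_single = remaining

    if state.linker_free.shape[0] == 0:
        return
    sig = np.sqrt(2.0 * mech.crosslink_diffusivity * dt)
    pos = state.linker_free + sig * rng.standard_normal(state.linker_free.shape)
    lo, hi = box
    pos = np.where(pos < lo, 2 * lo - pos, pos)
    pos = np.where(pos > hi, 2 * hi - pos, pos)
    state.linker_free = pos

    # candidates: near a sample point AND passing the rate draw; exact
    # point-segment distances are evaluated only for those few
    dist, _ = tree.query(pos, k=1, distance_upper_bound=mech.binding_range + 0.026)
    cand = np.nonzero(np.isfinite(dist) & (rng.random(pos.shape[0]) < p_bind))[0]
    if cand.size == 0:
        return
    bound_mask = np.zeros(pos.shape[0], dtype=bool)
    for i in cand:
        best = None
        for k in tree.query_ball_point(pos[i], r=mech.binding_range + 0.026):
            fil = int(pts_fil[k])
            dseg, arc = _segment_distance_arc(pos[i], starts[fil], units[fil], ell[fil])
            if dseg <= mech.binding_range and (best is None or dseg < best[0]):
                best = (float(dseg), fil, float(arc))
        if best is not None:
            bound_mask[i] = True
            _bind_first(state, mech, rng, pos[i], best[1], best[2], geo)
    if bound_mask.any():
        state.linker_free = state.linker_free[~bound_mask]


def _bind_first(state, mech, rng, p, fil, arc, geo):
    """Attach a particle to its first filament and enumerate partners."""
    starts, units, ell, tree, pts_fil, _ = geo
    attach = starts[fil] + arc * units[fil]
    # partner filaments within range of the attachment point
    near = tree.query_ball_point(attach, r=mech.binding_range + 0.06)
    partners = []
    seen = set()
    for k in near:
        f2 = int(pts_fil[k])
        if f2 == fil or f2 in seen:
            continue
        seen.add(f2)
        d2, arc2 = _segment_distance_arc(attach, starts[f2], units[f2], ell[f2])
        if d2 <= mech.binding_range:
            partners.append((d2, f2, float(arc2)))
    partners.sort()
    t_double = state.t + rng.exponential(1.0 / mech.binding_rate) if partners else np.inf
    state.linker_single.append(
        (fil, arc, t_double, [(f, a) for _, f, a in partners])
    )


# helpers used by binding that must address both network and boundary chains
def _global_chain_point(state: MechState, fil: int, arc: float) -> tuple[int, float]:
    """(base vertex, weight) for 'extended filament index' fil, where
    network filaments come first and the two boundary filaments last."""
    g = state.network_group
    if fil < g.n_chains:
        return state.filament_point(fil, arc)
    gb = state.groups[1]
    k = fil - g.n_chains
    kk = min(int(arc / gb.h), gb.n_vertices - 2)
    w = arc / gb.h - kk
    return gb.start + k * gb.n_vertices + kk, float(np.clip(w, 0.0, 1.0))


def _add_spring_ext(state: MechState, fil_a: int, arc_a: float, fil_b: int, arc_b: float):
    ia, wa = _global_chain_point(state, fil_a, arc_a)
    ib, wb = _global_chain_point(state, fil_b, arc_b)
    state.spring_i = np.append(state.spring_i, ia)
    state.spring_wi = np.append(state.spring_wi, wa)
    state.spring_j = np.append(state.spring_j, ib)
    state.spring_wj = np.append(state.spring_wj, wb)
    state.topology_version += 1


MechState.filament_point_any = _global_chain_point
MechState.add_spring_any = lambda self, fa, aa, fb, ab, mech=None: _add_spring_ext(
    self, fa, aa, fb, ab
)


def _build_linker_geometry(state: MechState, net: AstralNetwork, mech: MechParams):
    """Straight-filament geometry + KD-tree used during the crosslinking
    phase (filaments are effectively stationary while binding happens)."""
    s = net.params.domain_size
    starts = np.vstack(
        [net.segment_starts, [[0.0, 0.0]], [[0.0, s]]]
    )
    th = net.orientations.ravel()
    units = np.vstack([np.column_stack([np.cos(th), np.sin(th)]), [[1.0, 0.0]], [[1.0, 0.0]]])
    ell = np.concatenate([np.full(net.n_filaments, net.params.filament_length), [s, s]])
    # sample points every 0.05 um for neighbor queries
    pts, pts_fil = [], []
    for f in range(len(ell)):
        n = max(2, int(np.ceil(ell[f] / 0.05)) + 1)
        tt = np.linspace(0.0, ell[f], n)
        pts.append(starts[f] + tt[:, None] * units[f])
        pts_fil.append(np.full(n, f, dtype=int))
    tree = cKDTree(np.vstack(pts))
    box = (np.array([-1.5, -1.5]), np.array([s + 1.5, s + 1.5]))
    state._ops["linker_geo"] = (
        starts,
        units,
        ell,
        tree,
        np.concatenate(pts_fil),
        box,
    )


def simulate_crosslinking(
    state: MechState,
    net: AstralNetwork,
    mech: MechParams,
    rng: np.random.Generator,
    duration: float = 5.0,
) -> MechState:
    """Run the crosslinking phase: crosslinkers diffuse and bind while
    both boundary filaments are anchored and no force is applied.

    With thermal noise off the filaments carry no force until springs
    form, and the sub-binding-range spring strains are resolved by a
    short relaxation at the end of the phase, so filament geometry is
    held at its initial configuration while binding is simulated.
    """
    _build_linker_geometry(state, net, mech)
    nsteps = int(round(duration / mech.dt))
    for _ in range(nsteps):
        _update_linkers(state, mech, mech.dt, rng)
        state.t += mech.dt
    # particles still free or singly bound at phase end never form links
    state.linker_single = []
    state.linker_free = np.empty((0, 2))
    state._ops.pop("linker_geo", None)
    # resolve residual crosslink strain (< binding range) quasi-statically
    relax(state, mech, max_time=2.0, tol=1e-9)
    return state


def relax(
    state: MechState,
    mech: MechParams,
    max_time: float = 5.0,
    tol: float = 1e-9,
    dt: Optional[float] = None,
) -> int:
    """Step without noise/binding until the largest per-step vertex
    displacement falls below ``tol`` (um); returns steps taken."""
    if dt is None:
        dt = mech.dt
    nmax = int(round(max_time / dt))
    for k in range(nmax):
        prev = state.xy.copy()
        step(state, mech, dt=dt, thermal=False, bind=False)
        if float(np.max(np.abs(state.xy - prev))) < tol:
            return k + 1
    return nmax


# ---------------------------------------------------------------------------
# experiment protocol


@dataclass
class ExperimentResult:
    """Outcome of one two-phase loading experiment."""

    mode: str
    force: float
    initial: np.ndarray       # network filament vertices at force onset
    final: np.ndarray         # same vertices at the end of the force phase
    displacement: np.ndarray  # COM displacement vector (dx, dy)
    delta: float              # component along the loading direction
    steps_run: int = 0


def prepare_state(
    net: AstralNetwork, mech: MechParams, mode: str, seed: int, t_crosslink: float = 5.0
) -> MechState:
    """Discretize and run the crosslinking phase once (reusable across
    forces: the same seed gives the same crosslinking outcome)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    state = discretize(net, mech, mode=mode, rng=rng)
    simulate_crosslinking(state, net, mech, rng, duration=t_crosslink)
    return state


def _apply_protocol_force(state: MechState, mech: MechParams, protocol: Protocol) -> None:
    gb = state.groups[1]
    top_first = gb.start + gb.n_vertices
    top_last = top_first + gb.n_vertices - 1
    if protocol.mode == "shear":
        state.force_idx = np.array([top_last])
        state.force_vec = np.array([[protocol.force, 0.0]])
    else:
        state.force_idx = np.array([top_first, top_last])
        state.force_vec = np.array(
            [[0.0, protocol.force / 2.0], [0.0, protocol.force / 2.0]]
        )
    # release the top boundary anchors
    keep = state.anchor_idx < top_first
    state.anchor_idx = state.anchor_idx[keep]
    state.anchor_pos = state.anchor_pos[keep]
    state.anchor_k = state.anchor_k[keep]
    state.invalidate()


def _network_vertices(state: MechState) -> np.ndarray:
    g = state.network_group
    return state.xy[g.start : g.stop]


def run_force_phase(
    state: MechState,
    mech: MechParams,
    protocol: Protocol,
    rng: Optional[np.random.Generator] = None,
    steady_tol: float = 1e-9,
) -> ExperimentResult:
    """Apply the protocol force to a crosslinked state and run the force
    phase; mutates ``state``.  Early exit once the per-step displacement
    is below ``steady_tol`` for several consecutive steps (the dynamics
    is autonomous, so a stationary state stays stationary)."""
    _apply_protocol_force(state, mech, protocol)
    initial = _network_vertices(state).copy()
    nsteps = int(round(protocol.t_force / mech.dt))
    calm = 0
    k = 0
    for k in range(nsteps):
        prev = state.xy.copy()
        step(state, mech, thermal=mech.thermal, rng=rng, bind=False)
        if float(np.max(np.abs(state.xy - prev))) < steady_tol:
            calm += 1
            if calm >= 5:
                k = nsteps - 1
                break
        else:
            calm = 0
    final = _network_vertices(state).copy()
    disp = (final - initial).mean(axis=0) if final.size else np.zeros(2)
    delta = float(disp[0] if protocol.mode == "shear" else disp[1])
    return ExperimentResult(
        mode=protocol.mode,
        force=protocol.force,
        initial=initial,
        final=final,
        displacement=disp,
        delta=delta,
        steps_run=k + 1,
    )


def trajectory_frame(state: MechState):
    """Flat snapshot of all filament vertices (CSV-ready).

    Columns: t_s, group (0 network / 1 boundary), filament, vertex,
    x_um, y_um.  Concatenate frames from successive times to build a
    trajectory table.
    """
    import pandas as pd

    rows = []
    for gi, g in enumerate(state.groups):
        p = g.view(state.xy)
        fil, ver = np.meshgrid(
            np.arange(g.n_chains), np.arange(g.n_vertices), indexing="ij"
        )
        rows.append(
            pd.DataFrame(
                {
                    "t_s": state.t,
                    "group": gi,
                    "filament": fil.ravel(),
                    "vertex": ver.ravel(),
                    "x_um": p[..., 0].ravel(),
                    "y_um": p[..., 1].ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def run_experiment(
    net: AstralNetwork,
    mech: MechParams,
    protocol: Protocol,
    seed: int = 0,
    state: Optional[MechState] = None,
) -> ExperimentResult:
    """Full two-phase experiment on a sampled network.

    Phase 1 (``t_crosslink``): both boundaries anchored, no force,
    crosslinkers bind.  Phase 2 (``t_force``): top anchors removed,
    constant force applied; the network center-of-mass displacement
    (boundary filaments excluded) between the phase boundaries is the
    response, reported along the loading direction.
    """
    if state is None:
        state = prepare_state(net, mech, protocol.mode, seed, protocol.t_crosslink)
    work = state.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**21]))
    return run_force_phase(work, mech, protocol, rng=rng)
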
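"""Connectivity and percolation analysis of astral networks.

Two notions of percolation are measured on random networks:

* **spanning** — some connected component owns crosslink/crossing points
  both at-or-beyond the bottom boundary line (``y <= 0``) and at-or-beyond
  the top line (``y >= s``);
* **connectivity** — the whole network forms a unique connected
  component (isolated asters count as components, so they break it).

Graph vertices are asters; parallel crosslinks between the same aster
pair collapse to a single edge.  This is equivalent to the
filament-vertex formulation for connectivity purposes because filaments
of one aster share the central node.

Critical densities ``rho_c(a_n)`` are the densities where a smoothing
spline fitted to Monte Carlo percolation probabilities crosses 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import bisect
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.proportion import proportion_confint

from .netgen import AstralNetwork, NetworkParams, _crosslink_arrays, sample_network

__all__ = [
    "CrosslinkGraph",
    "PercolationCurve",
    "PercolationEstimate",
    "FitError",
    "build_graph",
    "is_spanning",
    "is_fully_connected",
    "percolation_probability",
    "percolation_curves",
    "fit_critical_density",
    "critical_density_table",
]


class FitError(RuntimeError):
    """Raised when a percolation curve cannot be fitted / bracketed."""


@dataclass
class CrosslinkGraph:
    """Aster-level crosslink graph of one network.

    ``labels[i]`` is the component id of aster ``i``; components are a
    partition of all asters (isolated asters are singletons).  Per
    component, ``has_point_above``/``has_point_below`` record whether the
    component owns a crosslink or boundary-crossing point with
    ``y >= s`` / ``y <= 0``.
    """

    n_vertices: int
    edges: np.ndarray  # (E, 2) unique aster pairs, i < j
    labels: np.ndarray
    n_components: int
    has_point_above: np.ndarray  # (n_components,) bool
    has_point_below: np.ndarray


def build_graph(
    net: AstralNetwork, crosslinks: Optional[dict] = None, include_boundaries: bool = True
) -> CrosslinkGraph:
    """Build the aster-level crosslink graph.

    ``crosslinks`` may be the array dict from the generator's internal
    intersection routine; by default it is computed from ``net``.
    Boundary-line crossings are recorded as per-component marks, never as
    vertices.
    """
    if crosslinks is None:
        crosslinks = _crosslink_arrays(net)
    n = net.params.n_asters
    if n == 0:
        raise ValueError("empty network")
    ai, aj = crosslinks["aster_i"], crosslinks["aster_j"]
    if ai.size:
        pairs = np.unique(np.sort(np.column_stack([ai, aj]), axis=1), axis=0)
    else:
        pairs = np.empty((0, 2), dtype=int)
    if pairs.size:
        m = sparse.coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        ncomp, labels = connected_components(m, directed=False)
    else:
        ncomp, labels = n, np.arange(n)

    above = np.zeros(ncomp, dtype=bool)
    below = np.zeros(ncomp, dtype=bool)
    s = net.params.domain_size
    if ai.size:
        y = crosslinks["points"][:, 1]
        for a, yy in ((ai, y), (aj, y)):
            np.logical_or.at(above, labels[a], yy >= s)
            np.logical_or.at(below, labels[a], yy <= 0.0)
    if include_boundaries:
        bc = net.boundary_crossings()
        if len(bc):
            comp = labels[bc["aster"].to_numpy()]
            top = (bc["boundary"] == "top").to_numpy()
            np.logical_or.at(above, comp[top], True)
            np.logical_or.at(below, comp[~top], True)
    return CrosslinkGraph(
        n_vertices=n,
        edges=pairs,
        labels=labels,
        n_components=ncomp,
        has_point_above=above,
        has_point_below=below,
    )


def _as_graph(net_or_graph) -> CrosslinkGraph:
    if isinstance(net_or_graph, CrosslinkGraph):
        return net_or_graph
    return build_graph(net_or_graph)


def is_spanning(net_or_graph: Union[AstralNetwork, CrosslinkGraph]) -> bool:
    """True iff one component has crosslink/crossing points both with
    ``y >= s`` and with ``y <= 0``."""
    g = _as_graph(net_or_graph)
    return bool(np.any(g.has_point_above & g.has_point_below))


def is_fully_connected(net_or_graph: Union[AstralNetwork, CrosslinkGraph]) -> bool:
    """True iff the network has a unique connected component (isolated
    asters included in the count)."""
    g = _as_graph(net_or_graph)
    return g.n_components == 1


@dataclass
class PercolationEstimate:
    """Monte Carlo percolation proportion with a Wilson 95% CI."""

    mode: str
    a_n: int
    rho: float
    n_samples: int
    n_percolating: int
    probability: float
    ci_low: float
    ci_high: float


@dataclass
class PercolationCurve:
    """Percolation probability vs density for one mode and astral number."""

    mode: str  # {"spanning", "connectivity"}
    a_n: int
    densities: np.ndarray
    probabilities: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.densities = np.asarray(self.densities, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if np.any(np.diff(self.densities) <= 0):
            raise ValueError("densities must be strictly increasing")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        lo, hi = proportion_confint(
            np.round(self.probabilities * self.n_samples).astype(int),
            self.n_samples,
            alpha=0.05,
            method="wilson",
        )
        return pd.DataFrame(
            {
                "mode": self.mode,
                "a_n": self.a_n,
                "rho_per_um": self.densities,
                "n_samples": self.n_samples,
                "p_hat": self.probabilities,
                "ci_lo": lo,
                "ci_hi": hi,
            }
        )


def _sample_outcomes(
    a_n: int, rho: float, ell: float, s: float, n_samples: int, seed
) -> tuple[int, int]:
    """Count (spanning, connected) outcomes over ``n_samples`` networks."""
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    n_span = n_conn = 0
    for child in ss.spawn(n_samples):
        rng = np.random.default_rng(child)
        params = NetworkParams(
            astral_number=a_n, filament_length=ell, domain_size=s, density=rho
        )
        if params.n_asters == 0:
            continue
        net = sample_network(params, rng=rng)
        g = build_graph(net)
        n_span += is_spanning(g)
        n_conn += is_fully_connected(g)
    return n_span, n_conn


def percolation_probability(
    a_n: int,
    rho: float,
    ell: float = 1.0,
    s: float = 10.0,
    mode: str = "spanning",
    n_samples: int = 200,
    seed=0,
) -> PercolationEstimate:
    """Monte Carlo percolation probability with Wilson 95% CI."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mode not in ("spanning", "connectivity"):
        raise ValueError(f"unknown mode {mode!r}")
    n_span, n_conn = _sample_outcomes(a_n, rho, ell, s, n_samples, seed)
    k = n_span if mode == "spanning" else n_conn
    lo, hi = proportion_confint(k, n_samples, alpha=0.05, method="wilson")
    return PercolationEstimate(
        mode=mode,
        a_n=a_n,
        rho=rho,
        n_samples=n_samples,
        n_percolating=k,
        probability=k / n_samples,
        ci_low=float(lo),
        ci_high=float(hi),
    )


def percolation_curves(
    a_n: int,
    densities: Sequence[float],
    ell: float = 1.0,
    s: float = 10.0,
    n_samples: int = 200,
    seed=0,
) -> dict[str, PercolationCurve]:
    """Spanning and connectivity percolation curves from shared samples.

    Each sampled network is scored under both definitions, so one Monte
    Carlo pass yields both curves.
    """
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    kids = ss.spawn(len(densities))
    p_span, p_conn = [], []
    for rho, child in zip(densities, kids):
        n_span, n_conn = _sample_outcomes(a_n, rho, ell, s, n_samples, child)
        p_span.append(n_span / n_samples)
        p_conn.append(n_conn / n_samples)
    return {
        "spanning": PercolationCurve("spanning", a_n, densities, p_span, n_samples),
        "connectivity": PercolationCurve("connectivity", a_n, densities, p_conn, n_samples),
    }


def fit_critical_density(
    curve: PercolationCurve, lam: Optional[float] = None, xtol: float = 1e-4
) -> float:
    """Density at which the fitted percolation curve crosses 0.5.

    A smoothing spline (generalized cross-validation smoothing by
    default; override with ``lam``) is fitted to the Monte Carlo
    proportions and the upward 0.5-crossing nearest the empirical 50%
    point is located by bisection (tolerance ``xtol``).

    Raises :class:`FitError` when the data do not bracket 0.5.
    """
    x, y = curve.densities, curve.probabilities
    if not (y.min() < 0.5 < y.max()):
        raise FitError(
            f"percolation data do not bracket 0.5: probabilities span "
            f"[{y.min():.3f}, {y.max():.3f}] over rho [{x[0]:g}, {x[-1]:g}]"
        )
    if len(x) >= 5:
        spl = make_smoothing_spline(x, y, lam=lam)
        f = lambda r: float(spl(r)) - 0.5
    else:  # too few points for a cubic smoother: linear interpolation
        f = lambda r: float(np.interp(r, x, y)) - 0.5
    grid = np.linspace(x[0], x[-1], 2001)
    vals = np.array([f(g) for g in grid])
    up = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if up.size == 0:
        raise FitError(
            f"fitted curve has no upward 0.5-crossing in rho [{x[0]:g}, {x[-1]:g}]"
        )
    # empirical 50% point: first density where the raw proportion reaches 0.5
    above = np.nonzero(y >= 0.5)[0]
    target = x[above[0]] if above.size else x[-1]
    k = up[np.argmin(np.abs(grid[up] - target))]
    return float(bisect(f, grid[k], grid[k + 1], xtol=xtol))


def critical_density_table(
    astral_numbers: Sequence[int],
    densities: Sequence[float],
    ell: float = 1.0,
    s: float = 10.0,
    n_samples: int = 200,
    seed=0,
) -> pd.DataFrame:
    """Critical densities rho_c for both modes across astral numbers.

    Returns a DataFrame (mode, a_n, rho_c_per_um); cells whose curves do
    not bracket 0.5 are reported as NaN.
    """
    ss = np.random.SeedSequence(seed)
    rows = []
    for a_n, child in zip(astral_numbers, ss.spawn(len(astral_numbers))):
        curves = percolation_curves(a_n, densities, ell, s, n_samples, seed=child)
        for mode, curve in curves.items():
            try:
                rho_c = fit_critical_density(curve)
            except FitError:
                rho_c = np.nan
            rows.append({"mode": mode, "a_n": a_n, "rho_c_per_um": rho_c})
    return pd.DataFrame(rows)
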
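"""Elastic modulus estimation from force sweeps.

Each sampled network is subjected to ``k`` equally spaced force
magnitudes (0..F_max; 5 pN for shear, 20 pN for tension by default) and
the center-of-mass displacement at steady state is recorded.  The 2D
(line) modulus is the zero-intercept least-squares slope of force vs
displacement: stress is F/s and strain is displacement/s, so the two
factors of s cancel and the modulus carries units pN/um.

Fractured networks drift without bound, showing up as huge
displacements; regression through all pairs then gives a modulus near
zero.  A negative fitted slope (network never caught the moving
boundary) is assigned modulus 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mechanics import MechParams, Protocol, prepare_state, run_force_phase
from .netgen import AstralNetwork

__all__ = [
    "ModulusSample",
    "DEFAULT_FORCE_MAX",
    "force_sweep",
    "estimate_modulus",
    "sweep_modulus",
    "weak_fraction",
    "lower_median",
    "modulus_distribution",
    "criticality_correlation",
]

#: default force-sweep maxima (pN) per loading mode
DEFAULT_FORCE_MAX = {"shear": 5.0, "tensile": 20.0}


@dataclass
class ModulusSample:
    """Force-displacement pairs and fitted modulus for one network."""

    a_n: int
    rho: float
    seed: int
    mode: str
    forces: np.ndarray         # pN
    displacements: np.ndarray  # um, along the loading direction
    modulus: float             # pN/um

    def to_rows(self) -> list[dict]:
        return [
            {
                "mode": self.mode,
                "a_n": self.a_n,
                "rho_per_um": self.rho,
                "seed": self.seed,
                "force_pN": float(f),
                "displacement_um": float(d),
                "modulus_pN_per_um": self.modulus,
            }
            for f, d in zip(self.forces, self.displacements)
        ]


def force_sweep(
    net: AstralNetwork,
    mech: MechParams,
    mode: str = "shear",
    k: int = 6,
    f_max: Optional[float] = None,
    seed: int = 0,
    t_crosslink: float = 5.0,
    t_force: float = 40.0,
    steady_tol: float = 1e-9,
) -> list[tuple[float, float]]:
    """Sweep ``k`` equally spaced forces from 0 to ``f_max`` on one network.

    The crosslinking phase runs once (same seed => same network and the
    same crosslinking outcome) and each force starts from the recorded
    initial state, mirroring a seed-pinned sweep.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if f_max is None:
        f_max = DEFAULT_FORCE_MAX[mode]
    base = prepare_state(net, mech, mode, seed, t_crosslink)
    pairs = []
    for f in np.linspace(0.0, f_max, k):
        proto = Protocol(mode=mode, force=float(f), t_force=t_force)
        res = run_force_phase(base.copy(), mech, proto, steady_tol=steady_tol)
        pairs.append((float(f), res.delta))
    return pairs


def estimate_modulus(pairs: Sequence[tuple[float, float]]) -> float:
    """Zero-intercept slope of force vs displacement, in pN/um.

    All pairs enter the regression even when the response is curved.
    Negative slope -> 0 (network failed to engage the boundary).  All
    displacements exactly zero under nonzero force -> inf (the load had
    nothing compliant to move; flags a rigid-anchored artifact).
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (force, displacement) pairs")
    f, d = arr[:, 0], arr[:, 1]
    ss = float(np.sum(d * d))
    if ss == 0.0:
        return float("inf") if np.any(f > 0) else 0.0
    slope = float(np.sum(f * d) / ss)  # slope of F vs displacement
    return max(slope, 0.0)


def sweep_modulus(
    net: AstralNetwork,
    mech: MechParams,
    mode: str = "shear",
    k: int = 6,
    f_max: Optional[float] = None,
    seed: int = 0,
    **kw,
) -> ModulusSample:
    """Force sweep plus modulus fit, packaged with metadata."""
    pairs = force_sweep(net, mech, mode=mode, k=k, f_max=f_max, seed=seed, **kw)
    arr = np.asarray(pairs)
    return ModulusSample(
        a_n=net.params.astral_number,
        rho=net.params.density,
        seed=seed,
        mode=mode,
        forces=arr[:, 0],
        displacements=arr[:, 1],
        modulus=estimate_modulus(pairs),
    )


def lower_median(values: Sequence[float]) -> float:
    """Median with the lower-median convention for even-length samples."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty sample")
    return float(v[(v.size - 1) // 2])


def weak_fraction(moduli: Sequence[float]) -> float:
    """Proportion of networks weaker than half the (lower) median modulus."""
    m = np.asarray(moduli, dtype=float)
    if m.size < 2:
        raise ValueError("need at least two modulus samples")
    return float(np.mean(m < 0.5 * lower_median(m)))


@dataclass
class ModulusDistribution:
    """Empirical distribution of moduli with a near-zero-mass diagnostic.

    ``near_zero_mass`` is the ECDF evaluated at 10% of the median: ~0 for
    Gaussian-like ensembles (histogram sits away from the origin), > 0
    for exponential-like ensembles with weight at small moduli.
    """

    values: np.ndarray
    ecdf_x: np.ndarray
    ecdf_y: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    near_zero_mass: float

    def ecdf(self, x: float) -> float:
        return float(np.searchsorted(self.ecdf_x, x, side="right")) / self.values.size


def modulus_distribution(moduli: Sequence[float], bins: int = 20) -> ModulusDistribution:
    m = np.asarray(moduli, dtype=float)
    if m.size < 10:
        raise ValueError("need at least 10 modulus samples")
    xs = np.sort(m)
    ys = np.arange(1, m.size + 1) / m.size
    counts, edges = np.histogram(m, bins=bins)
    med = lower_median(m)
    near_zero = float(np.mean(m <= 0.1 * med)) if med > 0 else float(np.mean(m == 0))
    return ModulusDistribution(
        values=xs,
        ecdf_x=xs,
        ecdf_y=ys,
        hist_counts=counts,
        hist_edges=edges,
        near_zero_mass=near_zero,
    )


@dataclass
class CriticalityCorrelation:
    """Pearson correlation between modulus and distance to criticality."""

    r: float
    p_value: float
    n_used: int
    n_zero_excluded: int
    n_nonpositive_dr_excluded: int
    log_x: bool
    r_alternative: float  # the other x-transform, for reference


def criticality_correlation(
    samples: pd.DataFrame,
    rho_c: dict[int, float],
    log_x: bool = True,
) -> CriticalityCorrelation:
    """Correlate log10(modulus) with the distance to the connectivity
    percolation threshold, Delta-rho = rho - rho_c(a_n).

    ``samples`` needs columns (a_n, rho_per_um, modulus_pN_per_um).
    Zero moduli are excluded from the log transform; with ``log_x``
    (default) the x axis is log10(Delta-rho) and non-positive Delta-rho
    rows are excluded too.  Exclusion counts are reported.
    """
    need = {"a_n", "rho_per_um", "modulus_pN_per_um"}
    if not need.issubset(samples.columns):
        raise ValueError(f"samples must have columns {sorted(need)}")
    missing = set(samples["a_n"].unique()) - set(rho_c)
    if missing:
        raise ValueError(f"rho_c missing for astral numbers {sorted(missing)}")
    df = samples.copy()
    df["dr"] = df["rho_per_um"] - df["a_n"].map(rho_c)
    m = df["modulus_pN_per_um"].to_numpy(dtype=float)
    n_zero = int(np.sum(m <= 0))
    keep = m > 0
    n_nonpos = int(np.sum(keep & (df["dr"].to_numpy() <= 0)))

    def pearson(use_log_x: bool):
        sel = keep & ((df["dr"] > 0) if use_log_x else np.ones(len(df), dtype=bool))
        x = df.loc[sel, "dr"].to_numpy(dtype=float)
        y = np.log10(df.loc[sel, "modulus_pN_per_um"].to_numpy(dtype=float))
        if use_log_x:
            x = np.log10(x)
        if x.size < 3 or np.ptp(x) == 0:
            return np.nan, np.nan, int(x.size)
        r, p = stats.pearsonr(x, y)
        return float(r), float(p), int(x.size)

    r, p, n = pearson(log_x)
    r_alt, _, _ = pearson(not log_x)
    return CriticalityCorrelation(
        r=r,
        p_value=p,
        n_used=n,
        n_zero_excluded=n_zero,
        n_nonpositive_dr_excluded=n_nonpos if log_x else 0,
        log_x=log_x,
        r_alternative=r_alt,
    )
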
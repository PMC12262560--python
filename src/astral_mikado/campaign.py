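"""Reproducible experiment campaigns over (a_n, rho, mode) grids.

A campaign runs one analysis kind — ``geometry``, ``percolation`` or
``mechanics`` — over a parameter grid, with per-network seeds derived
deterministically from a master seed by a counter-based scheme:
network ``k`` of grid cell ``j`` uses ``SeedSequence([master, j, k])``,
so any cell is reproducible in isolation.  Completed cells (existing
CSVs) are skipped on re-run; a manifest records the full configuration.

All quantities are carried in (um, pN, s) units; CSV headers embed the
unit labels.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geomstats import geometry_summary
from .graphs import FitError, fit_critical_density, percolation_curves
from .mechanics import MechParams
from .moduli import sweep_modulus
from .netgen import NetworkParams, sample_network

__all__ = ["Campaign", "cell_seed", "run_campaign", "load_campaign", "save_campaign"]


@dataclass
class Campaign:
    """Declarative description of one experiment campaign."""

    kind: str  # {"geometry", "percolation", "mechanics"}
    astral_numbers: list
    densities: list
    modes: list = field(default_factory=lambda: ["shear"])
    networks_per_cell: int = 10
    forces_per_network: int = 3
    n_samples: int = 200  # percolation only
    filament_length: float = 1.0
    domain_size: float = 10.0
    master_seed: int = 0
    t_force: float = 40.0
    steady_tol: float = 1e-6
    outdir: str = "campaign_out"

    def __post_init__(self) -> None:
        if self.kind not in ("geometry", "percolation", "mechanics"):
            raise ValueError(f"unknown campaign kind {self.kind!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Campaign":
        return cls(**d)


def save_campaign(campaign: Campaign, path) -> None:
    Path(path).write_text(yaml.safe_dump(campaign.to_dict(), sort_keys=True))


def load_campaign(path) -> Campaign:
    return Campaign.from_dict(yaml.safe_load(Path(path).read_text()))


def cell_seed(master: int, cell: int, k: int) -> np.random.SeedSequence:
    """Seed sequence for network ``k`` of grid cell ``cell``."""
    return np.random.SeedSequence([int(master), int(cell), int(k)])


def _cell_int_seed(master: int, cell: int, k: int) -> int:
    return int(cell_seed(master, cell, k).generate_state(1)[0] % 2**31)


def run_campaign(campaign: Campaign, log=print) -> dict:
    """Execute a campaign; returns the manifest (also written to disk).

    Idempotent: cells whose result CSV already exists are skipped.
    Failing cells are flagged in the manifest and the campaign continues.
    """
    out = Path(campaign.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": campaign.to_dict(),
        "cells": [],
    }
    cells = [
        (a_n, rho, mode)
        for a_n in campaign.astral_numbers
        for rho in campaign.densities
        for mode in (campaign.modes if campaign.kind == "mechanics" else [None])
    ]
    for j, (a_n, rho, mode) in enumerate(cells):
        tag = f"an{a_n}_rho{rho:g}" + (f"_{mode}" if mode else "")
        path = out / f"{campaign.kind}_{tag}.csv"
        entry = {"cell": j, "a_n": a_n, "rho": rho, "mode": mode, "file": path.name}
        t0 = time.time()
        if path.exists():
            entry["status"] = "skipped"
            manifest["cells"].append(entry)
            continue
        try:
            df = _run_cell(campaign, j, a_n, rho, mode)
            df.to_csv(path, index=False)
            entry["status"] = "ok"
        except Exception as exc:  # flag and continue
            entry["status"] = "failed"
            entry["error"] = f"{type(exc).__name__}: {exc}"
            log(f"cell {tag} failed: {entry['error']}")
        entry["runtime_s"] = round(time.time() - t0, 2)
        entry["seeds"] = [
            _cell_int_seed(campaign.master_seed, j, k)
            for k in range(campaign.networks_per_cell)
        ]
        manifest["cells"].append(entry)
        log(f"cell {tag}: {entry['status']} ({entry['runtime_s']} s)")
    if campaign.kind == "percolation":
        _write_critical_densities(campaign, out)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    save_campaign(campaign, out / "config.yaml")
    return manifest


def _run_cell(campaign: Campaign, j: int, a_n: int, rho: float, mode) -> pd.DataFrame:
    ell, s = campaign.filament_length, campaign.domain_size
    if campaign.kind == "geometry":
        rows = []
        for k in range(campaign.networks_per_cell):
            seed = _cell_int_seed(campaign.master_seed, j, k)
            net = sample_network(
                NetworkParams(
                    astral_number=a_n,
                    density=rho,
                    filament_length=ell,
                    domain_size=s,
                    seed=seed,
                )
            )
            rows.append(geometry_summary(net))
        return pd.DataFrame(rows)
    if campaign.kind == "percolation":
        curves = percolation_curves(
            a_n, [rho], ell, s, campaign.n_samples, seed=cell_seed(campaign.master_seed, j, 0)
        )
        return pd.concat([c.to_frame() for c in curves.values()], ignore_index=True)
    # mechanics
    mech = MechParams()
    rows = []
    for k in range(campaign.networks_per_cell):
        seed = _cell_int_seed(campaign.master_seed, j, k)
        net = sample_network(
            NetworkParams(
                astral_number=a_n,
                density=rho,
                filament_length=ell,
                domain_size=s,
                seed=seed,
            )
        )
        sample = sweep_modulus(
            net,
            mech,
            mode=mode,
            k=campaign.forces_per_network,
            seed=seed,
            t_force=campaign.t_force,
            steady_tol=campaign.steady_tol,
        )
        rows.extend(sample.to_rows())
    return pd.DataFrame(rows)


def _write_critical_densities(campaign: Campaign, out: Path) -> None:
    """Aggregate per-density percolation CSVs into a rho_c table."""
    frames = []
    for p in sorted(out.glob("percolation_*.csv")):
        frames.append(pd.read_csv(p))
    if not frames:
        return
    data = pd.concat(frames, ignore_index=True)
    rows = []
    from .graphs import PercolationCurve

    for (mode, a_n), grp in data.groupby(["mode", "a_n"]):
        grp = grp.sort_values("rho_per_um")
        try:
            curve = PercolationCurve(
                mode=mode,
                a_n=int(a_n),
                densities=grp["rho_per_um"].to_numpy(),
                probabilities=grp["p_hat"].to_numpy(),
                n_samples=int(grp["n_samples"].iloc[0]),
            )
            rho_c = fit_critical_density(curve)
        except (FitError, ValueError) as exc:
            rho_c = np.nan
        rows.append({"mode": mode, "a_n": int(a_n), "rho_c_per_um": rho_c})
    pd.DataFrame(rows).to_csv(out / "critical_densities.csv", index=False)
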
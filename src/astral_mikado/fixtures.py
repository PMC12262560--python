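"""Deterministic tiny networks used in tests and examples.

Each fixture is a hand-constructed :class:`AstralNetwork` whose
connectivity and geometry are known exactly; they exercise specific
code paths (spanning detection, component splitting, node counting)
without any randomness.
"""

from __future__ import annotations

import numpy as np

from .netgen import AstralNetwork, NetworkParams

__all__ = ["FIXTURES", "make_fixture"]


def _net(a_n, ell, s, centers, orientations):
    centers = np.asarray(centers, dtype=float)
    params = NetworkParams(
        astral_number=a_n,
        filament_length=ell,
        domain_size=s,
        n_asters=len(centers),
        seed=0,
    )
    return AstralNetwork(
        params=params, centers=centers, orientations=np.asarray(orientations, dtype=float)
    )


def _two_crossing_filaments() -> AstralNetwork:
    # horizontal and vertical unit filaments crossing at (0.7, 1.0)
    return _net(
        1,
        1.0,
        2.0,
        [[0.2, 1.0], [0.7, 0.5]],
        [[0.0], [np.pi / 2]],
    )


def _plus_sign() -> AstralNetwork:
    # two length-2 filaments crossing mid-way at (1.5, 1.5); four more
    # filaments crosslink each of their arms, so the central node has
    # four incident productive segments
    v = np.pi / 2
    return _net(
        1,
        2.0,
        3.0,
        [
            [0.5, 1.5],  # A: horizontal through (1.5, 1.5)
            [1.5, 0.5],  # B: vertical through (1.5, 1.5)
            [0.7, 0.5],  # C: vertical, crosses A at x=0.7
            [2.3, 0.5],  # D: vertical, crosses A at x=2.3
            [0.5, 0.7],  # E: horizontal, crosses B (and C, D) at y=0.7
            [0.5, 2.3],  # F: horizontal, crosses B (and C, D) at y=2.3
        ],
        [[0.0], [v], [v], [v], [0.0], [0.0]],
    )


def _spanning_chain() -> AstralNetwork:
    # two vertical filaments poking below y=0 and above y=s, bridged by a
    # horizontal filament: a single component spanning both boundaries
    s = 1.5
    return _net(
        1,
        1.0,
        s,
        [[0.75, 0.9], [0.75, 0.6], [0.25, 0.75]],
        [[-np.pi / 2], [np.pi / 2], [0.0]],
    )


def _two_halves() -> AstralNetwork:
    # two internally crosslinked pairs with no bridging crosslink
    tilt = 80 * np.pi / 180
    return _net(
        1,
        1.0,
        4.0,
        [[0.5, 1.0], [0.2, 1.8], [2.7, 1.0], [2.4, 1.8]],
        [[tilt], [0.0], [tilt], [0.0]],
    )


def _single_aster() -> AstralNetwork:
    return _net(4, 1.0, 4.0, [[2.0, 2.0]], [[0.0, np.pi / 2, np.pi, 3 * np.pi / 2]])


FIXTURES = {
    "two-crossing-filaments": _two_crossing_filaments,
    "plus-sign": _plus_sign,
    "spanning-chain": _spanning_chain,
    "two-halves": _two_halves,
    "single-aster": _single_aster,
}


def make_fixture(name: str) -> AstralNetwork:
    """Build one of the documented deterministic fixture networks."""
    try:
        return FIXTURES[name]()
    except KeyError:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
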
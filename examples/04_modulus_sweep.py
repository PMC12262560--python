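"""Estimate a shear modulus from a force sweep on one network.

Runs the two-phase protocol (5 s crosslinking, then a constant shear
force on the top boundary filament until steady state) for three force
magnitudes on the same network, and fits the zero-intercept slope of
force vs center-of-mass displacement.  The slope is the 2D shear
modulus in pN/um (stress F/s over strain dx/s; the domain size cancels).
Kept small (5 um box) so it runs in about a minute.
"""

import numpy as np

from astral_mikado import MechParams, NetworkParams, sample_network
from astral_mikado.moduli import sweep_modulus

net = sample_network(NetworkParams(astral_number=4, density=10.5, domain_size=5.0, seed=11))
sample = sweep_modulus(net, MechParams(), mode="shear", k=3, seed=11, t_force=20.0, steady_tol=1e-6)
for f, d in zip(sample.forces, sample.displacements):
    print(f"F = {f:4.1f} pN  ->  dx = {d:8.4f} um")
print(f"shear modulus G = {sample.modulus:.3f} pN/um")
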
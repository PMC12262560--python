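"""Percolation probability curves and critical densities.

Estimates spanning and connectivity percolation probabilities by Monte
Carlo for a few astral numbers on a reduced domain (5 um), then locates
the critical density where each fitted curve crosses 50%.  Both
thresholds are non-monotonic in astral number: a_n=1 networks are
handicapped by stray isolated filaments, very astral networks by the
gaps between their few hubs.
"""

import numpy as np

from astral_mikado import fit_critical_density, percolation_curves

S = 5.0
for a_n, dens in ((1, np.linspace(3, 8, 6)), (2, np.linspace(2, 7, 6)), (16, np.linspace(5, 12, 6))):
    curves = percolation_curves(a_n, dens, s=S, n_samples=100, seed=3)
    c = curves["spanning"]
    rho_c = fit_critical_density(c)
    print(
        f"a_n={a_n:2d}: spanning P over rho {dens[0]:.0f}..{dens[-1]:.0f} = "
        f"{np.round(c.probabilities, 2)}  ->  rho_c = {rho_c:.2f} /um"
    )
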
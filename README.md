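# astral-mikado

Simulation and analysis of **astral Mikado networks**: two-dimensional
random networks of stiff filaments organized into *asters* — radial
bundles of `a_n` filaments sharing a central node — crosslinked wherever
filaments from different asters intersect.  Networks like these are a
minimal model for aster-rich F-actin structures (the cell cortex, the
early cytokinetic ring, aster-based biomimetic materials), and the
package exists to answer one question quantitatively: *for a fixed
amount of polymer, how does nanoscale astral organization change the
mechanical strength of the network?*

The short answer the model gives: rigidity peaks at an intermediate
astral number, and the peak is explained by connectivity percolation —
the distance between the working density and the percolation threshold
`rho_c(a_n)`, which is itself non-monotonic in `a_n`.

## Model

- A network is `N_n` asters dropped uniformly in an `s x s` domain
  (default `s = 10 um`), each with `a_n` filaments of length
  `ell = 1 um` at uniform random orientations.  The network density is

  `rho = a_n * N_n * ell / s^2`   (default `7.5 /um`),

  so `a_n` can be varied at fixed total polymer.
- **Geometry/percolation layer** (`netgen`, `graphs`, `geomstats`):
  crosslinks are placed at every inter-aster filament intersection.
  *Spanning* percolation asks whether one connected component holds
  crosslink points beyond both horizontal boundaries; *connectivity*
  percolation asks whether the whole network is a single component.
  Critical densities are the 50% crossings of smoothing-spline fits to
  Monte Carlo percolation probabilities.  Dangling ends (filament spans
  not bounded by two connections) and the use-fraction
  `1 - dangling/total length` quantify how much polymer is mechanically
  productive.
- **Mechanics layer** (`mechanics`, `moduli`): a Cytosim-style
  overdamped simulation — inextensible filament chains (segmentation
  0.2 um, bending rigidity 20 pN um^2), aster centers holding filament
  ends by two springs, diffusing crosslinkers that bind irreversibly
  within 0.01 um, and two stiff boundary filaments.  After a 5 s
  crosslinking phase, a constant force is applied to the top boundary
  filament (rightward at one end for shear; upward, split across both
  ends, for tension) and the steady-state center-of-mass displacement
  is recorded.  The 2D elastic modulus is the zero-intercept slope of
  force vs displacement (stress `F/s` over strain `dx/s`; `s` cancels),
  in pN/um.

## Worked example

```python
from astral_mikado import MechParams, NetworkParams, sample_network
from astral_mikado.moduli import sweep_modulus

net = sample_network(NetworkParams(astral_number=4, density=10.5,
                                   domain_size=5.0, seed=11))
s = sweep_modulus(net, MechParams(), mode="shear", k=3, seed=11,
                  t_force=20.0, steady_tol=1e-6)
for f, d in zip(s.forces, s.displacements):
    print(f"F = {f:4.1f} pN  ->  dx = {d:8.4f} um")
print(f"shear modulus G = {s.modulus:.3f} pN/um")
```

prints

```
F =  0.0 pN  ->  dx =   0.0064 um
F =  2.5 pN  ->  dx =   0.1339 um
F =  5.0 pN  ->  dx =   0.2438 um
shear modulus G = 20.069 pN/um
```

i.e. this particular 4-filament-per-aster network displaces ~0.13 um per
2.5 pN of shear on a 5 um domain, giving a line shear modulus of about
20 pN/um.  (The small displacement at zero force is the transient from
releasing the top boundary anchors.)  Running the same sweep over seeds
and astral numbers reproduces the rigidity peak: at this density the
mean shear modulus is ~1.7 pN/um for `a_n=1`, ~11 pN/um for `a_n=4` and
~3.4 pN/um (with far larger scatter) for `a_n=16`.

The `examples/` scripts walk through each capability (generation,
percolation curves, dangling-end geometry, modulus sweeps), and the
`astral-mikado` CLI exposes the same operations for shell use, e.g.

```sh
astral-mikado sweep --mode shear --an 4 --rho 7.5 --networks 30 \
    --forces 6 --seed 17 --out results.csv
```

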
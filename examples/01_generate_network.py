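"""Sample a random astral network and inspect its basic geometry.

Builds one network at the reference density (7.5 um of filament per
um^2, unit-length filaments, 10 um box) for two astral numbers and
prints the aster count, crosslink count and the realized density.
"""

from astral_mikado import NetworkParams, sample_network
from astral_mikado.netgen import crosslink_table

for a_n in (1, 4):
    params = NetworkParams(astral_number=a_n, density=7.5, seed=7)
    net = sample_network(params)
    links = crosslink_table(net)
    print(
        f"a_n={a_n}: {params.n_asters} asters, {net.n_filaments} filaments, "
        f"realized density {params.density:.3f} /um, {len(links)} crosslinks"
    )

# The filament count a_n * N_n is fixed by the density, so higher astral
# number concentrates the same total polymer into fewer, denser hubs;
# the crosslink count drops because same-aster filaments never crosslink.
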
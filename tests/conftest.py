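import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference_networks():
    """Ten networks at the reference geometry conditions (rho=7.5 /um,
    ell=1 um, s=10 um) for each astral number used repeatedly in
    geometry statistics tests."""
    from astral_mikado import NetworkParams, sample_network

    def build(a_n, n=10, rho=7.5, s=10.0, seed0=100):
        return [
            sample_network(
                NetworkParams(astral_number=a_n, density=rho, domain_size=s, seed=seed0 + k)
            )
            for k in range(n)
        ]

    return build
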
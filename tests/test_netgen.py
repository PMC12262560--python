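"""Network generation: density arithmetic, sampling, intersections."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from astral_mikado import NetworkParams, all_crosslinks, sample_network, segment_intersection
from astral_mikado.netgen import (
    AstralNetwork,
    _crosslink_arrays,
    density,
    n_asters_for_density,
)


class TestDensity:
    def test_reference_parameters(self):
        # 750 unit filaments in a 10 um box give the reference density
        assert density(1, 750, 1.0, 10.0) == pytest.approx(7.5)

    def test_empty_network(self):
        assert density(3, 0, 1.0, 10.0) == 0.0

    def test_inverse_rounding(self):
        # target rho=7.5 with 24 filaments per aster: 31.25 asters rounds
        # to 31, and the realized density is recomputed from the rounding
        n = n_asters_for_density(7.5, 24, 1.0, 10.0)
        assert n == 31
        p = NetworkParams(astral_number=24, density=7.5)
        assert p.n_asters == 31
        assert p.density == pytest.approx(7.44)

    @pytest.mark.parametrize("bad", [dict(a_n=0), dict(ell=-1.0), dict(s=0.0)])
    def test_invalid_arguments(self, bad):
        kw = dict(a_n=1, n_asters=10, ell=1.0, s=10.0)
        kw.update(bad)
        with pytest.raises(ValueError):
            density(kw["a_n"], kw["n_asters"], kw["ell"], kw["s"])

    def test_exactly_one_of_density_n_asters(self):
        with pytest.raises(ValueError):
            NetworkParams(astral_number=1, density=7.5, n_asters=10)
        with pytest.raises(ValueError):
            NetworkParams(astral_number=1)


class TestSampling:
    def test_filaments_share_aster_center(self):
        net = sample_network(NetworkParams(astral_number=2, n_asters=1, seed=3))
        starts = net.segment_starts
        assert np.allclose(starts[0], starts[1])
        assert net.n_filaments == 2

    def test_total_length_conservation(self):
        net = sample_network(
            NetworkParams(astral_number=4, n_asters=100, filament_length=1.0, seed=0)
        )
        seg = net.segment_ends - net.segment_starts
        assert np.linalg.norm(seg, axis=1) == pytest.approx(1.0)
        assert net.total_filament_length == pytest.approx(400.0)

    def test_seed_determinism(self):
        p = NetworkParams(astral_number=3, n_asters=20, seed=42)
        a, b = sample_network(p), sample_network(p)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.orientations, b.orientations)

    def test_center_uniformity(self):
        # KS test per coordinate on 10^4 aster centers
        from scipy import stats

        net = sample_network(NetworkParams(astral_number=1, n_asters=10_000, seed=5))
        for c in range(2):
            p = stats.kstest(net.centers[:, c] / 10.0, "uniform").pvalue
            assert p > 0.01

    def test_json_roundtrip(self):
        net = sample_network(NetworkParams(astral_number=2, n_asters=5, seed=9))
        back = AstralNetwork.from_json(net.to_json())
        assert np.allclose(back.centers, net.centers)
        assert np.allclose(back.orientations, net.orientations)
        assert back.params == net.params


class TestSegmentIntersection:
    @pytest.mark.parametrize(
        "a0,a1,b0,b1,expected",
        [
            ((0, 0), (1, 0), (0.5, -0.5), (0.5, 0.5), (0.5, 0.0)),
            ((0, 0), (1, 1), (0, 1), (1, 0), (0.5, 0.5)),
            ((0, 0), (1, 0), (0, 1), (1, 1), None),  # parallel
            ((0, 0), (1, 0), (2, -1), (2, 1), None),  # miss
            ((0, 0), (1, 0), (0.5, 0), (1.5, 0), None),  # collinear overlap
        ],
    )
    def test_examples(self, a0, a1, b0, b1, expected):
        out = segment_intersection(a0, a1, b0, b1)
        if expected is None:
            assert out is None
        else:
            assert out == pytest.approx(expected)

    def test_degenerate_segment_raises(self):
        with pytest.raises(ValueError):
            segment_intersection((0, 0), (0, 0), (0, 1), (1, 0))

    @given(st.integers(0, 10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, (4, 2))
        a = segment_intersection(pts[0], pts[1], pts[2], pts[3])
        b = segment_intersection(pts[2], pts[3], pts[0], pts[1])
        if a is None or b is None:
            assert a is None and b is None
        else:
            assert np.allclose(a, b, atol=1e-9)


def _brute_force_crosslinks(net):
    """O(n^2) oracle: all intersections between distinct-aster filaments."""
    starts, ends = net.segment_starts, net.segment_ends
    aster = net.filament_aster
    out = []
    for i in range(net.n_filaments):
        for j in range(i + 1, net.n_filaments):
            if aster[i] == aster[j]:
                continue
            p = segment_intersection(starts[i], ends[i], starts[j], ends[j])
            if p is not None:
                out.append((i, j, p))
    return out


class TestAllCrosslinks:
    def test_single_aster_has_none(self):
        net = sample_network(NetworkParams(astral_number=8, n_asters=1, seed=1))
        assert all_crosslinks(net) == []

    def test_matches_brute_force_oracle(self):
        for seed in range(20):
            net = sample_network(
                NetworkParams(astral_number=1, n_asters=50, domain_size=10.0, seed=seed)
            )
            fast = _crosslink_arrays(net)
            oracle = _brute_force_crosslinks(net)
            assert fast["fil_i"].size == len(oracle)
            got = {(int(i), int(j)) for i, j in zip(fast["fil_i"], fast["fil_j"])}
            assert got == {(i, j) for i, j, _ in oracle}

    def test_crosslink_points_lie_on_both_segments(self):
        net = sample_network(NetworkParams(astral_number=2, n_asters=40, seed=8))
        arr = _crosslink_arrays(net)
        starts = net.segment_starts
        ends = net.segment_ends
        for fil, arc in (("fil_i", "arc_i"), ("fil_j", "arc_j")):
            f = arr[fil]
            t = (arr[arc] / net.params.filament_length)[:, None]
            recon = starts[f] * (1 - t) + ends[f] * t
            assert np.abs(recon - arr["points"]).max() < 1e-7

    def test_aster_order_invariance(self):
        net = sample_network(NetworkParams(astral_number=1, n_asters=30, seed=4))
        perm = np.random.default_rng(0).permutation(net.params.n_asters)
        net2 = AstralNetwork(
            params=net.params,
            centers=net.centers[perm],
            orientations=net.orientations[perm],
        )
        pts1 = {tuple(np.round(p, 9)) for p in _crosslink_arrays(net)["points"]}
        pts2 = {tuple(np.round(p, 9)) for p in _crosslink_arrays(net2)["points"]}
        assert pts1 == pts2

    def test_boundary_crossings_included_when_requested(self):
        from astral_mikado import make_fixture

        net = make_fixture("spanning-chain")
        plain = all_crosslinks(net, include_boundaries=False)
        with_b = all_crosslinks(net, include_boundaries=True)
        tags = [m for link in with_b for m in link.members if isinstance(m, str)]
        assert len(with_b) == len(plain) + 2
        assert sorted(tags) == ["bottom", "top"]
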
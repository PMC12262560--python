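"""Crosslink graphs, spanning/connectivity tests, percolation fitting."""

import numpy as np
import pytest

from astral_mikado import (
    NetworkParams,
    build_graph,
    fit_critical_density,
    is_fully_connected,
    is_spanning,
    make_fixture,
    percolation_probability,
    sample_network,
)
from astral_mikado.graphs import FitError, PercolationCurve, percolation_curves
from astral_mikado.netgen import _crosslink_arrays


class _UnionFind:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, x):
        while self.p[x] != x:
            self.p[x] = self.p[self.p[x]]
            x = self.p[x]
        return x

    def union(self, a, b):
        self.p[self.find(a)] = self.find(b)


class TestBuildGraph:
    def test_chain_forms_single_component(self):
        net = make_fixture("spanning-chain")
        g = build_graph(net)
        assert g.n_components == 1

    def test_no_crosslinks_all_singletons(self):
        net = sample_network(NetworkParams(astral_number=1, n_asters=7, domain_size=100.0, seed=0))
        g = build_graph(net)
        assert g.n_components == 7
        assert g.edges.shape[0] == 0

    def test_components_match_union_find_oracle(self):
        for seed in range(5):
            net = sample_network(NetworkParams(astral_number=1, n_asters=20, seed=seed))
            arr = _crosslink_arrays(net)
            uf = _UnionFind(20)
            for a, b in zip(arr["aster_i"], arr["aster_j"]):
                uf.union(int(a), int(b))
            roots = {uf.find(i) for i in range(20)}
            g = build_graph(net)
            assert g.n_components == len(roots)
            # same partition
            labels = np.array([uf.find(i) for i in range(20)])
            for c in range(g.n_components):
                members = np.nonzero(g.labels == c)[0]
                assert len(set(labels[members])) == 1


class TestSpanning:
    def test_spanning_chain(self):
        assert is_spanning(make_fixture("spanning-chain"))

    def test_interior_network_does_not_span(self):
        assert not is_spanning(make_fixture("two-crossing-filaments"))

    def test_crossing_only_one_boundary_is_not_spanning(self):
        from astral_mikado.netgen import AstralNetwork

        # vertical chain reaching above y=s only
        net = make_fixture("spanning-chain")
        shifted = AstralNetwork(
            params=net.params,
            centers=net.centers + [0.0, 0.3],
            orientations=net.orientations,
        )
        g = build_graph(shifted)
        assert np.any(g.has_point_above) and not np.any(g.has_point_below)
        assert not is_spanning(shifted)

    def test_connected_network_crossing_both_lines_spans(self):
        # connectivity + points beyond both boundaries implies spanning
        net = make_fixture("spanning-chain")
        g = build_graph(net)
        assert is_fully_connected(g) and is_spanning(g)


class TestFullyConnected:
    def test_single_aster_is_connected(self):
        assert is_fully_connected(make_fixture("single-aster"))

    def test_isolated_aster_breaks_connectivity(self):
        net = sample_network(NetworkParams(astral_number=1, n_asters=5, domain_size=50.0, seed=2))
        assert not is_fully_connected(net)

    def test_two_halves_fixture(self):
        net = make_fixture("two-halves")
        g = build_graph(net)
        assert g.n_components == 2
        assert not is_fully_connected(g)

    def test_empty_network_raises(self):
        net = sample_network(NetworkParams(astral_number=1, n_asters=0, seed=0))
        with pytest.raises(ValueError):
            is_fully_connected(net)


class TestPercolationProbability:
    def test_single_aster_connectivity_limit(self):
        est = percolation_probability(
            2, 0.02, s=10.0, mode="connectivity", n_samples=20, seed=0
        )
        # N_n = 1: a unique component by definition
        assert est.probability == 1.0

    def test_dense_limit_percolates(self):
        # spanning saturates for dense non-astral networks; strict
        # connectivity needs a_n >= 2 (a stray edge filament with a_n=1
        # keeps a singleton component at any practical density)
        est = percolation_probability(1, 30.0, s=4.0, mode="spanning", n_samples=15, seed=1)
        assert est.probability >= 0.9
        est = percolation_probability(
            4, 30.0, s=4.0, mode="connectivity", n_samples=15, seed=1
        )
        assert est.probability >= 0.9

    def test_wilson_interval_brackets_estimate(self):
        est = percolation_probability(1, 5.0, s=5.0, n_samples=50, seed=3)
        assert est.ci_low <= est.probability <= est.ci_high
        assert 0.0 <= est.ci_low and est.ci_high <= 1.0

    def test_tiny_system_matches_oversampled_oracle(self):
        # s=2, ell=1: the 10x-sampled estimate is the reference; the
        # small-sample estimate must fall inside its own Wilson CI band
        kw = dict(rho=3.0, ell=1.0, s=2.0, mode="spanning")
        small = percolation_probability(1, n_samples=100, seed=11, **kw)
        big = percolation_probability(1, n_samples=1000, seed=12, **kw)
        assert small.ci_low - 0.02 <= big.probability <= small.ci_high + 0.02

    def test_monotone_trend_in_density(self):
        dens = [2.0, 4.0, 6.0, 8.0]
        cv = percolation_curves(1, dens, s=5.0, n_samples=60, seed=4)["spanning"]
        # statistical monotonicity: Spearman correlation positive
        from scipy.stats import spearmanr

        rho_s = spearmanr(dens, cv.probabilities).statistic
        assert rho_s > 0
        assert cv.probabilities[-1] > cv.probabilities[0]


class TestFitCriticalDensity:
    def test_exact_logistic_midpoint(self):
        rho = np.linspace(2.0, 8.0, 25)
        p = 1.0 / (1.0 + np.exp(-4.0 * (rho - 5.0)))
        curve = PercolationCurve("spanning", 1, rho, p, 1000)
        assert fit_critical_density(curve) == pytest.approx(5.0, abs=0.05)

    def test_step_data_brackets(self):
        curve = PercolationCurve("spanning", 1, [1, 2, 3, 4], [0, 0, 1, 1], 100)
        rc = fit_critical_density(curve)
        assert 2.0 < rc < 3.0

    def test_stable_under_sample_halving(self):
        # noisy logistic curves from n and n/2 Bernoulli samples agree to 2%
        rng = np.random.default_rng(7)
        rho = np.linspace(2, 8, 13)
        p = 1.0 / (1.0 + np.exp(-3.0 * (rho - 5.0)))
        est = []
        for n in (2000, 1000):
            phat = rng.binomial(n, p) / n
            est.append(fit_critical_density(PercolationCurve("spanning", 1, rho, phat, n)))
        assert abs(est[0] - est[1]) / est[0] < 0.02

    def test_unbracketed_curve_raises(self):
        curve = PercolationCurve("spanning", 1, [1, 2, 3], [0.6, 0.8, 0.9], 100)
        with pytest.raises(FitError, match="bracket"):
            fit_critical_density(curve)

    def test_densities_must_increase(self):
        with pytest.raises(ValueError):
            PercolationCurve("spanning", 1, [1, 1, 2], [0, 0.5, 1], 10)
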
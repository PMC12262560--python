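"""Overdamped dynamics: oracles with closed-form answers and invariants."""

import numpy as np
import pytest

from astral_mikado import MechParams, NetworkParams, Protocol, sample_network
from astral_mikado.mechanics import (
    discretize,
    make_chain_state,
    prepare_state,
    relax,
    run_experiment,
    run_force_phase,
    step,
)


@pytest.fixture(scope="module")
def mech():
    return MechParams()


def _chain(n, h=0.1):
    return np.array([[[i * h, 0.0] for i in range(n)]])


class TestDiscretize:
    def test_vertex_counts_and_segmentation(self, mech):
        net = sample_network(NetworkParams(astral_number=1, n_asters=10, seed=0))
        st = discretize(net, mech, rng=np.random.default_rng(0))
        g = st.network_group
        # ell=1, seg=0.2: 6 vertices, 5 segments per filament
        assert g.n_vertices == 6
        assert g.h == pytest.approx(0.2)
        gb = st.groups[1]
        assert gb.n_vertices == 21  # s=10, seg=0.5

    def test_crosslinker_budget_at_reference_density(self, mech):
        # 30 x filaments at rho=7.5, s=10 -> 22500 bulk particles
        # (225 per um^2) plus 10*s per boundary
        net = sample_network(NetworkParams(astral_number=1, density=7.5, seed=1))
        st = discretize(net, mech, rng=np.random.default_rng(0))
        s = net.params.domain_size
        n_bulk = mech.crosslinkers_per_filament * net.n_filaments
        assert n_bulk == 22_500
        assert n_bulk / s**2 == pytest.approx(225.0)
        assert st.linker_free.shape[0] == n_bulk + 2 * round(10 * s)

    def test_straight_filaments_have_zero_bending_energy(self, mech):
        net = sample_network(NetworkParams(astral_number=4, n_asters=5, seed=2))
        st = discretize(net, mech, rng=np.random.default_rng(0))
        assert st.bending_energy() == pytest.approx(0.0, abs=1e-20)


class TestStepOracles:
    def test_zero_force_no_motion(self, mech):
        st = make_chain_state(_chain(6, 0.2), mech)
        xy0 = st.xy.copy()
        for _ in range(10):
            step(st, mech, bind=False)
        assert np.abs(st.xy - xy0).max() < 1e-9

    def test_rigid_drift_speed_matches_stokes(self, mech):
        # constant force on a free chain: drift speed F / sum(gamma)
        st = make_chain_state(_chain(6, 0.2), mech)
        F = np.array([0.3, 0.2])
        st.force_idx = np.array([5])
        st.force_vec = F[None, :]
        v_exp = F / st.gamma.sum()
        x0 = st.xy.mean(axis=0).copy()
        n = 200
        for _ in range(n):
            step(st, mech, bind=False)
        v = (st.xy.mean(axis=0) - x0) / (n * mech.dt)
        assert np.allclose(v, v_exp, rtol=0.01)

    def test_cantilever_discrete_closed_form(self, mech):
        # clamped discrete chain, transverse tip force: compliance is
        # exactly (h^3/kappa) * sum_{i=1..m} i^2 for hinge chains
        n, h, f = 12, 0.1, 0.5
        st = make_chain_state(_chain(n, h), mech, pinned=[0, 1])
        st.force_idx = np.array([n - 1])
        st.force_vec = np.array([[0.0, f]])
        relax(st, mech, max_time=30.0, tol=1e-11)
        m = n - 2
        expected = f * h**3 * m * (m + 1) * (2 * m + 1) / (6 * mech.k_bend)
        assert st.xy[n - 1, 1] == pytest.approx(expected, rel=1e-3)

    def test_cantilever_matches_continuum_beam(self, mech):
        # finer discretization: tip deflection ~ f L^3 / (3 kappa), L
        # measured from the clamped vertex; small-deflection regime
        h, L, f = 0.025, 1.0, 0.5
        n = int(L / h) + 2  # one extra pinned segment forms the clamp
        st = make_chain_state(_chain(n, h), mech, pinned=[0, 1])
        st.force_idx = np.array([n - 1])
        st.force_vec = np.array([[0.0, f]])
        relax(st, mech, max_time=60.0, tol=1e-11)
        deflection = st.xy[n - 1, 1]
        theory = f * L**3 / (3 * mech.k_bend)
        assert deflection < 0.05 * L
        assert deflection == pytest.approx(theory, rel=0.05)

    def test_halved_timestep_agrees(self, mech):
        n, h, f = 12, 0.1, 0.5
        tips = []
        for dt in (0.01, 0.005):
            st = make_chain_state(_chain(n, h), mech, pinned=[0, 1])
            st.force_idx = np.array([n - 1])
            st.force_vec = np.array([[0.0, f]])
            relax(st, mech, max_time=30.0, tol=1e-11, dt=dt)
            tips.append(st.xy[n - 1, 1])
        assert abs(tips[1] - tips[0]) / abs(tips[0]) < 0.02

    def test_inextensibility_maintained(self, mech):
        st = make_chain_state(_chain(8, 0.1), mech, pinned=[0])
        st.force_idx = np.array([7])
        st.force_vec = np.array([[0.5, 0.8]])
        worst = 0.0
        for _ in range(100):
            step(st, mech, bind=False)
            seg = np.linalg.norm(np.diff(st.xy, axis=0), axis=1)
            worst = max(worst, np.abs(seg - 0.1).max())
        assert worst < 1e-4 * 0.1

    def test_energy_monotone_without_noise(self, mech):
        # potential (elastic - work) non-increasing under constant force
        st = make_chain_state(_chain(10, 0.1), mech, pinned=[0, 1])
        st.force_idx = np.array([9])
        st.force_vec = np.array([[0.0, 0.4]])
        prev = st.total_energy(mech)
        for _ in range(200):
            step(st, mech, bind=False)
            e = st.total_energy(mech)
            assert e <= prev + 1e-10
            prev = e


@pytest.fixture(scope="module")
def small_net():
    return sample_network(
        NetworkParams(astral_number=2, density=9.0, domain_size=3.0, seed=5)
    )


@pytest.fixture(scope="module")
def small_state(small_net, mech):
    return prepare_state(small_net, mech, "shear", seed=5)


class TestExperiment:
    def test_zero_force_small_release_transient(self, small_net, mech, small_state):
        res = run_experiment(
            small_net, mech, Protocol("shear", 0.0, t_force=10.0), seed=5, state=small_state
        )
        # only the anchor-release transient remains, well below the
        # force-driven displacements (~0.1 um and larger)
        assert abs(res.delta) < 1e-2

    def test_linear_response_doubling(self, small_net, mech, small_state):
        deltas = []
        for f in (0.25, 0.5):
            res = run_experiment(
                small_net, mech, Protocol("shear", f, t_force=20.0), seed=5, state=small_state
            )
            deltas.append(res.delta)
        assert deltas[1] == pytest.approx(2.0 * deltas[0], rel=0.10)

    def test_steady_state_reached(self, small_net, mech, small_state):
        work = small_state.copy()
        res = run_force_phase(work, mech, Protocol("shear", 0.5, t_force=40.0))
        before = work.xy.copy()
        step(work, mech, bind=False)
        com_speed = np.abs(work.xy - before).mean() / mech.dt
        assert com_speed < 1e-4

    def test_mirror_symmetry(self, mech):
        # reflecting the network about x=s/2 and negating the shear force
        # negates the displacement
        from astral_mikado.netgen import AstralNetwork

        net = sample_network(
            NetworkParams(astral_number=1, density=8.0, domain_size=3.0, seed=8)
        )
        s = net.params.domain_size
        mirrored = AstralNetwork(
            params=net.params,
            centers=np.column_stack([s - net.centers[:, 0], net.centers[:, 1]]),
            orientations=np.pi - net.orientations,
        )
        proto = Protocol("shear", 1.0, t_force=15.0)
        base = prepare_state(net, mech, "shear", seed=8)
        mirror = base.copy()
        # mirror the crosslinked state directly so binding randomness cancels
        mirror.xy = np.column_stack([s - base.xy[:, 0], base.xy[:, 1]])
        mirror.aster_centers = np.column_stack(
            [s - base.aster_centers[:, 0], base.aster_centers[:, 1]]
        )
        mirror.aster_ref_angles = np.pi - base.aster_ref_angles
        mirror.aster_angles = -base.aster_angles
        mirror.anchor_pos = np.column_stack(
            [s - base.anchor_pos[:, 0], base.anchor_pos[:, 1]]
        )
        r1 = run_force_phase(base.copy(), mech, proto)
        work = mirror.copy()
        from astral_mikado.mechanics import _apply_protocol_force

        _apply_protocol_force(work, mech, proto)
        work.force_vec = -work.force_vec  # leftward force on mirrored net
        initial = work.xy[: work.network_group.stop].copy()
        for _ in range(int(15.0 / mech.dt)):
            step(work, mech, bind=False)
        final = work.xy[: work.network_group.stop]
        d2 = (final - initial).mean(axis=0)[0]
        assert d2 == pytest.approx(-r1.delta, abs=max(1e-4, 0.02 * abs(r1.delta)))

    def test_seed_reproducibility(self, small_net, mech):
        a = prepare_state(small_net, mech, "shear", seed=77)
        b = prepare_state(small_net, mech, "shear", seed=77)
        assert np.array_equal(a.xy, b.xy)
        assert np.array_equal(a.spring_i, b.spring_i)
        assert np.array_equal(a.spring_wi, b.spring_wi)
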
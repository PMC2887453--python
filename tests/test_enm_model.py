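"""Network construction, elastic energy/forces, and the Hessian.

The force oracle throughout is the central finite difference of the
energy; the Hessian oracle is the finite difference of the forces.
"""

import numpy as np
import pytest

import enmrelax as ex
from enmrelax.enm_model import read_network_text, write_network_text
from enmrelax.synthetic_data import FixtureSpec, make_toy_chain


def finite_difference_forces(net, R, h=1e-5):
    F = np.zeros_like(R)
    for i in range(R.shape[0]):
        for k in range(3):
            rp, rm = R.copy(), R.copy()
            rp[i, k] += h
            rm[i, k] -= h
            F[i, k] = -(ex.elastic_energy(net, rp)
                        - ex.elastic_energy(net, rm)) / (2 * h)
    return F


def random_conformation(net, rng, amplitude=0.3):
    return net.R0 + amplitude * rng.standard_normal(net.R0.shape)


@pytest.fixture(scope="module")
def fixture_nets():
    """Three small networks of different geometry for oracle sweeps."""
    chain = make_toy_chain(FixtureSpec(kind="chain", n_particles=8))
    helix = make_toy_chain(FixtureSpec(kind="helix", n_particles=10))
    rng = np.random.default_rng(7)
    blob = rng.uniform(0, 8, size=(10, 3))
    return [
        ex.build_network(chain, cutoff=10.0),
        ex.build_network(helix, cutoff=7.0),
        ex.build_network(blob, cutoff=6.0),
    ]


class TestBuildNetwork:
    def test_unit_square_links_edges_not_diagonals(self):
        square = np.array(
            [[0.0, 0, 0], [1.0, 0, 0], [1.0, 1, 0], [0.0, 1, 0]]
        )
        net = ex.build_network(square, cutoff=1.2)
        assert net.n_links == 4
        assert not any(
            {tuple(e)} == {(0, 2)} or {tuple(e)} == {(1, 3)}
            for e in net.edges
        )

    def test_chain_links_nearest_and_next_nearest(self):
        chain = make_toy_chain(FixtureSpec(kind="chain", n_particles=10))
        net = ex.build_network(chain, cutoff=10.0)
        assert net.n_links == 2 * 10 - 3

    def test_natural_lengths_equal_reference_distances(self, hinge):
        net = hinge["net"]
        d = np.linalg.norm(
            net.R0[net.edges[:, 0]] - net.R0[net.edges[:, 1]], axis=1
        )
        np.testing.assert_allclose(d, net.d0, rtol=0, atol=1e-12)
        assert np.all(net.d0 < net.cutoff)

    def test_adjacency_symmetric_zero_diagonal(self, hinge):
        a = hinge["net"].adjacency
        assert np.array_equal(a, a.T)
        assert np.all(np.diag(a) == 0)

    def test_strict_inequality_at_cutoff(self):
        pair = np.array([[0.0, 0, 0], [2.0, 0, 0], [0.0, 5, 0]])
        with pytest.warns(UserWarning):
            net = ex.build_network(pair, cutoff=2.0)
        assert net.n_links == 0  # d == cutoff is excluded

    def test_too_few_particles_is_an_error(self):
        with pytest.raises(ValueError):
            ex.build_network(np.zeros((1, 3)), cutoff=5.0)

    def test_disconnected_graph_warns(self):
        coords = np.vstack([np.zeros((2, 3)), np.full((2, 3), 100.0)])
        coords[1, 0] = 1.0
        coords[3, 0] = 101.0
        with pytest.warns(UserWarning, match="disconnected"):
            ex.build_network(coords, cutoff=2.0)

    def test_edge_list_round_trip(self, hinge):
        net = hinge["net"]
        net2 = read_network_text(write_network_text(net))
        assert np.array_equal(net.edges, net2.edges)
        np.testing.assert_allclose(net.R0, net2.R0, atol=1e-6)
        np.testing.assert_allclose(net.d0, net2.d0, atol=1e-6)
        assert net2.cutoff == net.cutoff


class TestEnergy:
    def test_zero_at_reference(self, hinge):
        assert ex.elastic_energy(hinge["net"], hinge["net"].R0) == 0.0

    def test_single_spring_hooke_value(self, spring_net):
        conf = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        assert ex.elastic_energy(spring_net, conf) == pytest.approx(0.125)

    def test_quadratic_form_matches_hessian_for_small_displacement(
        self, hinge
    ):
        net = hinge["net"]
        H = ex.hessian(net)
        rng = np.random.default_rng(11)
        delta = 1e-3 * rng.standard_normal(net.R0.shape)
        e = ex.elastic_energy(net, net.R0 + delta)
        quad = 0.5 * delta.ravel() @ H @ delta.ravel()
        assert e == pytest.approx(quad, rel=1e-2)

    def test_rigid_motion_invariance(self, hinge):
        from scipy.spatial.transform import Rotation

        net = hinge["net"]
        rng = np.random.default_rng(5)
        conf = random_conformation(net, rng)
        e0 = ex.elastic_energy(net, conf)
        rot = Rotation.random(random_state=1)
        moved = rot.apply(conf) + np.array([11.0, -3.0, 42.0])
        assert ex.elastic_energy(net, moved) == pytest.approx(
            e0, rel=1e-10
        )


class TestForces:
    def test_zero_at_reference(self, hinge):
        f = ex.elastic_forces(hinge["net"], hinge["net"].R0)
        assert np.max(np.abs(f)) < 1e-12

    def test_single_spring_pulls_particles_together(self, spring_net):
        conf = np.array([[0.0, 0, 0], [1.5, 0, 0]])
        f = ex.elastic_forces(spring_net, conf)
        np.testing.assert_allclose(
            f, [[0.5, 0, 0], [-0.5, 0, 0]], atol=1e-12
        )

    def test_matches_finite_difference_gradient(self, fixture_nets):
        rng = np.random.default_rng(2)
        for net in fixture_nets:
            for _ in range(20):
                conf = random_conformation(net, rng)
                f = ex.elastic_forces(net, conf)
                fd = finite_difference_forces(net, conf)
                scale = max(np.abs(fd).max(), 1e-12)
                assert np.abs(f - fd).max() / scale < 1e-6

    def test_total_force_and_torque_vanish(self, hinge):
        net = hinge["net"]
        rng = np.random.default_rng(8)
        conf = random_conformation(net, rng)
        f = ex.elastic_forces(net, conf)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-10)
        torque = np.cross(conf - conf.mean(axis=0), f).sum(axis=0)
        np.testing.assert_allclose(torque, 0.0, atol=1e-10)

    def test_coincident_linked_particles_error(self, spring_net):
        conf = np.zeros((2, 3))
        with pytest.raises(ValueError, match="coincide"):
            ex.elastic_forces(spring_net, conf)


class TestHessian:
    def test_single_spring_spectrum(self, spring_net):
        lam = np.linalg.eigvalsh(ex.hessian(spring_net))
        np.testing.assert_allclose(lam[:5], 0.0, atol=1e-10)
        assert lam[5] == pytest.approx(2.0)

    def test_symmetric_and_psd(self, hinge):
        H = ex.hessian(hinge["net"])
        assert np.array_equal(H, H.T)
        lam = np.linalg.eigvalsh(H)
        assert lam[0] > -1e-10 * lam[-1]

    def test_row_block_sums_vanish(self, hinge):
        H = ex.hessian(hinge["net"])
        n = hinge["net"].n_particles
        blocks = H.reshape(n, 3, n, 3).sum(axis=2)
        np.testing.assert_allclose(blocks, 0.0, atol=1e-10)

    def test_generic_network_has_exactly_six_zero_eigenvalues(self, hinge):
        lam = np.linalg.eigvalsh(ex.hessian(hinge["net"]))
        assert int(np.sum(lam < 1e-8 * lam[-1])) == 6

    def test_matches_finite_difference_force_jacobian(self, fixture_nets):
        net = fixture_nets[1]  # helix
        H = ex.hessian(net)
        n3 = 3 * net.n_particles
        h = 1e-5
        fd = np.zeros((n3, n3))
        for col in range(n3):
            rp = net.R0.ravel().copy()
            rm = rp.copy()
            rp[col] += h
            rm[col] -= h
            fp = ex.elastic_forces(net, rp.reshape(-1, 3)).ravel()
            fm = ex.elastic_forces(net, rm.reshape(-1, 3)).ravel()
            fd[:, col] = -(fp - fm) / (2 * h)
        assert np.abs(H - fd).max() < 1e-6
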
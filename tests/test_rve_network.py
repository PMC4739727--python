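"""Fiber-network RVE: force law, generation, equilibrium, stress averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fibergel.rve_network import (
    FiberNetwork,
    GenerationError,
    NetworkMaterial,
    fiber_force,
    generate_network,
    internal_forces,
    network_orientation,
    orientation_tensor_2d,
    shorten_reference_lengths,
    solve_equilibrium,
    volume_avg_stress,
)

from conftest import random_truss


class TestFiberForce:
    def test_zero_at_unit_stretch(self, material):
        assert fiber_force(1.0, material) == 0.0

    def test_reference_value(self, material):
        # direct arithmetic: eps = 0.5(1.1^2 - 1) = 0.105,
        # F = (3e-10/4) (exp(0.42) - 1) = 3.9147e-11 N
        assert fiber_force(1.1, material) == pytest.approx(3.9147e-11, rel=1e-4)

    def test_strictly_increasing(self, material):
        lams = np.linspace(0.5, 2.0, 200)
        f = fiber_force(lams, material)
        assert np.all(np.diff(f) > 0)

    def test_small_b_branch_matches_linear_law(self):
        lin = NetworkMaterial(EfAf=3e-10, B=0.0)
        lam = 1.3
        eps = 0.5 * (lam**2 - 1)
        assert fiber_force(lam, lin) == pytest.approx(3e-10 * eps, rel=1e-12)

    def test_small_strain_linear_agreement(self, material):
        # relative agreement with EfAf*eps to <1% for |eps| < 1e-3 at B = 4
        for eps in (1e-3, -1e-3, 1e-4):
            lam = np.sqrt(2 * eps + 1)
            assert fiber_force(lam, material) == pytest.approx(
                material.EfAf * eps, rel=0.01
            )

    def test_rejects_bad_stretch(self, material):
        with pytest.raises(ValueError):
            fiber_force(np.nan, material)
        with pytest.raises(ValueError):
            fiber_force(-0.5, material)


class TestGeneration:
    def test_deterministic_per_seed(self):
        a = generate_network(7, target_fibers=60)
        b = generate_network(7, target_fibers=60)
        assert np.array_equal(a.node_positions, b.node_positions)
        assert np.array_equal(a.fibers, b.fibers)
        assert np.array_equal(a.ref_lengths, b.ref_lengths)
        assert np.array_equal(a.boundary, b.boundary)

    def test_structure_invariants(self):
        net = generate_network(11)
        assert np.all(net.fibers[:, 0] != net.fibers[:, 1])
        assert np.all(net.ref_lengths > 0)
        # boundary nodes on cube faces
        pos = net.node_positions[net.boundary]
        on_face = np.any((pos < 1e-9) | (pos > 1 - 1e-9), axis=1)
        assert np.all(on_face)
        # no isolated interior node
        deg = np.bincount(net.fibers.ravel(), minlength=net.n_nodes)
        assert np.all(deg[~net.boundary] >= 2)

    def test_near_isotropy_of_projection(self):
        for seed in (1, 2, 3, 4, 5):
            assert network_orientation(generate_network(seed)).alpha < 0.15

    def test_mean_fiber_count_short_sweep(self):
        counts = [generate_network(s).n_fibers for s in range(1, 21)]
        assert np.mean(counts) == pytest.approx(337, abs=25)

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            generate_network(1, target_fibers=0)


class TestEquilibrium:
    def test_stress_free_reference(self, material):
        net = generate_network(5, target_fibers=60)
        sol = solve_equilibrium(
            net, np.zeros((len(net.boundary_idx), 3)), material
        )
        assert sol.converged
        assert np.allclose(sol.deformed_positions, net.node_positions)
        assert np.allclose(sol.avg_stress, 0.0)

    def test_split_fiber_midpoint_symmetry(self, material):
        # interior node on a uniaxially stretched fiber settles where both
        # segments carry equal stretch
        net = FiberNetwork(
            np.array([[0.0, 0.5, 0.5], [0.3, 0.5, 0.5], [1.0, 0.5, 0.5]]),
            np.array([[0, 1], [1, 2]]),
            np.array([0.3, 0.7]),
            np.array([True, False, True]),
        )
        sol = solve_equilibrium(
            net, np.array([[0.0, 0, 0], [0.2, 0, 0]]), material, rel_tol=1e-9
        )
        assert sol.deformed_positions[1, 0] == pytest.approx(0.36, rel=1e-6)

    def test_toy_network_matches_energy_minimization_oracle(self, material):
        # 5-node, 6-fiber toy network; independent oracle: minimize the
        # total strain energy over interior coordinates with scipy (BFGS on
        # a loop-written energy/gradient, no code shared with the solver)
        from scipy.integrate import quad
        from scipy.optimize import minimize

        rng = np.random.default_rng(0)
        pos = np.array(
            [
                [0.0, 0.0, 0.0], [1.0, 0.0, 0.1], [1.0, 1.0, 0.0],
                [0.0, 1.0, 0.2], [0.4, 0.5, 0.6],
            ]
        )
        fibers = np.array([[0, 4], [1, 4], [2, 4], [3, 4], [0, 1], [2, 3]])
        lengths = np.linalg.norm(pos[fibers[:, 1]] - pos[fibers[:, 0]], axis=1)
        net = FiberNetwork(pos, fibers, lengths * 0.95,
                           np.array([True, True, True, True, False]))
        bd = 0.05 * rng.standard_normal((4, 3))
        sol = solve_equilibrium(net, bd, material, rel_tol=1e-9)

        def force(lam):
            # per unit EfAf so the oracle optimizes O(1) numbers
            return (np.exp(material.B * 0.5 * (lam**2 - 1)) - 1.0) / material.B

        fixed = pos[:4] + bd

        def energy(q):
            x = np.vstack([fixed, q.reshape(1, 3)])
            e = 0.0
            for (a, b), L0 in zip(fibers, net.ref_lengths):
                lam = np.linalg.norm(x[b] - x[a]) / L0
                e += L0 * quad(force, 1.0, lam)[0]
            return e

        def grad(q):
            x = np.vstack([fixed, q.reshape(1, 3)])
            g = np.zeros(3)
            for (a, b), L0 in zip(fibers, net.ref_lengths):
                if a != 4 and b != 4:
                    continue
                d = x[b] - x[a]
                l = np.linalg.norm(d)
                f = force(l / L0)
                u = d / l
                g += f * u if b == 4 else -f * u
            return g

        res = minimize(energy, pos[4], jac=grad, method="BFGS",
                       options={"gtol": 1e-13, "maxiter": 500})
        assert np.linalg.norm(sol.deformed_positions[4] - res.x) <= 1e-8 * (
            1.0 + np.linalg.norm(res.x)
        )

    def test_converged_residual_at_or_below_reported_threshold(self, material):
        net = generate_network(9, target_fibers=60)
        xb = net.node_positions[net.boundary_idx]
        bd = 0.05 * (xb - 0.5)  # 5% dilation
        sol = solve_equilibrium(net, bd, material)
        assert sol.converged
        g = internal_forces(sol.deformed_positions, net, material)
        res = np.max(np.linalg.norm(g[net.interior_idx], axis=1))
        assert res == pytest.approx(sol.residual_norm, rel=1e-9)

    def test_wrong_boundary_displacement_shape(self, material):
        net = generate_network(5, target_fibers=60)
        with pytest.raises(ValueError):
            solve_equilibrium(net, np.zeros((3, 3)), material)


class TestVolumeAvgStress:
    def test_undeformed_is_zero(self, material):
        net = generate_network(6, target_fibers=60)
        sol = solve_equilibrium(net, np.zeros((len(net.boundary_idx), 3)),
                                material)
        assert np.allclose(volume_avg_stress(sol, net), 0.0)

    def test_single_fiber_hand_value(self, material):
        # fiber spanning the cube along x stretched to lambda:
        # sigma_xx = lambda * F / V, everything else zero
        lam = 1.1
        net = FiberNetwork(
            np.array([[0.0, 0.5, 0.5], [1.0, 0.5, 0.5]]),
            np.array([[0, 1]]), np.array([1.0]), np.array([True, True]),
        )
        sol = solve_equilibrium(
            net, np.array([[0.0, 0, 0], [lam - 1, 0, 0]]), material
        )
        expected = lam * fiber_force(lam, material)
        s = volume_avg_stress(sol, net)
        assert s[0, 0] == pytest.approx(expected, rel=1e-9)
        s_off = s.copy()
        s_off[0, 0] = 0.0
        assert np.allclose(s_off, 0.0, atol=1e-25)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed, material):
        # independent oracle: per-boundary-node external force from a
        # loop-written force law, then the plain dyadic sum of Eq-form
        net = random_truss(seed)
        rng = np.random.default_rng(1000 + seed)
        bd = 0.03 * rng.standard_normal((len(net.boundary_idx), 3))
        sol = solve_equilibrium(net, bd, material, rel_tol=1e-8)
        assert sol.converged
        x = sol.deformed_positions
        oracle = np.zeros((3, 3))
        for bi, node in enumerate(net.boundary_idx):
            f_ext = np.zeros(3)
            for (a, b), L0 in zip(net.fibers, net.ref_lengths):
                if node not in (a, b):
                    continue
                other = b if a == node else a
                d = x[other] - x[node]
                l = np.linalg.norm(d)
                lam = l / L0
                fmag = material.EfAf / material.B * (
                    np.exp(material.B * 0.5 * (lam**2 - 1)) - 1.0
                )
                f_ext -= fmag * d / l  # reaction balancing the fiber pull
            oracle += np.outer(x[node], f_ext) / net.volume
        got = volume_avg_stress(sol, net)
        scale = max(np.abs(oracle).max(), 1e-30)
        assert np.allclose(got, oracle, atol=1e-6 * scale)


class TestShortening:
    def test_zero_fraction_identity(self):
        net = generate_network(3, target_fibers=60)
        out = shorten_reference_lengths(net, 0.0)
        assert np.array_equal(out.ref_lengths, net.ref_lengths)
        assert np.array_equal(out.fibers, net.fibers)

    def test_nominal_traction_fraction(self):
        net = generate_network(3, target_fibers=60)
        out = shorten_reference_lengths(net, 0.24)
        assert np.allclose(out.ref_lengths, 0.76 * net.ref_lengths)

    def test_multiplicative_composition(self):
        net = generate_network(3, target_fibers=60)
        twice = shorten_reference_lengths(
            shorten_reference_lengths(net, 0.12), 0.12
        )
        once = shorten_reference_lengths(net, 1.0 - 0.88**2)
        assert np.allclose(twice.ref_lengths, once.ref_lengths)

    def test_rejects_full_shortening(self):
        net = generate_network(3, target_fibers=60)
        with pytest.raises(ValueError):
            shorten_reference_lengths(net, 1.0)


class TestOrientationTensor:
    def test_single_fiber_along_x(self):
        seg = np.array([[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]])
        r = orientation_tensor_2d(seg)
        assert np.allclose(r.tensor, [[1, 0], [0, 0]], atol=1e-15)
        assert r.alpha == pytest.approx(1.0)

    def test_orthogonal_pair_isotropic(self):
        segs = np.array(
            [
                [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]],
                [[0.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
            ]
        )
        r = orientation_tensor_2d(segs)
        assert np.allclose(r.tensor, 0.5 * np.eye(2), atol=1e-15)
        assert r.alpha == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_fiber(self):
        seg = np.array([[[0.0, 0.0, 0.0], [1.0, 1.0, 0.0]]])
        r = orientation_tensor_2d(seg)
        assert np.allclose(r.tensor, [[0.5, 0.5], [0.5, 0.5]], atol=1e-15)
        assert r.alpha == pytest.approx(1.0)
        assert r.angle == pytest.approx(np.pi / 4)

    def test_degenerate_projection_rejected(self):
        seg = np.array([[[0.0, 0.0, 0.0], [0.0, 0.0, 1.0]]])  # out of plane
        with pytest.raises(ValueError):
            orientation_tensor_2d(seg)

    @given(
        seed=st.integers(0, 10_000),
        theta=st.floats(0.0, np.pi, allow_nan=False),
    )
    @settings(max_examples=40, deadline=None)
    def test_trace_bounds_and_rotation_equivariance(self, seed, theta):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        p0 = rng.standard_normal((n, 2))
        p1 = p0 + rng.standard_normal((n, 2)) + 0.1
        segs = np.stack([p0, p1], axis=1)
        r = orientation_tensor_2d(segs)
        assert np.trace(r.tensor) == pytest.approx(1.0, abs=1e-12)
        assert 0.0 <= r.alpha <= 1.0 + 1e-12
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        r2 = orientation_tensor_2d(segs @ rot.T)
        if r.alpha > 1e-6:  # the principal angle of a near-isotropic set is noise
            d = (r2.angle - r.angle - theta) % np.pi
            assert min(d, np.pi - d) < 1e-6
        assert r2.alpha == pytest.approx(r.alpha, abs=1e-9)


class TestSerialization:
    def test_hdf5_round_trip(self, tmp_path):
        net = generate_network(4, target_fibers=60)
        path = tmp_path / "net.h5"
        net.save(path)
        back = FiberNetwork.load(path)
        assert np.array_equal(back.node_positions, net.node_positions)
        assert np.array_equal(back.fibers, net.fibers)
        assert np.array_equal(back.ref_lengths, net.ref_lengths)
        assert back.seed == net.seed

    def test_fiber_table_csv(self, tmp_path):
        import pandas as pd

        net = generate_network(4, target_fibers=60)
        table = net.fiber_table()
        assert {"node_a", "node_b", "ref_length", "length"} <= set(table.columns)
        assert len(table) == net.n_fibers
        path = tmp_path / "fibers.csv"
        table.to_csv(path, index=False)
        assert pd.read_csv(path).shape == table.shape


def test_generation_error_names_the_seed():
    with pytest.raises(GenerationError, match="seed 13"):
        generate_network(13, target_fibers=60, max_retries=0)
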
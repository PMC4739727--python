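"""Macro mesh, domains, continuum stress and the coupled model."""

import numpy as np
import pytest

from fibergel import rve_network as rvn
from fibergel.macro_model import (
    ContinuumMaterial,
    ExplantLayout,
    MultiscaleModel,
    SimulationConfig,
    assign_domains,
    build_mesh,
    desk_config,
    element_regions,
    fixed_bc,
    free_bc,
    neo_hookean_stress,
    reference_config,
    reference_layout,
    write_vtk,
)


class TestMesh:
    @pytest.mark.parametrize(
        "nx,ny,nz",
        [(1, 1, 1), (3, 2, 1), (46, 46, 4), (12, 12, 1)],
    )
    def test_node_and_element_count_formulae(self, nx, ny, nz):
        m = build_mesh(nx, ny, nz, 8.0, 8.0, 0.8)
        assert m.n_elements == nx * ny * nz
        assert m.n_nodes == (nx + 1) * (ny + 1) * (nz + 1)

    def test_gel_scale_mesh(self):
        m = build_mesh(46, 46, 4, 8.0, 8.0, 0.8)
        assert m.n_elements == 8464
        assert m.n_nodes == 11045
        assert m.spacing[0] == pytest.approx(8.0 / 46)

    def test_positive_volumes(self):
        m = build_mesh(3, 2, 2, 1.0, 2.0, 0.5)
        for e in range(m.n_elements):
            x = m.coords[m.elements[e]]
            # regular grid: each element spans a positive box
            assert np.all(x.max(axis=0) - x.min(axis=0) > 0)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            build_mesh(0, 1, 1, 1, 1, 1)
        with pytest.raises(ValueError):
            build_mesh(1, 1, 1, 0, 1, 1)


class TestDomains:
    def test_gel_scale_layout_geometry(self):
        m = build_mesh(46, 46, 4, 8.0, 8.0, 0.8)
        lab = assign_domains(m, reference_layout())
        assert len(lab.cellular_elements) == 48  # 3 patches x 16
        h = 8.0 / 46
        assert 16 * h * h == pytest.approx(0.484, abs=5e-4)
        d = np.sort(lab.centroid_distances())
        assert d[2] == pytest.approx(2.09, abs=5e-3)  # top pair
        assert d[0] == pytest.approx(2.03, abs=5e-3)
        assert d[1] == pytest.approx(2.03, abs=5e-3)

    def test_patches_on_top_layer_only(self):
        m = build_mesh(46, 46, 4, 8.0, 8.0, 0.8)
        lab = assign_domains(m, reference_layout())
        k_top = 3
        for ids in lab.patches:
            assert np.all(ids // (46 * 46) == k_top)

    def test_overlap_rejected(self):
        m = build_mesh(12, 12, 1, 8.0, 8.0, 0.8)
        with pytest.raises(ValueError):
            assign_domains(m, ExplantLayout([(2, 2), (3, 2)], patch_size=2))

    def test_out_of_bounds_rejected(self):
        m = build_mesh(12, 12, 1, 8.0, 8.0, 0.8)
        with pytest.raises(ValueError):
            assign_domains(m, ExplantLayout([(11, 11)], patch_size=2))


class TestBoundaryConditions:
    def test_fixed_keeps_top_free(self):
        m = build_mesh(4, 4, 2, 8.0, 8.0, 0.8)
        bc = fixed_bc(m)
        fixed = set(bc.fixed_nodes.tolist())
        top_interior = [
            m.node_id(i, j, 2) for i in range(1, 4) for j in range(1, 4)
        ]
        assert not (set(top_interior) & fixed)
        # every bottom and lateral node is fixed
        c = m.coords
        expect = np.flatnonzero(
            (c[:, 2] < 1e-9) | (c[:, 0] < 1e-9) | (c[:, 0] > 8 - 1e-9)
            | (c[:, 1] < 1e-9) | (c[:, 1] > 8 - 1e-9)
        )
        assert fixed == set(expect.tolist())

    def test_free_anchor_patch(self):
        m = build_mesh(46, 46, 4, 8.0, 8.0, 0.8)
        bc = free_bc(m, anchor_mm=1.74)
        c = m.coords[bc.fixed_nodes]
        assert np.all(c[:, 2] < 1e-9)
        assert np.all(np.abs(c[:, 0] - 4.0) <= 0.87 + 1e-6)
        # 1.74 mm at h = 8/46 mm spans 10 elements -> 11 x 11 nodes
        assert len(bc.fixed_nodes) == 121

    def test_free_anchor_must_catch_nodes(self):
        m = build_mesh(3, 3, 1, 8.0, 8.0, 0.8)  # no node at the gel center
        with pytest.raises(ValueError):
            free_bc(m, anchor_mm=0.1)


class TestNeoHookean:
    def test_identity_is_stress_free(self):
        assert np.allclose(neo_hookean_stress(np.eye(3), ContinuumMaterial()), 0)

    def test_simple_shear_closed_form(self):
        # J = 1: sigma = G (B - I); gamma = 0.1 gives s12 = G gamma,
        # s11 = G gamma^2
        F = np.eye(3)
        F[0, 1] = 0.1
        s = neo_hookean_stress(F, ContinuumMaterial(G=1.0, nu=0.3))
        assert s[0, 1] == pytest.approx(0.1)
        assert s[0, 0] == pytest.approx(0.01)
        assert s[2, 2] == pytest.approx(0.0, abs=1e-15)

    def test_dilation_closed_form(self):
        s = neo_hookean_stress(1.01 * np.eye(3), ContinuumMaterial(G=1.0, nu=0.3))
        assert s[0, 0] == pytest.approx(0.0630, abs=2e-4)
        assert s[0, 0] == pytest.approx(s[1, 1]) == pytest.approx(s[2, 2])

    def test_inverted_element_rejected(self):
        F = np.diag([1.0, 1.0, -0.5])
        with pytest.raises(ValueError):
            neo_hookean_stress(F, ContinuumMaterial())

    def test_material_validation(self):
        with pytest.raises(ValueError):
            ContinuumMaterial(G=-1.0)
        with pytest.raises(ValueError):
            ContinuumMaterial(nu=0.5)


class TestRVEAttachment:
    def test_gel_scale_rve_count_by_counting(self):
        model = MultiscaleModel(reference_config("fixed"))
        assert model.n_rves == 67712  # 8464 elements x 8 Gauss points

    def test_desk_scale_one_per_element(self):
        model = MultiscaleModel(desk_config("free"))
        assert model.n_rves == model.mesh.n_elements == 144

    def test_slot_seeds_unique_and_deterministic(self):
        a = MultiscaleModel(desk_config("free", seed=3))
        b = MultiscaleModel(desk_config("free", seed=3))
        seeds_a = [s.seed for s in a.slots]
        assert seeds_a == [s.seed for s in b.slots]
        assert len(set(seeds_a)) == len(seeds_a)


class TestCoupledModel:
    def test_zero_compaction_zero_displacement(self):
        cfg = SimulationConfig(
            nx=4, ny=4, nz=1, patch_origins=[(0, 3), (3, 3), (1, 0)],
            patch_size=1, target_fibers=40, bc_case="fixed", seed=1,
        )
        model = MultiscaleModel(cfg)
        model.macro_solve()
        assert np.allclose(model.u, 0.0)

    def test_single_element_two_path_stress_consistency(self):
        # the stress the coupled model sees at a quadrature point must equal
        # the standalone pipeline: generate -> affine boundary solve ->
        # dyadic average / (J a^2) + neo-Hookean term
        cfg = SimulationConfig(
            nx=1, ny=1, nz=1, patch_origins=[(0, 0)], patch_size=1,
            target_fibers=40, bc_case="fixed", seed=2, B=1e-12,
        )
        model = MultiscaleModel(cfg)
        F = np.array([[1.04, 0.01, 0.0], [0.0, 0.97, 0.0], [0.0, 0.0, 1.02]])
        slot = model.slots[0]
        sigma, _, _ = model._slot_stress(slot, F)

        net = rvn.generate_network(slot.seed, target_fibers=40)
        c = np.full(3, 0.5)
        xb = net.node_positions[net.boundary_idx]
        bd = (xb - c) @ F.T + c - xb
        sol = rvn.solve_equilibrium(net, bd, rvn.NetworkMaterial(cfg.EfAf, cfg.B),
                                    rel_tol=1e-8)
        S = rvn.volume_avg_stress(sol, net)
        J = np.linalg.det(F)
        expected = 0.5 * (S + S.T) / (J * cfg.rve_side**2) + neo_hookean_stress(
            F, ContinuumMaterial(cfg.G, cfg.nu)
        )
        assert np.allclose(sigma, expected, rtol=1e-6, atol=1e-12)

    def test_compaction_run_outputs(self, small_compaction):
        res = small_compaction
        assert res.displacements.shape[0] == 3  # reference + 2 increments
        assert np.allclose(res.displacements[0], 0.0)
        # explant area decreases monotonically with compaction
        mean_area = res.areas.mean(axis=1)
        assert np.all(np.diff(mean_area) < 0)
        assert res.compaction[-1] == pytest.approx(0.10, abs=1e-12)
        # alignment changes concentrate around the explants
        reg = element_regions(res.model.mesh, res.model.labels)
        assert res.delta_alpha[reg["near"]].mean() > res.delta_alpha[
            reg["far"]
        ].mean()

    def test_reaction_forces_balance(self, small_compaction):
        model = small_compaction.model
        reactions = model.reaction_forces()
        scale = np.abs(reactions).max()
        assert scale > 0
        # net force on the supports vanishes to within the macro solve
        # tolerance (the interior residual is what is left unbalanced)
        assert np.abs(reactions.sum(axis=0)).max() < 1e-3 * scale

    def test_unknown_bc_case_rejected(self):
        with pytest.raises(ValueError):
            MultiscaleModel(desk_config("clamped"))


class TestConfigAndExport:
    def test_config_round_trip(self):
        cfg = reference_config("free", seed=11)
        again = SimulationConfig.from_dict(cfg.to_dict())
        assert again == cfg

    def test_yaml_config_round_trip(self, tmp_path):
        cfg = desk_config("free", seed=7, n_increments=3)
        path = tmp_path / "run.yaml"
        cfg.to_yaml(path)
        assert SimulationConfig.from_yaml(path) == cfg

    def test_write_vtk(self, tmp_path):
        m = build_mesh(2, 2, 1, 1.0, 1.0, 0.5)
        path = tmp_path / "out.vtk"
        write_vtk(
            path, m,
            point_data={"displacement": np.zeros((m.n_nodes, 3))},
            cell_data={"alpha": np.arange(m.n_elements, dtype=float)},
        )
        text = path.read_text()
        assert "UNSTRUCTURED_GRID" in text
        assert f"POINTS {m.n_nodes}" in text
        assert "VECTORS displacement" in text
        assert "SCALARS alpha" in text


class TestCouplingTerm:
    def test_toggle_runs_and_reports_magnitude(self):
        cfg = SimulationConfig(
            nx=2, ny=2, nz=1, patch_origins=[(0, 0)], patch_size=1,
            target_fibers=40, n_increments=1, total_shortening=0.03,
            bc_case="fixed", seed=4, include_coupling=True,
        )
        model = MultiscaleModel(cfg)
        model.apply_shortening(0.03)
        model.macro_solve()
        assert len(model.coupling_log) == 1
        assert model.coupling_log[0] >= 0.0
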
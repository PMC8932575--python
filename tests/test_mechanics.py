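"""Energy functional, analytic forces, solvers, pressure, ground state."""

import numpy as np
import pytest

from epivertex.mesh import Cell, TissueState, cell_area, validate
from epivertex.mechanics import (
    GeometryCache,
    MechanicsParams,
    cell_pressure,
    energy,
    forces,
    relax_quasistatic,
    relax_viscous,
    soft_network_transition,
    HEX_PERIMETER,
)


def single_cell(coords, **kw):
    return TissueState(vertices=np.asarray(coords, float),
                       cells={0: Cell(vertices=list(range(len(coords))), **kw)})


SQ = [[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]]


class TestEnergy:
    def test_relaxed_square_zero_energy(self):
        t = single_cell(SQ, gamma=0.0)
        p = MechanicsParams(line_tension=0.0, boundary_tension=0.0, contractility=0.0)
        assert energy(t, p).total == pytest.approx(0.0, abs=1e-15)

    def test_unit_square_hand_summation(self):
        # E = 0 (area) + 0.12 * 4 (tension) + 0.02 * 16 (contractility) = 0.80
        t = single_cell(SQ, gamma=0.04)
        p = MechanicsParams(line_tension=0.12, boundary_tension=0.12, contractility=0.04)
        eb = energy(t, p)
        assert eb.area_term == pytest.approx(0.0, abs=1e-15)
        assert eb.tension_term == pytest.approx(0.48)
        assert eb.contractility_term == pytest.approx(0.32)
        assert eb.total == pytest.approx(0.80)

    def test_breakdown_sums_to_total(self, circle_tissue, params):
        eb = energy(circle_tissue, params)
        assert eb.total == pytest.approx(
            eb.area_term + eb.tension_term + eb.contractility_term, rel=1e-12
        )

    def test_tension_term_linear_in_tension(self, circle_tissue, params):
        import dataclasses

        doubled = dataclasses.replace(
            params,
            line_tension=2 * params.line_tension,
            boundary_tension=2 * params.boundary_tension,
        )
        e1, e2 = energy(circle_tissue, params), energy(circle_tissue, doubled)
        assert e2.tension_term == pytest.approx(2 * e1.tension_term, rel=1e-12)
        assert e2.area_term == pytest.approx(e1.area_term, rel=1e-12)
        assert e2.contractility_term == pytest.approx(e1.contractility_term, rel=1e-12)

    def test_rigid_motion_invariance(self, circle_tissue, params):
        e0 = energy(circle_tissue, params).total
        moved = circle_tissue.copy()
        moved.vertices = moved.vertices + np.array([13.7, -4.2])
        assert energy(moved, params).total == pytest.approx(e0, abs=1e-10)
        th = 0.83
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = circle_tissue.copy()
        rotated.vertices = circle_tissue.vertices @ rot.T
        assert energy(rotated, params).total == pytest.approx(e0, abs=1e-10)

    def test_inactive_cells_carry_no_energy(self, circle_tissue, params):
        t = circle_tissue.copy()
        for cell in t.cells.values():
            cell.active = False
        assert energy(t, params).total == pytest.approx(0.0, abs=1e-15)


class TestForces:
    def test_matches_finite_differences(self, circle_tissue, params):
        t = circle_tissue.copy()
        rng = np.random.default_rng(2)
        t.vertices = t.vertices + rng.normal(0, 0.03, t.vertices.shape)
        cache = GeometryCache(t, params)
        x = cache.coords0.copy()
        g = cache.gradient(x)
        eps = 1e-6
        rng2 = np.random.default_rng(3)
        for i in rng2.choice(cache.nv, size=25, replace=False):
            for j in (0, 1):
                xp, xm = x.copy(), x.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                fd = (cache.energy(xp) - cache.energy(xm)) / (2 * eps)
                # abs floor covers central-difference roundoff (E ~ 100)
                assert g[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-6)

    def test_stationary_at_isolated_ground_state(self):
        # regular hexagon at its preferred area with no line terms
        ang = np.arange(6) * np.pi / 3
        side = np.sqrt(2.0 / (3 * np.sqrt(3)))  # unit area
        t = single_cell(np.stack([side * np.cos(ang), side * np.sin(ang)], 1), gamma=0.0)
        p = MechanicsParams(line_tension=0.0, boundary_tension=0.0, contractility=0.0)
        f = forces(t, p)
        assert max(np.linalg.norm(v) for v in f.values()) < 1e-8

    def test_translation_leaves_forces_unchanged(self, circle_tissue, params):
        f0 = forces(circle_tissue, params)
        moved = circle_tissue.copy()
        moved.vertices = moved.vertices + np.array([3.0, 1.0])
        f1 = forces(moved, params)
        for v in f0:
            assert f1[v] == pytest.approx(f0[v], abs=1e-9)

    def test_inactive_only_vertices_feel_no_force(self, circle_tissue, params):
        t = circle_tissue.copy()
        for cell in t.cells.values():
            cell.active = False
        f = forces(t, params)
        assert max(np.linalg.norm(v) for v in f.values()) == pytest.approx(0.0)


class TestQuasistatic:
    def test_fixed_point_of_relaxed_state(self, circle_tissue, params):
        t = circle_tissue.copy()
        e0 = energy(t, params).total
        rep = relax_quasistatic(t, params)
        assert rep.energy_final <= e0 + 1e-12
        assert rep.energy_final == pytest.approx(e0, abs=1e-6)

    def test_perturbation_recovery(self, circle_tissue, params):
        t = circle_tissue.copy()
        e_min = energy(t, params).total
        rng = np.random.default_rng(4)
        t.vertices = t.vertices + rng.normal(0, 0.01, t.vertices.shape)
        rep = relax_quasistatic(t, params, topology_enabled=False)
        assert rep.energy_final <= energy(circle_tissue, params).total + 1e-6
        assert rep.energy_final == pytest.approx(e_min, abs=1e-6)

    def test_energy_never_increases(self, circle_tissue, params):
        t = circle_tissue.copy()
        rng = np.random.default_rng(7)
        t.vertices = t.vertices + rng.normal(0, 0.05, t.vertices.shape)
        e0 = energy(t, params).total
        rep = relax_quasistatic(t, params)
        assert rep.energy_final <= e0 + 1e-12

    def test_single_cell_relaxes_to_preferred_area(self):
        t = single_cell(0.5 * np.asarray(SQ), gamma=0.0)
        p = MechanicsParams(line_tension=0.0, boundary_tension=0.0, contractility=0.0)
        relax_quasistatic(t, p, topology_enabled=False)
        assert cell_area(t, 0) == pytest.approx(1.0, abs=1e-5)


class TestViscous:
    def test_zero_force_is_identity(self):
        t = single_cell(SQ, gamma=0.0)
        p = MechanicsParams(line_tension=0.0, boundary_tension=0.0, contractility=0.0,
                            solver="viscous", viscosity=1.0)
        before = t.vertices.copy()
        relax_viscous(t, p, dt=1.0)
        assert np.array_equal(t.vertices, before)

    def test_low_viscosity_approaches_quasistatic_area(self):
        p = MechanicsParams(line_tension=0.0, boundary_tension=0.0, contractility=0.0,
                            viscosity=0.02, viscous_substeps=100)
        tq = single_cell(0.7 * np.asarray(SQ), gamma=0.0)
        relax_quasistatic(tq, p, topology_enabled=False)
        tv = single_cell(0.7 * np.asarray(SQ), gamma=0.0)
        relax_viscous(tv, p, dt=1.0)
        assert cell_area(tv, 0) == pytest.approx(cell_area(tq, 0), rel=0.01)

    def test_trajectory_is_deterministic(self, circle_tissue):
        p = MechanicsParams(viscosity=1.0, viscous_substeps=20)
        t1, t2 = circle_tissue.copy(), circle_tissue.copy()
        relax_viscous(t1, p, dt=0.1)
        relax_viscous(t2, p, dt=0.1)
        assert np.array_equal(t1.vertices, t2.vertices)

    def test_positive_viscosity_required(self, circle_tissue):
        p = MechanicsParams(viscosity=0.0)
        with pytest.raises(ValueError):
            relax_viscous(circle_tissue.copy(), p, dt=0.1)


class TestPressure:
    def test_closed_form_area_only_cell(self):
        # K=1, A=0.9, A0=1: p = -2K(A - A0) = 0.2
        t = single_cell(np.sqrt(0.9) * np.asarray(SQ), gamma=0.0)
        p = MechanicsParams(line_tension=0.0, boundary_tension=0.0, contractility=0.0)
        assert cell_pressure(t, p).pressure[0] == pytest.approx(0.2, abs=1e-12)

    def test_zero_at_relaxed_isolated_cell(self):
        t = single_cell(SQ, gamma=0.0)
        p = MechanicsParams(line_tension=0.0, boundary_tension=0.0, contractility=0.0)
        assert cell_pressure(t, p).pressure[0] == pytest.approx(0.0, abs=1e-12)

    def test_compression_gives_positive_pressure(self):
        t = single_cell(0.8 * np.asarray(SQ), gamma=0.0)
        p = MechanicsParams(line_tension=0.0, boundary_tension=0.0, contractility=0.0)
        assert cell_pressure(t, p).pressure[0] > 0

    def test_rescaling_and_log_transform(self):
        t = single_cell(SQ, gamma=0.0)
        p = MechanicsParams(line_tension=0.0, boundary_tension=0.0, contractility=0.0)
        pf = cell_pressure(t, p)
        pf.pressure[0] = 0.005
        assert pf.rescaled[0] == pytest.approx(5.0)
        assert pf.log_visual[0] == pytest.approx(np.log10(6.0))
        pf.pressure[0] = -0.005
        assert pf.log_visual[0] == pytest.approx(-np.log10(6.0))

    def test_equal_pressure_on_perfect_hex_interior(self, hex_patch, params):
        pf = cell_pressure(hex_patch, params)
        nmap = hex_patch.neighbors()
        interior = [cid for cid in hex_patch.cells if len(nmap[cid]) == 6]
        vals = [pf.pressure[c] for c in interior]
        assert len(interior) >= 3
        assert np.ptp(vals) < 1e-6

    def test_finite_difference_dilation_cross_check(self):
        # virial pressure equals -dE/dA under affine dilation about the centroid
        t = single_cell(np.sqrt(0.85) * np.asarray(SQ), gamma=0.02)
        p = MechanicsParams(line_tension=0.07, boundary_tension=0.07, contractility=0.02)
        pc = cell_pressure(t, p).pressure[0]
        g = t.vertices.mean(axis=0)
        eps = 1e-6

        def e_at(scale):
            tt = t.copy()
            tt.vertices = g + scale * (t.vertices - g)
            return energy(tt, p).total

        A = cell_area(t, 0)
        # p = -(1/A) dE/ds with A(s) = s^2 A, i.e. p = -2 dE/dA
        dE_ds = (e_at(1 + eps) - e_at(1 - eps)) / (2 * eps)
        assert pc == pytest.approx(-dE_ds / A, rel=1e-4)


class TestGroundState:
    def test_soft_transition_location(self):
        # shape degeneracy sets in where the preferred perimeter reaches
        # the hexagonal perimeter at unit area
        lam_c = soft_network_transition(contractility=0.04)
        assert lam_c == pytest.approx(-2 * 0.04 * HEX_PERIMETER, abs=1e-3)

    def test_transition_scales_with_contractility(self):
        l1 = soft_network_transition(contractility=0.04)
        l2 = soft_network_transition(contractility=0.08)
        assert l2 == pytest.approx(2 * l1, rel=1e-2)
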
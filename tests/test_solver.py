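"""Discrete Laplace solver: stencil, boundary conditions, derived fields."""

import numpy as np
import pytest

from fieldlab.errors import ConvergenceError, GeometryError, MaskError, TopologyError
from fieldlab.solver import (
    assemble_system,
    compute_current_density,
    compute_efield,
    solve_potential,
    surface_current,
)


def _column(n, sigma_profile=None):
    """An n-voxel 1-D column (1 mm voxels) with Dirichlet end voxels."""
    sigma = np.ones((n, 1, 1)) if sigma_profile is None else sigma_profile
    anode = np.zeros_like(sigma, dtype=bool)
    cathode = np.zeros_like(sigma, dtype=bool)
    anode[0] = True
    cathode[-1] = True
    return sigma, anode, cathode


class TestAssembly:
    def test_interior_row_sums_are_zero(self):
        sigma, anode, cathode = _column(10)
        system = assemble_system(sigma, anode, cathode, 1.0)
        rowsums = np.asarray(system.A.sum(axis=1)).ravel()
        # rows 1..n-2 of the unknown vector have no Dirichlet neighbor
        assert np.allclose(rowsums[1:-1], 0.0, atol=1e-18)

    def test_interface_face_conductance_is_harmonic_mean(self):
        sigma = np.ones((10, 1, 1))
        sigma[5:] = 0.5
        _, anode, cathode = _column(10)
        system = assemble_system(sigma, anode, cathode, 1.0)
        g = system.face_conductance[0][:, 0, 0]
        h_m = 1e-3
        assert g[4] == pytest.approx(2 * (1.0 * 0.5) / 1.5 * h_m)  # 0.667 relative
        assert g[1] == pytest.approx(1.0 * h_m)
        assert g[7] == pytest.approx(0.5 * h_m)

    def test_air_gap_is_a_topology_error(self):
        sigma, anode, cathode = _column(10)
        sigma[5] = 0.0
        with pytest.raises(TopologyError):
            assemble_system(sigma, anode, cathode, 1.0)

    def test_empty_or_overlapping_masks_rejected(self):
        sigma, anode, cathode = _column(10)
        with pytest.raises(MaskError):
            assemble_system(sigma, np.zeros_like(anode), cathode, 1.0)
        with pytest.raises(MaskError):
            assemble_system(sigma, anode, anode, 1.0)


class TestSolvePotential:
    def test_ohms_law_uniform_column(self):
        # resistive path between electrode centers: 10 mm, A = 1 mm², σ = 1
        sigma, anode, cathode = _column(11)
        system = assemble_system(sigma, anode, cathode, 1.0)
        sol = solve_potential(system, total_current_mA=1.0)
        dv = sol.V[0, 0, 0] - sol.V[-1, 0, 0]
        assert dv == pytest.approx(10.0, rel=1e-12)  # I·L/(σA)

    def test_series_column_against_resistor_network(self):
        # independent oracle: explicit 1-D resistor chain with harmonic faces
        sigma = np.ones((12, 1, 1))
        sigma[6:] = 0.5
        _, anode, cathode = _column(12)
        system = assemble_system(sigma, anode, cathode, 1.0)
        sol = solve_potential(system, total_current_mA=1.0)

        h_m = 1e-3
        g = np.array(
            [2 * sigma[i, 0, 0] * sigma[i + 1, 0, 0]
             / (sigma[i, 0, 0] + sigma[i + 1, 0, 0]) * h_m for i in range(11)]
        )
        R = 1.0 / g
        I = 1e-3
        # V[i] = I * (total resistance between voxel i and the cathode)
        expected = I * np.concatenate([np.cumsum(R[::-1])[::-1], [0.0]])
        assert np.allclose(sol.V[:, 0, 0], expected, rtol=1e-10)
        # interface potential splits the drop in the resistance ratio
        v_interface = sol.V[6, 0, 0]
        total = sol.V[0, 0, 0]
        assert v_interface / total == pytest.approx(R[6:].sum() / R.sum(), rel=1e-10)

    def test_linearity_in_total_current(self):
        sigma, anode, cathode = _column(11)
        system = assemble_system(sigma, anode, cathode, 1.0)
        v1 = solve_potential(system, total_current_mA=1.0).V
        v2 = solve_potential(system, total_current_mA=2.0).V
        assert np.array_equal(v2, 2.0 * v1)

    def test_convergence_failure_raises(self):
        sigma, anode, cathode = _column(30)
        system = assemble_system(sigma, anode, cathode, 1.0)
        with pytest.raises(ConvergenceError):
            solve_potential(system, rel_tol=1e-8, maxiter=2)

    def test_rel_tol_validation(self):
        sigma, anode, cathode = _column(10)
        system = assemble_system(sigma, anode, cathode, 1.0)
        with pytest.raises(ValueError):
            solve_potential(system, rel_tol=1e-2)


class TestDerivedFields:
    def test_linear_potential_gives_constant_field(self):
        shape = (20, 5, 5)
        x = np.arange(shape[0]) * 1e-3  # meters at 1 mm spacing
        V = -np.broadcast_to(x[:, None, None], shape).copy()
        conductive = np.ones(shape, dtype=bool)
        E = compute_efield(V, conductive, 1.0)
        assert np.allclose(E[..., 0], 1.0)
        assert np.allclose(E[..., 1:], 0.0)

    def test_constant_potential_gives_zero_field(self):
        V = np.full((10, 10, 10), 3.7)
        E = compute_efield(V, np.ones(V.shape, bool), 2.0)
        assert np.allclose(E, 0.0)

    def test_interior_gradient_second_order_convergence(self):
        # central differences are exact on quadratics; a cubic potential
        # exposes the genuine O(h²) interior truncation error (Richardson
        # error ratio ≈ 4 when h halves)
        errors = []
        for h_mm in (4.0, 2.0):
            n = int(1000 / h_mm) + 1
            x = np.arange(n) * h_mm * 1e-3
            V = np.broadcast_to((x**3)[:, None, None], (n, 3, 3)).copy()
            E = compute_efield(V, np.ones(V.shape, bool), h_mm)
            exact = -3 * x**2
            err = np.abs(E[1:-1, 1, 1, 0] - exact[1:-1])
            errors.append(err.max())
        assert errors[0] / errors[1] == pytest.approx(4.0, rel=0.05)

    def test_current_density_is_sigma_times_field(self):
        E = np.zeros((4, 4, 4, 3))
        E[..., 0] = 0.18  # brainstem-scale field, V/m
        sigma = np.full((4, 4, 4), 0.126)
        J = compute_current_density(E, sigma)
        assert np.allclose(np.linalg.norm(J, axis=-1), 0.0227, atol=5e-5)
        assert np.allclose(compute_current_density(np.zeros_like(E), sigma), 0.0)
        # gray matter at 1 V/m
        J2 = compute_current_density(np.ones((2, 2, 2, 3)) / np.sqrt(3), np.full((2, 2, 2), 0.276))
        assert np.allclose(np.linalg.norm(J2, axis=-1), 0.276)


class TestCurrentsAndSymmetries:
    def test_delivered_and_returned_current(self, small_sphere_solution):
        _, system, solution = small_sphere_solution
        diag = solution.diagnostics
        assert diag["delivered_current_mA"] == pytest.approx(1.0, rel=5e-3)
        assert diag["cathode_current_mA"] == pytest.approx(-1.0, rel=5e-3)
        # flux out of anode contact via the surface integral
        assert surface_current(system, solution.V, system.anode_mask) == pytest.approx(
            1.0, rel=5e-3
        )

    def test_midplane_surface_current(self, small_sphere_solution):
        vol, system, solution = small_sphere_solution
        nz = vol.labels.shape[2]
        upper = np.zeros(vol.labels.shape, dtype=bool)
        upper[:, :, nz // 2:] = True  # half-domain containing the anode
        assert surface_current(system, solution.V, upper) == pytest.approx(1.0, rel=0.01)

    def test_surface_current_errors(self, small_sphere_solution):
        _, system, solution = small_sphere_solution
        with pytest.raises(GeometryError):
            surface_current(system, solution.V, np.zeros(system.sigma.shape, bool))
        both = system.anode_mask | system.cathode_mask
        with pytest.raises(GeometryError):
            surface_current(system, solution.V, both)

    def test_interior_flux_conservation(self, small_sphere_solution):
        # net flux out of every interior unknown voxel vanishes at the
        # solver tolerance (A x = b up to the rescaled residual)
        _, system, solution = small_sphere_solution
        x = solution.V[system.unknown_index >= 0]
        order = system.unknown_index[system.unknown_index >= 0]
        xv = np.empty_like(x)
        xv[order] = x
        scale = solution.diagnostics["scale_factor"]
        residual = system.A @ xv - system.b * scale
        assert np.linalg.norm(residual) <= 1e-6 * np.linalg.norm(system.b * scale)

    def test_reciprocity_swapping_electrodes_negates_field(self):
        rng_shape = (9, 9, 9)
        sigma = np.ones(rng_shape)
        anode = np.zeros(rng_shape, bool)
        cathode = np.zeros(rng_shape, bool)
        anode[1, 1, 1] = True
        cathode[7, 7, 7] = True
        s1 = assemble_system(sigma, anode, cathode, 1.0)
        s2 = assemble_system(sigma, cathode, anode, 1.0)
        sol1 = solve_potential(s1)
        sol2 = solve_potential(s2)
        e1 = compute_efield(sol1.V, s1.conductive, 1.0)
        e2 = compute_efield(sol2.V, s2.conductive, 1.0)
        assert np.allclose(e1, -e2, atol=1e-9 * np.abs(e1).max())
        # potentials sum to a constant (gauge shift)
        total = sol1.V + sol2.V
        assert np.ptp(total) <= 1e-8 * np.ptp(sol1.V)

    def test_superposition_of_symmetric_sources(self):
        # two anodes placed symmetrically: the equipotential split is 50/50,
        # so single-anode solutions must superpose to the two-anode solution
        shape = (17, 17, 9)
        sigma = np.ones(shape)
        e1 = np.zeros(shape, bool)
        e2 = np.zeros(shape, bool)
        cat = np.zeros(shape, bool)
        e1[4, 8, 8] = True
        e2[12, 8, 8] = True
        cat[8, 8, 0] = True
        sol_a = solve_potential(assemble_system(sigma, e1, cat, 1.0), 1.0)
        sol_b = solve_potential(assemble_system(sigma, e2, cat, 1.0), 1.0)
        sol_ab = solve_potential(assemble_system(sigma, e1 | e2, cat, 1.0), 2.0)
        combined = sol_a.V + sol_b.V
        # compare away from the Dirichlet voxels, where the single-anode
        # solutions are not constrained to be equipotential
        mask = np.ones(shape, bool)
        mask[e1 | e2 | cat] = False
        diff = np.abs(combined - sol_ab.V)[mask].max()
        assert diff <= 0.02 * np.ptp(sol_ab.V)
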
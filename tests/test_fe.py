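"""FE core: element stiffness oracle, solver contracts, strain recovery,
SED, virtual instrumentation."""

import numpy as np
import pytest

from boneplug import fe
from boneplug.geometry import AssemblyMesh, AssemblySpec, build_assembly_mesh
from boneplug.loads import LoadCase, equivalent_face_loads
from boneplug.materials import MaterialCard, default_cards, stiffness_matrix

ISO = MaterialCard(E=10e9, nu=0.25)
ALL_ISO = {p: ISO for p in ("stem", "cement", "bone_layer", "outer_bone")}


def single_element_mesh(coords: np.ndarray) -> AssemblyMesh:
    """Minimal one-hex mesh for element-level oracles."""
    return AssemblyMesh(nodes=coords, elems=np.arange(8)[None, :],
                        part=np.array([0]), layer=np.array([0]),
                        slice_index=np.array([-1]), node_sets={},
                        spec=AssemblySpec(element_edge_length=1.0))


UNIT_CUBE = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float)


def reference_cube_stiffness(C: np.ndarray, n_gauss: int = 4) -> np.ndarray:
    """Independent stiffness integral for the unit cube: test-local shape
    gradients and a dense Gauss-Legendre rule (exact for the polynomial
    integrand)."""
    signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                      [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]])
    pts, wts = np.polynomial.legendre.leggauss(n_gauss)
    K = np.zeros((24, 24))
    for a, wa in zip(pts, wts):
        for b, wb in zip(pts, wts):
            for c, wc in zip(pts, wts):
                # gradients wrt physical coords: x = (xi + 1) / 2 etc.
                g = np.empty((8, 3))
                for i, s in enumerate(signs):
                    g[i, 0] = 0.25 * s[0] * (1 + s[1] * b) * (1 + s[2] * c)
                    g[i, 1] = 0.25 * s[1] * (1 + s[0] * a) * (1 + s[2] * c)
                    g[i, 2] = 0.25 * s[2] * (1 + s[0] * a) * (1 + s[1] * b)
                B = np.zeros((6, 24))
                B[0, 0::3] = g[:, 0]
                B[1, 1::3] = g[:, 1]
                B[2, 2::3] = g[:, 2]
                B[3, 1::3] = g[:, 2]
                B[3, 2::3] = g[:, 1]
                B[4, 0::3] = g[:, 2]
                B[4, 2::3] = g[:, 0]
                B[5, 0::3] = g[:, 1]
                B[5, 1::3] = g[:, 0]
                K += wa * wb * wc * 0.125 * B.T @ C @ B
    return K


class TestAssemble:
    def test_unit_cube_matches_independent_integral(self):
        mesh = single_element_mesh(UNIT_CUBE)
        K = fe.assemble(mesh, ALL_ISO).K.toarray()
        K_ref = reference_cube_stiffness(stiffness_matrix(ISO))
        assert np.allclose(K, K_ref, rtol=1e-10, atol=1e-10 * np.abs(K_ref).max())

    def test_rigid_translation_in_null_space(self):
        mesh = single_element_mesh(UNIT_CUBE)
        K = fe.assemble(mesh, ALL_ISO).K
        for axis in range(3):
            e = np.zeros(24)
            e[axis::3] = 1.0
            assert np.abs(K @ e).max() < 1e-6 * np.abs(K.toarray()).max()

    def test_linearity_in_moduli(self):
        mesh = single_element_mesh(UNIT_CUBE)
        K1 = fe.assemble(mesh, ALL_ISO).K.toarray()
        twice = {p: MaterialCard(E=2 * ISO.E, nu=ISO.nu) for p in ALL_ISO}
        K2 = fe.assemble(mesh, twice).K.toarray()
        assert np.allclose(K2, 2 * K1, rtol=1e-12)

    def test_missing_card_rejected(self, sliced_mesh):
        with pytest.raises(ValueError, match="missing material"):
            fe.assemble(sliced_mesh, {"stem": ISO})


class TestSolve:
    def test_zero_load_zero_displacement(self, uniform_composite):
        system = fe.assemble(uniform_composite, ALL_ISO)
        u = fe.solve(system, np.zeros(system.ndof))
        assert np.all(u.u == 0)

    def test_axial_composite_strain_matches_transformed_section(self, uniform_composite):
        """Far-field axial strain of the bonded composite under pure axial
        load equals -F / sum(E_i A_i) (transformed-section oracle)."""
        mesh = uniform_composite
        mats = default_cards()
        system = fe.assemble(mesh, mats)
        F = 842.8
        f = equivalent_face_loads(LoadCase(0, -F, 0, lever_arm=(0, 0, 0)), mesh)
        fixed = np.flatnonzero(np.abs(mesh.nodes[:, 1]) < 1e-9)
        u = fe.solve(system, f, fixed_nodes=fixed)
        tensors = fe.strain_stress(mesh, mats, u, elem_C=system.elem_C)
        cy = mesh.element_centroids()[:, 1]
        mid = (cy > 0.04) & (cy < 0.08)
        eyy = np.average(tensors.strain[mid, 1],
                         weights=mesh.element_volumes()[mid])
        # areas of the flush untapered section
        r_s, t_c, t_b = 0.006, 0.001, 0.002
        r_c, r_b = r_s + t_c, r_s + t_c + t_b
        r_o = r_b + mesh.spec.outer_bone_wall_thickness
        A = np.pi * np.array([r_s ** 2, r_c ** 2 - r_s ** 2,
                              r_b ** 2 - r_c ** 2, r_o ** 2 - r_b ** 2])
        EA = A @ np.array([115e9, 2e9, 20e9, 20e9])
        assert eyy == pytest.approx(-F / EA, rel=0.02)
        # the three-part section's closed form is -55.8 microstrain
        EA3 = A[:3] @ np.array([115e9, 2e9, 20e9])
        assert -F / EA3 * 1e6 == pytest.approx(-55.8, abs=0.05)

    def test_load_scaling_is_exactly_linear(self, uniform_composite):
        """u(alpha F) = alpha u(F) to 1e-10 relative (linear elasticity),
        covering the 0.33-3.5 BW schedule."""
        mesh = uniform_composite
        system = fe.assemble(mesh, ALL_ISO)
        f = equivalent_face_loads(LoadCase(10.0, -100.0, 5.0), mesh)
        u1 = fe.solve(system, f)
        u2 = fe.solve(system, 3.5 * f)
        assert np.allclose(u2.u, 3.5 * u1.u,
                           rtol=1e-10, atol=1e-10 * np.abs(u1.u).max())

    def test_unconstrained_model_raises(self, uniform_composite):
        system = fe.assemble(uniform_composite, ALL_ISO)
        f = equivalent_face_loads(LoadCase(0, -100.0, 0), uniform_composite)
        with pytest.raises(RuntimeError):
            fe.solve(system, f, fixed_nodes=np.array([], dtype=int))

    def test_energy_balance_and_equilibrium(self, solved_lc2):
        """Sum U V = 1/2 f.u and reactions balance the applied resultant,
        both to 1e-8 relative, on the baseline solve."""
        mesh, f, u, tensors, sed_field = solved_lc2
        work = 0.5 * float(f.ravel() @ u.flat)
        assert sed_field.total_energy == pytest.approx(work, rel=1e-8)
        applied = f.sum(axis=0)
        reacted = u.reactions.sum(axis=0)
        assert np.allclose(reacted, -applied, rtol=1e-8,
                           atol=1e-8 * np.linalg.norm(applied))


class TestStrainRecovery:
    def test_uniform_stretch_patch(self, uniform_composite):
        """A linear displacement field reproduces its constant strain in
        every element (patch test, no solve)."""
        mesh = uniform_composite
        a = 1e-4
        u = np.zeros_like(mesh.nodes)
        u[:, 1] = a * mesh.nodes[:, 1]
        tensors = fe.strain_stress(mesh, ALL_ISO, u)
        assert np.allclose(tensors.strain[:, 1], a, rtol=1e-9)
        assert np.abs(tensors.strain[:, [0, 2, 3, 4, 5]]).max() < 1e-9 * a

    def test_poisson_effect_uniaxial_stress(self, uniform_composite):
        """Manufactured uniaxial-stress displacement field: eps_xx =
        -nu eps_yy and sigma_xx = 0."""
        mesh = uniform_composite
        sig, E, nu = 1e6, ISO.E, ISO.nu
        u = np.column_stack([-nu * sig / E * mesh.nodes[:, 0],
                             sig / E * mesh.nodes[:, 1],
                             -nu * sig / E * mesh.nodes[:, 2]])
        tensors = fe.strain_stress(mesh, ALL_ISO, u)
        assert np.allclose(tensors.strain[:, 0], -nu * tensors.strain[:, 1],
                           rtol=1e-9)
        assert np.allclose(tensors.stress[:, 1], sig, rtol=1e-9)
        assert np.abs(tensors.stress[:, 0]).max() < 1e-9 * sig

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_random_element_strain_matches_finite_differences(self):
        """Strains of a randomly displaced element equal central finite
        differences of the trilinear displacement interpolant."""
        rng = np.random.default_rng(7)
        coords = UNIT_CUBE + 0.05 * rng.normal(size=(8, 3))
        mesh = single_element_mesh(coords)
        ue = 1e-3 * rng.normal(size=(8, 3))
        tensors = fe.strain_stress(mesh, ALL_ISO, ue)

        signs = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                          [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]])

        def interp(xi):
            N = 0.125 * np.prod(1 + signs * xi, axis=1)
            return N @ ue, N @ coords

        # invert the map numerically around the centre, then central-diff u(x)
        from scipy.optimize import fsolve

        def u_at(x):
            # minpack may warn about slow progress at tight xtol even though
            # the root is found to full precision; the residual is asserted
            xi = fsolve(lambda s: interp(s)[1] - x, np.zeros(3), xtol=1e-11)
            assert np.linalg.norm(interp(xi)[1] - x) < 1e-12
            return interp(xi)[0]

        x0 = interp(np.zeros(3))[1]
        h = 1e-6
        grad = np.empty((3, 3))
        for j in range(3):
            dx = np.zeros(3)
            dx[j] = h
            grad[:, j] = (u_at(x0 + dx) - u_at(x0 - dx)) / (2 * h)
        eps_fd = 0.5 * (grad + grad.T)
        voigt = np.array([eps_fd[0, 0], eps_fd[1, 1], eps_fd[2, 2],
                          2 * eps_fd[1, 2], 2 * eps_fd[0, 2], 2 * eps_fd[0, 1]])
        # strain at the element centre from the implementation's B operator
        B, _ = fe._b_matrices(coords[None], np.zeros(3))
        eps_centre = B[0] @ ue.ravel()
        assert np.allclose(eps_centre, voigt, rtol=1e-6, atol=1e-12)
        # the Gauss-point mean agrees to the element-distortion error
        assert np.allclose(tensors.strain_gp.mean(axis=1)[0], voigt, rtol=0.02,
                           atol=1e-10)


class TestSED:
    def test_uniaxial_closed_form(self):
        """Uniaxial stress sigma stores U = sigma^2 / 2E."""
        mesh = single_element_mesh(UNIT_CUBE)
        sig, E, nu = 2e6, ISO.E, ISO.nu
        u = np.column_stack([-nu * sig / E * UNIT_CUBE[:, 0],
                             sig / E * UNIT_CUBE[:, 1],
                             -nu * sig / E * UNIT_CUBE[:, 2]])
        sed_field = fe.sed(fe.strain_stress(mesh, ALL_ISO, u))
        assert sed_field.U[0] == pytest.approx(sig ** 2 / (2 * E), rel=1e-9)

    def test_pure_shear_closed_form(self):
        """Engineering shear gamma stores U = G gamma^2 / 2."""
        mesh = single_element_mesh(UNIT_CUBE)
        gamma = 1e-3
        u = np.zeros((8, 3))
        u[:, 0] = gamma * UNIT_CUBE[:, 1]
        G = ISO.E / (2 * (1 + ISO.nu))
        sed_field = fe.sed(fe.strain_stress(mesh, ALL_ISO, u))
        assert sed_field.U[0] == pytest.approx(G * gamma ** 2 / 2, rel=1e-9)

    def test_zero_strain_zero_energy(self):
        mesh = single_element_mesh(UNIT_CUBE)
        sed_field = fe.sed(fe.strain_stress(mesh, ALL_ISO, np.zeros((8, 3))))
        assert sed_field.U[0] == 0.0


class TestVirtualGauge:
    def test_uniform_strain_field_read_exactly(self, sliced_mesh):
        u = np.zeros_like(sliced_mesh.nodes)
        u[:, 1] = -500e-6 * sliced_mesh.nodes[:, 1]
        tensors = fe.strain_stress(sliced_mesh, ALL_ISO, u)
        site = fe.GaugeSite(0.1, 0.0, 0.02)
        assert fe.virtual_gauge(sliced_mesh, tensors, site) \
            == pytest.approx(-500.0, rel=1e-6)

    def test_linear_strain_field_reads_centroid_value(self, sliced_mesh):
        """For strain linear in y the footprint mean equals the strain at
        the footprint centre within discretisation error."""
        a = 1e-2  # strain gradient per metre
        u = np.zeros_like(sliced_mesh.nodes)
        u[:, 1] = 0.5 * a * sliced_mesh.nodes[:, 1] ** 2
        tensors = fe.strain_stress(sliced_mesh, ALL_ISO, u)
        y0 = 0.10
        got = fe.virtual_gauge(sliced_mesh, tensors, fe.GaugeSite(y0, 0.0, 0.02))
        assert got == pytest.approx(a * y0 * 1e6, rel=0.05)

    def test_single_node_footprint_reads_that_node(self, sliced_mesh):
        u = np.zeros_like(sliced_mesh.nodes)
        u[:, 1] = 1e-4 * sliced_mesh.nodes[:, 1]
        tensors = fe.strain_stress(sliced_mesh, ALL_ISO, u)
        surf = sliced_mesh.node_sets["outer_surface"]
        n = surf[len(surf) // 2]
        x, y, z = sliced_mesh.nodes[n]
        site = fe.GaugeSite(float(y), float(np.degrees(np.arctan2(z, x))), 1e-6)
        expected = fe.nodal_axial_strain(sliced_mesh, tensors)[n] * 1e6
        assert fe.virtual_gauge(sliced_mesh, tensors, site) \
            == pytest.approx(expected, rel=1e-12)

    def test_empty_footprint_rejected(self, sliced_mesh, solved_lc2):
        tensors = solved_lc2[3]
        with pytest.raises(ValueError, match="empty gauge footprint"):
            fe.virtual_gauge(sliced_mesh, tensors,
                             fe.GaugeSite(0.5, 0.0, 0.001))


class TestDisplacementSpan:
    def test_uniform_grid_percentile_arithmetic(self):
        vals = np.zeros((101, 3))
        vals[:, 0] = np.arange(101.0)
        assert fe.displacement_span(vals, 0, np.arange(101), ci=0.95) \
            == pytest.approx(95.0)

    def test_full_ci_is_range(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(50, 3))
        span = fe.displacement_span(vals, 2, np.arange(50), ci=1.0)
        assert span == pytest.approx(vals[:, 2].max() - vals[:, 2].min())

    def test_gaussian_span_near_two_sigma_quantile(self):
        """1000 standard-normal values: 95% span ~ 2 x 1.96 within 5%
        (Monte-Carlo percentile check)."""
        rng = np.random.default_rng(42)
        vals = rng.standard_normal((1000, 3))
        span = fe.displacement_span(vals, 1, np.arange(1000), ci=0.95)
        assert span == pytest.approx(2 * 1.959964, rel=0.05)

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError):
            fe.displacement_span(np.zeros((5, 3)), 0, np.array([], dtype=int))
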
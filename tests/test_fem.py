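"""FE solver: analytic oracles, strain transforms, invariants."""

import numpy as np
import pytest

from athero_ifem import (
    MMHG_TO_KPA,
    LinearElastic,
    MaterialSet,
    NeoHooke,
    annulus_mesh,
    inflate,
    inflate_linear_increment,
    lame_annulus,
    max_principal_stress,
    neo_hooke_from_linear,
    strain_fields,
)
from athero_ifem.fem import (
    PlaneStrainProblem,
    SolverConfig,
    StrainField,
    neo_hooke_annulus_pressure,
)
from athero_ifem.materials import cauchy_stress, Kinematics


def radial_component(mesh, u):
    r = np.linalg.norm(mesh.nodes, axis=1)
    return np.einsum("ni,ni->n", u, mesh.nodes / r[:, None]), r


class TestLinearIncrement:
    def test_zero_pressure_gives_zero_field(self, small_annulus, fib600):
        u = inflate_linear_increment(small_annulus, fib600, 0.0)
        assert np.allclose(u, 0.0, atol=1e-14)

    def test_displacements_scale_exactly_linearly(self, small_annulus, fib600):
        u1 = inflate_linear_increment(small_annulus, fib600, 5.0)
        u2 = inflate_linear_increment(small_annulus, fib600, 10.0)
        assert np.allclose(u2, 2.0 * u1, rtol=1e-12, atol=1e-16)

    def test_lame_oracle_within_one_percent(self):
        E, nu, a, b = 600.0, 0.49, 1.5, 4.0
        mesh = annulus_mesh(a, b, 24, 96)
        mats = MaterialSet({"fibrotic": LinearElastic(E, nu)})
        u = inflate_linear_increment(mesh, mats, 5.0, bc="roller_outer")
        ur, r = radial_component(mesh, u)
        exact = lame_annulus(E, nu, a, b, 5.0 * MMHG_TO_KPA)(r)
        assert np.abs(ur - exact).max() / np.abs(exact).max() < 0.01

    def test_lame_error_decreases_under_refinement(self):
        E, nu, a, b = 600.0, 0.49, 1.5, 4.0
        mats = MaterialSet({"fibrotic": LinearElastic(E, nu)})
        errors = []
        for n in (4, 8, 16):
            mesh = annulus_mesh(a, b, n, 4 * n)
            u = inflate_linear_increment(mesh, mats, 5.0, bc="roller_outer")
            ur, r = radial_component(mesh, u)
            exact = lame_annulus(E, nu, a, b, 5.0 * MMHG_TO_KPA)(r)
            errors.append(np.abs(ur - exact).max())
        assert errors[0] > errors[1] > errors[2]

    def test_softer_lipid_strains_more(self, rng):
        from athero_ifem import default_plaque_spec, generate_plaque, mesh_plaque

        mesh = mesh_plaque(generate_plaque(
            default_plaque_spec(include_calcification=False, seed=2)), 0.1)
        center = mesh.lumen_centroid()
        out = {}
        for e_lip in (10.0, 100.0):
            mats = MaterialSet({"fibrotic": LinearElastic(600.0, 0.49),
                                "lipid_1": LinearElastic(e_lip, 0.49)})
            u = inflate_linear_increment(mesh, mats, 5.0)
            f = strain_fields(mesh, u, center)
            out[e_lip] = np.abs(f.err[mesh.labels == "lipid_1"]).mean()
        assert out[10.0] > out[100.0]

    def test_hyperelastic_material_rejected(self, small_annulus):
        mats = MaterialSet({"fibrotic": NeoHooke(103.45, 0.001)})
        with pytest.raises(TypeError):
            inflate_linear_increment(small_annulus, mats, 5.0)


class TestNonlinearInflation:
    def test_zero_pressure_solution(self, small_annulus, fib600):
        sol = inflate(small_annulus, fib600, 0.0)
        assert np.allclose(sol.displacements, 0.0)
        assert sol.converged

    def test_neo_hooke_annulus_matches_semianalytic_integral(self):
        C10 = 103.45
        A, B = 1.5, 4.0
        nu_eq = 0.499  # nearly incompressible
        mats = MaterialSet({"fibrotic": NeoHooke(
            C10, 6 * (1 - 2 * nu_eq) / (4 * (1 + nu_eq) * C10))})
        mesh = annulus_mesh(A, B, 14, 72)
        sol = inflate(mesh, mats, 110.0,
                      SolverConfig(bc="roller_outer", load_steps=10))
        inner = np.isclose(np.linalg.norm(mesh.nodes, axis=1), A)
        a_def = np.linalg.norm(
            (mesh.nodes + sol.displacements)[inner], axis=1).mean()
        p_exact = neo_hooke_annulus_pressure(C10, A, B, a_def)
        p_fe = 110.0 * MMHG_TO_KPA
        assert abs(p_fe - p_exact) / p_fe < 0.02

    def test_energy_balance_within_one_percent(self, small_annulus):
        mats = MaterialSet({"fibrotic": NeoHooke(*neo_hooke_from_linear(600, 0.45))})
        sol = inflate(small_annulus, mats, 110.0, SolverConfig(load_steps=20))
        assert sol.external_work == pytest.approx(sol.strain_energy, rel=0.01)

    def test_bitwise_deterministic(self, small_annulus):
        mats = MaterialSet({"fibrotic": NeoHooke(*neo_hooke_from_linear(600, 0.45))})
        a = inflate(small_annulus, mats, 50.0, SolverConfig(load_steps=5))
        b = inflate(small_annulus, mats, 50.0, SolverConfig(load_steps=5))
        assert np.array_equal(a.displacements, b.displacements)
        assert np.array_equal(a.cauchy, b.cauchy)

    def test_negative_pressure_rejected(self, small_annulus, fib600):
        with pytest.raises(ValueError):
            inflate(small_annulus, fib600, -1.0)


class TestStrainFields:
    def test_rigid_translation_has_zero_strain(self, small_annulus):
        u = np.tile([0.3, -0.2], (small_annulus.n_nodes, 1))
        f = strain_fields(small_annulus, u, np.zeros(2))
        for comp in (f.exx, f.eyy, f.exy, f.err, f.ett, f.ert, f.evm):
            assert np.allclose(comp, 0.0, atol=1e-12)

    def test_uniform_radial_expansion(self, small_annulus):
        alpha = 1e-3
        u = alpha * small_annulus.nodes
        f = strain_fields(small_annulus, u, np.zeros(2))
        assert np.allclose(f.err, alpha, atol=1e-12)
        assert np.allclose(f.ett, alpha, atol=1e-12)
        assert np.allclose(f.ert, 0.0, atol=1e-12)

    def test_cylindrical_equals_tensor_rotation(self, small_annulus, rng):
        u = 1e-3 * rng.standard_normal((small_annulus.n_nodes, 2))
        f = strain_fields(small_annulus, u, np.zeros(2))
        for k in rng.integers(0, small_annulus.n_elements, size=20):
            eps = np.array([[f.exx[k], f.exy[k]], [f.exy[k], f.eyy[k]]])
            t = f.angles[k]
            Q = np.array([[np.cos(t), np.sin(t)], [-np.sin(t), np.cos(t)]])
            cyl = Q @ eps @ Q.T
            assert f.err[k] == pytest.approx(cyl[0, 0], abs=1e-14)
            assert f.ett[k] == pytest.approx(cyl[1, 1], abs=1e-14)
            assert f.ert[k] == pytest.approx(cyl[0, 1], abs=1e-14)

    def test_trace_invariance_and_principal_order(self, small_annulus, rng):
        u = 1e-3 * rng.standard_normal((small_annulus.n_nodes, 2))
        f = strain_fields(small_annulus, u, np.zeros(2))
        assert np.allclose(f.err + f.ett, f.exx + f.eyy, atol=1e-10)
        assert np.all(f.e1 >= f.e2 - 1e-15)

    def test_center_on_element_rejected(self, small_annulus):
        u = np.zeros((small_annulus.n_nodes, 2))
        centroid = small_annulus.centroids()[0]
        with pytest.raises(ValueError):
            strain_fields(small_annulus, u, centroid)

    def test_affine_patch_reproduces_constant_strain(self, small_annulus):
        A = np.array([[2e-3, 5e-4], [1e-4, -1e-3]])
        u = small_annulus.nodes @ A.T
        f = strain_fields(small_annulus, u, np.zeros(2))
        assert np.allclose(f.exx, A[0, 0], atol=1e-13)
        assert np.allclose(f.eyy, A[1, 1], atol=1e-13)
        assert np.allclose(f.exy, 0.5 * (A[0, 1] + A[1, 0]), atol=1e-13)


class TestMaxPrincipalStress:
    def test_zero_at_rest(self, small_annulus, fib600):
        sol = inflate(small_annulus, fib600, 0.0)
        assert np.allclose(max_principal_stress(sol).sigma_max, 0.0)

    def test_matches_material_stress_on_uniaxial_patch(self, small_annulus):
        """sigma_max of a manufactured uniform-stretch state equals the
        principal Cauchy stress of the constitutive law."""
        mat = NeoHooke(103.45, 0.001)
        lam = 1.05
        F2 = np.array([[lam, 0.0], [0.0, 1.0]])
        sol = inflate(small_annulus,
                      MaterialSet({"fibrotic": mat}), 0.0)
        M = small_annulus.n_elements
        sol.deformation_gradients = np.broadcast_to(F2, (M, 2, 2)).copy()
        from athero_ifem.materials import plane_strain_cauchy

        sol.cauchy = plane_strain_cauchy(mat, sol.deformation_gradients)
        sig = max_principal_stress(sol).sigma_max
        expect = np.linalg.eigvalsh(
            cauchy_stress(mat, Kinematics.plane_strain(F2)))[-1]
        assert np.allclose(sig, expect, rtol=1e-10)

    def test_peak_stress_in_fibrotic_cap_not_lipid(self, nonlinear_study):
        mesh = nonlinear_study["mesh"]
        sol = inflate(mesh, nonlinear_study["truth"], 115.0,
                      SolverConfig(load_steps=10))
        sig = max_principal_stress(sol).sigma_max
        fib = mesh.labels == "fibrotic"
        lip = mesh.labels == "lipid_1"
        assert sig[fib].max() > sig[lip].max()
        # global peak lies in fibrotic tissue near the lumen
        k = int(np.argmax(sig))
        assert mesh.labels[k] == "fibrotic"
        center = mesh.lumen_centroid()
        d_peak = np.linalg.norm(mesh.centroids()[k] - center)
        assert d_peak < np.linalg.norm(mesh.centroids() - center, axis=1).mean()


class TestLameClosedForm:
    def test_zero_pressure_zero_displacement(self):
        u = lame_annulus(600.0, 0.49, 1.5, 4.0, 0.0)
        assert np.allclose(u(np.linspace(1.5, 4.0, 5)), 0.0)

    def test_displacement_decreases_outward(self):
        u = lame_annulus(600.0, 0.49, 1.5, 4.0, 1.0)
        r = np.linspace(1.5, 4.0, 50)
        assert np.all(np.diff(u(r)) < 0)

    def test_textbook_formula(self):
        E, nu, a, b, p = 600.0, 0.3, 1.0, 2.0, 1.0
        r = 1.5
        expect = (1 + nu) * p * a**2 / (E * (b**2 - a**2)) \
            * ((1 - 2 * nu) * r + b**2 / r)
        assert lame_annulus(E, nu, a, b, p)(r) == pytest.approx(expect, rel=1e-12)
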
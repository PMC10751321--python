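"""Constitutive models: conversions, stresses vs independent oracles, curves."""

import numpy as np
import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from athero_ifem import (
    GOH,
    BehaviorCurve,
    Kinematics,
    LinearElastic,
    MaterialSet,
    NeoHooke,
    cauchy_stress,
    curve_r2,
    lhs_sample,
    linear_from_neo_hooke,
    neo_hooke_from_linear,
    strain_energy,
    uniaxial_curve,
)
from athero_ifem.materials import plane_strain_cauchy, plane_strain_response

from conftest import CALCIFIED_1, CELLULAR


class TestConversions:
    def test_fibrotic_reference_values(self):
        c10, d1 = neo_hooke_from_linear(600.0, 0.45)
        assert round(c10, 2) == 103.45
        assert round(d1, 3) == 0.001

    def test_lipid_reference_values(self):
        c10, d1 = neo_hooke_from_linear(10.0, 0.45)
        assert round(c10, 2) == 1.72
        assert round(d1, 2) == 0.06

    def test_inverse_recovers_reference_moduli(self):
        E, nu = linear_from_neo_hooke(103.45, 0.001)
        assert E == pytest.approx(600.0, rel=1e-3)
        E, nu = linear_from_neo_hooke(1.72, 0.06)
        assert E == pytest.approx(10.0, rel=5e-3)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(E=st.floats(1.0, 1e4), nu=st.floats(0.01, 0.49))
    def test_round_trip_machine_precision(self, E, nu):
        c10, d1 = neo_hooke_from_linear(E, nu)
        E2, nu2 = linear_from_neo_hooke(c10, d1)
        assert E2 == pytest.approx(E, rel=1e-12)
        assert nu2 == pytest.approx(nu, rel=1e-12, abs=1e-13)

    def test_invalid_poisson_rejected(self):
        with pytest.raises(ValueError):
            neo_hooke_from_linear(600.0, 0.5)
        with pytest.raises(ValueError):
            linear_from_neo_hooke(103.45, 10.0)  # implies nu <= 0


class TestStrainEnergy:
    @pytest.mark.parametrize("mat", [
        NeoHooke(103.45, 0.001), CALCIFIED_1, LinearElastic(600.0, 0.49)])
    def test_zero_at_identity(self, mat):
        assert strain_energy(mat, Kinematics(np.eye(3))) == pytest.approx(0.0)

    def test_neo_hooke_direct_substitution(self):
        # J = 1, I1 = 4 for F = diag(l, 1/l, 1) with l^2 = (3 + sqrt 5)/2
        lam = np.sqrt((3 + np.sqrt(5.0)) / 2.0)
        kin = Kinematics(np.diag([lam, 1 / lam, 1.0]))
        assert kin.J == pytest.approx(1.0)
        assert kin.I1 == pytest.approx(4.0)
        assert strain_energy(NeoHooke(1.0, 0.06), kin) == pytest.approx(1.0)

    def test_goh_matches_symbolic_evaluation(self):
        """Independent sympy evaluation of the GOH energy at uniaxial stretch."""
        lam_v = 1.05
        mu, k1, k2, D, kap = sp.symbols("mu k1 k2 D kappa", positive=True)
        lam = sp.Symbol("lam", positive=True)
        F = sp.diag(lam, 1 / sp.sqrt(lam), 1 / sp.sqrt(lam))
        J = F.det()
        I1 = (F.T * F).trace()
        Ib1 = J ** sp.Rational(-2, 3) * I1
        a = sp.Matrix([1, 0, 0])
        I4 = (a.T * F.T * F * a)[0]
        Ib4 = J ** sp.Rational(-2, 3) * I4
        e = kap * (Ib1 - 3) + (1 - 3 * kap) * (Ib4 - 1)
        psi = (1 / D) * (J - 1) ** 2 + mu * (Ib1 - 3) \
            + 2 * (k1 / (2 * k2)) * (sp.exp(k2 * e ** 2) - 1)
        expected = float(psi.subs({mu: 9.58, k1: 17564, k2: 0.51,
                                   D: 0.005, kap: sp.Rational(1, 3),
                                   lam: lam_v}))
        got = strain_energy(CALCIFIED_1, Kinematics.uniaxial(lam_v))
        assert got == pytest.approx(expected, rel=1e-9)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            Kinematics(np.diag([-1.0, 1.0, 1.0]))


class TestCauchyStress:
    @pytest.mark.parametrize("mat", [
        NeoHooke(1.72, 0.06), CALCIFIED_1, LinearElastic(10.0, 0.45)])
    def test_zero_and_symmetric_at_identity(self, mat):
        sig = cauchy_stress(mat, Kinematics(np.eye(3)))
        assert np.allclose(sig, 0.0, atol=1e-12)

    @pytest.mark.parametrize("mat", [NeoHooke(103.45, 0.001), CALCIFIED_1,
                                     GOH(2.0, 10.0, 3.0, kappa=0.2)])
    def test_consistent_with_energy_finite_differences(self, mat, rng):
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        kin = Kinematics(F)
        sig = cauchy_stress(mat, kin)
        h = 1e-6
        P_fd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                P_fd[i, j] = (strain_energy(mat, Kinematics(Fp))
                              - strain_energy(mat, Kinematics(Fm))) / (2 * h)
        sig_fd = P_fd @ F.T / np.linalg.det(F)
        sig_fd = 0.5 * (sig_fd + sig_fd.T)
        assert np.allclose(sig, sig_fd, rtol=1e-5, atol=1e-8)

    def test_linear_small_strain_matches_hooke(self, rng):
        E, nu = 600.0, 0.49
        eps = 1e-4 * rng.standard_normal((3, 3))
        eps = 0.5 * (eps + eps.T)
        sig = cauchy_stress(LinearElastic(E, nu), Kinematics(np.eye(3) + eps))
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        hooke = lam * np.trace(eps) * np.eye(3) + 2 * mu * eps
        assert np.allclose(sig, hooke, rtol=1e-10, atol=1e-12)

    def test_neo_hooke_equivalent_matches_hooke_to_second_order(self):
        """The hyperelastic model linearizes to the converted Hooke law."""
        E, nu = 600.0, 0.45
        nh = NeoHooke(*neo_hooke_from_linear(E, nu))
        scale_err = []
        for s in (1e-3, 5e-4):
            eps = s * np.array([[1.0, 0.3, 0.0], [0.3, -0.5, 0.0], [0.0, 0.0, 0.0]])
            sig = cauchy_stress(nh, Kinematics(np.eye(3) + eps))
            lam = E * nu / ((1 + nu) * (1 - 2 * nu))
            mu = E / (2 * (1 + nu))
            hooke = lam * np.trace(eps) * np.eye(3) + 2 * mu * eps
            scale_err.append(np.abs(sig - hooke).max() / np.abs(hooke).max())
        assert scale_err[0] < 5e-3                      # O(eps^2) residual
        assert scale_err[1] < 0.6 * scale_err[0]        # shrinks with eps


class TestPlaneStrainBatch:
    @pytest.mark.parametrize("mat", [NeoHooke(1.72, 0.06), CALCIFIED_1])
    def test_matches_general_path_and_fd_tangent(self, mat, rng):
        F2 = np.eye(2) + 0.04 * rng.standard_normal((5, 2, 2))
        psi, P, P33, A = plane_strain_response(mat, F2)
        for k in range(5):
            kin = Kinematics.plane_strain(F2[k])
            assert psi[k] == pytest.approx(strain_energy(mat, kin), rel=1e-10)
        sig = plane_strain_cauchy(mat, F2)
        for k in range(5):
            full = cauchy_stress(mat, Kinematics.plane_strain(F2[k]))
            assert np.allclose(sig[k], full, rtol=1e-8, atol=1e-10)


class TestUniaxialCurves:
    def test_neo_hooke_closed_form(self):
        c = uniaxial_curve(NeoHooke(1.72, 0.06), lam_max=1.2, n_points=6)
        assert c.stress[0] == pytest.approx(0.0, abs=1e-12)
        lam = c.stretch[-1]
        assert c.stress[-1] == pytest.approx(2 * 1.72 * (lam ** 2 - 1 / lam),
                                             rel=1e-10)

    def test_stiffness_ordering_calcified_above_cellular(self):
        lam = 1.1
        cal = uniaxial_curve(CALCIFIED_1, lam_max=lam, n_points=11)
        cel = uniaxial_curve(CELLULAR, lam_max=lam, n_points=11)
        assert cal.stress[-1] > cel.stress[-1]

    def test_goh_hardening_nondecreasing_stiffness(self):
        c = uniaxial_curve(CALCIFIED_1, lam_max=1.3, n_points=200)
        slopes = np.diff(c.stress) / np.diff(c.stretch)
        assert np.all(np.diff(slopes) > -1e-8)

    def test_fiber_angles_inert_at_kappa_third(self):
        a = GOH(9.58, 17564.0, 0.51,
                fiber_angles=np.array([[1.0, 0, 0], [1, 0, 0]]))
        b = GOH(9.58, 17564.0, 0.51,
                fiber_angles=np.array([[0.6, 0.8, 0], [0, 1, 0]]))
        ca, cb = uniaxial_curve(a, 1.25, 20), uniaxial_curve(b, 1.25, 20)
        assert np.allclose(ca.stress, cb.stress, rtol=0, atol=1e-12)

    def test_invalid_stretch_range_rejected(self):
        with pytest.raises(ValueError):
            uniaxial_curve(NeoHooke(1.0, 0.01), lam_max=1.0)


class TestCurveR2:
    def test_identical_curves_give_one(self):
        c = uniaxial_curve(NeoHooke(1.72, 0.06))
        assert curve_r2(c, c) == pytest.approx(1.0)

    def test_offset_decreases_r2_monotonically(self):
        c = uniaxial_curve(NeoHooke(1.72, 0.06))
        r2 = [curve_r2(c, BehaviorCurve(c.stretch, c.stress + d))
              for d in (0.0, 0.5, 1.0)]
        assert r2[0] > r2[1] > r2[2]

    def test_three_point_hand_computation(self):
        ref = BehaviorCurve(np.array([1.0, 1.1, 1.2]), np.array([0.0, 1.0, 2.0]))
        cand = BehaviorCurve(np.array([1.0, 1.1, 1.2]), np.array([0.0, 1.5, 2.0]))
        # SS_res = 0.25, SS_tot = 2 -> R2 = 0.875
        assert curve_r2(ref, cand) == pytest.approx(0.875)

    def test_constant_reference_rejected(self):
        flat = BehaviorCurve(np.array([1.0, 1.1]), np.array([0.0, 0.0]))
        with pytest.raises(ValueError):
            curve_r2(flat, flat)


class TestLHS:
    def test_fifteen_samples_stratified_per_dimension(self):
        s = lhs_sample([[1.0, 100.0], [390.0, 1200.0]], 15, seed=3)
        assert s.shape == (15, 2)
        for d, (lo, hi) in enumerate([(1.0, 100.0), (390.0, 1200.0)]):
            strata = ((s[:, d] - lo) / (hi - lo) * 15).astype(int)
            assert np.array_equal(np.sort(strata), np.arange(15))

    def test_single_sample_inside_box(self):
        s = lhs_sample([[0.0, 1.0]], 1, seed=0)
        assert 0.0 <= s[0, 0] <= 1.0

    def test_deterministic_per_seed(self):
        a = lhs_sample([[0.0, 1.0], [2.0, 3.0]], 7, seed=5)
        b = lhs_sample([[0.0, 1.0], [2.0, 3.0]], 7, seed=5)
        assert np.array_equal(a, b)


class TestMaterialSet:
    def test_validate_reports_missing_labels(self):
        ms = MaterialSet({"fibrotic": LinearElastic(600, 0.49)})
        with pytest.raises(KeyError, match="lipid_1"):
            ms.validate(["fibrotic", "lipid_1"])

    def test_dict_round_trip(self):
        ms = MaterialSet({"fibrotic": CALCIFIED_1,
                          "lipid_1": NeoHooke(1.72, 0.06),
                          "calcification_1": LinearElastic(5000.0, 0.333)})
        ms2 = MaterialSet.from_dict(ms.to_dict())
        assert ms2["fibrotic"].mu == pytest.approx(9.58)
        assert ms2["lipid_1"].D1 == pytest.approx(0.06)
        assert ms2["calcification_1"].nu == pytest.approx(0.333)
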
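"""Constitutive-law unit and property tests: invariants, stress,
continuity relations, grading stiffness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from conftest import random_ti_params
from tigrade.presets import BULK_MODULUS, material
from tigrade.ti_core import (
    InvalidKinematicsError,
    Kinematics,
    TIParams,
    c1_continuity_C5,
    c6_from_c0,
    cauchy_stress,
    deviatoric_invariants,
    discontinuity_index,
    fiber_stress_term,
    gamma1,
    gamma2,
    grading_stiffness,
    strain_energy,
)

E1 = np.array([1.0, 0.0, 0.0])


def uniaxial_kin(lam: float, axis: int = 0) -> Kinematics:
    d = np.full(3, lam ** -0.5)
    d[axis] = lam
    a0 = np.zeros(3)
    a0[axis] = 1.0
    return Kinematics(F=np.diag(d), a0=a0)


class TestDeviatoricInvariants:
    def test_identity(self):
        kin = Kinematics(F=np.eye(3), a0=E1)
        assert deviatoric_invariants(kin) == pytest.approx((3.0, 3.0, 1.0, 1.0))

    def test_isochoric_transverse_stretch(self):
        # volume-preserving stretch of 1.2 along the fiber (axis 2)
        F = np.diag([1 / math.sqrt(1.2), 1.2, 1 / math.sqrt(1.2)])
        kin = Kinematics(F=F, a0=np.array([0.0, 1.0, 0.0]))
        i1, i2, i4, lt = deviatoric_invariants(kin)
        assert i4 == pytest.approx(1.44, rel=1e-12)
        assert lt == pytest.approx(1.2, rel=1e-12)
        assert i1 == pytest.approx(1.44 + 2 / 1.2, rel=1e-12)

    @given(c=st.floats(0.3, 3.0))
    @settings(max_examples=25, deadline=None)
    def test_volumetric_scaling_invariance(self, c):
        # deviatoric invariants ignore a uniform volume change cF
        rng = np.random.default_rng(5)
        F = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
        if np.linalg.det(F) <= 0.05:
            F = np.eye(3)
        k1 = Kinematics(F=F, a0=E1)
        k2 = Kinematics(F=c * F, a0=E1)
        assert deviatoric_invariants(k2) == pytest.approx(
            deviatoric_invariants(k1), rel=1e-10
        )

    def test_invalid_kinematics(self):
        with pytest.raises(InvalidKinematicsError):
            Kinematics(F=np.zeros((3, 3)), a0=E1)
        with pytest.raises(InvalidKinematicsError):
            Kinematics(F=np.full((3, 3), np.nan), a0=E1)
        with pytest.raises(ValueError):
            Kinematics(F=np.eye(3), a0=np.array([1.0, 1.0, 0.0]))


class TestFiberStressTerm:
    def test_inactive_in_compression(self, valve_materials):
        for p in valve_materials.values():
            assert fiber_stress_term(0.95, p) == 0.0
            assert fiber_stress_term(1.0, p) == 0.0

    def test_exponential_branch_tv_ll(self, valve_materials):
        # C3 (e^{C4 (lt - 1)} - 1) with TV leaflet coefficients
        val = fiber_stress_term(1.1, valve_materials["TV_LL"])
        assert val == pytest.approx(1e5 * (math.exp(1.35) - 1.0), rel=1e-12)

    def test_c0_continuity_at_lambda_star(self, rng):
        for _ in range(20):
            p = random_ti_params(rng)
            ls = p.lambda_star
            expo = p.C3 * (math.exp(p.C4 * (ls - 1.0)) - 1.0)
            linear = p.C5 * ls + p.C6
            assert linear == pytest.approx(expo, rel=1e-9)
            # continuity of the evaluated function across the boundary
            assert fiber_stress_term(ls - 1e-9, p) == pytest.approx(
                fiber_stress_term(ls + 1e-9, p), rel=1e-6
            )

    def test_continuity_at_unity(self, valve_materials):
        p = valve_materials["TV_LL"]
        assert fiber_stress_term(1.0 + 1e-10, p) == pytest.approx(0.0, abs=1e-3)


class TestContinuityRelations:
    @pytest.mark.parametrize(
        "name, rel",
        [("TV_PM", 5e-3), ("MV_PM", 5e-3), ("MV_CT", 5e-3)],
    )
    def test_slope_continuity_matches_fitted_c5(self, valve_materials, name, rel):
        # these three valve fits happen to be numerically slope-continuous:
        # C3 C4 e^{C4 (lambda* - 1)} reproduces the independently fitted C5
        p = valve_materials[name]
        assert c1_continuity_C5(p) == pytest.approx(p.C5, rel=rel)

    def test_lambda_star_unity_limit(self):
        p = TIParams(0, 0, 10.0, 5.0, 1.0, 0.0, 1.0, BULK_MODULUS)
        assert c1_continuity_C5(p) == pytest.approx(50.0)

    def test_c6_value_tv_ll(self, valve_materials):
        p = valve_materials["TV_LL"]
        expected = 1e5 * (math.exp(13.5 * 0.28) - 1.0) - 4.80e7 * 1.28
        assert c6_from_c0(p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(-5.716e7, rel=1e-3)

    def test_joint_c1_continuity(self, rng):
        # C5 from slope continuity + C6 from value continuity => both
        # branches and their slopes agree at lambda*
        for _ in range(10):
            p0 = random_ti_params(rng)
            c5 = c1_continuity_C5(p0)
            p = TIParams(p0.C1, p0.C2, p0.C3, p0.C4, c5, 0.0,
                         p0.lambda_star, p0.K).with_c0_continuity()
            ls = p.lambda_star
            slope_exp = p.C3 * p.C4 * math.exp(p.C4 * (ls - 1.0))
            assert slope_exp == pytest.approx(p.C5, rel=1e-9)
            assert fiber_stress_term(ls, p) == pytest.approx(
                p.C5 * ls + p.C6, rel=1e-9
            )


class TestDiscontinuityIndex:
    def test_unity_under_slope_continuity(self, rng):
        p0 = random_ti_params(rng)
        c5 = c1_continuity_C5(p0)
        p = TIParams(p0.C1, p0.C2, p0.C3, p0.C4, c5, 0.0, p0.lambda_star, p0.K)
        assert discontinuity_index(p) == pytest.approx(1.0, rel=1e-14)

    def test_tv_ll_value(self, valve_materials):
        assert discontinuity_index(valve_materials["TV_LL"]) == pytest.approx(
            0.81, abs=5e-3
        )

    def test_linear_in_c5(self, valve_materials):
        p = valve_materials["TV_PM"]
        doubled = TIParams(p.C1, p.C2, p.C3, p.C4, 2 * p.C5, p.C6,
                           p.lambda_star, p.K)
        assert discontinuity_index(doubled) == pytest.approx(
            2 * discontinuity_index(p), rel=1e-12
        )

    def test_undefined_for_isotropic(self):
        p = TIParams(1e4, 0, 0.0, 1.0, 0.0, 0.0, 1.0, BULK_MODULUS)
        with pytest.raises(ValueError):
            discontinuity_index(p)


class TestCauchyStress:
    def test_zero_at_reference(self, rng):
        for _ in range(10):
            p = random_ti_params(rng)
            sig = cauchy_stress(Kinematics(F=np.eye(3), a0=E1), p)
            assert np.allclose(sig, 0.0, atol=1e-8 * p.C1 + 1e-12)

    def test_neo_hookean_uniaxial_closed_form(self):
        # incompressible neo-Hookean limit: axial - lateral stress
        # difference is 2 C1 (lam^2 - 1/lam)
        p = TIParams(1e4, 0, 0, 1.0, 0, 0, 1.0, BULK_MODULUS)
        kin = uniaxial_kin(1.2)
        sig = cauchy_stress(kin, p)
        diff = sig[0, 0] - sig[1, 1]
        assert diff == pytest.approx(2e4 * (1.2**2 - 1 / 1.2), rel=1e-12)
        assert diff == pytest.approx(1.2133e4, rel=1e-4)

    def test_objectivity(self, rng):
        # sigma(QF) = Q sigma(F) Q^T for any rotation Q
        for i in range(10):
            p = random_ti_params(rng)
            F = np.eye(3) + 0.2 * rng.standard_normal((3, 3))
            if np.linalg.det(F) <= 0.1:
                continue
            Q = Rotation.random(random_state=int(rng.integers(1 << 31))).as_matrix()
            kin = Kinematics(F=F, a0=E1)
            kin_rot = Kinematics(F=Q @ F, a0=E1)
            lhs = cauchy_stress(kin_rot, p)
            rhs = Q @ cauchy_stress(kin, p) @ Q.T
            scale = max(np.abs(rhs).max(), 1.0)
            assert np.allclose(lhs, rhs, atol=1e-8 * scale)

    def test_pure_volumetric_when_deviatoric_off(self):
        p = TIParams(0, 0, 0, 1.0, 0, 0, 1.0, BULK_MODULUS)
        kin = Kinematics(F=1.05 * np.eye(3), a0=E1)
        sig = cauchy_stress(kin, p)
        J = 1.05**3
        expected = BULK_MODULUS * math.log(J) / J
        assert np.allclose(sig, expected * np.eye(3), rtol=1e-12)

    def test_energy_consistency_uniaxial(self, rng):
        # nominal axial stress from the stress tensor equals dW/dlam on
        # the incompressible uniaxial path (central differences)
        h = 1e-6
        checked = 0
        while checked < 100:
            p = random_ti_params(rng)
            lam = rng.uniform(1.02, 1.35)
            if min(abs(lam - 1.0), abs(lam - p.lambda_star)) < 5 * h:
                continue
            sig = cauchy_stress(uniaxial_kin(lam), p)
            nominal = (sig[0, 0] - sig[1, 1]) / lam  # lateral traction-free
            w_hi = strain_energy(uniaxial_kin(lam + h), p)
            w_lo = strain_energy(uniaxial_kin(lam - h), p)
            fd = (w_hi - w_lo) / (2 * h)
            assert nominal == pytest.approx(fd, rel=1e-4, abs=1e-3)
            checked += 1


class TestGradingStiffness:
    def test_linear_regime_fiber_only(self, valve_materials):
        # with a negligible matrix, kg -> (2/3) C5 beyond lambda*
        p0 = valve_materials["TV_CT"]
        p = TIParams(0, 0, p0.C3, p0.C4, p0.C5, p0.C6, p0.lambda_star, p0.K)
        kg = grading_stiffness(p, 1.15, mode="analytic")
        assert kg == pytest.approx(2.0 / 3.0 * p.C5, rel=1e-14)

    def test_matrix_weights_at_unity(self):
        assert gamma1(1.0) == pytest.approx(4.0)
        assert gamma2(1.0) == pytest.approx(4.0)
        p = TIParams(1e4, 2e3, 0, 1.0, 0, 0, 1.0, BULK_MODULUS)
        assert grading_stiffness(p, 1.0) == pytest.approx(4 * (1e4 + 2e3), rel=1e-12)

    def test_no_fiber_contribution_in_compression(self, valve_materials):
        p = valve_materials["TV_LL"]
        kg = grading_stiffness(p, 0.95)
        expected = p.C1 * gamma1(0.95) + p.C2 * gamma2(0.95)
        assert kg == pytest.approx(expected, rel=1e-12)

    def test_analytic_matches_finite_difference(self, rng):
        # oracle agreement on draws away from the regime boundaries
        checked = 0
        while checked < 50:
            p = random_ti_params(rng)
            lam = rng.uniform(1.02, 1.4)
            if min(abs(lam - 1.0), abs(lam - p.lambda_star)) < 1e-3:
                continue
            ana = grading_stiffness(p, lam, mode="analytic")
            fd = grading_stiffness(p, lam, mode="finite_difference")
            assert ana == pytest.approx(fd, rel=1e-4)
            checked += 1

    def test_boundary_straddle_warns(self, valve_materials):
        p = valve_materials["TV_LL"]
        with pytest.warns(RuntimeWarning):
            grading_stiffness(p, p.lambda_star, mode="finite_difference")


class TestTIParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(C1=-1.0), dict(C4=0.0), dict(lambda_star=0.9), dict(K=0.0),
        ],
    )
    def test_rejects_invalid(self, kwargs):
        base = dict(C1=1e4, C2=0, C3=1e3, C4=10.0, C5=1e5, C6=0.0,
                    lambda_star=1.1, K=BULK_MODULUS)
        base.update(kwargs)
        with pytest.raises(ValueError):
            TIParams(**base)
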
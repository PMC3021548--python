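"""Energy landscapes: well calibration, analytic gradients, geometry."""

import math

import numpy as np
import pytest

from polbd.flexible_model import FlexibleModelParams
from polbd.potentials import (
    PotentialSpec,
    RigidPotential,
    binding_well_energy,
    binding_well_forces,
    flexible_energy,
    flexible_generalized_forces,
    linker_extension,
    spring_energy,
    spring_forces,
)

U0 = 16 * 4.1143
FORMS = ("morse", "gaussian")


@pytest.mark.parametrize("form", FORMS)
class TestRigidWells:
    def test_minima_at_both_sites(self, form):
        pot = RigidPotential(U0, form=form)
        assert pot.energy([0.0, 0.0, 0.0]) == pytest.approx(-U0, rel=1e-5)
        assert pot.energy([7.0, 0.0, 0.0]) == pytest.approx(-U0, rel=1e-5)

    def test_negligible_at_midpoint(self, form):
        pot = RigidPotential(U0, form=form)
        assert abs(pot.energy([3.5, 0.0, 0.0])) < 1e-2 * U0

    def test_forces_vanish_at_centres(self, form):
        # stationary up to the other well's tail (< 1e-5 of the peak force)
        pot = RigidPotential(U0, form=form)
        for c in ([0.0, 0.0, 0.0], [7.0, 0.0, 0.0]):
            assert np.allclose(pot.force(c), 0.0, atol=1e-3)

    def test_restoring_direction(self, form):
        pot = RigidPotential(U0, form=form)
        f = pot.force([0.5, 0.0, 0.0])
        assert f[0] < 0  # pulled back toward the origin well

    def test_mirror_symmetry(self, form):
        pot = RigidPotential(U0, form=form)
        up = pot.force([2.0, 1.3, 0.0])
        dn = pot.force([2.0, -1.3, 0.0])
        assert up[1] == pytest.approx(-dn[1])
        assert up[0] == pytest.approx(dn[0])

    def test_gradient_matches_finite_differences(self, form):
        """Analytic −∇U equals central differences at 1e-6 relative."""
        pot = RigidPotential(U0, form=form)
        rng = np.random.default_rng(11)
        pos = rng.uniform(-9, 9, size=(10_000, 3))
        f = pot.force(pos)
        h = 1e-4
        for ax in range(3):
            dp = np.zeros(3)
            dp[ax] = h
            fd = -(pot.energy(pos + dp) - pot.energy(pos - dp)) / (2 * h)
            scale = np.maximum(np.abs(f[:, ax]), 1e-3)
            assert np.max(np.abs(fd - f[:, ax]) / scale) < 1e-6

    def test_depth_calibration(self, form):
        """Minimum of the well over a dense grid equals −depth within 1%."""
        pot = RigidPotential(U0, form=form)
        xs = np.linspace(-2, 9, 551)
        ys = np.linspace(-1, 1, 101)
        X, Y = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([X, Y, np.zeros_like(X)], axis=-1)
        assert pot.energy(pts).min() == pytest.approx(-U0, rel=0.01)


class TestRigidAxisymmetric:
    def test_energy_xr_consistent_with_energy(self):
        pot = RigidPotential(U0)
        rng = np.random.default_rng(3)
        x = rng.uniform(-9, 9, 500)
        rho = rng.uniform(0, 9, 500)
        phi = rng.uniform(0, 2 * np.pi, 500)
        pos = np.stack([x, rho * np.cos(phi), rho * np.sin(phi)], axis=-1)
        assert np.allclose(pot.energy_xr(x, rho), pot.energy(pos), rtol=1e-12)


class TestPotentialSpec:
    def test_validation(self):
        with pytest.raises(ValueError):
            PotentialSpec(form="triangle")
        with pytest.raises(ValueError):
            PotentialSpec(depth=-1.0)
        with pytest.raises(ValueError):
            PotentialSpec(range_translational=0.0)


class TestLinkerGeometry:
    def test_resting_pose_unstretched(self):
        assert linker_extension(3.5, 0.0, 0.0, r=3.5) == pytest.approx(0.0)

    def test_active_pose_extension_equals_d(self):
        assert linker_extension(-3.5, 2.0, math.pi, r=3.5) == pytest.approx(2.0)

    def test_overstretched_pose(self):
        # (−r, 0, 0): attachment at (r, 0) -> R = 2r = 7 > 4.8 cap
        R = linker_extension(-3.5, 0.0, 0.0, r=3.5)
        assert R == pytest.approx(7.0, rel=1e-12)
        assert R > 4.8
        # (0, 0, π/2): attachment at (0, r) -> R = r, still within the cap
        assert linker_extension(0.0, 0.0, math.pi / 2, r=3.5) == pytest.approx(3.5)


class TestFlexibleForces:
    def test_resting_pose_force_free(self):
        p = FlexibleModelParams(v0_kbt=0.0, F_load=0.0)
        fx, fy, tq = flexible_generalized_forces(3.5, 0.0, 0.0, p)
        assert (fx, fy, tq) == pytest.approx((0.0, 0.0, 0.0))

    def test_active_pose_force_free_without_spring(self):
        p = FlexibleModelParams(K=0.0, F_load=0.0, d=2.0)
        fx, fy, tq = flexible_generalized_forces(-3.5, 2.0, math.pi, p)
        assert (fx, fy, tq) == pytest.approx((0.0, 0.0, 0.0), abs=1e-9)

    def test_spring_force_example(self):
        # pose (r, 1, 0): R = 1 along y, so Fy = −K·1
        p = FlexibleModelParams(v0_kbt=0.0, K=8.56)
        fx, fy, tq = flexible_generalized_forces(3.5, 1.0, 0.0, p)
        assert fy == pytest.approx(-8.56)
        assert fx == pytest.approx(0.0)

    @pytest.mark.parametrize("form", FORMS)
    def test_gradients_match_finite_differences(self, form):
        p = FlexibleModelParams(form=form, F_load=0.0, K=8.56, d=2.0)
        rng = np.random.default_rng(5)
        poses = np.stack(
            [
                rng.uniform(-5, 5, 10_000),
                rng.uniform(-5, 5, 10_000),
                rng.uniform(-math.pi, math.pi, 10_000),
            ],
            axis=-1,
        )
        fx, fy, tq = flexible_generalized_forces(
            poses[:, 0], poses[:, 1], poses[:, 2], p
        )
        h = 1e-5
        for ax, analytic in ((0, fx), (1, fy), (2, tq)):
            dp = np.zeros(3)
            dp[ax] = h
            hi = flexible_energy(*(poses + dp).T, p)
            lo = flexible_energy(*(poses - dp).T, p)
            fd = -(hi - lo) / (2 * h)
            scale = np.maximum(np.abs(analytic), 1e-2)
            assert np.max(np.abs(fd - analytic) / scale) < 1e-6

    def test_load_terms(self):
        base = FlexibleModelParams(v0_kbt=0.0, K=0.0)
        loaded = base.replace(F_load=2.0, load_torque="lever")
        th = 1.0
        fx0, _, tq0 = flexible_generalized_forces(0.0, 0.0, th, base)
        fx1, _, tq1 = flexible_generalized_forces(0.0, 0.0, th, loaded)
        assert fx1 - fx0 == pytest.approx(2.0)
        assert tq1 - tq0 == pytest.approx(-2.0 * 3.5 * math.sin(th))
        no_lever = loaded.replace(load_torque="none")
        _, _, tq2 = flexible_generalized_forces(0.0, 0.0, th, no_lever)
        assert tq2 == pytest.approx(tq0)

    @pytest.mark.parametrize("form", FORMS)
    def test_binding_well_depth_calibration(self, form):
        p = FlexibleModelParams(form=form, d=2.0)
        u = np.linspace(-4, 0, 201)
        v = np.linspace(0, 4, 201)
        U, V = np.meshgrid(u, v, indexing="ij")
        e = binding_well_energy(
            U, V, math.pi, V0=p.v0, A=p.A, B=p.B, r=p.r, d=p.d, form=form
        )
        assert e.min() == pytest.approx(-p.v0, rel=0.01)

    def test_energy_decreases_into_well(self):
        p = FlexibleModelParams(d=2.0)
        # straight path from just outside the well to its centre
        ts = np.linspace(0.0, 1.0, 50)
        poses = np.array(
            [(-3.5 + (1 - t) * 1.5, 2.0, math.pi) for t in ts]
        )
        e = binding_well_energy(
            poses[:, 0], poses[:, 1], poses[:, 2],
            V0=p.v0, A=p.A, B=p.B, r=p.r, d=p.d, form=p.form,
        )
        assert np.all(np.diff(e) < 0)


class TestKernelForceConsistency:
    """The numba kernels' inlined forces equal the reference implementation."""

    @pytest.mark.parametrize("form_name,form_id", [("morse", 0), ("gaussian", 1)])
    def test_rigid(self, form_name, form_id, warm_kernels):
        pot = RigidPotential(U0, form=form_name)
        rng = np.random.default_rng(7)
        for pos in rng.uniform(-9, 9, size=(200, 3)):
            ref = pot.force(pos)
            got = warm_kernels._rigid_force(*pos, U0, 0.5, 7.0, form_id)
            assert np.allclose(got, ref, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize("form_name,form_id", [("morse", 0), ("gaussian", 1)])
    def test_flexible(self, form_name, form_id, warm_kernels):
        p = FlexibleModelParams(form=form_name, F_load=1.2, d=2.0, K=8.56)
        rng = np.random.default_rng(8)
        for pose in rng.uniform(-4, 4, size=(200, 3)):
            ref = flexible_generalized_forces(*pose, p)
            fx, fy, fz, ft = warm_kernels._flex_force(
                pose[0], pose[1], 0.0, pose[2], p.v0, p.A, p.B, p.r, p.d,
                p.spring_constant, p.F_load, True, form_id, False,
            )
            assert np.allclose((fx, fy, ft), ref, rtol=1e-10, atol=1e-12)
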
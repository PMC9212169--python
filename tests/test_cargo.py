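"""Cargo Langevin dynamics: steric/external forces, translation, rotation."""

import math

import numpy as np
import pytest

import fluidcargo as fc
from fluidcargo import cargo
from fluidcargo.engine import run_single_cargo, initialize_run, InitialState


@pytest.fixture(scope="module")
def params():
    return fc.default_kinesin_parameters()


class TestStericForce:
    def test_zero_at_contact(self, params):
        X = [0.0, 0.0, 262.5]
        assert np.allclose(cargo.steric_force(X, params), 0.0)

    def test_overlap_spring(self, params):
        """1 nm overlap → 10 k_mot × 1 = 3.2 pN away from the axis."""
        f = cargo.steric_force([5.0, 0.0, 261.5], params)
        assert f == pytest.approx([0.0, 0.0, 3.2])

    def test_no_x_component(self, params):
        f = cargo.steric_force([100.0, 30.0, 200.0], params)
        assert f[0] == 0.0
        assert np.linalg.norm(f) > 0


class TestExternalForce:
    def test_constant_hindering(self):
        lp = fc.LoadProtocol(kind="constant_hindering", f_h=2.0)
        assert cargo.external_force(lp, [50.0, 0, 0]) == pytest.approx(
            [-2.0, 0, 0]
        )

    def test_trap_at_center_is_zero(self):
        lp = fc.LoadProtocol(kind="optical_trap", trap_center=(1.0, 2.0, 3.0))
        assert np.allclose(cargo.external_force(lp, [1.0, 2.0, 3.0]), 0.0)

    def test_trap_restoring(self):
        lp = fc.LoadProtocol(kind="optical_trap", k_trap=0.06,
                             trap_center=(0.0, 0.0, 0.0))
        f = cargo.external_force(lp, [100.0, 0.0, 0.0])
        assert f == pytest.approx([-6.0, 0.0, 0.0])

    def test_trap_x_only_switch(self):
        lp = fc.LoadProtocol(kind="optical_trap", k_trap=0.06,
                             trap_center=(0.0, 0.0, 0.0), trap_x_only=True)
        f = cargo.external_force(lp, [100.0, 50.0, 20.0])
        assert f == pytest.approx([-6.0, 0.0, 0.0])

    def test_none(self):
        assert np.allclose(
            cargo.external_force(fc.LoadProtocol(), [9.0, 9.0, 9.0]), 0.0
        )


class TestTranslation:
    def test_drift_velocity(self, params, rng):
        """Constant force, negligible noise → drift f/γ_c."""
        cold = params.with_overrides(environment={"temperature": 1e-9})
        X = np.zeros(3)
        f = np.array([2.0, 0.0, 0.0])
        dt = 1e-6
        for _ in range(1000):
            X = cargo.translational_step(X, f, dt, cold, rng)
        v = X[0] / (1000 * dt)
        assert v == pytest.approx(2.0 / params.gamma_c, rel=1e-3)

    def test_free_cargo_msd(self, params):
        """Unbound cargo is 3-D Brownian with D_c = kT/γ_c (within 3%)."""
        ps = params.with_overrides(
            cargo={"motor_count": 1, "rotation_enabled": False},
            run={"max_time": 4.0, "record_forces": False,
                 "record_anchors": False, "record_orientation": False},
        )
        init = initialize_run(ps, np.random.default_rng(0))
        init.bound[:] = False
        # accumulate displacement over several independent replicas
        disp2 = []
        lag = 10  # samples = 0.1 s
        for seed in range(6):
            traj, _ = run_single_cargo(ps, seed, initial=init,
                                       kinetics_enabled=False)
            d = traj.X[lag:] - traj.X[:-lag]
            disp2.append((d**2).sum(axis=1))
        msd = np.concatenate(disp2).mean()
        D_c = ps.kT / ps.gamma_c
        assert msd == pytest.approx(6 * D_c * 0.1, rel=0.03)

    def test_trap_equipartition(self, params):
        """Stationary trap variance is kT/k_trap per axis (within 5%)."""
        ps = params.with_overrides(
            cargo={"motor_count": 1, "rotation_enabled": False},
            load={"kind": "optical_trap", "k_trap": 0.06,
                  "trap_center": (0.0, 0.0, 1.0e5)},
            run={"max_time": 4.0, "record_forces": False,
                 "record_anchors": False, "record_orientation": False},
        )
        init = initialize_run(ps, np.random.default_rng(0))
        init.bound[:] = False
        init.center = np.array([0.0, 0.0, 1.0e5])  # far from the MT
        init.anchors = init.center + (init.anchors - [0.0, 0.0, 262.5])
        var = []
        for seed in range(8):
            traj, _ = run_single_cargo(ps, seed, initial=init,
                                       kinetics_enabled=False)
            burn = 50
            var.append(np.var(traj.X[burn:] - [0.0, 0.0, 1.0e5], axis=0))
        var = np.mean(var, axis=0)
        expected = ps.kT / 0.06
        for axis in range(3):
            assert var[axis] == pytest.approx(expected, rel=0.05)


class TestTorqueAndRotation:
    def test_parallel_force_no_torque(self):
        X = np.zeros(3)
        r = np.array([[0.0, 0.0, 250.0]])
        f = np.array([[0.0, 0.0, 5.0]])
        assert np.allclose(cargo.total_torque(r, f, X), 0.0)

    def test_cross_product_example(self):
        tau = cargo.total_torque(
            [[0.0, 0.0, -250.0]], [[2.0, 0.0, 0.0]], np.zeros(3)
        )
        assert tau == pytest.approx([0.0, -500.0, 0.0])

    def test_mirror_symmetric_pair_cancels(self):
        """A motor pair mirror-symmetric about the x-z plane: torque is a
        pseudovector, so the in-plane components (x, z) cancel and only
        the normal (y) component survives."""
        anchors = [[0.0, 100.0, -200.0], [0.0, -100.0, -200.0]]
        forces = [[3.0, 1.0, 0.5], [3.0, -1.0, 0.5]]
        tau = cargo.total_torque(anchors, forces, np.zeros(3))
        assert tau[0] == pytest.approx(0.0, abs=1e-12)
        assert tau[2] == pytest.approx(0.0, abs=1e-12)

    def test_rotation_disabled_is_identity(self, params, rng):
        ps = params.with_overrides(cargo={"rotation_enabled": False})
        dtheta = cargo.rotational_step([1e3, 0, 0], 1e-6, ps, rng)
        assert np.allclose(dtheta, 0.0)

    def test_zero_alpha_zero_noise(self, params, rng):
        ps = params.with_overrides(cargo={"alpha": 0.0})
        dtheta = cargo.rotational_step([0.0, 0.0, 0.0], 1e-6, ps, rng)
        assert np.allclose(dtheta, 0.0)

    def test_noise_magnitude(self, params, rng):
        """Zero torque: |Δθ|² = α² 4 D_R Δt exactly per draw."""
        ps = params.with_overrides(cargo={"alpha": 0.5})
        dt = 1e-6
        mags = [
            np.linalg.norm(cargo.rotational_step([0, 0, 0], dt, ps, rng))
            for _ in range(100)
        ]
        expected = 0.5 * math.sqrt(4 * ps.D_R * dt)
        assert np.allclose(mags, expected, rtol=1e-12)

    def test_constant_torque_angular_velocity(self, params):
        """No noise: angular velocity τ/γ_R about the torque axis."""
        ps = params.with_overrides(cargo={"alpha": 0.0})
        tau = np.array([0.0, 0.0, 1.0e4])
        dt = 1e-6

        class _NoRandom:
            def random(self):
                return 0.5

        dtheta = cargo.rotational_step(tau, dt, ps, _NoRandom())
        assert dtheta == pytest.approx(tau * dt / ps.gamma_R, rel=1e-12)

    def test_apply_rotation_preserves_radii(self, params, rng):
        center = np.array([0.0, 0.0, 262.5])
        u = rng.standard_normal((6, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        anchors = center + 250.0 * u
        dtheta = np.array([0.01, -0.02, 0.005])
        out, orient = cargo.apply_rotation(dtheta, center, anchors, np.eye(3))
        assert np.allclose(
            np.linalg.norm(out - center, axis=1), 250.0, rtol=1e-9
        )
        assert np.allclose(orient.T @ orient, np.eye(3), atol=1e-10)


def test_anchors_stay_on_sphere_through_full_dynamics(params):
    """Coupled translate+rotate+diffuse updates keep |A - X| = R."""
    ps = params.with_overrides(
        motor={"surface_diffusion": 1.0},
        cargo={"motor_count": 8, "rotation_enabled": True},
        run={"max_time": 0.2, "record_anchors": True,
             "record_orientation": True},
    )
    traj, _ = run_single_cargo(ps, 5)
    radii = np.linalg.norm(traj.anchors - traj.X[:, None, :], axis=2)
    assert np.allclose(radii, 250.0, rtol=1e-9)
    # orientation stays orthonormal
    last = traj.orientation[-1]
    assert np.allclose(last.T @ last, np.eye(3), atol=1e-9)


class TestCalibrateAlpha:
    """Root-finder logic, isolated from the expensive estimator."""

    def _patch(self, monkeypatch, fn):
        from fluidcargo import cargo as cargo_mod

        def fake_measure(params, seed, total_time=30.0, n_reps=6, **kw):
            return fn(params.cargo.alpha)

        monkeypatch.setattr(cargo_mod, "measure_rotational_diffusion",
                            fake_measure)

    def test_converges_to_root(self, params, monkeypatch):
        self._patch(monkeypatch, lambda a: 0.04 + 0.9 * a)
        alpha = cargo.calibrate_alpha(params, target_DR=0.07)
        assert 0.9 * alpha + 0.04 == pytest.approx(0.07, rel=0.05)

    def test_unbracketed_target_raises(self, params, monkeypatch):
        self._patch(monkeypatch, lambda a: 0.2 + a)  # always above target
        with pytest.raises(RuntimeError, match="not bracketed"):
            cargo.calibrate_alpha(params, target_DR=0.07)
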
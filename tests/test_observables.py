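"""Estimator layer, validated against synthetic trajectories with known
ground truth (parameter-recovery suite)."""

import math

import numpy as np
import pytest

from fluidcargo import observables as obs
from fluidcargo.engine import TrajectoryRecord


def _linear_trajectory(v=500.0, T=10.0, rate=100.0, N=2):
    traj, ev = obs.make_synthetic_trajectory(
        N=N, bind_rate=1.0, unbind_rate=1e-9, speed=v, noise_sigma=0.0,
        max_time=T, sampling_rate=rate, n_always_bound=N, seed=0,
    )
    return traj, ev


class TestRunLengthAndVelocity:
    def test_run_length_exact_on_linear_motion(self):
        traj, _ = _linear_trajectory(v=500.0, T=10.0)
        assert obs.run_length(traj) == pytest.approx(500.0 * 10.0, rel=1e-9)

    def test_effective_velocity_exact_on_linear_motion(self):
        traj, _ = _linear_trajectory(v=500.0, T=10.0)
        table = obs.effective_velocity([traj], window=0.1)
        assert table["v_mean"].iloc[0] == pytest.approx(500.0, rel=1e-9)

    def test_effective_velocity_zero_for_pure_noise(self):
        traj, _ = obs.make_synthetic_trajectory(
            N=1, bind_rate=1.0, unbind_rate=1e-9, speed=0.0,
            noise_sigma=50.0, max_time=200.0, n_always_bound=1, seed=4,
        )
        table = obs.effective_velocity([traj], window=0.1)
        v, sem = table["v_mean"].iloc[0], table["v_sem"].iloc[0]
        assert abs(v) < 3 * sem

    def test_immediate_detachment_run_length_zero(self):
        traj, _ = obs.make_synthetic_trajectory(
            N=1, bind_rate=1e-9, unbind_rate=1e9, speed=500.0, seed=1,
        )
        assert abs(obs.run_length(traj)) < 1.0


class TestMeanBoundMotors:
    def test_all_always_bound(self):
        traj, _ = _linear_trajectory(N=3)
        res = obs.mean_bound_motors([traj])
        assert res["pooled_mean"] == pytest.approx(3.0)

    def test_two_state_occupancy_closed_form(self):
        """n = 1↔2 chain: P(2) = λ/(λ+μ), so ⟨n⟩ = 1 + λ/(λ+μ)."""
        lam, mu = 2.0, 3.0
        trajs = []
        for seed in range(20):
            tr, _ = obs.make_synthetic_trajectory(
                N=2, bind_rate=lam, unbind_rate=mu, speed=0.0,
                max_time=200.0, n_always_bound=1, seed=seed,
            )
            trajs.append(tr)
        res = obs.mean_bound_motors(trajs)
        expected = 1.0 + lam / (lam + mu)
        assert abs(res["pooled_mean"] - expected) < 3 * max(
            res["pooled_sem"], 3e-3
        )


class TestOffRate:
    def test_inverse_mean_duration(self):
        class _Fake:
            def __init__(self, durations):
                self._d = np.asarray(durations)

            def engagement_durations(self):
                return self._d, np.array([])

        res = obs.off_rate_estimate([_Fake([1.0, 2.0, 3.0])])
        assert res["off_rate"] == pytest.approx(0.5)
        assert res["n_engagements"] == 3

    def test_recovery_from_synthetic_events(self):
        mu = 0.5
        logs = []
        n_events = 0
        for seed in range(40):
            _, ev = obs.make_synthetic_trajectory(
                N=4, bind_rate=2.0, unbind_rate=mu, speed=0.0,
                max_time=100.0, seed=seed, stop_on_detach=False,
            )
            logs.append(ev)
            n_events += ev.engagement_durations()[0].size
        assert n_events > 1000
        res = obs.off_rate_estimate(logs)
        assert abs(res["off_rate"] - mu) < 3 * res["sem"]

    def test_error_with_no_engagements(self):
        class _Empty:
            def engagement_durations(self):
                return np.array([]), np.array([])

        with pytest.raises(ValueError):
            obs.off_rate_estimate([_Empty()])

    def test_kaplan_meier_close_to_plain_when_uncensored(self):
        _, ev = obs.make_synthetic_trajectory(
            N=3, bind_rate=2.0, unbind_rate=0.7, speed=0.0, max_time=100.0,
            seed=2, stop_on_detach=False,
        )
        plain = obs.off_rate_estimate([ev])["off_rate"]
        km = obs.off_rate_estimate([ev], kaplan_meier=True)["off_rate"]
        assert km == pytest.approx(plain, rel=0.2)


class TestConditionalOnRate:
    def test_recovery_from_birth_death_chain(self):
        lam = 1.5
        logs = []
        for seed in range(30):
            _, ev = obs.make_synthetic_trajectory(
                N=5, bind_rate=lam, unbind_rate=1.0, speed=0.0,
                max_time=100.0, seed=seed, stop_on_detach=False,
            )
            logs.append(ev)
        for n in (1, 2, 3):
            res = obs.conditional_on_rate(logs, n, 5)
            assert res["defined"]
            assert abs(res["rate"] - lam) < 3 * res["sem"]

    def test_undefined_when_saturated(self):
        _, ev = obs.make_synthetic_trajectory(N=2, seed=0)
        res = obs.conditional_on_rate([ev], 2, 2)
        assert not res["defined"]


def _manual_trajectory(forces, bound=None):
    """Tiny hand-built trajectory with given (T, N, 3) forces."""
    forces = np.asarray(forces, dtype=float)
    T, N, _ = forces.shape
    if bound is None:
        bound = np.ones((T, N), dtype=bool)
    t = np.arange(T) * 0.01
    X = np.zeros((T, 3))
    return TrajectoryRecord(
        t=t, X=X, n_bound=bound.sum(axis=1), bound=bound,
        head_x=np.zeros((T, N)), anchors=None, forces=forces,
        orientation=None, meta={"termination": "max_time", "t_end": t[-1]},
    )


class TestForceStatistics:
    def test_antagonistic_pair(self):
        """Two motors at +f/-f: pair correlation -f², variance of |f| zero."""
        f = 2.0
        forces = np.zeros((50, 2, 3))
        forces[:, 0, 0] = f
        forces[:, 1, 0] = -f
        stats_ = obs.force_statistics(
            [_manual_trajectory(forces)], n=2, sample_size=500,
        )
        assert stats_.pair_correlation == pytest.approx(-(f**2))
        assert stats_.mean_variance == pytest.approx(0.0, abs=1e-12)
        assert stats_.frac_nonnegligible == pytest.approx(1.0)

    def test_all_zero_forces(self):
        forces = np.zeros((200, 2, 3))
        stats_ = obs.force_statistics(
            [_manual_trajectory(forces)], n=2, sample_size=500,
        )
        assert stats_.frac_nonnegligible == 0.0
        assert stats_.mean_variance == 0.0
        assert stats_.pair_correlation == 0.0

    def test_low_sample_warning(self):
        forces = np.zeros((5, 2, 3))
        with pytest.warns(RuntimeWarning):
            stats_ = obs.force_statistics(
                [_manual_trajectory(forces)], n=2, sample_size=100,
            )
        assert stats_.low_sample_warning

    def test_independent_forces_uncorrelated(self, rng):
        forces = np.zeros((5000, 2, 3))
        forces[:, :, 0] = rng.standard_normal((5000, 2))
        stats_ = obs.force_statistics(
            [_manual_trajectory(forces)], n=2, sample_size=5000,
        )
        assert abs(stats_.pair_correlation) < 3 * stats_.pair_correlation_sem


class TestSpatialDistributions:
    def _traj_with_anchors(self, direction):
        T, N = 20, 4
        t = np.arange(T) * 0.01
        X = np.zeros((T, 3))
        anchors = np.tile(250.0 * np.asarray(direction), (T, N, 1))
        bound = np.ones((T, N), dtype=bool)
        return TrajectoryRecord(
            t=t, X=X, n_bound=bound.sum(axis=1), bound=bound,
            head_x=np.zeros((T, N)), anchors=anchors,
            forces=np.zeros((T, N, 3)),
            orientation=np.broadcast_to(np.eye(3), (T, 3, 3)).copy(),
            meta={"termination": "max_time", "t_end": t[-1]},
        )

    def test_bottom_pole_concentrates_at_pi(self):
        traj = self._traj_with_anchors([0.0, 0.0, -1.0])
        res = obs.spatial_distributions([traj], n_time_bins=2)
        dens = res["theta_density"]
        assert np.argmax(dens[0]) == dens.shape[1] - 1

    def test_density_normalized_per_time_bin(self):
        traj = self._traj_with_anchors([0.0, 1.0, 0.0])
        res = obs.spatial_distributions([traj], n_time_bins=3)
        d_th = res["theta_edges"][1] - res["theta_edges"][0]
        sums = res["theta_density"].sum(axis=1) * d_th
        assert np.allclose(sums[sums > 0], 1.0)

    def test_uniform_anchors_sine_density(self, rng):
        T, N = 400, 16
        u = rng.standard_normal((T, N, 3))
        u /= np.linalg.norm(u, axis=2, keepdims=True)
        t = np.arange(T) * 0.01
        X = np.zeros((T, 3))
        bound = np.ones((T, N), dtype=bool)
        traj = TrajectoryRecord(
            t=t, X=X, n_bound=bound.sum(axis=1), bound=bound,
            head_x=np.zeros((T, N)), anchors=250.0 * u,
            forces=np.zeros((T, N, 3)), orientation=None,
            meta={"termination": "max_time", "t_end": t[-1]},
        )
        res = obs.spatial_distributions([traj], n_time_bins=1, n_theta=18)
        centers = 0.5 * (res["theta_edges"][:-1] + res["theta_edges"][1:])
        expected = 0.5 * np.sin(centers)
        # relative agreement with the sin θ law
        assert np.corrcoef(res["theta_density"][0], expected)[0, 1] > 0.98

    def test_body_map_normalized(self):
        traj = self._traj_with_anchors([0.0, 0.0, -1.0])
        res = obs.spatial_distributions([traj])
        d_th = res["theta_edges"][1] - res["theta_edges"][0]
        d_ph = res["phi_edges"][1] - res["phi_edges"][0]
        assert res["body_map"].sum() * d_th * d_ph == pytest.approx(1.0)


class TestRescaledForce:
    def test_constant_total(self):
        forces = np.zeros((30, 4, 3))
        forces[:, :, 0] = 3.5  # total 14 pN
        traj = _manual_trajectory(forces)
        assert obs.rescaled_collective_force([traj], 4, 7.0) == (
            pytest.approx(14.0 / 28.0)
        )

    def test_never_bound_is_zero(self):
        forces = np.zeros((30, 4, 3))
        forces[:, :, 0] = 99.0
        bound = np.zeros((30, 4), dtype=bool)
        traj = _manual_trajectory(forces, bound)
        assert obs.rescaled_collective_force([traj], 4, 7.0) == 0.0
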
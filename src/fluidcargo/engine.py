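"""Orchestration of cargo runs and ensembles.

Single runs, deterministic seeded ensembles, and the special-purpose
virtual experiments: the fixed-height on-rate measurement and the
optical-trap collective-force scan.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .parameters import ParameterSet
from .motor import SATURATING_ATP

__all__ = [
    "InitialState",
    "TrajectoryRecord",
    "EventLog",
    "initialize_run",
    "run_single_cargo",
    "run_ensemble",
    "fixed_height_onrate_experiment",
    "trap_experiment",
    "child_seeds",
]

TERMINATION_NAMES = {
    _kernel.TERM_DETACHED: "detached",
    _kernel.TERM_MAX_TIME: "max_time",
    _kernel.TERM_EVENT_OVERFLOW: "event_overflow",
    _kernel.TERM_NONFINITE: "nonfinite",
}

EVENT_NAMES = {
    _kernel.EV_BIND: "bind",
    _kernel.EV_UNBIND: "unbind",
    _kernel.EV_STEP: "step",
}

_LOAD_CODES = {"none": _kernel.LOAD_NONE,
               "constant_hindering": _kernel.LOAD_CONSTANT,
               "optical_trap": _kernel.LOAD_TRAP}


@dataclass
class InitialState:
    """Cargo and motor state at t = 0."""

    center: np.ndarray
    anchors: np.ndarray
    bound: np.ndarray
    head_x: np.ndarray
    head_y: np.ndarray
    head_z: np.ndarray
    orientation: np.ndarray


@dataclass
class TrajectoryRecord:
    """Sampled states of one cargo run (sampling rate from the settings).

    ``forces`` holds the per-motor force **on the cargo**; the force on a
    motor head is its negative.  ``anchors``, ``forces`` and
    ``orientation`` may be None when recording was disabled.
    """

    t: np.ndarray
    X: np.ndarray
    n_bound: np.ndarray
    bound: np.ndarray
    head_x: np.ndarray
    anchors: np.ndarray | None
    forces: np.ndarray | None
    orientation: np.ndarray | None
    meta: dict = field(default_factory=dict)

    @property
    def termination(self) -> str:
        return self.meta.get("termination", "unknown")

    @property
    def censored(self) -> bool:
        return self.termination != "detached"

    def __len__(self) -> int:
        return self.t.size


@dataclass
class EventLog:
    """Discrete bind/unbind/step events of one run."""

    t: np.ndarray
    motor: np.ndarray
    kind: np.ndarray
    meta: dict = field(default_factory=dict)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "motor": self.motor,
                "kind": [EVENT_NAMES[k] for k in self.kind],
            }
        )

    def engagement_durations(self) -> tuple[np.ndarray, np.ndarray]:
        """(completed, censored) engagement durations in seconds.

        A completed engagement is a bind followed by an unbind of the same
        motor; an engagement still open at run end is censored at the run's
        final time.
        """
        completed = []
        censored = []
        t_end = self.meta.get("t_end", self.t[-1] if self.t.size else 0.0)
        open_bind: dict[int, float] = {}
        for t, m, k in zip(self.t, self.motor, self.kind):
            if k == _kernel.EV_BIND:
                open_bind[m] = t
            elif k == _kernel.EV_UNBIND:
                t0 = open_bind.pop(m, None)
                if t0 is not None:
                    completed.append(t - t0)
        for t0 in open_bind.values():
            censored.append(t_end - t0)
        return np.asarray(completed), np.asarray(censored)

    def __len__(self) -> int:
        return self.t.size


def _uniform_sphere_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n uniform directions via θ = arccos(2a-1), φ = 2πb."""
    a = rng.random(n)
    b = rng.random(n)
    ct = 2.0 * a - 1.0
    st = np.sqrt(np.maximum(0.0, 1.0 - ct**2))
    phi = 2.0 * np.pi * b
    return np.column_stack([st * np.cos(phi), st * np.sin(phi), ct])


def _rotation_to_bottom(u: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix carrying unit vector u to (0, 0, -1)."""
    target = np.array([0.0, 0.0, -1.0])
    c = float(np.dot(u, target))
    if c > 1.0 - 1e-12:
        return np.eye(3)
    if c < -1.0 + 1e-12:  # u = +z: rotate by π about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(u, target)
    axis /= np.linalg.norm(axis)
    from .sphere import rodrigues_matrix

    return rodrigues_matrix(axis, math.acos(c))


def initialize_run(params: ParameterSet, rng: np.random.Generator) -> InitialState:
    """Place the cargo above the microtubule with one motor bound.

    Anchors are uniform on the sphere; the whole configuration is rigidly
    rotated so that one (randomly chosen) anchor sits at the bottom of
    the cargo within reach of the microtubule, the cargo centre is at
    contact height R + r_MT, and that motor is bound with its head at the
    anchor's axial projection (zero initial strain).  Rotating a randomly
    chosen anchor — rather than the one that happened to start lowest —
    keeps the remaining anchors exactly uniform on the sphere.
    """
    N = params.cargo.motor_count
    R = params.cargo.radius
    r_MT = params.environment.MT_radius
    u = _uniform_sphere_directions(N, rng)
    i0 = 0  # anchors are i.i.d. uniform, so index 0 is a uniform choice
    rot = _rotation_to_bottom(u[i0])
    u = u @ rot.T
    center = np.array([0.0, 0.0, R + r_MT])
    anchors = center + R * u
    bound = np.zeros(N, dtype=np.bool_)
    bound[i0] = True
    head_x = np.zeros(N)
    head_y = np.zeros(N)
    head_z = np.zeros(N)
    a = anchors[i0]
    rho = math.hypot(a[1], a[2])
    head_x[i0] = a[0]
    if rho < 1e-9:
        head_y[i0], head_z[i0] = 0.0, r_MT
    else:
        head_y[i0] = r_MT * a[1] / rho
        head_z[i0] = r_MT * a[2] / rho
    return InitialState(center, anchors, bound, head_x, head_y, head_z, np.eye(3))


def _kernel_args(params: ParameterSet):
    m, c, e, ld, run = (params.motor, params.cargo, params.environment,
                        params.load, params.run)
    atp = e.ATP
    v0_atp = m.v_max * atp / (m.K_m + atp)
    v0_sat = m.v_max * SATURATING_ATP / (m.K_m + SATURATING_ATP)
    return dict(
        dt=run.timestep,
        L_mot=m.rest_length,
        k_mot=m.stiffness,
        pi0=m.binding_rate,
        eps0=m.unloaded_off_rate,
        F_s=m.stall_force,
        F_d=m.detachment_force,
        w_exp=m.fv_exponent,
        delta=m.step_size,
        asst_slope=m.assistive_slope,
        D_nm2=m.surface_diffusion_nm2,
        R=c.radius,
        k_steric=c.steric_stiffness_factor * m.stiffness,
        rotation_enabled=c.rotation_enabled,
        alpha=c.alpha,
        kT=e.kT,
        gamma_c=params.gamma_c,
        gamma_R=params.gamma_R,
        D_rot=params.D_R,
        r_MT=e.MT_radius,
        v0_atp=v0_atp,
        v0_sat=v0_sat,
        load_kind=_LOAD_CODES[ld.kind],
        f_h=ld.f_h,
        k_trap=ld.k_trap,
        trap_cx=ld.trap_center[0],
        trap_cy=ld.trap_center[1],
        trap_cz=ld.trap_center[2],
        trap_x_only=ld.trap_x_only,
    )


def run_single_cargo(
    params: ParameterSet,
    seed: int,
    initial: InitialState | None = None,
    kinetics_enabled: bool = True,
) -> tuple[TrajectoryRecord, EventLog]:
    """Advance one cargo run until full detachment or ``max_time``.

    The ``seed`` drives both the initial configuration and the kernel
    noise (a child stream each), so a (seed, params) pair fully determines
    the output.
    """
    params.validate()
    ss = np.random.SeedSequence(seed)
    init_seed, kernel_seed = ss.generate_state(2)
    if initial is None:
        initial = initialize_run(params, np.random.default_rng(init_seed))

    run = params.run
    n_steps_max = int(math.ceil(run.max_time / run.timestep))
    sample_every = run.sample_every
    samp_cap = n_steps_max // sample_every + 2
    N = params.cargo.motor_count

    ev_cap = 200_000
    if run.record_steps:
        expected = int(run.max_time * params.motor.v_max /
                       params.motor.step_size * N * 2) + 10_000
        ev_cap = max(ev_cap, expected)

    out_t = np.empty(samp_cap)
    out_X = np.empty((samp_cap, 3))
    out_nb = np.empty(samp_cap, dtype=np.int32)
    out_bound = np.empty((samp_cap, N), dtype=np.int8)
    out_headx = np.empty((samp_cap, N))
    out_anch = (np.empty((samp_cap, N, 3)) if run.record_anchors
                else np.empty((1, N, 3)))
    out_F = (np.empty((samp_cap, N, 3)) if run.record_forces
             else np.empty((1, N, 3)))
    out_orient = (np.empty((samp_cap, 3, 3)) if run.record_orientation
                  else np.empty((1, 3, 3)))
    ev_t = np.empty(ev_cap)
    ev_motor = np.empty(ev_cap, dtype=np.int32)
    ev_kind = np.empty(ev_cap, dtype=np.int8)

    X = initial.center.astype(float).copy()
    anchors = initial.anchors.astype(float).copy()
    bound = initial.bound.astype(np.bool_).copy()
    head_x = initial.head_x.astype(float).copy()
    head_y = initial.head_y.astype(float).copy()
    head_z = initial.head_z.astype(float).copy()
    orient = initial.orientation.astype(float).copy()

    # Noise is generated in bulk (numpy's SIMD paths are several times
    # faster than per-sample draws inside the jitted kernel) and handed
    # to the resumable kernel chunk by chunk.
    noise_rng = np.random.default_rng(int(kernel_seed))
    steps_per_chunk = min(n_steps_max, 400_000) + 1
    g_size = (2 * N + 3) * steps_per_chunk
    u_size = (2 * N + 2) * steps_per_chunk

    step = 0
    t = 0.0
    n_samp = 0
    n_ev = 0
    max_pdet = 0.0
    term = _kernel.TERM_MAX_TIME
    kernel_args = _kernel_args(params)
    while True:
        gbuf = noise_rng.standard_normal(g_size)
        ubuf = noise_rng.random(u_size)
        step, t, n_samp, n_ev, term, max_pdet = _kernel.run_chunk(
            step0=step,
            t0=t,
            n_steps_max=n_steps_max,
            sample_every=sample_every,
            n_samples0=n_samp,
            n_events0=n_ev,
            max_pdet0=max_pdet,
            kinetics_enabled=kinetics_enabled,
            record_steps=run.record_steps,
            rec_anchors=run.record_anchors,
            rec_forces=run.record_forces,
            rec_orient=run.record_orientation,
            gbuf=gbuf,
            ubuf=ubuf,
            X=X,
            anchors=anchors,
            bound=bound,
            head_x=head_x,
            head_y=head_y,
            head_z=head_z,
            orient=orient,
            out_t=out_t,
            out_X=out_X,
            out_orient=out_orient,
            out_nb=out_nb,
            out_bound=out_bound,
            out_headx=out_headx,
            out_anch=out_anch,
            out_F=out_F,
            ev_t=ev_t,
            ev_motor=ev_motor,
            ev_kind=ev_kind,
            **kernel_args,
        )
        if term != _kernel.TERM_RESUME:
            break
    t_end = t

    if max_pdet > 0.1:
        warnings.warn(
            f"per-attempt detachment probability reached {max_pdet:.2f}; "
            "the timestep is coarse for the forces encountered",
            RuntimeWarning,
            stacklevel=2,
        )
    if term == _kernel.TERM_NONFINITE:
        raise RuntimeError(
            f"cargo position became non-finite at t = {t_end:.6g} s"
        )

    meta = {
        "seed": seed,
        "termination": TERMINATION_NAMES[term],
        "t_end": t_end,
        "max_pdet": max_pdet,
        "params": params.to_dict(),
    }
    traj = TrajectoryRecord(
        t=out_t[:n_samp].copy(),
        X=out_X[:n_samp].copy(),
        n_bound=out_nb[:n_samp].copy(),
        bound=out_bound[:n_samp].copy().astype(bool),
        head_x=out_headx[:n_samp].copy(),
        anchors=out_anch[:n_samp].copy() if run.record_anchors else None,
        forces=out_F[:n_samp].copy() if run.record_forces else None,
        orientation=(out_orient[:n_samp].copy()
                     if run.record_orientation else None),
        meta=meta,
    )
    events = EventLog(
        t=ev_t[:n_ev].copy(),
        motor=ev_motor[:n_ev].copy(),
        kind=ev_kind[:n_ev].copy(),
        meta=meta,
    )
    return traj, events


def child_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-run child seeds derived from a master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n)


def run_ensemble(
    params: ParameterSet,
    n_runs: int,
    seed: int,
) -> list[tuple[TrajectoryRecord, EventLog]]:
    """Independent replicas with per-run seeds derived from ``seed``."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    seeds = child_seeds(seed, n_runs)
    return [run_single_cargo(params, int(s)) for s in seeds]


def fixed_height_onrate_experiment(
    params: ParameterSet,
    height: float,
    n_trials: int,
    seed: int,
    dt: float = 1.0e-5,
    t_cap: float = 200.0,
) -> dict:
    """Mean first-binding time of one diffusing motor on a held cargo.

    The cargo is clamped (no translation or rotation) with its centre a
    distance ``height`` above the microtubule axis; a single motor with
    anchor uniform on the sphere diffuses with the configured D until it
    binds.  The effective on-rate is the inverse mean first-binding time.
    Trials exceeding ``t_cap`` are censored; a warning is issued if more
    than 1% are.  Uses its own (coarser) timestep: the anchor undergoes
    pure diffusion, so the integration error is set by the ratio of the
    step length to the access-region scale, not by any spring stiffness.
    """
    D = params.motor.surface_diffusion_nm2
    if D <= 0:
        raise ValueError("fixed-height on-rate experiment requires D > 0")
    seeds = child_seeds(seed, n_trials)
    times = np.array(
        [
            _kernel.first_binding_time(
                int(s),
                height,
                params.cargo.radius,
                D,
                params.environment.MT_radius,
                params.motor.rest_length,
                params.motor.binding_rate,
                dt,
                t_cap,
            )
            for s in seeds
        ]
    )
    censored = times < 0
    frac_censored = censored.mean()
    if frac_censored > 0.01:
        warnings.warn(
            f"{frac_censored:.1%} of on-rate trials were censored at "
            f"{t_cap:g} s",
            RuntimeWarning,
            stacklevel=2,
        )
    ok = times[~censored]
    mean_time = ok.mean() if ok.size else math.inf
    rate = 0.0 if not ok.size else 1.0 / mean_time
    sem_rate = (rate * ok.std(ddof=1) / ok.mean() / math.sqrt(ok.size)
                if ok.size > 1 else math.nan)
    return {
        "on_rate": rate,
        "sem": sem_rate,
        "mean_time": mean_time,
        "frac_censored": frac_censored,
        "times": ok,
    }


def trap_experiment(
    params: ParameterSet,
    v0_grid,
    Fs_grid,
    n_runs: int,
    seed: int,
    max_time: float = 10.0,
) -> pd.DataFrame:
    """Rescaled collective force F̃ over a (v0, F_s) grid in an optical trap.

    For each cell, ``n_runs`` cargo runs are simulated in a harmonic trap
    centred at the initial cargo position, capped at ``max_time``; F̃ is
    the average over all samples and runs of the total motor-force
    x-component on the cargo, divided by N·F_s.  ``v0_grid`` is the
    unloaded velocity at the configured ATP; v_max is adjusted per cell.
    """
    from .observables import rescaled_collective_force

    atp = params.environment.ATP
    K_m = params.motor.K_m
    rows = []
    base_seed = np.random.SeedSequence(seed)
    cell_seeds = base_seed.generate_state(len(v0_grid) * len(Fs_grid))
    idx = 0
    for v0 in v0_grid:
        for Fs in Fs_grid:
            v_max = v0 * (K_m + atp) / atp
            ps = params.with_overrides(
                motor={"v_max": v_max, "stall_force": Fs,
                       "detachment_force": Fs},
                load={"kind": "optical_trap",
                      "trap_center": (0.0, 0.0,
                                      params.cargo.radius
                                      + params.environment.MT_radius)},
                run={"max_time": max_time},
            )
            runs = run_ensemble(ps, n_runs, int(cell_seeds[idx]))
            ftilde = rescaled_collective_force(
                [tr for tr, _ in runs], ps.cargo.motor_count, Fs
            )
            rows.append({"v0": v0, "F_s": Fs, "F_tilde": ftilde})
            idx += 1
    return pd.DataFrame(rows)
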
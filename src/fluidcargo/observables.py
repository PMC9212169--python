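"""Estimators and summary statistics computed from trajectories and events.

Every estimator here consumes :class:`~fluidcargo.engine.TrajectoryRecord`
/ :class:`~fluidcargo.engine.EventLog` objects, whether they come from the
physics engine or from :func:`make_synthetic_trajectory`, whose known
ground truth makes the whole layer testable independently of the
simulator.

Sign conventions: trajectories store the per-motor force on the cargo;
the load on a motor head is its negative, and a motor is under hindering
load when the head-force x-component is negative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import TrajectoryRecord, EventLog
from . import _kernel

__all__ = [
    "run_length",
    "mean_run_length",
    "mean_bound_motors",
    "mean_cargo_height",
    "ForceStatistics",
    "force_statistics",
    "off_rate_estimate",
    "conditional_on_rate",
    "spatial_distributions",
    "effective_velocity",
    "rescaled_collective_force",
    "make_synthetic_trajectory",
]


def run_length(traj: TrajectoryRecord) -> float:
    """Cargo x-displacement from the first sample to the final one (nm)."""
    return float(traj.X[-1, 0] - traj.X[0, 0])


def mean_run_length(trajs) -> tuple[float, float]:
    """(mean, SEM) of run lengths over an ensemble, in nm.

    Censored runs (terminated by the time cap) are included as lower
    bounds; the fraction censored is available per trajectory.
    """
    r = np.array([run_length(tr) for tr in trajs])
    return float(r.mean()), float(r.std(ddof=1) / math.sqrt(r.size))


def mean_bound_motors(trajs) -> dict:
    """Ensemble-averaged bound-motor count.

    Returns the per-time average over surviving runs (on the common
    sampling grid) and the pooled scalar mean over every time sample of
    every run.
    """
    pooled = np.concatenate([tr.n_bound for tr in trajs])
    n_max = max(len(tr) for tr in trajs)
    dt = None
    total = np.zeros(n_max)
    count = np.zeros(n_max, dtype=int)
    for tr in trajs:
        total[: len(tr)] += tr.n_bound
        count[: len(tr)] += 1
        if dt is None and len(tr) > 1:
            dt = tr.t[1] - tr.t[0]
    with np.errstate(invalid="ignore"):
        nbar = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    t = np.arange(n_max) * (dt if dt is not None else 0.0)
    return {
        "t": t,
        "nbar": nbar,
        "n_surviving": count,
        "pooled_mean": float(pooled.mean()),
        "pooled_sem": float(pooled.std(ddof=1) / math.sqrt(pooled.size)),
    }


def mean_cargo_height(trajs, n: int | None = None) -> float:
    """Mean distance of the cargo centre from the microtubule axis (nm).

    If ``n`` is given, restrict to samples with exactly n bound motors.
    """
    vals = []
    for tr in trajs:
        h = np.hypot(tr.X[:, 1], tr.X[:, 2])
        if n is None:
            vals.append(h)
        else:
            vals.append(h[tr.n_bound == n])
    v = np.concatenate(vals)
    if v.size == 0:
        raise ValueError(f"no samples with n = {n} bound motors")
    return float(v.mean())


@dataclass
class ForceStatistics:
    """Force statistics at a fixed number n of simultaneously bound motors."""

    n: int
    sample_size: int
    bin_edges: np.ndarray
    magnitude_density: np.ndarray
    magnitude_density_sem: np.ndarray
    hindering_density: np.ndarray
    assistive_density: np.ndarray
    frac_nonnegligible: float
    frac_nonnegligible_sem: float
    mean_variance: float
    mean_variance_sem: float
    pair_correlation: float
    pair_correlation_sem: float
    low_sample_warning: bool


def _collect_force_samples(trajs, n: int) -> np.ndarray:
    """Stack per-sample bound-motor cargo forces at samples with n bound.

    Returns an array of shape (M, n, 3).
    """
    out = []
    for tr in trajs:
        if tr.forces is None:
            raise ValueError("trajectories were recorded without forces")
        rows = np.nonzero(tr.n_bound == n)[0]
        for r in rows:
            out.append(tr.forces[r][tr.bound[r]])
    if not out:
        return np.empty((0, n, 3))
    return np.stack(out)


def force_statistics(
    trajs,
    n: int,
    stall_force: float = 7.0,
    sample_size: int = 10_000,
    bootstrap_size: int = 1_000,
    n_bootstrap: int = 10,
    bins: int = 40,
    force_range: tuple[float, float] = (0.0, 8.0),
    seed: int = 0,
) -> ForceStatistics:
    """Distribution and interference metrics of motor forces at fixed n.

    ``sample_size`` instances (each holding the n simultaneous bound-motor
    forces) are drawn with replacement from the pooled samples; the
    magnitude-distribution uncertainty is bootstrapped (resample size
    ``bootstrap_size``, ``n_bootstrap`` resamples); scalar metrics carry
    their SEM over instances.
    """
    pool = _collect_force_samples(trajs, n)
    M = pool.shape[0]
    low = M < 100
    if low:
        warnings.warn(
            f"only {M} samples with n = {n} bound motors", RuntimeWarning,
            stacklevel=2,
        )
    if M == 0:
        raise ValueError(f"no samples with n = {n} bound motors")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, M, size=sample_size)
    sample = pool[idx]  # (S, n, 3)
    mag = np.linalg.norm(sample, axis=2)  # (S, n)
    head_fx = -sample[:, :, 0]  # force on the head

    edges = np.linspace(*force_range, bins + 1)

    def density(values):
        h, _ = np.histogram(values, bins=edges, density=True)
        return h

    flat = mag.ravel()
    dens = density(flat)
    boots = np.empty((n_bootstrap, bins))
    for b in range(n_bootstrap):
        bidx = rng.integers(0, flat.size, size=bootstrap_size)
        boots[b] = density(flat[bidx])
    dens_sem = boots.std(axis=0, ddof=1) / math.sqrt(n_bootstrap)

    hind = np.abs(head_fx[head_fx < 0])
    asst = head_fx[head_fx > 0]
    hind_dens = density(hind) if hind.size else np.zeros(bins)
    asst_dens = density(asst) if asst.size else np.zeros(bins)

    nonneg = (mag >= 0.01 * stall_force).mean(axis=1)
    var_inst = mag.var(axis=1, ddof=0)

    fx = sample[:, :, 0]
    if n >= 2:
        sums = fx.sum(axis=1)
        sq = (fx**2).sum(axis=1)
        pair_inst = (sums**2 - sq) / (n * (n - 1))
    else:
        pair_inst = np.zeros(sample_size)

    sqrt_s = math.sqrt(sample_size)
    return ForceStatistics(
        n=n,
        sample_size=sample_size,
        bin_edges=edges,
        magnitude_density=dens,
        magnitude_density_sem=dens_sem,
        hindering_density=hind_dens,
        assistive_density=asst_dens,
        frac_nonnegligible=float(nonneg.mean()),
        frac_nonnegligible_sem=float(nonneg.std(ddof=1) / sqrt_s),
        mean_variance=float(var_inst.mean()),
        mean_variance_sem=float(var_inst.std(ddof=1) / sqrt_s),
        pair_correlation=float(pair_inst.mean()),
        pair_correlation_sem=float(pair_inst.std(ddof=1) / sqrt_s),
        low_sample_warning=low,
    )


def off_rate_estimate(event_logs, censoring: str = "exclude",
                      kaplan_meier: bool = False) -> dict:
    """Mean motor off-rate: inverse mean engagement duration.

    Completed engagements (bind followed by unbind of the same motor) are
    pooled over the logs.  Engagements still open when a run hits its time
    cap are handled per ``censoring``:

    * ``"exclude"`` — drop them (the plain printed estimator; unbiased
      only when runs end by full detachment, and upward-biased when a cap
      cuts off the longest engagements);
    * ``"mle"`` — the censored-exponential maximum likelihood, completed
      count divided by total observed engagement time (reduces to the
      plain estimator without censoring).

    A Kaplan–Meier restricted-mean variant is available for sensitivity.
    SEM by the delta method.
    """
    completed = []
    censored = []
    for ev in event_logs:
        comp, cens = ev.engagement_durations()
        completed.append(comp)
        censored.append(cens)
    comp = np.concatenate(completed) if completed else np.array([])
    cens = np.concatenate(censored) if censored else np.array([])
    if comp.size == 0:
        raise ValueError("no completed motor engagements in the event logs")
    if censoring not in ("exclude", "mle"):
        raise ValueError(f"unknown censoring mode {censoring!r}")
    if not kaplan_meier:
        if censoring == "mle":
            total = comp.sum() + cens.sum()
            rate = comp.size / total
            return {
                "off_rate": rate,
                "sem": rate / math.sqrt(comp.size),
                "n_engagements": int(comp.size),
                "n_censored": int(cens.size),
                "mean_duration": float(total / comp.size),
            }
        mean = comp.mean()
        sem_mean = comp.std(ddof=1) / math.sqrt(comp.size)
        rate = 1.0 / mean
        return {
            "off_rate": rate,
            "sem": sem_mean / mean**2,
            "n_engagements": int(comp.size),
            "n_censored": int(cens.size),
            "mean_duration": float(mean),
        }
    # Kaplan–Meier restricted mean including censored engagements
    times = np.concatenate([comp, cens])
    events = np.concatenate(
        [np.ones(comp.size, dtype=bool), np.zeros(cens.size, dtype=bool)]
    )
    order = np.argsort(times)
    times, events = times[order], events[order]
    at_risk = times.size - np.arange(times.size)
    surv = 1.0
    last_t = 0.0
    rmst = 0.0
    for t, e, r in zip(times, events, at_risk):
        rmst += surv * (t - last_t)
        last_t = t
        if e:
            surv *= 1.0 - 1.0 / r
    return {
        "off_rate": 1.0 / rmst,
        "sem": float("nan"),
        "n_engagements": int(comp.size),
        "n_censored": int(cens.size),
        "mean_duration": float(rmst),
    }


def _replay_bound_count(ev: EventLog) -> tuple[np.ndarray, np.ndarray]:
    """(times, n_after) of every bind/unbind transition, starting at t=0."""
    mask = ev.kind != _kernel.EV_STEP
    t = ev.t[mask]
    delta = np.where(ev.kind[mask] == _kernel.EV_BIND, 1, -1)
    return t, np.cumsum(delta)


def conditional_on_rate(event_logs, n: int, N: int) -> dict:
    """Per-unbound-motor conditional binding rate out of the n-bound state.

    All time spent with exactly n motors bound is accumulated, together
    with the number of n → n+1 transitions; the total up-rate (their
    ratio) is divided by the number of unbound motors N - n.  Returns
    ``{"rate": nan, "defined": False}`` when no time was spent at n or
    when n = N.
    """
    if n >= N:
        return {"rate": float("nan"), "defined": False,
                "n_transitions": 0, "total_time": 0.0}
    total_time = 0.0
    ups = 0
    for ev in event_logs:
        t_end = ev.meta.get("t_end", ev.t[-1] if len(ev) else 0.0)
        times, counts = _replay_bound_count(ev)
        # piecewise-constant n(t): segment i spans [times[i], times[i+1])
        seg_start = times
        seg_end = np.append(times[1:], t_end)
        seg_n = counts
        in_n = seg_n == n
        total_time += float(np.sum(seg_end[in_n] - seg_start[in_n]))
        went_up = in_n[:-1] & (seg_n[1:] == n + 1)
        ups += int(np.sum(went_up))
    if total_time <= 0.0:
        return {"rate": float("nan"), "defined": False,
                "n_transitions": ups, "total_time": total_time}
    rate = ups / total_time / (N - n)
    sem = math.sqrt(ups) / total_time / (N - n) if ups else float("nan")
    return {"rate": rate, "sem": sem, "defined": True,
            "n_transitions": ups, "total_time": total_time}


def spatial_distributions(
    trajs,
    n_theta: int = 36,
    n_phi: int = 36,
    n_time_bins: int = 10,
) -> dict:
    """Anchor-position densities.

    ``theta_density``: probability density of the motor polar angle θ
    (measured from the +z axis through the cargo centre, the microtubule
    lying below) in bins of time; each time row integrates to 1 over θ.
    ``body_map``: density of *bound* anchors over body-frame (θ, φ),
    restricted to samples with at least two bound motors, integrating
    to 1; requires recorded orientations.
    """
    th_edges = np.linspace(0.0, math.pi, n_theta + 1)
    t_max = max(tr.t[-1] for tr in trajs)
    t_edges = np.linspace(0.0, t_max + 1e-12, n_time_bins + 1)
    counts = np.zeros((n_time_bins, n_theta))

    ph_edges = np.linspace(-math.pi, math.pi, n_phi + 1)
    body_counts = np.zeros((n_theta, n_phi))

    for tr in trajs:
        if tr.anchors is None:
            raise ValueError("trajectories were recorded without anchors")
        rel = tr.anchors - tr.X[:, None, :]
        r = np.linalg.norm(rel, axis=2)
        cos_th = np.clip(rel[:, :, 2] / r, -1.0, 1.0)
        theta = np.arccos(cos_th)
        tbin = np.clip(
            np.searchsorted(t_edges, tr.t, side="right") - 1, 0,
            n_time_bins - 1,
        )
        for row in range(len(tr)):
            hist, _ = np.histogram(theta[row], bins=th_edges)
            counts[tbin[row]] += hist
        if tr.orientation is not None:
            multi = tr.n_bound >= 2
            for row in np.nonzero(multi)[0]:
                O = tr.orientation[row]
                body = rel[row][tr.bound[row]] @ O  # O^T applied row-wise
                rb = np.linalg.norm(body, axis=1)
                th_b = np.arccos(np.clip(body[:, 2] / rb, -1.0, 1.0))
                ph_b = np.arctan2(body[:, 1], body[:, 0])
                h, _, _ = np.histogram2d(th_b, ph_b, bins=[th_edges, ph_edges])
                body_counts += h

    d_th = th_edges[1] - th_edges[0]
    row_sums = counts.sum(axis=1, keepdims=True)
    theta_density = np.where(row_sums > 0, counts / row_sums / d_th, 0.0)
    d_ph = ph_edges[1] - ph_edges[0]
    total = body_counts.sum()
    body_map = body_counts / total / (d_th * d_ph) if total > 0 else body_counts
    return {
        "theta_edges": th_edges,
        "time_edges": t_edges,
        "theta_density": theta_density,
        "phi_edges": ph_edges,
        "body_map": body_map,
    }


def effective_velocity(
    trajs,
    window: float = 0.1,
    per_n: bool = False,
) -> pd.DataFrame:
    """Windowed cargo velocity v = Δx/δt over non-overlapping windows.

    With ``per_n`` the windows are restricted to stretches where the
    bound-motor count is constant and results are stratified by n.
    Returns a DataFrame with columns n (−1 = all), v_mean, v_sem, count.
    """
    by_n: dict[int, list] = {}
    for tr in trajs:
        if len(tr) < 2:
            continue
        dt = tr.t[1] - tr.t[0]
        span = max(1, int(round(window / dt)))
        starts = np.arange(0, len(tr) - span, span)
        for s in starts:
            v = (tr.X[s + span, 0] - tr.X[s, 0]) / (tr.t[s + span] - tr.t[s])
            if per_n:
                seg = tr.n_bound[s: s + span + 1]
                if not np.all(seg == seg[0]):
                    continue
                key = int(seg[0])
            else:
                key = -1
            by_n.setdefault(key, []).append(v)
    rows = []
    for key in sorted(by_n):
        v = np.asarray(by_n[key])
        rows.append(
            {
                "n": key,
                "v_mean": v.mean(),
                "v_sem": v.std(ddof=1) / math.sqrt(v.size) if v.size > 1
                else float("nan"),
                "count": v.size,
            }
        )
    return pd.DataFrame(rows)


def rescaled_collective_force(trajs, N: int, stall_force: float) -> float:
    """F̃ = ⟨Σ_i F_xi⟩ / (N F_s) over all samples and runs.

    F_xi are the x-components of the bound-motor forces on the cargo;
    samples with no bound motor contribute zero.
    """
    total = 0.0
    count = 0
    for tr in trajs:
        if tr.forces is None:
            raise ValueError("trajectories were recorded without forces")
        fx = np.where(tr.bound, tr.forces[:, :, 0], 0.0).sum(axis=1)
        total += fx.sum()
        count += fx.size
    if count == 0:
        return 0.0
    return float(total / count / (N * stall_force))


def make_synthetic_trajectory(
    N: int = 2,
    bind_rate: float = 1.0,
    unbind_rate: float = 0.5,
    speed: float = 500.0,
    noise_sigma: float = 0.0,
    max_time: float = 100.0,
    sampling_rate: float = 100.0,
    n_always_bound: int = 0,
    radius: float = 250.0,
    seed: int = 0,
    stop_on_detach: bool = True,
) -> tuple[TrajectoryRecord, EventLog]:
    """Markovian bind/unbind trajectory with known ground truth.

    Each unbound motor binds at ``bind_rate`` and each bound motor
    unbinds at ``unbind_rate`` (exponential waiting times, Gillespie
    draws); the first ``n_always_bound`` motors never unbind.  The cargo
    moves at ``speed`` along +x whenever at least one motor is bound,
    with optional Gaussian position noise per sample.  One motor starts
    bound.  The output mimics the simulator's containers so every
    estimator can be validated against the generator's parameters.
    """
    rng = np.random.default_rng(seed)
    bound = np.zeros(N, dtype=bool)
    bound[0] = True
    ev_t, ev_m, ev_k = [0.0], [0], [_kernel.EV_BIND]
    for i in range(1, n_always_bound):
        bound[i] = True
        ev_t.append(0.0)
        ev_m.append(i)
        ev_k.append(_kernel.EV_BIND)
    t = 0.0
    seg_t = [0.0]
    seg_n = [int(bound.sum())]
    while t < max_time:
        rates = np.where(
            bound,
            np.where(np.arange(N) < n_always_bound, 0.0, unbind_rate),
            bind_rate,
        )
        total = rates.sum()
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t >= max_time:
            break
        i = int(rng.choice(N, p=rates / total))
        if bound[i]:
            bound[i] = False
            ev_k.append(_kernel.EV_UNBIND)
        else:
            bound[i] = True
            ev_k.append(_kernel.EV_BIND)
        ev_t.append(t)
        ev_m.append(i)
        seg_t.append(t)
        seg_n.append(int(bound.sum()))
        if stop_on_detach and bound.sum() == 0:
            break
    t_end = min(t, max_time)
    if stop_on_detach and seg_n[-1] == 0:
        term = "detached"
    else:
        term = "max_time"
        t_end = max_time

    # sample on the regular grid
    ts = np.arange(0.0, t_end + 0.5 / sampling_rate, 1.0 / sampling_rate)
    seg_t_arr = np.asarray(seg_t)
    seg_n_arr = np.asarray(seg_n)
    idx = np.clip(np.searchsorted(seg_t_arr, ts, side="right") - 1, 0, None)
    n_at = seg_n_arr[idx]
    # x advances at `speed` while n >= 1
    moving = np.zeros_like(ts)
    # integrate piecewise: durations with n>=1 up to each sample
    change_t = np.append(seg_t_arr, t_end)
    seg_dur = np.diff(change_t)
    seg_moving = (seg_n_arr >= 1).astype(float)
    cum = np.concatenate([[0.0], np.cumsum(seg_dur * seg_moving)])
    moving = np.interp(ts, change_t, cum)
    x = speed * moving
    X = np.column_stack([x, np.zeros_like(x), np.zeros_like(x)])
    if noise_sigma > 0:
        X += noise_sigma * rng.standard_normal(X.shape)

    bound_arr = np.zeros((ts.size, N), dtype=bool)
    ev_t_arr = np.asarray(ev_t)
    ev_m_arr = np.asarray(ev_m, dtype=np.int32)
    ev_k_arr = np.asarray(ev_k, dtype=np.int8)
    state = np.zeros(N, dtype=bool)
    ptr = 0
    for row, tt in enumerate(ts):
        while ptr < ev_t_arr.size and ev_t_arr[ptr] <= tt:
            state[ev_m_arr[ptr]] = ev_k_arr[ptr] == _kernel.EV_BIND
            ptr += 1
        bound_arr[row] = state
    nb = bound_arr.sum(axis=1).astype(np.int32)

    # decorative geometry: anchors evenly spaced on the equator
    phi = 2.0 * np.pi * np.arange(N) / N
    base = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(N)]) * radius
    anchors = X[:, None, :] + base[None, :, :]
    meta = {"seed": seed, "termination": term, "t_end": float(t_end),
            "synthetic": True,
            "params": {"bind_rate": bind_rate, "unbind_rate": unbind_rate,
                       "speed": speed, "N": N}}
    traj = TrajectoryRecord(
        t=ts,
        X=X,
        n_bound=nb,
        bound=bound_arr,
        head_x=np.where(bound_arr, X[:, :1], np.nan),
        anchors=anchors,
        forces=np.zeros((ts.size, N, 3)),
        orientation=np.broadcast_to(np.eye(3), (ts.size, 3, 3)).copy(),
        meta=meta,
    )
    events = EventLog(t=ev_t_arr, motor=ev_m_arr, kind=ev_k_arr, meta=meta)
    return traj, events
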
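"""Compiled Brownian-dynamics core.

A numba-jitted routine advances one cargo run timestep by timestep.  The
per-step update order is: (1) motor binding/stepping/detachment using the
forces at the start of the step, (2) force recomputation, (3) anchor
surface diffusion, (4) cargo translation, (5) cargo rotation applied to
the anchors and the body frame.

The kernel is *resumable*: it consumes pre-generated noise arrays
(standard normals and uniforms, produced in bulk by numpy's generator,
which is several times faster than drawing samples one by one inside the
jitted code) and returns with a RESUME code when the buffers run low;
the Python driver refills them and calls again.  All quantities are in
internal units (nm, pN, s).  The scalar math mirrors the reference
implementations in :mod:`fluidcargo.sphere`, :mod:`fluidcargo.motor`
and :mod:`fluidcargo.cargo`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Event kinds
EV_BIND = 0
EV_UNBIND = 1
EV_STEP = 2

# Termination codes
TERM_DETACHED = 0
TERM_MAX_TIME = 1
TERM_EVENT_OVERFLOW = 2
TERM_NONFINITE = 3
TERM_RESUME = 4

# Load kinds
LOAD_NONE = 0
LOAD_CONSTANT = 1
LOAD_TRAP = 2


@njit(cache=True, fastmath=True, inline="always")
def _motor_force_inline(ax, ay, az, hx, hy, hz, L_mot, k_mot):
    """Return (Fx, Fy, Fz, magnitude) of the force on the cargo."""
    dx = ax - hx
    dy = ay - hy
    dz = az - hz
    L = math.sqrt(dx * dx + dy * dy + dz * dz)
    if L <= L_mot or L == 0.0:
        return 0.0, 0.0, 0.0, 0.0
    mag = k_mot * (L - L_mot)
    s = -mag / L
    return s * dx, s * dy, s * dz, mag


@njit(cache=True, fastmath=True)
def run_chunk(
    dt,
    step0,
    t0,
    n_steps_max,
    sample_every,
    n_samples0,
    n_events0,
    max_pdet0,
    # motor parameters
    L_mot,
    k_mot,
    pi0,
    eps0,
    F_s,
    F_d,
    w_exp,
    delta,
    asst_slope,
    D_nm2,
    # cargo / environment
    R,
    k_steric,
    rotation_enabled,
    alpha,
    kT,
    gamma_c,
    gamma_R,
    D_rot,
    r_MT,
    v0_atp,
    v0_sat,
    # load protocol
    load_kind,
    f_h,
    k_trap,
    trap_cx,
    trap_cy,
    trap_cz,
    trap_x_only,
    # mode switches
    kinetics_enabled,
    record_steps,
    rec_anchors,
    rec_forces,
    rec_orient,
    # noise buffers (consumed left to right)
    gbuf,
    ubuf,
    # state (modified in place)
    X,
    anchors,
    bound,
    head_x,
    head_y,
    head_z,
    orient,
    # outputs
    out_t,
    out_X,
    out_orient,
    out_nb,
    out_bound,
    out_headx,
    out_anch,
    out_F,
    ev_t,
    ev_motor,
    ev_kind,
):
    N = anchors.shape[0]
    ev_cap = ev_t.shape[0]
    samp_cap = out_t.shape[0]
    g_cap = gbuf.shape[0]
    u_cap = ubuf.shape[0]
    g_need = 2 * N + 3
    u_need = 2 * N + 2
    gpos = 0
    upos = 0

    p_bind = -math.expm1(-pi0 * dt)
    p_step0 = -math.expm1(-v0_atp * dt / delta)
    p_step0_sat = -math.expm1(-v0_sat * dt / delta)
    sig_trans = math.sqrt(2.0 * kT * dt / gamma_c)
    sig_surf = math.sqrt(2.0 * D_nm2 * dt)
    mob_surf = D_nm2 / kT * dt if D_nm2 > 0.0 else 0.0
    rot_noise = alpha * math.sqrt(4.0 * D_rot * dt)
    v_ratio = v0_atp / v0_sat if v0_sat > 0.0 else 0.0
    contact = R + r_MT
    reach2 = (r_MT + L_mot) * (r_MT + L_mot)
    pole_tol2 = (1.0e-6 * R) ** 2

    F = np.zeros((N, 3))
    Fmag = np.zeros(N)

    n_samples = n_samples0
    n_events = n_events0
    max_pdet = max_pdet0
    t = t0
    term = TERM_MAX_TIME

    # forces and bound count for the current configuration
    n_bound = 0
    for i in range(N):
        if bound[i]:
            fx, fy, fz, fm = _motor_force_inline(
                anchors[i, 0], anchors[i, 1], anchors[i, 2],
                head_x[i], head_y[i], head_z[i], L_mot, k_mot,
            )
            F[i, 0] = fx
            F[i, 1] = fy
            F[i, 2] = fz
            Fmag[i] = fm
            n_bound += 1

    if step0 == 0:
        # initial bind events and initial sample
        for i in range(N):
            if bound[i]:
                ev_t[n_events] = 0.0
                ev_motor[n_events] = i
                ev_kind[n_events] = EV_BIND
                n_events += 1
        out_t[0] = 0.0
        out_X[0, 0] = X[0]
        out_X[0, 1] = X[1]
        out_X[0, 2] = X[2]
        out_nb[0] = n_bound
        for i in range(N):
            out_bound[0, i] = 1 if bound[i] else 0
            out_headx[0, i] = head_x[i]
        if rec_anchors:
            for i in range(N):
                for c in range(3):
                    out_anch[0, i, c] = anchors[i, c]
        if rec_forces:
            for i in range(N):
                for c in range(3):
                    out_F[0, i, c] = F[i, c]
        if rec_orient:
            for a2 in range(3):
                for b2 in range(3):
                    out_orient[0, a2, b2] = orient[a2, b2]
        n_samples = 1

    step = step0
    while step < n_steps_max:
        if gpos > g_cap - g_need or upos > u_cap - u_need:
            term = TERM_RESUME
            break

        # ---- (1) motor kinetics using forces at start of step -------------
        if kinetics_enabled:
            for i in range(N):
                if not bound[i]:
                    rho2 = (anchors[i, 1] * anchors[i, 1]
                            + anchors[i, 2] * anchors[i, 2])
                    if rho2 <= reach2:
                        u = ubuf[upos]
                        upos += 1
                        if u < p_bind:
                            rho = math.sqrt(rho2)
                            bound[i] = True
                            head_x[i] = anchors[i, 0]
                            if rho < 1.0e-9:
                                head_y[i] = 0.0
                                head_z[i] = r_MT
                            else:
                                head_y[i] = r_MT * anchors[i, 1] / rho
                                head_z[i] = r_MT * anchors[i, 2] / rho
                            n_bound += 1
                            fx, fy, fz, fm = _motor_force_inline(
                                anchors[i, 0], anchors[i, 1], anchors[i, 2],
                                head_x[i], head_y[i], head_z[i], L_mot, k_mot,
                            )
                            F[i, 0] = fx
                            F[i, 1] = fy
                            F[i, 2] = fz
                            Fmag[i] = fm
                            if n_events < ev_cap:
                                ev_t[n_events] = t
                                ev_motor[n_events] = i
                                ev_kind[n_events] = EV_BIND
                                n_events += 1
                            else:
                                term = TERM_EVENT_OVERFLOW
                else:
                    fm = Fmag[i]
                    if fm == 0.0:
                        p = p_step0
                        p2 = p_step0_sat
                        eps_obs = eps0
                    else:
                        # hindering iff head-force x-component <= 0,
                        # i.e. cargo-force x-component >= 0
                        hindering = F[i, 0] >= 0.0
                        if hindering:
                            if fm >= F_s:
                                factor = 0.0
                            else:
                                factor = 1.0 - (fm / F_s) ** w_exp
                            eps_obs = eps0 * math.exp(fm / F_d)
                        else:
                            factor = 1.0
                            eps_obs = eps0 + asst_slope * fm
                        if factor == 1.0:
                            p = p_step0
                            p2 = p_step0_sat
                        elif factor == 0.0:
                            p = 0.0
                            p2 = 0.0
                        else:
                            p = -math.expm1(-v0_atp * factor * dt / delta)
                            p2 = -math.expm1(-v0_sat * factor * dt / delta)
                    if p2 > 0.0:
                        u = ubuf[upos]
                        upos += 1
                        if u < p:
                            pdet = eps_obs / p2 * dt
                            if pdet > max_pdet:
                                max_pdet = pdet
                            if pdet > 1.0:
                                pdet = 1.0
                            u2 = ubuf[upos]
                            upos += 1
                            if u2 < pdet:
                                bound[i] = False
                                n_bound -= 1
                                F[i, 0] = 0.0
                                F[i, 1] = 0.0
                                F[i, 2] = 0.0
                                Fmag[i] = 0.0
                                if n_events < ev_cap:
                                    ev_t[n_events] = t
                                    ev_motor[n_events] = i
                                    ev_kind[n_events] = EV_UNBIND
                                    n_events += 1
                                else:
                                    term = TERM_EVENT_OVERFLOW
                            else:
                                head_x[i] += delta
                                fx, fy, fz, fm2 = _motor_force_inline(
                                    anchors[i, 0], anchors[i, 1], anchors[i, 2],
                                    head_x[i], head_y[i], head_z[i],
                                    L_mot, k_mot,
                                )
                                F[i, 0] = fx
                                F[i, 1] = fy
                                F[i, 2] = fz
                                Fmag[i] = fm2
                                if record_steps:
                                    if n_events < ev_cap:
                                        ev_t[n_events] = t
                                        ev_motor[n_events] = i
                                        ev_kind[n_events] = EV_STEP
                                        n_events += 1
                                    else:
                                        term = TERM_EVENT_OVERFLOW
                    else:
                        # stalled: the per-attempt construction degenerates;
                        # the force factors cancel, leaving a Poisson rate
                        rate = eps_obs * v_ratio
                        u = ubuf[upos]
                        upos += 1
                        if u < -math.expm1(-rate * dt):
                            bound[i] = False
                            n_bound -= 1
                            F[i, 0] = 0.0
                            F[i, 1] = 0.0
                            F[i, 2] = 0.0
                            Fmag[i] = 0.0
                            if n_events < ev_cap:
                                ev_t[n_events] = t
                                ev_motor[n_events] = i
                                ev_kind[n_events] = EV_UNBIND
                                n_events += 1
                            else:
                                term = TERM_EVENT_OVERFLOW

            if n_bound == 0:
                term = TERM_DETACHED
                t += dt
                step += 1
                break

        # ---- (3) anchor surface diffusion ---------------------------------
        if D_nm2 > 0.0:
            for i in range(N):
                ux = anchors[i, 0] - X[0]
                uy = anchors[i, 1] - X[1]
                uz = anchors[i, 2] - X[2]
                s2 = ux * ux + uy * uy
                if s2 < pole_tol2:
                    # pole: fixed tangent pair (x̂, ŷ)
                    t1x, t1y, t1z = 1.0, 0.0, 0.0
                    t2x, t2y, t2z = 0.0, 1.0, 0.0
                else:
                    q = 1.0 / math.sqrt(s2)
                    qr = q / R
                    t1x = uz * ux * qr
                    t1y = uz * uy * qr
                    t1z = -s2 * qr
                    t2x = -uy * q
                    t2y = ux * q
                    t2z = 0.0
                dl1 = sig_surf * gbuf[gpos]
                dl2 = sig_surf * gbuf[gpos + 1]
                gpos += 2
                if bound[i] and Fmag[i] > 0.0:
                    ft = F[i, 0] * t1x + F[i, 1] * t1y + F[i, 2] * t1z
                    fp = F[i, 0] * t2x + F[i, 1] * t2y + F[i, 2] * t2z
                    dl1 += mob_surf * ft
                    dl2 += mob_surf * fp
                ux += dl1 * t1x + dl2 * t2x
                uy += dl1 * t1y + dl2 * t2y
                uz += dl1 * t1z + dl2 * t2z
                inv = R / math.sqrt(ux * ux + uy * uy + uz * uz)
                anchors[i, 0] = X[0] + ux * inv
                anchors[i, 1] = X[1] + uy * inv
                anchors[i, 2] = X[2] + uz * inv

        # ---- (4) cargo translation ----------------------------------------
        ftx = 0.0
        fty = 0.0
        ftz = 0.0
        for i in range(N):
            if bound[i]:
                ftx += F[i, 0]
                fty += F[i, 1]
                ftz += F[i, 2]
        # steric repulsion from the microtubule (y–z plane, radial)
        rho2_c = X[1] * X[1] + X[2] * X[2]
        if rho2_c < contact * contact and rho2_c > 1.0e-24:
            rho_c = math.sqrt(rho2_c)
            fs = k_steric * (contact - rho_c) / rho_c
            fty += fs * X[1]
            ftz += fs * X[2]
        # external load
        if load_kind == LOAD_CONSTANT:
            ftx -= f_h
        elif load_kind == LOAD_TRAP:
            ftx -= k_trap * (X[0] - trap_cx)
            if not trap_x_only:
                fty -= k_trap * (X[1] - trap_cy)
                ftz -= k_trap * (X[2] - trap_cz)
        dx = dt / gamma_c * ftx + sig_trans * gbuf[gpos]
        dy = dt / gamma_c * fty + sig_trans * gbuf[gpos + 1]
        dz = dt / gamma_c * ftz + sig_trans * gbuf[gpos + 2]
        gpos += 3
        X[0] += dx
        X[1] += dy
        X[2] += dz
        for i in range(N):
            anchors[i, 0] += dx
            anchors[i, 1] += dy
            anchors[i, 2] += dz

        # ---- (5) cargo rotation -------------------------------------------
        if rotation_enabled:
            tx = 0.0
            ty = 0.0
            tz = 0.0
            for i in range(N):
                if bound[i]:
                    rx = anchors[i, 0] - X[0]
                    ry = anchors[i, 1] - X[1]
                    rz = anchors[i, 2] - X[2]
                    tx += ry * F[i, 2] - rz * F[i, 1]
                    ty += rz * F[i, 0] - rx * F[i, 2]
                    tz += rx * F[i, 1] - ry * F[i, 0]
            a = ubuf[upos]
            b = ubuf[upos + 1]
            upos += 2
            ct = 2.0 * a - 1.0
            st = math.sqrt(max(0.0, 1.0 - ct * ct))
            phi = 2.0 * math.pi * b
            nx = st * math.cos(phi)
            ny = st * math.sin(phi)
            nz = ct
            scale = dt / gamma_R
            wx = scale * tx + rot_noise * nx
            wy = scale * ty + rot_noise * ny
            wz = scale * tz + rot_noise * nz
            ang = math.sqrt(wx * wx + wy * wy + wz * wz)
            if ang > 0.0:
                ux = wx / ang
                uy = wy / ang
                uz = wz / ang
                c = math.cos(ang)
                s = math.sin(ang)
                omc = 1.0 - c
                r00 = c + ux * ux * omc
                r01 = ux * uy * omc - uz * s
                r02 = ux * uz * omc + uy * s
                r10 = uy * ux * omc + uz * s
                r11 = c + uy * uy * omc
                r12 = uy * uz * omc - ux * s
                r20 = uz * ux * omc - uy * s
                r21 = uz * uy * omc + ux * s
                r22 = c + uz * uz * omc
                for i in range(N):
                    rx = anchors[i, 0] - X[0]
                    ry = anchors[i, 1] - X[1]
                    rz = anchors[i, 2] - X[2]
                    anchors[i, 0] = X[0] + r00 * rx + r01 * ry + r02 * rz
                    anchors[i, 1] = X[1] + r10 * rx + r11 * ry + r12 * rz
                    anchors[i, 2] = X[2] + r20 * rx + r21 * ry + r22 * rz
                # orient <- Rot @ orient
                for col in range(3):
                    o0 = orient[0, col]
                    o1 = orient[1, col]
                    o2 = orient[2, col]
                    orient[0, col] = r00 * o0 + r01 * o1 + r02 * o2
                    orient[1, col] = r10 * o0 + r11 * o1 + r12 * o2
                    orient[2, col] = r20 * o0 + r21 * o1 + r22 * o2

        t += dt
        step += 1

        # ---- recompute forces for the new configuration -------------------
        for i in range(N):
            if bound[i]:
                fx, fy, fz, fm = _motor_force_inline(
                    anchors[i, 0], anchors[i, 1], anchors[i, 2],
                    head_x[i], head_y[i], head_z[i], L_mot, k_mot,
                )
                F[i, 0] = fx
                F[i, 1] = fy
                F[i, 2] = fz
                Fmag[i] = fm

        # ---- sampling ------------------------------------------------------
        if step % sample_every == 0 and n_samples < samp_cap:
            out_t[n_samples] = t
            out_X[n_samples, 0] = X[0]
            out_X[n_samples, 1] = X[1]
            out_X[n_samples, 2] = X[2]
            out_nb[n_samples] = n_bound
            for i in range(N):
                out_bound[n_samples, i] = 1 if bound[i] else 0
                out_headx[n_samples, i] = head_x[i]
            if rec_anchors:
                for i in range(N):
                    for c in range(3):
                        out_anch[n_samples, i, c] = anchors[i, c]
            if rec_forces:
                for i in range(N):
                    for c in range(3):
                        out_F[n_samples, i, c] = F[i, c]
            if rec_orient:
                for a2 in range(3):
                    for b2 in range(3):
                        out_orient[n_samples, a2, b2] = orient[a2, b2]
            n_samples += 1

        if not (math.isfinite(X[0]) and math.isfinite(X[1])
                and math.isfinite(X[2])):
            term = TERM_NONFINITE
            break
        if term == TERM_EVENT_OVERFLOW:
            break

    if term != TERM_RESUME:
        # final sample at termination (if not already on the grid)
        if n_samples < samp_cap and (n_samples == 0
                                     or out_t[n_samples - 1] < t):
            out_t[n_samples] = t
            out_X[n_samples, 0] = X[0]
            out_X[n_samples, 1] = X[1]
            out_X[n_samples, 2] = X[2]
            out_nb[n_samples] = n_bound
            for i in range(N):
                out_bound[n_samples, i] = 1 if bound[i] else 0
                out_headx[n_samples, i] = head_x[i]
            if rec_anchors:
                for i in range(N):
                    for c in range(3):
                        out_anch[n_samples, i, c] = anchors[i, c]
            if rec_forces:
                for i in range(N):
                    for c in range(3):
                        out_F[n_samples, i, c] = F[i, c]
            if rec_orient:
                for a2 in range(3):
                    for b2 in range(3):
                        out_orient[n_samples, a2, b2] = orient[a2, b2]
            n_samples += 1

    return step, t, n_samples, n_events, term, max_pdet


@njit(cache=True, fastmath=True)
def first_binding_time(
    seed,
    H,
    R,
    D_nm2,
    r_MT,
    L_mot,
    pi0,
    dt,
    t_cap,
):
    """First binding time of a single diffusing motor on a held cargo.

    The cargo centre is fixed at (0, 0, H); the anchor starts uniformly
    distributed on the sphere, diffuses freely (no force bias) and binds
    with rate π0 whenever the microtubule surface is within the rest
    length.  Returns -1.0 if no binding occurred within ``t_cap``.
    """
    np.random.seed(seed)
    a = np.random.random()
    b = np.random.random()
    ct = 2.0 * a - 1.0
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    phi = 2.0 * math.pi * b
    ax = R * st * math.cos(phi)
    ay = R * st * math.sin(phi)
    az = H + R * ct

    p_bind = -math.expm1(-pi0 * dt)
    sig = math.sqrt(2.0 * D_nm2 * dt)
    n_steps = int(t_cap / dt)
    reach2 = (r_MT + L_mot) * (r_MT + L_mot)
    pole_tol2 = (1.0e-6 * R) ** 2
    nbuf = 16384
    gbuf = np.random.standard_normal(nbuf)
    gpos = 0
    ubuf = np.random.random(nbuf)
    upos = 0
    for step in range(n_steps):
        if gpos > nbuf - 2:
            gbuf = np.random.standard_normal(nbuf)
            gpos = 0
        if ay * ay + az * az <= reach2:
            if upos >= nbuf:
                ubuf = np.random.random(nbuf)
                upos = 0
            u = ubuf[upos]
            upos += 1
            if u < p_bind:
                return step * dt
        # tangent-plane diffusion step
        ux = ax
        uy = ay
        uz = az - H
        s2 = ux * ux + uy * uy
        if s2 < pole_tol2:
            t1x, t1y, t1z = 1.0, 0.0, 0.0
            t2x, t2y, t2z = 0.0, 1.0, 0.0
        else:
            q = 1.0 / math.sqrt(s2)
            qr = q / R
            t1x = uz * ux * qr
            t1y = uz * uy * qr
            t1z = -s2 * qr
            t2x = -uy * q
            t2y = ux * q
            t2z = 0.0
        dl1 = sig * gbuf[gpos]
        dl2 = sig * gbuf[gpos + 1]
        gpos += 2
        ux += dl1 * t1x + dl2 * t2x
        uy += dl1 * t1y + dl2 * t2y
        uz += dl1 * t1z + dl2 * t2z
        inv = R / math.sqrt(ux * ux + uy * uy + uz * uz)
        ax = ux * inv
        ay = uy * inv
        az = H + uz * inv
    return -1.0
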
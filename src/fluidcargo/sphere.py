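"""Geometry of points on the cargo sphere.

Rotations (Rodrigues form), spherical tangent frames, biased tangent-plane
surface diffusion with radial re-projection, and angular distances.  These
are the reference (numpy) implementations; the simulation kernel inlines
numerically identical scalar versions.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = [
    "random_unit_vector",
    "rodrigues_matrix",
    "rotate_anchors",
    "tangent_frame",
    "surface_diffusion_step",
    "angular_distance",
]

#: |sin θ| below which the spherical tangent frame is replaced by a fixed
#: orthonormal pair (pole singularity; measure-zero configuration).
POLE_TOL = 1.0e-6


def random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    """Uniform random direction on the unit sphere.

    Draws a, b uniform on [0, 1], sets θ_t = arccos(2a-1), φ_t = 2πb and
    returns (sinθ cosφ, sinθ sinφ, cosθ).
    """
    a = rng.random()
    b = rng.random()
    theta = math.acos(2.0 * a - 1.0)
    phi = 2.0 * math.pi * b
    st = math.sin(theta)
    return np.array([st * math.cos(phi), st * math.sin(phi), math.cos(theta)])


def _skew(axis: np.ndarray) -> np.ndarray:
    wx, wy, wz = axis
    return np.array([[0.0, -wz, wy], [wz, 0.0, -wx], [-wy, wx, 0.0]])


def rodrigues_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix R = I + ω̃ sinΔθ + ω̃² (1 - cosΔθ) about unit axis ω̂."""
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1.0e-8:
        raise ValueError("rotation axis must be a unit vector")
    w = _skew(axis)
    return np.eye(3) + w * math.sin(angle) + (w @ w) * (1.0 - math.cos(angle))


def rotate_anchors(
    anchors: np.ndarray,
    center: np.ndarray,
    rotation: np.ndarray,
    radius: float | None = None,
    tol: float = 1.0e-6,
) -> np.ndarray:
    """Rotate anchor points about the cargo centre: A ← X + R (A - X).

    If ``radius`` is given, each anchor is checked to lie on the sphere of
    that radius about ``center`` to relative tolerance ``tol``.
    """
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    center = np.asarray(center, dtype=float)
    rel = anchors - center
    if radius is not None:
        r = np.linalg.norm(rel, axis=1)
        if np.any(np.abs(r - radius) > tol * radius):
            raise ValueError("anchor off the cargo sphere beyond tolerance")
    return center + rel @ np.asarray(rotation, dtype=float).T


def tangent_frame(anchor: np.ndarray, center: np.ndarray):
    """Orthonormal spherical tangent basis (θ̂, φ̂) at an anchor point.

    θ̂ = (cosθ cosφ, cosθ sinφ, -sinθ) and φ̂ = (-sinφ, cosφ, 0) with (θ, φ)
    the polar/azimuthal angles of A - X.  Near the poles (|sinθ| < 1e-6) an
    arbitrary fixed tangent pair (x̂, ŷ) is returned.
    """
    rel = np.asarray(anchor, dtype=float) - np.asarray(center, dtype=float)
    r = np.linalg.norm(rel)
    u = rel / r
    s = math.hypot(u[0], u[1])  # sin θ
    if s < POLE_TOL:
        return np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    ct = u[2]
    cp, sp = u[0] / s, u[1] / s
    theta_hat = np.array([ct * cp, ct * sp, -s])
    phi_hat = np.array([-sp, cp, 0.0])
    return theta_hat, phi_hat


def tangential_force_components(
    force: np.ndarray, anchor: np.ndarray, center: np.ndarray
) -> tuple[float, float]:
    """(F_θ, F_φ): projection of a Cartesian force onto the tangent frame."""
    th, ph = tangent_frame(anchor, center)
    f = np.asarray(force, dtype=float)
    return float(f @ th), float(f @ ph)


def surface_diffusion_step(
    anchor: np.ndarray,
    center: np.ndarray,
    tangential_force: tuple[float, float],
    D_nm2: float,
    kT: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One biased diffusion step of an anchor in the local tangent plane.

    Δl = sqrt(2 D Δt) ξ + (Δt/γ_s) F_tangential with γ_s = kT/D, applied
    along (θ̂, φ̂) and followed by radial re-projection onto the sphere.
    D = 0 leaves the anchor unchanged in the body frame.

    Parameters use nm²/s for ``D_nm2`` and pN·nm for ``kT``.
    """
    if D_nm2 < 0:
        raise ValueError("surface diffusivity must be >= 0")
    anchor = np.asarray(anchor, dtype=float)
    center = np.asarray(center, dtype=float)
    if D_nm2 == 0.0:
        return anchor.copy()
    radius = float(np.linalg.norm(anchor - center))
    th, ph = tangent_frame(anchor, center)
    sig = math.sqrt(2.0 * D_nm2 * dt)
    mob = D_nm2 / kT * dt  # Δt/γ_s
    dth = sig * rng.standard_normal() + mob * tangential_force[0]
    dph = sig * rng.standard_normal() + mob * tangential_force[1]
    new = anchor + dth * th + dph * ph
    rel = new - center
    return center + rel * (radius / np.linalg.norm(rel))


def angular_distance(a1: np.ndarray, a2: np.ndarray, center: np.ndarray) -> float:
    """Great-circle angle ΔΘ ∈ [0, π] between two on-sphere points."""
    r1 = np.asarray(a1, dtype=float) - center
    r2 = np.asarray(a2, dtype=float) - center
    c = float(r1 @ r2 / (np.linalg.norm(r1) * np.linalg.norm(r2)))
    return math.acos(min(1.0, max(-1.0, c)))
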
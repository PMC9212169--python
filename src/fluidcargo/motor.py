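"""Single-motor mechanics and kinetics.

Spring force of the motor tether, ATP- and load-dependent stepping, and
force-dependent detachment, following the standard kinesin-1
parameterisation: Hookean tether beyond the rest length, Michaelis–Menten
ATP dependence, a concave force–velocity relation up to stall in the
hindering direction, an exponential (Kramers/Bell) hindering off-rate and
a linear assistive off-rate.

Sign convention (as in the model schematic): the classification of a load
as hindering or assistive uses the x-component of the force on the motor
*head*; a negative head-force x-component opposes stepping (hindering).
The force stored per motor everywhere in this package is the force on the
*cargo*, which is minus the force on the head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .parameters import MotorParameters

__all__ = [
    "HINDERING",
    "ASSISTIVE",
    "ZERO",
    "MotorForce",
    "motor_force",
    "unloaded_velocity",
    "force_velocity_factor",
    "step_probability",
    "observed_off_rate",
    "microscopic_off_rate",
    "detachment_event",
    "binding_event",
]

HINDERING = "hindering"
ASSISTIVE = "assistive"
ZERO = "zero"


@dataclass(frozen=True)
class MotorForce:
    """Force exerted by one bound motor.

    ``on_cargo`` points from the anchor toward the head (restoring);
    ``on_head`` is its negative.  ``direction_class`` is derived from the
    sign of the head-force x-component; the exactly-zero case is classed
    as hindering when the magnitude is non-zero (conservative choice for
    the stepping and detachment laws) and as ``zero`` otherwise.
    """

    on_cargo: np.ndarray
    magnitude: float
    direction_class: str

    @property
    def on_head(self) -> np.ndarray:
        return -self.on_cargo


def motor_force(anchor, head, motor: MotorParameters) -> MotorForce:
    """Tether force for a bound motor with anchor A and 3-D head position H.

    Zero below the rest length; Hookean of magnitude k_mot (L - L_mot)
    beyond it, where L = |A - H|.
    """
    anchor = np.asarray(anchor, dtype=float)
    head = np.asarray(head, dtype=float)
    rel = anchor - head
    L = float(np.linalg.norm(rel))
    if L == 0.0:
        raise ValueError("anchor and head coincide: force direction undefined")
    if L <= motor.rest_length:
        return MotorForce(np.zeros(3), 0.0, ZERO)
    mag = motor.stiffness * (L - motor.rest_length)
    on_cargo = -mag * rel / L  # from A toward H
    head_fx = -on_cargo[0]
    direction = ASSISTIVE if head_fx > 0 else HINDERING
    return MotorForce(on_cargo, mag, direction)


def unloaded_velocity(atp: float, motor: MotorParameters) -> float:
    """Michaelis–Menten no-load speed v0([ATP]) = v_max [ATP]/(K_m + [ATP])."""
    if atp < 0:
        raise ValueError("ATP concentration must be >= 0")
    return motor.v_max * atp / (motor.K_m + atp)


def force_velocity_factor(F: float, direction: str, motor: MotorParameters) -> float:
    """Dimensionless velocity factor ṽ(F).

    Hindering: 1 - (F/F_s)^w below stall, 0 at and beyond stall.
    Assistive (or zero load): 1.
    """
    if F < 0:
        raise ValueError("force magnitude must be >= 0")
    if direction == HINDERING:
        if F >= motor.stall_force:
            return 0.0
        return 1.0 - (F / motor.stall_force) ** motor.fv_exponent
    return 1.0


def step_probability(v: float, dt: float, motor: MotorParameters) -> float:
    """Per-timestep probability 1 - exp(-v Δt/δ) of attempting a forward step."""
    if v < 0:
        raise ValueError("velocity must be >= 0")
    return -math.expm1(-v * dt / motor.step_size)


def observed_off_rate(F: float, direction: str, motor: MotorParameters) -> float:
    """Observed (saturating-ATP) detachment rate ε_obs(F) in s⁻¹.

    Hindering: ε0 exp(F/F_d).  Assistive: ε0 + 1.56 s⁻¹/pN × F.
    Zero load returns ε0.
    """
    if F < 0:
        raise ValueError("force magnitude must be >= 0")
    if direction == HINDERING:
        return motor.unloaded_off_rate * math.exp(F / motor.detachment_force)
    if direction == ASSISTIVE:
        return motor.unloaded_off_rate + motor.assistive_slope * F
    return motor.unloaded_off_rate


#: ATP concentration (μM) at which the off-rate law was calibrated.
SATURATING_ATP = 2000.0


def microscopic_off_rate(
    F: float, direction: str, motor: MotorParameters, dt: float
) -> float:
    """ε_micro = ε_obs(F)/p_step([ATP] = 2 mM, F): detachment rate per attempt.

    Undefined (raises) at stall, where the per-attempt construction
    degenerates; see :func:`detachment_event` for the stall limit.
    """
    v2 = unloaded_velocity(SATURATING_ATP, motor) * force_velocity_factor(
        F, direction, motor
    )
    p2 = step_probability(v2, dt, motor)
    if p2 == 0.0:
        raise ZeroDivisionError("stepping probability vanishes (stalled motor)")
    return observed_off_rate(F, direction, motor) / p2


def detachment_event(
    F: float,
    direction: str,
    atp: float,
    dt: float,
    rng: np.random.Generator,
    motor: MotorParameters,
) -> tuple[bool, bool]:
    """One kinetic update of a bound motor under load.

    Two-stage draw: attempt a step with probability p_step([ATP], F); if
    attempting, detach before completing it with probability
    min(1, ε_micro Δt).  At saturating ATP the net per-timestep detachment
    probability is ε_obs(F) Δt exactly (the stepping factors cancel).

    At stall both stepping probabilities vanish and the force-dependent
    factors cancel identically in the net rate, leaving a Poisson
    detachment at rate ε_obs(F) v0([ATP])/v0(2 mM), which is applied
    directly.

    Returns ``(detached, stepped)``.
    """
    factor = force_velocity_factor(F, direction, motor)
    v = unloaded_velocity(atp, motor) * factor
    v2 = unloaded_velocity(SATURATING_ATP, motor) * factor
    p2 = step_probability(v2, dt, motor)
    if p2 == 0.0:
        rate = observed_off_rate(F, direction, motor) * (
            unloaded_velocity(atp, motor) / unloaded_velocity(SATURATING_ATP, motor)
        )
        return (rng.random() < -math.expm1(-rate * dt), False)
    if rng.random() >= step_probability(v, dt, motor):
        return (False, False)
    p_det = min(1.0, observed_off_rate(F, direction, motor) / p2 * dt)
    if rng.random() < p_det:
        return (True, False)
    return (False, True)


def binding_event(
    anchor,
    mt_radius: float,
    dt: float,
    rng: np.random.Generator,
    motor: MotorParameters,
) -> float | None:
    """Attempt to bind an unbound motor to the microtubule.

    The motor is eligible iff the distance from its anchor to the
    microtubule surface, sqrt(A_y² + A_z²) - r_MT, does not exceed the rest
    length (boundary included).  An eligible motor binds with probability
    1 - exp(-π0 Δt); on binding the head is placed at the microtubule point
    nearest the anchor's axial projection, x = A_x.

    Returns the new head x-position, or None if no binding occurred.
    """
    anchor = np.asarray(anchor, dtype=float)
    dist = math.hypot(anchor[1], anchor[2]) - mt_radius
    if dist > motor.rest_length:
        return None
    if rng.random() < -math.expm1(-motor.binding_rate * dt):
        return float(anchor[0])
    return None


def head_surface_point(anchor, head_x: float, mt_radius: float) -> np.ndarray:
    """3-D head position on the microtubule surface.

    The head sits on the cylinder surface at the azimuth of the anchor's
    (y, z) projection — the protofilament nearest the anchor.  A degenerate
    anchor on the axis defaults to the top of the cylinder.
    """
    anchor = np.asarray(anchor, dtype=float)
    rho = math.hypot(anchor[1], anchor[2])
    if rho < 1.0e-12:
        uy, uz = 0.0, 1.0
    else:
        uy, uz = anchor[1] / rho, anchor[2] / rho
    return np.array([head_x, mt_radius * uy, mt_radius * uz])
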
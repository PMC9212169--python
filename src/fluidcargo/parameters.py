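"""Physical and numerical parameters of the motor/cargo model.

This module is the single home for every model constant: kinesin-1
mechanochemistry, cargo geometry, the aqueous environment, external-load
protocols and the numerical settings of the Brownian-dynamics integrator.
All values are stored in the internal unit system (nm, pN, s, pN·nm;
concentrations in μM) — see :mod:`fluidcargo.units`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import yaml

from . import units

__all__ = [
    "MotorParameters",
    "CargoParameters",
    "Environment",
    "LoadProtocol",
    "SimulationSettings",
    "ParameterSet",
    "ConfigError",
    "default_kinesin_parameters",
    "validate_config",
    "ALPHA_RIGID",
]

#: Rotational-noise calibration constant for a rigid cargo, chosen so that
#: the measured angular mean-square-displacement slope of a one-motor rigid
#: cargo corresponds to a rotational diffusivity of 7e-2 rad²/s (the value
#: reported for a bead tethered to a microtubule by a single kinesin).
#: Obtained with :func:`fluidcargo.cargo.calibrate_alpha`.
ALPHA_RIGID = 0.084

#: Safety factor applied to the explicit-integrator stability bound.
STABILITY_SAFETY = 4.0


class ConfigError(ValueError):
    """Raised when a configuration document violates a model invariant."""


@dataclass(frozen=True)
class MotorParameters:
    """Single-kinesin mechanics and kinetics.

    Attributes
    ----------
    rest_length : float
        Motor rest length L_mot (nm).  The spring engages only beyond it.
    stiffness : float
        Spring constant k_mot of the motor tether (pN/nm).
    binding_rate : float
        Intrinsic binding rate π0 (s⁻¹) of a motor whose anchor can reach
        the microtubule.
    unloaded_off_rate : float
        Zero-load observed detachment rate ε0 (s⁻¹) at saturating ATP.
    stall_force : float
        Stall force F_s (pN): hindering load at which stepping stops.
    detachment_force : float
        Force scale F_d (pN) of the exponential hindering off-rate;
        approximated equal to the stall force.
    fv_exponent : float
        Exponent w of the hindering force–velocity relation 1-(F/F_s)^w.
    step_size : float
        Step size δ (nm) advanced per ATP hydrolysis.
    v_max : float
        Unloaded velocity at saturating ATP (nm/s).
    K_m : float
        Michaelis constant of the ATP dependence of velocity (μM).
    assistive_slope : float
        Linear coefficient (s⁻¹/pN) of the assistive off-rate.
    surface_diffusion : float
        Anchor diffusivity D on the cargo surface (μm²/s); 0 = rigid cargo.
    """

    rest_length: float = 57.0
    stiffness: float = 0.32
    binding_rate: float = 5.0
    unloaded_off_rate: float = 0.79
    stall_force: float = 7.0
    detachment_force: float = 7.0
    fv_exponent: float = 2.0
    step_size: float = 8.0
    v_max: float = 800.0
    K_m: float = 44.0
    assistive_slope: float = 1.56
    surface_diffusion: float = 0.0

    def validate(self) -> None:
        positive = (
            "rest_length stiffness binding_rate unloaded_off_rate "
            "stall_force detachment_force fv_exponent step_size v_max "
            "K_m assistive_slope"
        ).split()
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"motor.{name} must be strictly positive")
        if self.surface_diffusion < 0:
            raise ConfigError("motor.surface_diffusion must be >= 0")

    @property
    def surface_diffusion_nm2(self) -> float:
        """Anchor diffusivity in nm²/s."""
        return units.um2s_to_nm2s(self.surface_diffusion)


@dataclass(frozen=True)
class CargoParameters:
    """Spherical cargo geometry and rotational options."""

    radius: float = 250.0
    motor_count: int = 16
    steric_stiffness_factor: float = 10.0
    rotation_enabled: bool = True
    alpha: float = 1.0

    def validate(self) -> None:
        if not self.radius > 0:
            raise ConfigError("cargo.radius must be strictly positive")
        if self.motor_count < 1:
            raise ConfigError("cargo.motor_count must be >= 1")
        if not self.steric_stiffness_factor > 0:
            raise ConfigError("cargo.steric_stiffness_factor must be > 0")
        if self.alpha < 0:
            raise ConfigError("cargo.alpha must be >= 0")


@dataclass(frozen=True)
class Environment:
    """Thermal environment and microtubule geometry.

    The microtubule is an infinite straight cylinder along +x with its axis
    at y = z = 0.  Viscosity is stored in Pa·s; ATP in μM.
    """

    viscosity: float = 1.0e-3
    temperature: float = 293.15
    ATP: float = 2000.0
    MT_radius: float = 12.5

    def validate(self) -> None:
        for name in ("viscosity", "temperature", "MT_radius"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"environment.{name} must be > 0")
        if self.ATP < 0:
            raise ConfigError("environment.ATP must be >= 0")

    @property
    def kT(self) -> float:
        """Thermal energy in pN·nm."""
        return units.thermal_energy(self.temperature)

    @property
    def viscosity_internal(self) -> float:
        """Viscosity in pN·s/nm²."""
        return units.pas_to_internal(self.viscosity)

    def gamma_c(self, radius: float) -> float:
        """Translational drag γ_c = 18 π η_v R (pN·s/nm), as modelled."""
        return 18.0 * math.pi * self.viscosity_internal * radius

    def gamma_R(self, radius: float) -> float:
        """Rotational drag γ_R = 8 π η_v R³ (pN·nm·s)."""
        return 8.0 * math.pi * self.viscosity_internal * radius**3

    def D_R(self, radius: float) -> float:
        """Free-sphere rotational diffusivity kT/γ_R (rad²/s)."""
        return self.kT / self.gamma_R(radius)

    def gamma_s(self, surface_diffusion_nm2: float) -> float:
        """Surface-drag coefficient γ_s = kT/D (pN·s/nm) for D > 0."""
        if surface_diffusion_nm2 <= 0:
            raise ConfigError("gamma_s undefined for D <= 0")
        return self.kT / surface_diffusion_nm2


@dataclass(frozen=True)
class LoadProtocol:
    """External load on the cargo: none, constant hindering, or a trap."""

    kind: str = "none"
    f_h: float = 0.0
    k_trap: float = 0.06
    trap_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    trap_x_only: bool = False

    KINDS = ("none", "constant_hindering", "optical_trap")

    def validate(self) -> None:
        if self.kind not in self.KINDS:
            raise ConfigError(f"unknown load protocol kind {self.kind!r}")
        if self.kind == "constant_hindering" and self.f_h < 0:
            raise ConfigError("load.f_h must be >= 0")
        if self.kind == "optical_trap" and not self.k_trap > 0:
            raise ConfigError("load.k_trap must be > 0")


@dataclass(frozen=True)
class SimulationSettings:
    """Numerical settings of the integrator and of the ensemble driver."""

    timestep: float = 1.0e-6
    sampling_rate: float = 100.0
    max_time: float = 120.0
    seed: int = 0
    ensemble_size: int = 200
    record_steps: bool = False
    record_anchors: bool = True
    record_forces: bool = True
    record_orientation: bool = True

    def validate(self) -> None:
        if not self.timestep > 0:
            raise ConfigError("run.timestep must be > 0")
        if not self.sampling_rate > 0:
            raise ConfigError("run.sampling_rate must be > 0")
        if self.max_time < 0:
            raise ConfigError("run.max_time must be >= 0")
        if self.ensemble_size < 1:
            raise ConfigError("run.ensemble_size must be >= 1")
        interval = 1.0 / self.sampling_rate
        ratio = interval / self.timestep
        if abs(ratio - round(ratio)) > 1e-6 * ratio:
            raise ConfigError(
                "sampling interval must be an integer multiple of the timestep"
            )

    @property
    def sample_every(self) -> int:
        """Number of timesteps between samples."""
        return int(round(1.0 / (self.sampling_rate * self.timestep)))


@dataclass(frozen=True)
class ParameterSet:
    """Validated bundle of all model parameters."""

    motor: MotorParameters = field(default_factory=MotorParameters)
    cargo: CargoParameters = field(default_factory=CargoParameters)
    environment: Environment = field(default_factory=Environment)
    load: LoadProtocol = field(default_factory=LoadProtocol)
    run: SimulationSettings = field(default_factory=SimulationSettings)

    def validate(self) -> "ParameterSet":
        self.motor.validate()
        self.cargo.validate()
        self.environment.validate()
        self.load.validate()
        self.run.validate()
        # Stability of the explicit Euler–Maruyama update: the stiffest
        # relaxation time is γ_c over the steric spring constant.
        gamma_c = self.environment.gamma_c(self.cargo.radius)
        k_max = self.cargo.steric_stiffness_factor * self.motor.stiffness
        bound = gamma_c / k_max / STABILITY_SAFETY
        if self.run.timestep > bound:
            raise ConfigError(
                f"timestep {self.run.timestep:g} s exceeds the stability bound "
                f"gamma_c/({self.cargo.steric_stiffness_factor:g} k_mot)"
                f"/{STABILITY_SAFETY:g} = {bound:.3g} s"
            )
        return self

    # -- derived quantities -------------------------------------------------

    @property
    def gamma_c(self) -> float:
        return self.environment.gamma_c(self.cargo.radius)

    @property
    def gamma_R(self) -> float:
        return self.environment.gamma_R(self.cargo.radius)

    @property
    def D_R(self) -> float:
        return self.environment.D_R(self.cargo.radius)

    @property
    def kT(self) -> float:
        return self.environment.kT

    def unloaded_velocity(self) -> float:
        """Michaelis–Menten speed v0([ATP]) in nm/s."""
        atp = self.environment.ATP
        return self.motor.v_max * atp / (self.motor.K_m + atp)

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["load"]["trap_center"] = list(self.load.trap_center)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "ParameterSet":
        return validate_config(raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ParameterSet":
        with open(path) as fh:
            return validate_config(yaml.safe_load(fh))

    def with_overrides(self, **sections) -> "ParameterSet":
        """Return a copy with dataclass fields replaced per section.

        Example: ``ps.with_overrides(motor={"stiffness": 0.1})``.
        """
        updates = {}
        for section, kv in sections.items():
            if not hasattr(self, section):
                raise ConfigError(f"unknown section {section!r}")
            updates[section] = replace(getattr(self, section), **kv)
        return replace(self, **updates).validate()


def default_kinesin_parameters() -> ParameterSet:
    """The published kinesin-1 / 250-nm-cargo parameter set.

    Defaults describe a rigid cargo (D = 0) with N = 16 motors at
    saturating ATP (2 mM) and cargo rotation enabled, with the rigid-cargo
    rotational calibration constant.
    """
    ps = ParameterSet(
        cargo=CargoParameters(alpha=ALPHA_RIGID),
    )
    return ps.validate()


def validate_config(raw: dict) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a nested dictionary."""
    if not isinstance(raw, dict):
        raise ConfigError("configuration document must be a mapping")
    known = {"motor", "cargo", "environment", "load", "run"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown configuration sections: {sorted(unknown)}")
    kwargs = {}
    for section, cls in (
        ("motor", MotorParameters),
        ("cargo", CargoParameters),
        ("environment", Environment),
        ("load", LoadProtocol),
        ("run", SimulationSettings),
    ):
        sub = dict(raw.get(section, {}))
        field_names = {f for f in cls.__dataclass_fields__}
        bad = set(sub) - field_names
        if bad:
            raise ConfigError(f"unknown keys in [{section}]: {sorted(bad)}")
        if section == "load" and "trap_center" in sub:
            sub["trap_center"] = tuple(float(v) for v in sub["trap_center"])
        kwargs[section] = cls(**sub)
    return ParameterSet(**kwargs).validate()
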
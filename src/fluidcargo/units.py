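"""Internal unit system and conversions.

All internal quantities are expressed in nanometres (length), piconewtons
(force), seconds (time) and pN·nm (energy).  This keeps every published
kinesin constant within a few orders of magnitude of unity and makes the
thermal energy kT ≈ 4 pN·nm at room temperature.
"""

from __future__ import annotations

#: Boltzmann constant in pN·nm/K (1.380649e-23 J/K).
K_B = 1.380649e-2

#: Conversions between SI and the internal system.
NM_PER_M = 1.0e9
PN_PER_N = 1.0e12
#: 1 Pa·s = 1 N·s/m² = 1e12 pN·s / 1e18 nm² = 1e-6 pN·s/nm².
PNS_PER_NM2_PER_PAS = 1.0e-6
#: 1 μm²/s = 1e6 nm²/s.
NM2_PER_UM2 = 1.0e6


def nm_to_m(x: float) -> float:
    return x / NM_PER_M


def m_to_nm(x: float) -> float:
    return x * NM_PER_M


def pn_to_n(x: float) -> float:
    return x / PN_PER_N


def n_to_pn(x: float) -> float:
    return x * PN_PER_N


def pas_to_internal(eta: float) -> float:
    """Viscosity from Pa·s to pN·s/nm²."""
    return eta * PNS_PER_NM2_PER_PAS


def um2s_to_nm2s(d: float) -> float:
    """Surface diffusivity from μm²/s to nm²/s."""
    return d * NM2_PER_UM2


def thermal_energy(temperature: float) -> float:
    """kT in pN·nm for a temperature in kelvin."""
    return K_B * temperature
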
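"""Physical constants and unit conversions.

All internal computation is done in SI units (m, s, K, Pa·s).  Public
interfaces accept and report the units customary in the field: nm for
solute/fiber/mesh radii, μm²/s for diffusivities, mm for gel thickness,
and days as a convenience time unit for release experiments.  Every
conversion in the package goes through this module.
"""

from __future__ import annotations

#: Boltzmann constant, J/K (CODATA 2018 exact value).
BOLTZMANN_J_PER_K: float = 1.380649e-23

#: Default experiment temperature, K (incubator temperature of the release
#: and FRAP measurements).
DEFAULT_TEMPERATURE_K: float = 307.0

#: Viscosity of water at the experiment temperature, N·s/m².
DEFAULT_WATER_VISCOSITY_PA_S: float = 7.34e-4

SECONDS_PER_DAY: float = 86_400.0


def nm_to_m(x: float) -> float:
    return x * 1e-9


def m_to_nm(x: float) -> float:
    return x * 1e9


def mm_to_m(x: float) -> float:
    return x * 1e-3


def um_to_m(x: float) -> float:
    return x * 1e-6


def um2_per_s_to_m2_per_s(x: float) -> float:
    return x * 1e-12


def m2_per_s_to_um2_per_s(x: float) -> float:
    return x * 1e12


def days_to_seconds(x: float) -> float:
    return x * SECONDS_PER_DAY


def seconds_to_days(x: float) -> float:
    return x / SECONDS_PER_DAY
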
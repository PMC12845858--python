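"""Thermal-confinement feasibility for modulated excitation.

Under harmonic heating, heat diffuses over the characteristic length
``L = sqrt(alpha / (pi f))`` per modulation cycle.  Confining the absorbed
energy to the excitation spot (so it converts locally to pressure) requires
the modulation frequency to be well above ``f_min = alpha / (pi L^2)``
where L is the spot size.  For soft tissue (alpha = 1.3e-7 m^2/s) and a
100 nm spot this gives f_min ~4.14 MHz, i.e. f(MHz) ~ 4.14e4 / L(nm)^2.

Unit contract: alpha in m^2/s, lengths in nm, frequencies in MHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SOFT_TISSUE_DIFFUSIVITY",
    "ThermalSpec",
    "diffusion_length",
    "min_confinement_frequency",
    "is_confined",
]

#: typical thermal diffusivity of soft biological tissue (m^2/s)
SOFT_TISSUE_DIFFUSIVITY: float = 1.3e-7

_NM_PER_M = 1e9
_HZ_PER_MHZ = 1e6


@dataclass(frozen=True)
class ThermalSpec:
    """Thermal diffusivity with a consistent (length, frequency) pair."""

    alpha: float
    length_nm: float
    frequency_mhz: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.length_nm <= 0 or self.frequency_mhz <= 0:
            raise ValueError("alpha, length and frequency must all be positive")
        expected = diffusion_length(self.alpha, self.frequency_mhz)
        if abs(expected - self.length_nm) > 1e-9 * self.length_nm:
            raise ValueError(
                f"length {self.length_nm} nm and frequency {self.frequency_mhz} MHz "
                f"do not satisfy L = sqrt(alpha/(pi f)) (expected {expected:.6g} nm)"
            )

    @classmethod
    def from_frequency(cls, alpha: float, frequency_mhz: float) -> "ThermalSpec":
        return cls(alpha, diffusion_length(alpha, frequency_mhz), frequency_mhz)

    @classmethod
    def from_length(cls, alpha: float, length_nm: float) -> "ThermalSpec":
        return cls(alpha, length_nm, min_confinement_frequency(alpha, length_nm))


def diffusion_length(alpha: float, frequency_mhz: float) -> float:
    """Thermal diffusion length sqrt(alpha / (pi f)) in nm.

    Quadrupling the frequency halves the length.
    """
    if alpha <= 0 or frequency_mhz <= 0:
        raise ValueError("alpha and frequency must be positive")
    return math.sqrt(alpha / (math.pi * frequency_mhz * _HZ_PER_MHZ)) * _NM_PER_M


def min_confinement_frequency(alpha: float, length_nm: float) -> float:
    """Frequency (MHz) at which the diffusion length equals ``length_nm``.

    Inverse of :func:`diffusion_length`; for soft tissue this is
    approximately 4.14e4 / L(nm)^2 MHz.
    """
    if alpha <= 0 or length_nm <= 0:
        raise ValueError("alpha and length must be positive")
    return alpha / (math.pi * (length_nm / _NM_PER_M) ** 2) / _HZ_PER_MHZ


def is_confined(frequency_mhz: float, length_nm: float, alpha: float = SOFT_TISSUE_DIFFUSIVITY,
                safety_factor: float = 5.0) -> bool:
    """Advisory check: is f comfortably above the confinement minimum?

    The confinement condition only holds loosely at f = f_min; practical
    systems run well above it, hence the default safety factor of 5.
    """
    if safety_factor <= 0:
        raise ValueError("safety factor must be positive")
    return frequency_mhz >= safety_factor * min_confinement_frequency(alpha, length_nm)
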
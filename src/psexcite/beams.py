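"""Focal-plane intensity models for the TEM00 Gaussian and LG01 donut beams.

Both beams are treated as focused to the same waist ``w0`` at the focal
plane (z = 0) and are characterised entirely by their average intensity
profiles; the beams are assumed non-interfering (circular polarizations of
opposite handedness), so all downstream computation works with intensities
rather than fields.  The Gaussian intensity is

    I_G(r) = 2 P / (pi w0^2) * exp(-2 r^2 / w0^2)

and the donut (LG01, p=0, l=1) intensity, normalized so that it integrates
to the optical power P over the plane, is

    I_D(r) = 4 P / (pi w0^4) * r^2 * exp(-2 r^2 / w0^2).

The donut vanishes on axis and peaks at r = w0 / sqrt(2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAUSSIAN_FWHM_FACTOR",
    "BeamSpec",
    "RadialProfile",
    "IntensityMap",
    "gaussian_intensity",
    "donut_intensity",
    "donut_field_amplitude",
    "render_map",
]

#: FWHM of a Gaussian intensity profile in units of the beam waist:
#: sqrt(2 ln 2) = 1.17741...
GAUSSIAN_FWHM_FACTOR: float = math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class BeamSpec:
    """One focused beam: optical power and beam waist.

    Parameters
    ----------
    power
        Average optical power (arbitrary power units, >= 0).
    waist
        Beam waist ``w0`` at the focal plane (length units; 1.0 in
        normalized mode).  Paired beams share the same waist.
    """

    power: float
    waist: float = 1.0

    def __post_init__(self) -> None:
        if self.power < 0:
            raise ValueError(f"beam power must be >= 0, got {self.power}")
        if self.waist <= 0:
            raise ValueError(f"beam waist must be > 0, got {self.waist}")


@dataclass(frozen=True)
class RadialProfile:
    """A sampled 1D profile: intensity (or |ΔI| amplitude) versus radius."""

    radii: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "values", values)
        if radii.ndim != 1 or values.ndim != 1:
            raise ValueError("radii and values must be 1D")
        if radii.shape != values.shape:
            raise ValueError("radii and values must have the same length")
        if radii.size == 0:
            raise ValueError("profile must not be empty")
        if radii[0] != 0:
            raise ValueError("radii must start at 0")
        if np.any(np.diff(radii) <= 0):
            raise ValueError("radii must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("profile values must be nonnegative")


@dataclass(frozen=True)
class IntensityMap:
    """A square 2D intensity grid centered on the optical axis.

    The grid has odd dimensions so the axis (r = 0) lies exactly on a
    sample point.
    """

    values: np.ndarray
    pixel_size: float
    origin: tuple[float, float] = field(default=(0.0, 0.0))

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("intensity map must be a square 2D grid")
        if values.shape[0] % 2 == 0:
            raise ValueError("intensity map must have odd dimensions")
        if np.any(values < 0):
            raise ValueError("intensity map values must be nonnegative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def center_index(self) -> int:
        return self.values.shape[0] // 2

    def axis_coordinates(self) -> np.ndarray:
        """Physical coordinates of pixel centers along one axis."""
        c = self.center_index
        return (np.arange(self.values.shape[0]) - c) * self.pixel_size


def _check_radius(r) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radius must be nonnegative")
    return r


def gaussian_intensity(r, beam: BeamSpec):
    """Average Gaussian (TEM00) intensity at radius ``r`` in the focal plane.

    Integrating ``I * 2 pi r dr`` over the plane recovers ``beam.power``.
    Vectorizes over ``r``.
    """
    r = _check_radius(r)
    w0 = beam.waist
    return 2.0 * beam.power / (math.pi * w0**2) * np.exp(-2.0 * r**2 / w0**2)


def donut_intensity(r, beam: BeamSpec):
    """Average donut (LG01) intensity at radius ``r`` in the focal plane.

    Zero on axis; single maximum at ``r = w0 / sqrt(2)`` of value
    ``2 P / (pi e w0^2)``.  Integrates to ``beam.power`` over the plane.
    """
    r = _check_radius(r)
    w0 = beam.waist
    return 4.0 * beam.power / (math.pi * w0**4) * r**2 * np.exp(-2.0 * r**2 / w0**2)


def donut_field_amplitude(r, theta, beam: BeamSpec):
    """Unnormalized LG01 field amplitude (sqrt(2) r / w0) e^{-r^2/w0^2} e^{i theta}.

    The helical phase winds once per azimuthal revolution; ``|E|^2`` scaled
    by the power normalization ``A = 2 P / (pi w0^2)`` reproduces
    :func:`donut_intensity`.  Carried for completeness — the excitation
    model itself uses only intensities (the beams do not interfere).
    """
    r = _check_radius(r)
    theta = np.asarray(theta, dtype=float)
    w0 = beam.waist
    radial = math.sqrt(2.0) * r / w0 * np.exp(-(r**2) / w0**2)
    return radial * np.exp(1j * theta)


def render_map(intensity_fn, extent: float, n: int) -> IntensityMap:
    """Sample a radial intensity function on a centered Cartesian grid.

    Parameters
    ----------
    intensity_fn
        Callable ``f(r) -> intensity``, vectorized over ``r``.
    extent
        Half-width of the grid (same length units as ``r``).
    n
        Samples per side; must be odd (>= 3) so the axis is a sample point.
    """
    if extent <= 0:
        raise ValueError("extent must be positive")
    if n < 3 or n % 2 == 0:
        raise ValueError("n must be odd and >= 3 (center sample required)")
    axis = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(axis, axis)
    values = intensity_fn(np.hypot(xx, yy))
    return IntensityMap(values=values, pixel_size=2.0 * extent / (n - 1))
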
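"""Axial (orientation) statistics on angles defined modulo 180 degrees.

Orientation data — fiber axes, cell long axes, outgrowth directions about an
alignment axis — are *axial*: theta and theta + 180 deg describe the same
object. The standard device is angle doubling: an axial angle theta maps to
the circular angle phi = 2*theta, circular statistics are applied to phi, and
results are halved back. Concentration about a mean axis is parameterised by
the von Mises concentration kappa of the doubled angles; kappa = 0 is the
isotropic (uniform) case and kappa -> inf collapses onto the mean axis.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

__all__ = [
    "wrap_axial",
    "axial_difference",
    "sample_axial_vonmises",
    "axial_vonmises_band_fraction",
    "axial_vonmises_fwhm",
]


def wrap_axial(angles_deg):
    """Wrap angles (degrees) into the axial interval (-90, 90]."""
    a = np.asarray(angles_deg, dtype=float)
    wrapped = (a + 90.0) % 180.0 - 90.0
    # map the -90 representative onto +90 so the interval is half-open at -90
    wrapped = np.where(wrapped == -90.0, 90.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def axial_difference(a_deg, b_deg):
    """Absolute axial distance |a - b| mod 180, in [0, 90] degrees."""
    d = (np.asarray(a_deg, dtype=float) - np.asarray(b_deg, dtype=float)) % 180.0
    d = np.minimum(d, 180.0 - d)
    return d if d.ndim else float(d)


def sample_axial_vonmises(rng: np.random.Generator, kappa: float,
                          mean_deg: float, size: int):
    """Sample axial angles (degrees in (-90, 90]) about a mean axis.

    Angle-doubling construction: phi ~ von Mises(2*mean, kappa) on the full
    circle, theta = phi / 2 reduced mod 180. kappa = 0 gives the uniform
    axial distribution.
    """
    if kappa < 0:
        raise ValueError(f"kappa must be >= 0, got {kappa}")
    if kappa == 0:
        theta = rng.uniform(-90.0, 90.0, size)
    else:
        phi = rng.vonmises(np.deg2rad(2.0 * mean_deg), kappa, size)
        theta = np.rad2deg(phi) / 2.0
    return wrap_axial(theta)


def _axial_density_norm(kappa: float) -> float:
    val, _ = integrate.quad(
        lambda t: np.exp(kappa * np.cos(2.0 * t)), -np.pi / 2, np.pi / 2)
    return val


def axial_vonmises_band_fraction(kappa: float, half_width_deg: float) -> float:
    """P(|theta - mean axis| <= half_width) under the axial von Mises law.

    Computed by quadrature of exp(kappa * cos 2*theta) — the analytic oracle
    for generator calibration checks (e.g. the fraction of objects within
    +/-30 deg of the alignment axis).
    """
    if kappa == 0:
        return half_width_deg / 90.0
    hw = np.deg2rad(half_width_deg)
    num, _ = integrate.quad(lambda t: np.exp(kappa * np.cos(2.0 * t)), -hw, hw)
    return num / _axial_density_norm(kappa)


def axial_vonmises_fwhm(kappa: float) -> float:
    """Full width at half maximum (degrees) of the axial von Mises density.

    The density is proportional to exp(kappa * cos 2*theta); its half-max
    points solve cos 2*theta = 1 - ln2 / kappa, so
    FWHM = arccos(1 - ln2/kappa) in *doubled*-angle radians. If kappa is so
    small that the density never drops to half its peak on (-90, 90], the
    FWHM is 180 deg by convention.
    """
    if kappa <= 0:
        return 180.0
    c = 1.0 - np.log(2.0) / kappa
    if c <= -1.0:
        return 180.0
    return float(np.rad2deg(np.arccos(c)))
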
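"""Magnetostatics of the two-magnet gelation chamber.

The fiber-alignment chamber holds two coaxial cylindrical N52 neodymium
magnets facing each other with opposite poles (attracting configuration), so
the fields between the faces aid and the hydrogel at the midpoint sits in a
nearly homogeneous axial field. Each magnet is modeled as a uniformly
magnetized cylinder, i.e. an equivalent solenoid carrying an azimuthal
surface current density K = Br / mu0, in free space (mu_r = 1, open
boundary).

On the symmetry axis the field of one magnet a distance z outside its face
has the classic closed form

    B(z) = (Br / 2) * [ (z + L) / sqrt((z + L)^2 + R^2)
                        - z / sqrt(z^2 + R^2) ]

with radius R, length L and remanence Br. Datasheets print the *surface
field* Bs = B(0); remanence is recovered by inverting that relation
(calibrate_remanence). Off-axis fields (for the flux-density slice between
the magnets) are obtained by numerically stacking circular current loops,
whose fields are expressible in complete elliptic integrals.

All quantities are SI (meters, tesla) internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special

MU0 = 4e-7 * np.pi

__all__ = [
    "CylMagnet", "MagnetPair", "FieldProfile",
    "calibrate_remanence", "axial_field", "pair_axial_profile",
    "field_slice", "loop_field", "solenoid_field", "axial_field_quadrature",
]


@dataclass(frozen=True)
class CylMagnet:
    """Cylindrical permanent magnet on a shared axis.

    radius_m, length_m : geometry.
    remanence_t : remanent flux density Br (T).
    face_position_m : axial coordinate of the reference face.
    polarity : magnetization direction along the shared axis (+1 toward +z).
        An attracting face-to-face pair has *equal* polarity, so the fields
        between the faces aid.
    """
    radius_m: float
    length_m: float
    remanence_t: float
    face_position_m: float = 0.0
    polarity: int = +1

    def __post_init__(self):
        if self.radius_m <= 0 or self.length_m <= 0 or self.remanence_t <= 0:
            raise ValueError("radius, length and remanence must be positive")
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")

    @property
    def surface_field_t(self) -> float:
        """On-axis flux density at the face center (the datasheet value)."""
        R, L, Br = self.radius_m, self.length_m, self.remanence_t
        return Br / 2.0 * L / np.hypot(L, R)


def calibrate_remanence(radius_m: float, length_m: float,
                        surface_field_t: float) -> float:
    """Remanence Br reproducing a printed on-axis surface field Bs.

    Inverts Bs = (Br/2) * L / sqrt(L^2 + R^2). For the chamber's magnets
    (R = 1.905 cm, L = 3.81 cm, Bs = 661.9 mT) this gives Br ~ 1.480 T,
    consistent with N52 grade material (Br ~ 1.43-1.48 T).
    """
    if radius_m <= 0 or length_m <= 0 or surface_field_t <= 0:
        raise ValueError("all calibration inputs must be positive")
    return 2.0 * surface_field_t * np.hypot(length_m, radius_m) / length_m


def axial_field(magnet: CylMagnet, z_m) -> np.ndarray:
    """On-axis flux density magnitude a distance z >= 0 outside the face."""
    z = np.asarray(z_m, dtype=float)
    if np.any(z < 0):
        raise ValueError("z must be >= 0 (the magnet interior is not modeled)")
    R, L, Br = magnet.radius_m, magnet.length_m, magnet.remanence_t
    b = Br / 2.0 * ((z + L) / np.hypot(z + L, R) - z / np.hypot(z, R))
    return b if b.ndim else float(b)


def axial_field_quadrature(magnet: CylMagnet, z_m, n_nodes: int = 96):
    """Independent Biot-Savart oracle for the on-axis field.

    Integrates the on-axis field of circular current loops,
    dB = (mu0 K / 2) R^2 / (R^2 + s^2)^(3/2) ds with K = Br/mu0, over the
    magnet length by Gauss-Legendre quadrature. Used to cross-check the
    closed form; not the production path.
    """
    z = np.atleast_1d(np.asarray(z_m, dtype=float))
    R, L, Br = magnet.radius_m, magnet.length_m, magnet.remanence_t
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    s = (nodes + 1.0) * (L / 2.0)          # loop depth below the face, [0, L]
    w = weights * (L / 2.0)
    h = z[:, None] + s[None, :]
    integrand = R ** 2 / (R ** 2 + h ** 2) ** 1.5
    b = (Br / 2.0) * (integrand * w[None, :]).sum(axis=1)
    return b if np.ndim(z_m) else float(b[0])


@dataclass(frozen=True)
class MagnetPair:
    """Two coaxial magnets, opposite poles facing (fields aiding in the gap).

    The gap spans [-d/2, +d/2] on the z axis with the midpoint at z = 0;
    magnet 1 occupies [-d/2 - L1, -d/2], magnet 2 occupies [+d/2, +d/2 + L2].
    """
    magnet1: CylMagnet
    magnet2: CylMagnet
    spacing_m: float

    def __post_init__(self):
        if self.spacing_m <= 0:
            raise ValueError("magnet spacing must be positive")

    @classmethod
    def identical(cls, magnet: CylMagnet, spacing_m: float) -> "MagnetPair":
        return cls(magnet, magnet, spacing_m)

    def gap_field(self, z_m) -> np.ndarray:
        """Axial flux density at axial positions z in the gap (z=0 midpoint)."""
        z = np.asarray(z_m, dtype=float)
        d = self.spacing_m
        if np.any(np.abs(z) > d / 2.0):
            raise ValueError("grid point inside a magnet or beyond the gap")
        b = np.asarray(axial_field(self.magnet1, z + d / 2.0)) \
            + np.asarray(axial_field(self.magnet2, d / 2.0 - z))
        return b if b.ndim else float(b)


@dataclass(frozen=True)
class FieldProfile:
    """Sampled on-axis flux density; z = 0 at the gap midpoint."""
    z_m: np.ndarray
    b_t: np.ndarray
    spacing_m: float = field(default=float("nan"))

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame({"z_m": self.z_m, "B_T": self.b_t})


def pair_axial_profile(pair: MagnetPair, z_grid_m) -> FieldProfile:
    """On-axis profile across the air gap by superposition of the two magnets."""
    z = np.asarray(z_grid_m, dtype=float)
    return FieldProfile(z_m=z, b_t=pair.gap_field(z), spacing_m=pair.spacing_m)


def loop_field(loop_radius, current, rho, z):
    """(B_rho, B_z) of a circular current loop at radius `loop_radius` in the
    z = 0 plane, evaluated at cylindrical (rho, z). Elliptic-integral form.
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    a = loop_radius
    rho_safe = np.where(rho < 1e-12 * a, 1e-12 * a, rho)
    q = (a + rho_safe) ** 2 + z ** 2
    m = 4.0 * a * rho_safe / q          # elliptic parameter m = k^2
    K = special.ellipk(m)
    E = special.ellipe(m)
    denom = (a - rho_safe) ** 2 + z ** 2
    pref = MU0 * current / (2.0 * np.pi * np.sqrt(q))
    bz = pref * (K + (a ** 2 - rho_safe ** 2 - z ** 2) / denom * E)
    brho = pref * (z / rho_safe) * (-K + (a ** 2 + rho_safe ** 2 + z ** 2)
                                    / denom * E)
    brho = np.where(rho < 1e-12 * a, 0.0, brho)
    return brho, bz


def solenoid_field(radius_m, remanence_t, z_lo, z_hi, rho, z,
                   current_sign: int = +1, n_nodes: int = 96):
    """(B_rho, B_z) of an equivalent-solenoid sheet at cylindrical (rho, z).

    The uniformly magnetized cylinder spanning [z_lo, z_hi] is replaced by
    an azimuthal surface current sheet K = Br / mu0 (sign = magnetization
    direction); its field is integrated loop-by-loop with Gauss-Legendre
    quadrature along the length.
    """
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    L = z_hi - z_lo
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    s = z_lo + (nodes + 1.0) * (L / 2.0)
    w = weights * (L / 2.0)
    K_sheet = current_sign * remanence_t / MU0
    brho = np.zeros(np.broadcast(rho, z).shape)
    bz = np.zeros_like(brho)
    for si, wi in zip(s, w):
        dbr, dbz = loop_field(radius_m, K_sheet * wi, rho, z - si)
        brho += dbr
        bz += dbz
    return brho, bz


def field_slice(pair: MagnetPair, x_grid_m, z_grid_m, n_nodes: int = 96):
    """Flux density on a plane containing the magnet axis.

    Returns (B_magnitude, direction) where direction has shape (2, nz, nx)
    holding the unit (x, z) field components; grid points inside a magnet
    volume are masked NaN. x is the transverse coordinate (signed radius).
    Both magnets are magnetized toward +z (attracting pair), so the gap
    fields aid.
    """
    x = np.asarray(x_grid_m, dtype=float)
    z = np.asarray(z_grid_m, dtype=float)
    X, Z = np.meshgrid(x, z)
    rho = np.abs(X)
    sgn = np.sign(X)
    sgn[sgn == 0] = 1.0

    d = pair.spacing_m
    extents = [
        (pair.magnet1, -d / 2.0 - pair.magnet1.length_m, -d / 2.0),
        (pair.magnet2, +d / 2.0, +d / 2.0 + pair.magnet2.length_m),
    ]
    brho = np.zeros_like(X)
    bz = np.zeros_like(X)
    inside = np.zeros_like(X, dtype=bool)
    for m, z_lo, z_hi in extents:
        dbr, dbz = solenoid_field(m.radius_m, m.remanence_t, z_lo, z_hi,
                                  rho, Z, n_nodes=n_nodes)
        brho += dbr
        bz += dbz
        inside |= (rho <= m.radius_m) & (Z >= z_lo) & (Z <= z_hi)
    bx = brho * sgn
    if inside.any():
        warnings.warn("grid intersects magnet volume; interior values masked",
                      stacklevel=2)
        bx = np.where(inside, np.nan, bx)
        bz = np.where(inside, np.nan, bz)

    bmag = np.hypot(bx, bz)
    with np.errstate(invalid="ignore", divide="ignore"):
        direction = np.stack([bx / bmag, bz / bmag])
    return bmag, direction


def plot_field_slice(bmag, direction, x_grid_m, z_grid_m, ax=None,
                     arrow_stride: int = 6):
    """Render a flux-density heat map with field-direction arrows whose size
    is logarithmically proportional to the local flux density."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    extent = [x_grid_m[0], x_grid_m[-1], z_grid_m[0], z_grid_m[-1]]
    ax.imshow(bmag, origin="lower", extent=extent, aspect="auto",
              cmap="inferno")
    s = arrow_stride
    X, Z = np.meshgrid(x_grid_m, z_grid_m)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.log10(1.0 + bmag / np.nanmin(bmag[bmag > 0]))
    u = direction[0] * scale
    v = direction[1] * scale
    ax.quiver(X[::s, ::s], Z[::s, ::s], u[::s, ::s], v[::s, ::s],
              color="white", width=0.003)
    ax.set_xlabel("x (m)")
    ax.set_ylabel("z (m)")
    return ax
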
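"""Electron physics primitives: kinematics, gyroradius, stopping power, scattering.

All quantities use cm / g / MeV / tesla / rad.  The medium is water for the
whole simulation: under Fano conditions every material keeps its own mass
density but shares water's mass collision stopping power and scattering
behaviour, so a single set of medium constants suffices.

The jitted scalar helpers (prefixed ``_``) are the single source of truth;
both the public API here and the vectorized transport kernel call them, so the
reference and fast paths evaluate identical floating-point expressions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

#: electron rest energy m0 c^2 [MeV]
ELECTRON_REST_MEV = 0.5110
#: momentum-to-gyroradius conversion: r_G [cm] = pc [MeV] / (B_RIGIDITY * B [T] * sin)
B_RIGIDITY = 2.99792458
#: default transport cutoff (kinetic) below which the stopping power is never queried
CUTOFF_MEV = 1.0e-3


@dataclass(frozen=True)
class MediumConstants:
    """Water constants shared by every region (Fano substitution)."""

    Z_over_A: float = 0.55509
    I_value: float = 75.0e-6  # MeV
    X0_mass: float = 36.08  # g/cm^2, mass radiation length

    def __post_init__(self):
        if self.Z_over_A <= 0 or self.I_value <= 0 or self.X0_mass <= 0:
            raise ValueError("medium constants must be positive")


WATER = MediumConstants()

# Baked into the jitted helpers (one fixed medium for the whole simulation).
_Z_OVER_A = WATER.Z_over_A
_I_VALUE = WATER.I_value
_X0_MASS = WATER.X0_mass


@dataclass(frozen=True)
class KinematicState:
    """Relativistic kinematics of an electron of given kinetic energy."""

    kinetic_energy: float  # MeV
    gamma: float
    beta: float
    momentum_c: float  # p*c in MeV


@njit(cache=True)
def _momentum_c(T):
    return np.sqrt(T * (T + 2.0 * ELECTRON_REST_MEV))


@njit(cache=True)
def _stopping_power(T):
    """Moller/ICRU-form water collision stopping power, no density effect.

    Valid down to ~1 keV kinetic; the transport cutoff guarantees it is never
    queried below that.
    """
    tau = T / ELECTRON_REST_MEV
    gamma = 1.0 + tau
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    ratio = _I_VALUE / ELECTRON_REST_MEV
    f_tau = (1.0 - beta2
             + (tau * tau / 8.0 - (2.0 * tau + 1.0) * np.log(2.0))
             / ((tau + 1.0) * (tau + 1.0)))
    bracket = np.log(tau * tau * (tau + 2.0) / (2.0 * ratio * ratio)) + f_tau
    return 0.153536 * _Z_OVER_A / beta2 * bracket


@njit(cache=True)
def _highland_sigma(T, mass_thickness):
    """Highland multiple-scattering width for a mass thickness in g/cm^2."""
    if mass_thickness <= 0.0:
        return 0.0
    pc = _momentum_c(T)
    gamma = 1.0 + T / ELECTRON_REST_MEV
    beta = np.sqrt(1.0 - 1.0 / (gamma * gamma))
    x = mass_thickness / _X0_MASS
    bracket = 1.0 + 0.038 * np.log(x)
    if bracket < 0.25:
        bracket = 0.25
    theta0 = 13.6 / (beta * pc) * np.sqrt(x) * bracket
    if theta0 > 0.5:
        theta0 = 0.5
    return theta0


@njit(cache=True)
def _rotate_about_axis(ux, uy, uz, ax, ay, az, angle):
    """Rodrigues rotation of u about unit axis a (returns components)."""
    c = np.cos(angle)
    s = np.sin(angle)
    dot = ax * ux + ay * uy + az * uz
    cx = ay * uz - az * uy
    cy = az * ux - ax * uz
    cz = ax * uy - ay * ux
    k = dot * (1.0 - c)
    return (ux * c + cx * s + ax * k,
            uy * c + cy * s + ay * k,
            uz * c + cz * s + az * k)


@njit(cache=True)
def _ms_rate(T):
    """Angular diffusion rate d<theta^2>/dt in rad^2 per g/cm^2.

    Rossi-Greisen form (13.6 MeV / beta pc)^2 / X0, deliberately without the
    Highland logarithmic thickness correction: transport applies deflections
    on a fixed mass-depth grid, and only a variance exactly linear in mass
    thickness makes the angular process independent of how condensed-history
    steps are subdivided at region interfaces -- the uniformity the Fano
    consistency test requires.
    """
    pc = _momentum_c(T)
    gamma = 1.0 + T / ELECTRON_REST_MEV
    beta = np.sqrt(1.0 - 1.0 / (gamma * gamma))
    k = 13.6 / (beta * pc)
    return k * k / _X0_MASS


def csda_mass_range(energy: float, ecut: float = CUTOFF_MEV) -> float:
    """CSDA range in g/cm^2: integral of dT / S(T) from ecut to energy."""
    if energy <= ecut:
        return 0.0
    grid = np.geomspace(ecut, energy, 2048)
    return float(np.trapezoid(1.0 / np.array([_stopping_power(t) for t in grid]),
                              grid))


@njit(cache=True)
def _deflect_field(ux, uy, uz, bx, by, bz, bmag, pc, s, first_order):
    """Direction after a path s in field (bx,by,bz); exact transverse rotation.

    Rotation angle about B-hat is the pitch-independent gyration angle
    alpha = s * B_RIGIDITY * |B| / pc; the sense follows du/ds ~ +u x B.
    """
    alpha = s * B_RIGIDITY * bmag / pc
    ax = bx / bmag
    ay = by / bmag
    az = bz / bmag
    if first_order:
        # single-term update of the deflection equation, renormalized
        cx = uy * az - uz * ay
        cy = uz * ax - ux * az
        cz = ux * ay - uy * ax
        vx = ux + alpha * cx
        vy = uy + alpha * cy
        vz = uz + alpha * cz
        inv = 1.0 / np.sqrt(vx * vx + vy * vy + vz * vz)
        return vx * inv, vy * inv, vz * inv
    return _rotate_about_axis(ux, uy, uz, ax, ay, az, -alpha)


@njit(cache=True)
def _deflect_polar(ux, uy, uz, theta, phi):
    """Rotate u by polar angle theta (azimuth phi) about itself."""
    if abs(uz) < 0.99:
        e1x = -uy
        e1y = ux
        e1z = 0.0
    else:
        e1x = uz
        e1y = 0.0
        e1z = -ux
    inv = 1.0 / np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x *= inv
    e1y *= inv
    e1z *= inv
    e2x = uy * e1z - uz * e1y
    e2y = uz * e1x - ux * e1z
    e2z = ux * e1y - uy * e1x
    ct = np.cos(theta)
    st = np.sin(theta)
    cp = np.cos(phi)
    sp = np.sin(phi)
    vx = ct * ux + st * (cp * e1x + sp * e2x)
    vy = ct * uy + st * (cp * e1y + sp * e2y)
    vz = ct * uz + st * (cp * e1z + sp * e2z)
    inv = 1.0 / np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx * inv, vy * inv, vz * inv


def lorentz_kinematics(kinetic_energy: float) -> KinematicState:
    """Lorentz factor, speed fraction and p*c for a kinetic energy in MeV."""
    T = float(kinetic_energy)
    if T < 0.0:
        raise ValueError(f"kinetic energy must be >= 0, got {T}")
    gamma = 1.0 + T / ELECTRON_REST_MEV
    beta = np.sqrt(1.0 - 1.0 / (gamma * gamma))
    return KinematicState(T, gamma, beta, float(_momentum_c(T)))


def gyroradius(kinetic_energy: float, B_magnitude: float, sin_angle: float) -> float:
    """Larmor radius in cm; ``inf`` when the field exerts no deflection.

    The radius depends only on momentum, field strength and pitch -- never on
    the medium density.
    """
    if B_magnitude < 0.0:
        raise ValueError("B magnitude must be >= 0")
    if not 0.0 <= sin_angle <= 1.0:
        raise ValueError("sin_angle must lie in [0, 1]")
    if B_magnitude == 0.0 or sin_angle == 0.0:
        return np.inf  # no-deflection sentinel
    pc = lorentz_kinematics(kinetic_energy).momentum_c
    return pc / (B_RIGIDITY * B_magnitude * sin_angle)


def max_em_step(kinetic_energy: float, B_field, direction, em_estepe: float) -> float:
    """Magnetic step limit: em_estepe times the gyroradius (cm)."""
    if not 0.0 < em_estepe <= 1.0:
        raise ValueError("em_estepe must lie in (0, 1]")
    B = np.asarray(B_field, dtype=float)
    u = np.asarray(direction, dtype=float)
    Bmag = float(np.linalg.norm(B))
    if Bmag == 0.0:
        return np.inf
    cosang = float(np.dot(u, B)) / (Bmag * float(np.linalg.norm(u)))
    sin_angle = np.sqrt(max(0.0, 1.0 - cosang * cosang))
    return em_estepe * gyroradius(kinetic_energy, Bmag, sin_angle)


def collision_stopping_power(kinetic_energy: float) -> float:
    """Mass collision stopping power of water in MeV cm^2/g (no density effect)."""
    T = float(kinetic_energy)
    if T < CUTOFF_MEV:
        raise ValueError(
            f"stopping power queried below the {CUTOFF_MEV} MeV cutoff: {T}")
    return float(_stopping_power(T))


def multiple_scattering_sigma(kinetic_energy: float, mass_thickness: float) -> float:
    """Gaussian multiple-scattering width (rad) for a mass thickness in g/cm^2.

    Highland form with the logarithmic bracket clamped below at 0.25 and the
    width clamped above at 0.5 rad; a pure function of energy and rho*s, which
    is what Fano consistency requires.
    """
    if mass_thickness < 0.0:
        raise ValueError("mass thickness must be >= 0")
    return float(_highland_sigma(float(kinetic_energy), float(mass_thickness)))


def min_stopping_power(energy: float, ecut: float = CUTOFF_MEV) -> float:
    """A safe lower bound on S(E) over (ecut, energy] (MeV cm^2/g).

    Used by the exact local-absorption shortcut: an electron of energy T in a
    region of density rho can travel at most T / (rho * S_min) before it stops,
    so if no surface lies within that distance its whole energy provably ends
    up in the current region.  The grid minimum is deflated by 0.1% so the
    bound errs on the side of transporting.
    """
    if energy <= ecut:
        raise ValueError("energy must exceed ecut")
    grid = np.geomspace(ecut, energy, 512)
    return 0.999 * float(min(_stopping_power(t) for t in grid))


def _check_unit(v, name):
    n = float(np.linalg.norm(v))
    if abs(n - 1.0) > 1.0e-6:
        raise ValueError(f"{name} must be a unit vector (|{name}| = {n})")


def rotate_about_axis(direction, axis, angle: float) -> np.ndarray:
    """Rodrigues rotation of a unit vector about a unit axis."""
    u = np.asarray(direction, dtype=float)
    a = np.asarray(axis, dtype=float)
    _check_unit(u, "direction")
    _check_unit(a, "axis")
    ux, uy, uz = _rotate_about_axis(u[0], u[1], u[2], a[0], a[1], a[2], float(angle))
    return np.array([ux, uy, uz])


def magnetic_deflection(direction, B_field, path_length: float,
                        kinetic_energy: float, first_order: bool = False) -> np.ndarray:
    """Direction after travelling ``path_length`` along the field helix.

    Exact rotation of the transverse component: the direction turns about
    B-hat by alpha = s * B_RIGIDITY |B| / pc, the pitch-independent gyration
    angle, with the sense of du/ds ~ u x B taken literally from the printed
    (+e) form of the deflection equation.  ``first_order=True`` applies the
    single-term update u + alpha (u x B-hat) instead (renormalized), for
    step-size comparison studies.
    """
    u = np.asarray(direction, dtype=float)
    B = np.asarray(B_field, dtype=float)
    Bmag = float(np.linalg.norm(B))
    if Bmag == 0.0 or path_length == 0.0:
        return u.copy()
    pc = lorentz_kinematics(kinetic_energy).momentum_c
    if pc == 0.0:
        return u.copy()
    alpha = float(path_length) * B_RIGIDITY * Bmag / pc
    bhat = B / Bmag
    if first_order:
        unew = u + alpha * np.cross(u, bhat)
        return unew / np.linalg.norm(unew)
    ux, uy, uz = _rotate_about_axis(u[0], u[1], u[2],
                                    bhat[0], bhat[1], bhat[2], -alpha)
    return np.array([ux, uy, uz])
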
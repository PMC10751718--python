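"""The Fano radiation source.

Monoenergetic electrons are emitted inside a box centered on the detector,
with position density proportional to the local mass density and isotropic
direction.  With this source the expected dose in any region is the analytic
n_i E0 / m_i regardless of the magnetic field, which is what turns the
simulation into a consistency test of the transport algorithm.

Position sampling is plain rejection against the largest density of any region
intersecting the box (accept a uniform proposal x with probability
rho(x)/rho_max), which realizes the density-proportional law pointwise without
precomputing box/region intersection volumes.  Directions use a uniform
cosine of the polar angle and a uniform azimuth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry, GeometryError, _locate
from .physics import CUTOFF_MEV
from .rng import RandomStream


@dataclass(frozen=True)
class FanoSourceConfig:
    """Source energy (MeV) and box dimensions (cm, centered at the origin)."""

    energy: float
    box_size: tuple

    def __post_init__(self):
        if self.energy <= CUTOFF_MEV:
            raise ValueError("source energy must exceed the transport cutoff")
        if len(self.box_size) != 3 or min(self.box_size) <= 0:
            raise ValueError("box_size must be three positive lengths")

    def validate_inside(self, geometry: Geometry):
        half = np.asarray(self.box_size, float) / 2.0
        if np.any(half > np.asarray(geometry.phantom.half)):
            raise GeometryError("source box does not fit inside the phantom")


@dataclass(frozen=True)
class Emission:
    position: np.ndarray
    direction: np.ndarray
    region_id: int
    energy: float


def sample_emission(geometry: Geometry, config: FanoSourceConfig,
                    stream: RandomStream) -> Emission:
    """Draw one emission: density-proportional position, isotropic direction.

    The draw order (three position coordinates, one acceptance uniform per
    proposal, then cos(theta) and phi) matches the vectorized engine exactly,
    so a given (seed, history) pair produces the same emission on both paths.
    """
    config.validate_inside(geometry)
    kind, par, dens = geometry.packed
    hx, hy, hz = np.asarray(config.box_size, float) / 2.0
    rho_max = geometry.max_density_in_box(config.box_size)
    if rho_max <= 0:
        raise GeometryError("no positive-density region intersects the source box")
    while True:
        x = (2.0 * stream.uniform() - 1.0) * hx
        y = (2.0 * stream.uniform() - 1.0) * hy
        z = (2.0 * stream.uniform() - 1.0) * hz
        rid = int(_locate(kind, par, x, y, z))
        accept = stream.uniform()
        if rid >= 0 and accept * rho_max < dens[rid]:
            break
    cos_t = 2.0 * stream.uniform() - 1.0
    phi = 2.0 * np.pi * stream.uniform()
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    direction = np.array([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])
    return Emission(np.array([x, y, z]), direction, rid, config.energy)
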
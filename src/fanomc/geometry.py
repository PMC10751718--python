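"""Analytic multi-region geometry: nested boxes and z-cylinders with densities.

A :class:`Geometry` is a water-equivalent phantom box containing an ordered
list of shapes.  Later entries carve out earlier ones (last-listed wins), which
is the simplest unambiguous tiling for nested detector parts: every point of
the phantom belongs to exactly one region, and region volumes follow in closed
form from the containment tree.  All lengths are cm, densities g/cm^3.

Shapes are axis-aligned: ``Box``, ``ZCylinder`` (finite cylinder along z) and
``ZShell`` (annular cylinder along z).  The detector symmetry axis is z; the
magnetic field of the shipped studies points along x, perpendicular to it.

Point location and straight-ray chord distances are jitted and shared by the
python reference transport and the vectorized engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from numba import njit

__all__ = [
    "Box", "ZCylinder", "ZShell", "Region", "Geometry",
    "GeometryError", "OutsideWorldError", "load_geometry", "save_geometry",
]

_EPS_SURFACE = 1.0e-15   # minimum positive ray parameter counted as a crossing;
                         # small enough that a point nudged or rounded just inside
                         # a face still sees its outward crossing
_TOL_LOCATE = 0.0        # closed boundaries: an exactly-on-face point goes to the inner
                         # region; the transport nudge keeps moving points off faces
_TOL_PROOF = 1.0e-12     # roundoff slack for containment/disjointness proofs

KIND_BOX = 0
KIND_CYL = 1
KIND_SHELL = 2


class GeometryError(ValueError):
    """Invalid or unprovable geometry description."""


class OutsideWorldError(GeometryError):
    """A queried point lies outside the phantom."""


# --------------------------------------------------------------------------
# shapes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Box:
    center: tuple
    half: tuple  # half-widths (hx, hy, hz)

    def __post_init__(self):
        if min(self.half) <= 0:
            raise GeometryError("box half-widths must be positive")

    @property
    def volume(self) -> float:
        hx, hy, hz = self.half
        return 8.0 * hx * hy * hz

    def bounds(self):
        c, h = np.asarray(self.center, float), np.asarray(self.half, float)
        return c - h, c + h

    def pack(self):
        return KIND_BOX, [*self.center, *self.half]


@dataclass(frozen=True)
class ZCylinder:
    cx: float
    cy: float
    radius: float
    z0: float
    z1: float

    def __post_init__(self):
        if self.radius <= 0 or self.z1 <= self.z0:
            raise GeometryError("cylinder needs radius > 0 and z1 > z0")

    @property
    def volume(self) -> float:
        return np.pi * self.radius ** 2 * (self.z1 - self.z0)

    def bounds(self):
        r = self.radius
        return (np.array([self.cx - r, self.cy - r, self.z0]),
                np.array([self.cx + r, self.cy + r, self.z1]))

    def pack(self):
        return KIND_CYL, [self.cx, self.cy, self.radius, self.z0, self.z1, 0.0]


@dataclass(frozen=True)
class ZShell:
    cx: float
    cy: float
    r_inner: float
    r_outer: float
    z0: float
    z1: float

    def __post_init__(self):
        if not 0 < self.r_inner < self.r_outer or self.z1 <= self.z0:
            raise GeometryError("shell needs 0 < r_inner < r_outer and z1 > z0")

    @property
    def volume(self) -> float:
        return np.pi * (self.r_outer ** 2 - self.r_inner ** 2) * (self.z1 - self.z0)

    def bounds(self):
        r = self.r_outer
        return (np.array([self.cx - r, self.cy - r, self.z0]),
                np.array([self.cx + r, self.cy + r, self.z1]))

    def pack(self):
        return KIND_SHELL, [self.cx, self.cy, self.r_inner, self.r_outer,
                            self.z0, self.z1]


Shape = Box | ZCylinder | ZShell


def _z_interval(shape):
    if isinstance(shape, Box):
        return shape.center[2] - shape.half[2], shape.center[2] + shape.half[2]
    return shape.z0, shape.z1


def _contains_shape(outer: Shape, inner: Shape) -> bool:
    """True only when containment of ``inner`` in ``outer`` is provable."""
    tol = _TOL_PROOF
    zo0, zo1 = _z_interval(outer)
    zi0, zi1 = _z_interval(inner)
    if not (zo0 <= zi0 + tol and zi1 <= zo1 + tol):
        return False
    if isinstance(outer, Box):
        lo, hi = outer.bounds()
        ilo, ihi = inner.bounds()
        return bool(np.all(lo <= ilo + tol) and np.all(ihi <= hi + tol))
    # outer is cylindrical: need the inner shape's xy extent inside the annulus/disk
    if isinstance(inner, Box):
        lo, hi = inner.bounds()
        dx = max(abs(lo[0] - outer.cx), abs(hi[0] - outer.cx))
        dy = max(abs(lo[1] - outer.cy), abs(hi[1] - outer.cy))
        r_far = np.hypot(dx, dy)
        # nearest xy distance from outer axis to the box footprint
        nx = max(lo[0] - outer.cx, 0.0, outer.cx - hi[0])
        ny = max(lo[1] - outer.cy, 0.0, outer.cy - hi[1])
        r_near = np.hypot(nx, ny)
    else:
        d = np.hypot(inner.cx - outer.cx, inner.cy - outer.cy)
        r_shape = inner.radius if isinstance(inner, ZCylinder) else inner.r_outer
        r_far = d + r_shape
        r_near = max(d - r_shape, 0.0)
        if isinstance(inner, ZShell):
            r_near = max(d - inner.r_outer, 0.0)
    r_out = outer.radius if isinstance(outer, ZCylinder) else outer.r_outer
    if r_far > r_out + _TOL_PROOF:
        return False
    if isinstance(outer, ZShell):
        return r_near >= outer.r_inner - _TOL_PROOF
    return True


def _disjoint_shapes(a: Shape, b: Shape) -> bool:
    """True only when disjointness of the two solids is provable."""
    tol = _TOL_PROOF
    za0, za1 = _z_interval(a)
    zb0, zb1 = _z_interval(b)
    if za1 <= zb0 + tol or zb1 <= za0 + tol:
        return True
    alo, ahi = a.bounds()
    blo, bhi = b.bounds()
    if np.any(ahi[:2] <= blo[:2] + tol) or np.any(bhi[:2] <= alo[:2] + tol):
        return True
    if isinstance(a, (ZCylinder, ZShell)) and isinstance(b, (ZCylinder, ZShell)):
        d = np.hypot(a.cx - b.cx, a.cy - b.cy)
        ra = a.radius if isinstance(a, ZCylinder) else a.r_outer
        rb = b.radius if isinstance(b, ZCylinder) else b.r_outer
        if d >= ra + rb - tol:
            return True
    # a solid entirely inside a shell's hole is disjoint from the shell
    for shell, other in ((a, b), (b, a)):
        if isinstance(shell, ZShell) and isinstance(other, (ZCylinder, Box)):
            if isinstance(other, ZCylinder):
                d = np.hypot(other.cx - shell.cx, other.cy - shell.cy)
                if d + other.radius <= shell.r_inner:
                    return True
            else:
                lo, hi = other.bounds()
                dx = max(abs(lo[0] - shell.cx), abs(hi[0] - shell.cx))
                dy = max(abs(lo[1] - shell.cy), abs(hi[1] - shell.cy))
                if np.hypot(dx, dy) <= shell.r_inner:
                    return True
    return False


# --------------------------------------------------------------------------
# jitted queries on packed shape arrays
# --------------------------------------------------------------------------

@njit(cache=True)
def _shape_contains(kind, par, i, x, y, z):
    tol = _TOL_LOCATE
    if kind[i] == 0:  # box
        return (abs(x - par[i, 0]) <= par[i, 3] + tol
                and abs(y - par[i, 1]) <= par[i, 4] + tol
                and abs(z - par[i, 2]) <= par[i, 5] + tol)
    dx = x - par[i, 0]
    dy = y - par[i, 1]
    d2 = dx * dx + dy * dy
    if kind[i] == 1:  # cylinder
        if z < par[i, 3] - tol or z > par[i, 4] + tol:
            return False
        r = par[i, 2] + tol
        return d2 <= r * r
    # shell
    if z < par[i, 4] - tol or z > par[i, 5] + tol:
        return False
    ro = par[i, 3] + tol
    ri = par[i, 2] - tol
    if ri < 0.0:
        ri = 0.0
    return ri * ri <= d2 <= ro * ro


@njit(cache=True)
def _nearest_surface(kind, par, x, y, z):
    """Unsigned distance from a point to the nearest shape surface.

    Within a ball of this radius around the point the density is uniform,
    which is what licenses the exact range-based local-absorption shortcut.
    """
    best = 1.0e30
    n = kind.shape[0]
    for i in range(n):
        if kind[i] == 0:
            ax = abs(x - par[i, 0]) - par[i, 3]
            ay = abs(y - par[i, 1]) - par[i, 4]
            az = abs(z - par[i, 2]) - par[i, 5]
            if ax > 0.0 or ay > 0.0 or az > 0.0:
                px = ax if ax > 0.0 else 0.0
                py = ay if ay > 0.0 else 0.0
                pz = az if az > 0.0 else 0.0
                d = np.sqrt(px * px + py * py + pz * pz)
            else:
                m = ax
                if ay > m:
                    m = ay
                if az > m:
                    m = az
                d = -m
        else:
            dx = x - par[i, 0]
            dy = y - par[i, 1]
            r = np.sqrt(dx * dx + dy * dy)
            if kind[i] == 1:
                rd_out = r - par[i, 2]
                rd_in = -1.0e30
                zd = par[i, 3] - z if par[i, 3] - z > z - par[i, 4] else z - par[i, 4]
            else:
                rd_out = r - par[i, 3]
                rd_in = par[i, 2] - r
                zd = par[i, 4] - z if par[i, 4] - z > z - par[i, 5] else z - par[i, 5]
            a = rd_out if rd_out > rd_in else rd_in
            if a < 0.0:
                a = 0.0
            b = zd if zd > 0.0 else 0.0
            if a > 0.0 or b > 0.0:
                d = np.sqrt(a * a + b * b)
            else:
                d = -rd_out
                if -rd_in < d:
                    d = -rd_in
                if -zd < d:
                    d = -zd
        if d < best:
            best = d
    return best


@njit(cache=True)
def _locate(kind, par, x, y, z):
    """Region id of a point: the last-listed (highest-priority) shape wins."""
    for i in range(kind.shape[0] - 1, -1, -1):
        if _shape_contains(kind, par, i, x, y, z):
            return i
    return -1


@njit(cache=True)
def _plane_hit(t, best):
    if _EPS_SURFACE < t < best:
        return t
    return best


@njit(cache=True)
def _chord(kind, par, x, y, z, ux, uy, uz):
    """Distance to the nearest shape surface along the ray (never overestimates).

    Every boundary surface of every shape is a stopping plane; crossings of
    surfaces that do not change the region cost an extra (harmless) step.
    """
    best = 1.0e30
    n = kind.shape[0]
    for i in range(n):
        # exact early rejects: the ray cannot reach a shape whose z or radial
        # extent lies behind it
        if kind[i] == 0:
            zlo = par[i, 2] - par[i, 5]
            zhi = par[i, 2] + par[i, 5]
        elif kind[i] == 1:
            zlo = par[i, 3]
            zhi = par[i, 4]
        else:
            zlo = par[i, 4]
            zhi = par[i, 5]
        if (z < zlo and uz <= 0.0) or (z > zhi and uz >= 0.0):
            continue
        if kind[i] == 0:
            cx = par[i, 0]; cy = par[i, 1]; cz = par[i, 2]
            hx = par[i, 3]; hy = par[i, 4]; hz = par[i, 5]
            if (x < cx - hx and ux <= 0.0) or (x > cx + hx and ux >= 0.0):
                continue
            if (y < cy - hy and uy <= 0.0) or (y > cy + hy and uy >= 0.0):
                continue
            if abs(ux) > 1.0e-14:
                for face in (cx - hx, cx + hx):
                    t = (face - x) / ux
                    if _EPS_SURFACE < t < best:
                        if (abs(y + t * uy - cy) <= hy
                                and abs(z + t * uz - cz) <= hz):
                            best = t
            if abs(uy) > 1.0e-14:
                for face in (cy - hy, cy + hy):
                    t = (face - y) / uy
                    if _EPS_SURFACE < t < best:
                        if (abs(x + t * ux - cx) <= hx
                                and abs(z + t * uz - cz) <= hz):
                            best = t
            if abs(uz) > 1.0e-14:
                for face in (cz - hz, cz + hz):
                    t = (face - z) / uz
                    if _EPS_SURFACE < t < best:
                        if (abs(x + t * ux - cx) <= hx
                                and abs(y + t * uy - cy) <= hy):
                            best = t
        else:
            cx = par[i, 0]; cy = par[i, 1]
            if kind[i] == 1:
                r_out = par[i, 2]; r_in = -1.0
                z0 = par[i, 3]; z1 = par[i, 4]
            else:
                r_in = par[i, 2]; r_out = par[i, 3]
                z0 = par[i, 4]; z1 = par[i, 5]
            dx = x - cx
            dy = y - cy
            d2 = dx * dx + dy * dy
            if d2 > r_out * r_out and dx * ux + dy * uy >= 0.0:
                continue  # outside the outer radius and moving away
            a = ux * ux + uy * uy
            if a > 1.0e-28:
                b = dx * ux + dy * uy
                for rr in (r_out, r_in):
                    if rr <= 0.0:
                        continue
                    c = dx * dx + dy * dy - rr * rr
                    disc = b * b - a * c
                    if disc > 0.0:
                        sq = np.sqrt(disc)
                        for t in ((-b - sq) / a, (-b + sq) / a):
                            if _EPS_SURFACE < t < best:
                                zt = z + t * uz
                                if z0 <= zt <= z1:
                                    best = t
            if abs(uz) > 1.0e-14:
                for zc in (z0, z1):
                    t = (zc - z) / uz
                    if _EPS_SURFACE < t < best:
                        xt = x + t * ux - cx
                        yt = y + t * uy - cy
                        d2 = xt * xt + yt * yt
                        if d2 <= r_out * r_out and (r_in < 0.0 or d2 >= r_in * r_in):
                            best = t
    return best


# --------------------------------------------------------------------------
# geometry container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    region_id: int
    name: str
    shape: Shape
    density: float
    volume: float  # net volume after carve-outs

    @property
    def mass(self) -> float:
        return self.density * self.volume


class Geometry:
    """Phantom box plus an ordered carve-out list of shaped regions."""

    def __init__(self, phantom: Box, phantom_density: float = 1.0,
                 regions: Sequence[tuple[str, Shape, float]] = (),
                 phantom_name: str = "phantom"):
        if not isinstance(phantom, Box):
            raise GeometryError("the phantom must be a Box")
        self.shapes: list[Shape] = [phantom]
        self.names: list[str] = [phantom_name]
        self._densities = [float(phantom_density)]
        for name, shape, density in regions:
            self.shapes.append(shape)
            self.names.append(str(name))
            self._densities.append(float(density))
        if any(d <= 0 for d in self._densities):
            raise GeometryError("all densities must be positive")
        self._validate_and_build()

    # -- construction ------------------------------------------------------

    def _validate_and_build(self):
        shapes = self.shapes
        n = len(shapes)
        for j in range(1, n):
            if not _contains_shape(shapes[0], shapes[j]):
                raise GeometryError(
                    f"region '{self.names[j]}' is not provably inside the phantom")
        for i in range(1, n):
            for j in range(i + 1, n):
                if _contains_shape(shapes[i], shapes[j]):
                    continue
                if _disjoint_shapes(shapes[i], shapes[j]):
                    continue
                if _contains_shape(shapes[j], shapes[i]):
                    raise GeometryError(
                        f"later region '{self.names[j]}' swallows earlier "
                        f"region '{self.names[i]}' completely")
                raise GeometryError(
                    f"regions '{self.names[i]}' and '{self.names[j]}' overlap "
                    "without provable nesting")
        # containment tree: parent of j = smallest-volume earlier container
        parents = np.zeros(n, dtype=int)
        net = np.array([s.volume for s in shapes], dtype=float)
        for j in range(1, n):
            containers = [i for i in range(j) if _contains_shape(shapes[i], shapes[j])]
            parent = min(containers, key=lambda i: shapes[i].volume)
            parents[j] = parent
        for j in range(n - 1, 0, -1):
            net[parents[j]] -= shapes[j].volume
        if np.any(net <= 0):
            bad = self.names[int(np.argmin(net))]
            raise GeometryError(f"region '{bad}' has no remaining volume")
        self._parents = parents
        self._net_volumes = net
        self.regions = [
            Region(i, self.names[i], shapes[i], self._densities[i], float(net[i]))
            for i in range(n)
        ]

    # -- packed arrays for the jitted queries ------------------------------

    @cached_property
    def packed(self):
        n = len(self.shapes)
        kind = np.empty(n, dtype=np.int64)
        par = np.zeros((n, 6), dtype=np.float64)
        for i, s in enumerate(self.shapes):
            k, p = s.pack()
            kind[i] = k
            par[i, :len(p)] = p
        dens = np.array(self._densities, dtype=np.float64)
        return kind, par, dens

    # -- public queries ----------------------------------------------------

    @property
    def n_regions(self) -> int:
        return len(self.shapes)

    @property
    def phantom(self) -> Box:
        return self.shapes[0]

    @property
    def densities(self) -> np.ndarray:
        return np.array(self._densities)

    def density_of(self, region_id: int) -> float:
        return self._densities[region_id]

    def locate(self, point) -> int:
        x, y, z = np.asarray(point, dtype=float)
        kind, par, _ = self.packed
        rid = int(_locate(kind, par, x, y, z))
        if rid < 0:
            raise OutsideWorldError(f"point {point} lies outside the phantom")
        return rid

    def chord_distance(self, point, direction) -> float:
        p = np.asarray(point, dtype=float)
        u = np.asarray(direction, dtype=float)
        self.locate(p)  # raises if outside
        kind, par, _ = self.packed
        return float(_chord(kind, par, p[0], p[1], p[2], u[0], u[1], u[2]))

    def region_masses(self) -> pd.DataFrame:
        rows = [(r.region_id, r.name, r.density, r.volume, r.mass)
                for r in self.regions]
        return pd.DataFrame(
            rows, columns=["region_id", "name", "density", "volume_cm3", "mass_g"])

    def masses(self) -> np.ndarray:
        return np.array([r.mass for r in self.regions])

    def check_tiling(self, rtol: float = 1.0e-9):
        total = float(np.sum(self._net_volumes))
        if abs(total - self.phantom.volume) > rtol * self.phantom.volume:
            raise GeometryError("net region volumes do not tile the phantom")

    def masses_in_box(self, box_size) -> np.ndarray:
        """Per-region mass inside a centered box (closed form).

        Every non-phantom region must lie provably inside or outside the box
        (the study geometries do); the phantom takes the remainder.  These
        masses set the expected emission share of each region under a
        density-proportional source.
        """
        half = tuple(np.asarray(box_size, dtype=float) / 2.0)
        box = Box(center=(0.0, 0.0, 0.0), half=half)
        if not _contains_shape(self.phantom, box):
            raise GeometryError("box does not fit inside the phantom")
        masses = np.zeros(self.n_regions)
        inside_net_volume = 0.0
        for r in self.regions[1:]:
            if _contains_shape(box, r.shape):
                masses[r.region_id] = r.mass
                inside_net_volume += r.volume
            elif _disjoint_shapes(box, r.shape):
                masses[r.region_id] = 0.0
            else:
                raise GeometryError(
                    f"region '{r.name}' straddles the box boundary; "
                    "its contained mass has no closed form")
        masses[0] = self._densities[0] * (box.volume - inside_net_volume)
        return masses

    def max_density_in_box(self, box_size) -> float:
        """Largest region density whose shape can intersect a centered box."""
        half = np.asarray(box_size, dtype=float) / 2.0
        rho_max = 0.0
        for r in self.regions:
            lo, hi = r.shape.bounds()
            if np.all(lo <= half) and np.all(hi >= -half):
                rho_max = max(rho_max, r.density)
        return rho_max

    def __repr__(self):
        return (f"Geometry({self.n_regions} regions, phantom "
                f"{tuple(2 * h for h in self.phantom.half)} cm)")


# --------------------------------------------------------------------------
# structured-text (YAML) description
# --------------------------------------------------------------------------

def _shape_from_dict(d: dict) -> Shape:
    kind = d["shape"]
    if kind == "box":
        return Box(center=tuple(d.get("center", (0.0, 0.0, 0.0))),
                   half=tuple(np.asarray(d["size"], float) / 2.0))
    cx, cy = d.get("center", (0.0, 0.0))[:2]
    z0, z1 = d["z"]
    if kind == "cylinder":
        return ZCylinder(cx=cx, cy=cy, radius=float(d["radius"]), z0=z0, z1=z1)
    if kind == "shell":
        ri, ro = d["radius"]
        return ZShell(cx=cx, cy=cy, r_inner=float(ri), r_outer=float(ro),
                      z0=z0, z1=z1)
    raise GeometryError(f"unknown shape kind '{kind}'")


def _shape_to_dict(shape: Shape) -> dict:
    if isinstance(shape, Box):
        return {"shape": "box", "center": [float(c) for c in shape.center],
                "size": [2.0 * float(h) for h in shape.half]}
    if isinstance(shape, ZCylinder):
        return {"shape": "cylinder", "center": [float(shape.cx), float(shape.cy)],
                "radius": float(shape.radius),
                "z": [float(shape.z0), float(shape.z1)]}
    return {"shape": "shell", "center": [float(shape.cx), float(shape.cy)],
            "radius": [float(shape.r_inner), float(shape.r_outer)],
            "z": [float(shape.z0), float(shape.z1)]}


def load_geometry(path) -> Geometry:
    """Read a geometry from its YAML description and validate the invariants."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        phantom = doc["phantom"]
        box = Box(center=tuple(phantom.get("center", (0.0, 0.0, 0.0))),
                  half=tuple(np.asarray(phantom["size"], float) / 2.0))
        regions = [(r.get("name", f"region_{i+1}"), _shape_from_dict(r),
                    float(r["density"]))
                   for i, r in enumerate(doc.get("regions", []))]
        geom = Geometry(box, float(phantom.get("density", 1.0)), regions,
                        phantom_name=phantom.get("name", "phantom"))
    except KeyError as exc:
        raise GeometryError(f"missing geometry key: {exc}") from exc
    geom.check_tiling()
    return geom


def save_geometry(geom: Geometry, path):
    doc = {
        "phantom": {"name": geom.names[0],
                    "center": [float(c) for c in geom.phantom.center],
                    "size": [2.0 * float(h) for h in geom.phantom.half],
                    "density": float(geom._densities[0])},
        "regions": [
            {"name": geom.names[i], "density": float(geom._densities[i]),
             **_shape_to_dict(geom.shapes[i])}
            for i in range(1, geom.n_regions)
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
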
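"""Reference condensed-history stepping engine (one electron at a time).

This is the readable, object-level implementation of the transport loop; the
vectorized engine in :mod:`fanomc.engine` executes the same floating-point
recipe through the same jitted primitives, and a test pins the two paths to
identical per-region deposits for identical (seed, history) pairs.

One condensed-history step, in order:

1. step length = min(geometry chord, energy limit ``estepe*T/(S rho)``,
   magnetic limit ``em_estepe * r_G``); record which bound was active;
2. CSDA energy loss ``dE = S(E_mid) rho s`` with the one-term midpoint energy
   ``E_mid = T - S(T) rho s / 2``, deposited in the current region;
3. advance the position by ``s`` along the pre-step direction (straight chord);
4. rotate the direction: exact field gyration, then a Gaussian multiple-
   scattering polar angle (Highland width, uniform azimuth);
5. geometry-limited endpoints are nudged 1e-8 cm along the new direction and
   relocated;
6. once the remaining energy falls to the cutoff it is deposited in the
   endpoint's region and the history ends.

There are no secondary particles: continuous slowing-down with local
absorption keeps the analytic Fano expectation exactly applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .geometry import Geometry, _chord, _locate, _nearest_surface
from .physics import B_RIGIDITY, _deflect_field, _deflect_polar, _highland_sigma, \
    _momentum_c, _ms_rate, _stopping_power
from .rng import RandomStream
from .source import Emission, FanoSourceConfig, sample_emission


class Limiter(IntEnum):
    GEOMETRY = 0
    ENERGY = 1
    FIELD = 2


@dataclass
class ElectronState:
    """A particle in flight."""

    position: np.ndarray
    direction: np.ndarray
    kinetic_energy: float
    region_id: int
    alive: bool = True
    mass_depth: float = 0.0   # accumulated g/cm^2 along the track
    ms_count: int = 0         # scattering thresholds already consumed


@dataclass(frozen=True)
class TransportParams:
    """All knobs of the condensed-history algorithm.

    em_estepe     maximum step as a fraction of the gyroradius (magnetic limit)
    estepe        maximum fractional energy loss per step
    ecut          kinetic cutoff energy in MeV (remainder absorbed locally)
    b_field       uniform magnetic field vector in tesla
    boundary_nudge  post-crossing offset in cm for deterministic relocation
    stopping_scale  global stopping-power multiplier (Fano robustness checks)
    multiple_scattering  toggle for the Highland sampler (diagnostics)
    first_order_field    first-order deflection update instead of the exact
                         rotation (step-size comparison studies)
    range_shortcut  exact local absorption of electrons that provably cannot
                    reach any surface (no approximation: with continuous
                    slowing-down and no secondaries, an electron farther from
                    every surface than T/(rho S_min) deposits all of T in its
                    current region); disable for step-level diagnostics
    ms_grid         mass-depth quantum of the scattering grid in g/cm^2
                    (None: auto, 0.02 capped at 1/20 of the CSDA range)
    """

    em_estepe: float = 0.25
    estepe: float = 0.25
    ecut: float = 1.0e-3
    b_field: tuple = (0.0, 0.0, 0.0)
    boundary_nudge: float = 1.0e-8
    stopping_scale: float = 1.0
    multiple_scattering: bool = True
    first_order_field: bool = False
    range_shortcut: bool = True
    ms_grid: float | None = None
    max_steps: int = 10_000_000

    def __post_init__(self):
        if not 0.0 < self.em_estepe <= 1.0:
            raise ValueError("em_estepe must lie in (0, 1]")
        if not 0.0 < self.estepe < 1.0:
            raise ValueError("estepe must lie in (0, 1)")
        if self.ecut <= 0.0:
            raise ValueError("ecut must be positive")
        if self.boundary_nudge <= 0.0:
            raise ValueError("boundary_nudge must be positive")
        if self.stopping_scale < 0.0:
            raise ValueError("stopping_scale must be >= 0")
        if len(self.b_field) != 3:
            raise ValueError("b_field must be a 3-vector")

    @property
    def b_magnitude(self) -> float:
        return float(np.linalg.norm(self.b_field))


@dataclass
class StepRecord:
    """Per-step log entry written in debug mode."""

    region_id: int
    length: float
    limiter: Limiter
    energy_deposit: float
    kinetic_energy: float


def propose_step(state: ElectronState, geometry: Geometry,
                 params: TransportParams) -> tuple[float, Limiter]:
    """Step length = min(chord, energy limit, field limit) and its limiter."""
    s, limiter, _, _, _ = _propose(state, geometry, params)
    return s, limiter


def _propose(state, geometry, params):
    kind, par, dens = geometry.packed
    x, y, z = state.position
    ux, uy, uz = state.direction
    T = state.kinetic_energy
    rho = dens[state.region_id]
    s_geom = _chord(kind, par, x, y, z, ux, uy, uz)
    S0 = params.stopping_scale * _stopping_power(T)
    s_en = params.estepe * T / (S0 * rho) if S0 > 0.0 else np.inf
    bx, by, bz = params.b_field
    bmag2 = bx * bx + by * by + bz * bz
    s_field = np.inf
    pc = _momentum_c(T)
    if bmag2 > 0.0:
        bmag = np.sqrt(bmag2)
        cosang = (ux * bx + uy * by + uz * bz) / bmag
        sin2 = 1.0 - cosang * cosang
        if sin2 > 0.0:
            sina = np.sqrt(sin2)
            s_field = params.em_estepe * pc / (B_RIGIDITY * bmag * sina)
    if s_geom <= s_en and s_geom <= s_field:
        return s_geom, Limiter.GEOMETRY, S0, pc, s_geom
    if s_en <= s_field:
        return s_en, Limiter.ENERGY, S0, pc, s_geom
    return s_field, Limiter.FIELD, S0, pc, s_geom


def do_step(state: ElectronState, geometry: Geometry, params: TransportParams,
            stream: RandomStream) -> list[tuple[int, float]]:
    """Advance one condensed-history step; return (region, MeV) deposits."""
    kind, par, dens = geometry.packed
    T = state.kinetic_energy
    rho = dens[state.region_id]
    s, limiter, S0, pc, s_geom = _propose(state, geometry, params)

    e_mid = T - 0.5 * S0 * rho * s
    if e_mid < params.ecut:
        e_mid = params.ecut
    de = params.stopping_scale * _stopping_power(e_mid) * rho * s
    if de > T:
        de = T
    t_new = T - de

    x, y, z = state.position
    ux, uy, uz = state.direction
    bx, by, bz = params.b_field
    bmag2 = bx * bx + by * by + bz * bz
    bmag = np.sqrt(bmag2)
    if params.multiple_scattering:
        # Mass-grid scattering: deflections live on a fixed grid of the
        # electron's accumulated mass depth (one Gaussian kick of variance
        # _ms_rate(T) * dq per dq of mass traversed), applied exactly where
        # the trajectory crosses each threshold.  The angular process is a
        # function of mass depth alone, so it cannot depend on how steps are
        # subdivided at region interfaces -- the uniformity the Fano test
        # requires.  Each post-kick sub-segment is chord-capped along its own
        # direction; a capped step ends on the surface with the energy loss
        # rescaled to the path actually travelled.
        dq = params.ms_grid if params.ms_grid is not None else 0.02
        depth = state.mass_depth
        msc = state.ms_count
        traveled = 0.0
        remaining = s
        cur_chord = s_geom
        clipped = False
        while True:
            d_kick = ((msc + 1) * dq - depth) / rho
            if d_kick < 0.0:
                d_kick = 0.0
            seg = remaining
            kick = False
            if d_kick < seg:
                seg = d_kick
                kick = True
            if cur_chord < seg:
                seg = cur_chord
                kick = False
                clipped = True
            x += seg * ux
            y += seg * uy
            z += seg * uz
            if bmag2 > 0.0:
                ux, uy, uz = _deflect_field(ux, uy, uz, bx, by, bz, bmag,
                                            pc, seg, params.first_order_field)
            traveled += seg
            depth += rho * seg
            remaining -= seg
            if clipped:
                limiter = Limiter.GEOMETRY
                break
            if kick:
                msc += 1
                # energy interpolated to the kick position so the kick width
                # is a function of mass depth, not of the step grid
                t_at = T - de * (traveled / s)
                if t_at < 0.5 * params.ecut:
                    t_at = 0.5 * params.ecut
                sq = np.sqrt(_ms_rate(t_at) * dq)
                u1 = stream.uniform()
                u2 = stream.uniform()
                theta = sq * np.sqrt(-2.0 * np.log(1.0 - u1))
                if theta > np.pi:
                    theta = np.pi
                ux, uy, uz = _deflect_polar(ux, uy, uz, theta,
                                            2.0 * np.pi * u2)
                cur_chord = _chord(kind, par, x, y, z, ux, uy, uz)
            else:
                cur_chord -= seg
            if remaining <= 0.0:
                break
        if clipped and traveled < s:
            # boundary-truncated step: redo the midpoint energy loss for the
            # path actually travelled (a linear rescale of the full-step de
            # would keep the full step's midpoint stopping power and bias
            # the spectrum at interfaces)
            e_mid = T - 0.5 * S0 * rho * traveled
            if e_mid < params.ecut:
                e_mid = params.ecut
            de = params.stopping_scale * _stopping_power(e_mid) * rho * traveled
            if de > T:
                de = T
            t_new = T - de
        state.mass_depth = depth
        state.ms_count = msc
    else:
        x += s * ux
        y += s * uy
        z += s * uz
        if bmag2 > 0.0:
            ux, uy, uz = _deflect_field(ux, uy, uz, bx, by, bz, bmag,
                                        pc, s, params.first_order_field)
        state.mass_depth = state.mass_depth + rho * s
    state.position = np.array([x, y, z])
    state.direction = np.array([ux, uy, uz])
    deposits = [(state.region_id, de)]
    state.position = np.array([x, y, z])
    state.direction = np.array([ux, uy, uz])

    terminal = t_new <= params.ecut
    # nudge then relocate after every step: the offset along the outgoing
    # direction takes the endpoint off any surface it landed on, so the new
    # region tag always matches the side of the boundary being entered (a
    # grazing trajectory can otherwise sit on a face with an inconsistent tag)
    state.position = state.position + params.boundary_nudge * state.direction
    rid = int(_locate(kind, par, *state.position))
    if rid < 0:
        # left the phantom: absorb the remainder in the last region
        deposits.append((state.region_id, t_new))
        state.kinetic_energy = 0.0
        state.alive = False
        state.region_id = -1
        return deposits
    state.region_id = rid
    if terminal:
        deposits.append((state.region_id, t_new))
        state.alive = False
        state.kinetic_energy = 0.0
        return deposits
    state.kinetic_energy = t_new
    return deposits


def transport_history(emission: Emission, geometry: Geometry,
                      params: TransportParams, stream: RandomStream,
                      step_log: list | None = None) -> dict[int, float]:
    """Follow one emission to absorption; return the per-region deposit map.

    The local-absorption shortcut is checked at emission, after every region
    change and every 16th step (the vectorized engine uses the identical
    cadence, keeping the two paths step-for-step equivalent).
    """
    from .physics import min_stopping_power  # local import avoids a cycle

    state = ElectronState(position=np.array(emission.position, dtype=float),
                          direction=np.array(emission.direction, dtype=float),
                          kinetic_energy=float(emission.energy),
                          region_id=int(emission.region_id))
    from dataclasses import replace as _replace

    from .engine import resolve_ms_grid
    if params.ms_grid is None:
        params = _replace(params, ms_grid=resolve_ms_grid(params, emission.energy))
    kind, par, dens = geometry.packed
    smin_eff = 0.0
    if params.range_shortcut and params.stopping_scale > 0.0:
        smin_eff = params.stopping_scale * min_stopping_power(
            emission.energy, params.ecut)
    deposits: dict[int, float] = {}
    n_steps = 0
    check = smin_eff > 0.0
    while state.alive:
        if smin_eff > 0.0 and (check or (n_steps > 0 and n_steps % 16 == 0)):
            check = False
            d_near = _nearest_surface(kind, par, *state.position)
            rho = dens[state.region_id]
            if d_near * rho * smin_eff > state.kinetic_energy * 1.000001:
                deposits[state.region_id] = (deposits.get(state.region_id, 0.0)
                                             + state.kinetic_energy)
                state.kinetic_energy = 0.0
                state.alive = False
                break
        n_steps += 1
        if n_steps > params.max_steps:
            raise RuntimeError(
                "history exceeded the step circuit breaker; stepping bug suspected")
        before = state.kinetic_energy
        region_before = state.region_id
        s, limiter = propose_step(state, geometry, params)
        step = do_step(state, geometry, params, stream)
        for rid, de in step:
            deposits[rid] = deposits.get(rid, 0.0) + de
        if state.region_id != region_before:
            check = True
        if step_log is not None:
            step_log.append(StepRecord(region_before, s, limiter,
                                       sum(d for _, d in step), before))
    return deposits


def write_step_log(records: list[StepRecord], path):
    """Write a per-step debug log (CSV: index, region, length, limiter, dE, T)."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["step", "region_id", "length_cm", "limiter",
                         "energy_deposit_mev", "kinetic_energy_mev"])
        for i, rec in enumerate(records):
            writer.writerow([i, rec.region_id, repr(rec.length),
                             rec.limiter.name, repr(rec.energy_deposit),
                             repr(rec.kinetic_energy)])


def run_history(geometry: Geometry, source: FanoSourceConfig,
                params: TransportParams, seed: int, history: int,
                step_log: list | None = None) -> tuple[Emission, dict[int, float]]:
    """Emission + transport for one (seed, history) pair on the reference path."""
    stream = RandomStream(seed, history)
    emission = sample_emission(geometry, source, stream)
    return emission, transport_history(emission, geometry, params, stream,
                                       step_log=step_log)
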
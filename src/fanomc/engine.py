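"""Vectorized transport engine: the jitted batch loop over histories.

This executes exactly the per-step recipe of :mod:`fanomc.transport` (same
jitted primitives, same operation order, same per-history random sub-streams)
but as one compiled loop, accumulating per-region emission counts, deposits
and per-history deposit squares for the history-by-history variance estimate.

Histories are indexed absolutely: history ``h`` of base seed ``s`` always
consumes the stream derived from ``(s, h)``, so splitting a run into batches
(for progress reporting or parallel cells) cannot change any result.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
from numba import njit

from .geometry import Geometry, _chord, _locate, _nearest_surface
from .physics import B_RIGIDITY, _deflect_field, _deflect_polar, _highland_sigma, \
    _momentum_c, _ms_rate, _stopping_power
from .rng import substream_state, uniform
from .source import FanoSourceConfig
from .transport import TransportParams

def resolve_ms_grid(params: "TransportParams", energy: float) -> float:
    """Mass-depth quantum of the scattering grid for a run of energy E0.

    Defaults to 0.02 g/cm^2, reduced so a full-range track receives at least
    ~20 deflections at low energies.
    """
    if params.ms_grid is not None:
        return float(params.ms_grid)
    from .physics import csda_mass_range
    return float(min(0.02, csda_mass_range(energy, params.ecut) / 20.0))


_CTR_STEPS = 0
_CTR_ESCAPES = 1
_CTR_STEPCAP = 2


@njit(cache=True)
def _run_batch(kind, par, dens, box_half, rho_max, E0,
               em_estepe, estepe, ecut, nudge, stop_scale,
               bx, by, bz, scatter_on, first_order, max_steps, smin_eff, ms_grid,
               seed, h_start, n_histories,
               n_emit, dep_sum, dep_sq, limiter_counts, counters):
    n_reg = dens.shape[0]
    dep = np.zeros(n_reg, dtype=np.float64)
    bmag2 = bx * bx + by * by + bz * bz
    bmag = np.sqrt(bmag2)
    for h in range(h_start, h_start + n_histories):
        state = substream_state(seed, h)
        # ---- emission: density-proportional position, isotropic direction
        while True:
            x = (2.0 * uniform(state) - 1.0) * box_half[0]
            y = (2.0 * uniform(state) - 1.0) * box_half[1]
            z = (2.0 * uniform(state) - 1.0) * box_half[2]
            reg = _locate(kind, par, x, y, z)
            accept = uniform(state)
            if reg >= 0 and accept * rho_max < dens[reg]:
                break
        n_emit[reg] += 1
        cos_t = 2.0 * uniform(state) - 1.0
        phi = 2.0 * np.pi * uniform(state)
        sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
        ux = sin_t * np.cos(phi)
        uy = sin_t * np.sin(phi)
        uz = cos_t
        T = E0
        for i in range(n_reg):
            dep[i] = 0.0
        alive = True
        steps = 0
        depth = 0.0   # accumulated mass path, g/cm^2
        msc = 0       # scattering thresholds consumed
        check = smin_eff > 0.0
        # ---- condensed-history stepping
        while alive:
            # exact local absorption: checked at emission, after every region
            # change and every 16th step (same cadence as the reference path)
            if smin_eff > 0.0 and (check or (steps > 0 and steps % 16 == 0)):
                check = False
                d_near = _nearest_surface(kind, par, x, y, z)
                if d_near * dens[reg] * smin_eff > T * 1.000001:
                    dep[reg] += T
                    alive = False
                    break
            steps += 1
            if steps > max_steps:
                counters[_CTR_STEPCAP] += 1
                alive = False
                break
            rho = dens[reg]
            s_geom = _chord(kind, par, x, y, z, ux, uy, uz)
            S0 = stop_scale * _stopping_power(T)
            s_en = estepe * T / (S0 * rho) if S0 > 0.0 else 1.0e30
            pc = _momentum_c(T)
            s_field = 1.0e30
            if bmag2 > 0.0:
                cosang = (ux * bx + uy * by + uz * bz) / bmag
                sin2 = 1.0 - cosang * cosang
                if sin2 > 0.0:
                    sina = np.sqrt(sin2)
                    s_field = em_estepe * pc / (B_RIGIDITY * bmag * sina)
            if s_geom <= s_en and s_geom <= s_field:
                s = s_geom
                limiter = 0
            elif s_en <= s_field:
                s = s_en
                limiter = 1
            else:
                s = s_field
                limiter = 2
            limiter_counts[limiter] += 1

            e_mid = T - 0.5 * S0 * rho * s
            if e_mid < ecut:
                e_mid = ecut
            de = stop_scale * _stopping_power(e_mid) * rho * s
            if de > T:
                de = T
            t_new = T - de

            if scatter_on:
                # mass-grid scattering: kicks at fixed mass-depth thresholds,
                # chord-capped sub-segments (see transport.do_step)
                traveled = 0.0
                remaining = s
                cur_chord = s_geom
                clipped = False
                while True:
                    d_kick = ((msc + 1) * ms_grid - depth) / rho
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
                        ux, uy, uz = _deflect_field(ux, uy, uz, bx, by, bz,
                                                    bmag, pc, seg, first_order)
                    traveled += seg
                    depth += rho * seg
                    remaining -= seg
                    if clipped:
                        limiter = 0
                        break
                    if kick:
                        msc += 1
                        t_at = T - de * (traveled / s)
                        if t_at < 0.5 * ecut:
                            t_at = 0.5 * ecut
                        sq = np.sqrt(_ms_rate(t_at) * ms_grid)
                        u1 = uniform(state)
                        u2 = uniform(state)
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
                    # redo the midpoint energy loss for the truncated path
                    # (see transport.do_step)
                    e_mid = T - 0.5 * S0 * rho * traveled
                    if e_mid < ecut:
                        e_mid = ecut
                    de = stop_scale * _stopping_power(e_mid) * rho * traveled
                    if de > T:
                        de = T
                    t_new = T - de
            else:
                x += s * ux
                y += s * uy
                z += s * uz
                if bmag2 > 0.0:
                    ux, uy, uz = _deflect_field(ux, uy, uz, bx, by, bz, bmag,
                                                pc, s, first_order)
                depth += rho * s
            dep[reg] += de

            terminal = t_new <= ecut
            # nudge along the outgoing direction, then relocate: keeps the
            # endpoint off surfaces and the region tag on the correct side
            # (see transport.do_step)
            x += nudge * ux
            y += nudge * uy
            z += nudge * uz
            rid = _locate(kind, par, x, y, z)
            if rid < 0:
                dep[reg] += t_new
                counters[_CTR_ESCAPES] += 1
                alive = False
                break
            if rid != reg:
                check = True
                reg = rid
            if terminal:
                dep[reg] += t_new
                alive = False
                break
            T = t_new
        counters[_CTR_STEPS] += steps
        for i in range(n_reg):
            dep_sum[i] += dep[i]
            dep_sq[i] += dep[i] * dep[i]


@dataclass
class RawRun:
    """Raw tallies of one transport run (before dose analysis)."""

    n_histories: int
    energy: float
    n_emitted: np.ndarray    # per region
    dep_sum: np.ndarray      # MeV per region
    dep_sq: np.ndarray       # MeV^2 of per-history deposits
    limiter_counts: np.ndarray  # steps limited by [geometry, energy, field]
    n_steps: int
    n_escapes: int
    elapsed_s: float
    seed: int

    @property
    def total_deposit(self) -> float:
        return float(np.sum(self.dep_sum))

    @property
    def conservation_error(self) -> float:
        """Relative error of the total deposited energy vs N * E0."""
        expected = self.n_histories * self.energy
        return abs(self.total_deposit - expected) / expected

    def limiter_fractions(self) -> dict[str, float]:
        total = max(int(self.limiter_counts.sum()), 1)
        return {name: int(c) / total for name, c in
                zip(("geometry", "energy", "field"), self.limiter_counts)}

    def merged_with(self, other: "RawRun") -> "RawRun":
        if other.energy != self.energy or other.seed != self.seed:
            raise ValueError("can only merge batches of the same run")
        return RawRun(
            self.n_histories + other.n_histories, self.energy,
            self.n_emitted + other.n_emitted, self.dep_sum + other.dep_sum,
            self.dep_sq + other.dep_sq,
            self.limiter_counts + other.limiter_counts,
            self.n_steps + other.n_steps, self.n_escapes + other.n_escapes,
            self.elapsed_s + other.elapsed_s, self.seed)


def run_transport(geometry: Geometry, source: FanoSourceConfig,
                  params: TransportParams, n_histories: int, seed: int,
                  history_offset: int = 0, batches: int = 1,
                  progress: bool = False) -> RawRun:
    """Run ``n_histories`` histories through the jitted engine.

    ``history_offset`` selects the absolute history indices
    ``[offset, offset + n)``; results are independent of ``batches``.
    """
    source.validate_inside(geometry)
    kind, par, dens = geometry.packed
    box_half = np.asarray(source.box_size, dtype=float) / 2.0
    rho_max = geometry.max_density_in_box(source.box_size)
    bx, by, bz = (float(b) for b in params.b_field)
    smin_eff = 0.0
    if params.range_shortcut and params.stopping_scale > 0.0:
        from .physics import min_stopping_power
        smin_eff = params.stopping_scale * min_stopping_power(
            source.energy, params.ecut)
    ms_grid = resolve_ms_grid(params, source.energy)

    n_reg = geometry.n_regions
    n_emit = np.zeros(n_reg, dtype=np.int64)
    dep_sum = np.zeros(n_reg, dtype=np.float64)
    dep_sq = np.zeros(n_reg, dtype=np.float64)
    limiter_counts = np.zeros(3, dtype=np.int64)
    counters = np.zeros(3, dtype=np.int64)

    edges = np.linspace(0, int(n_histories), max(int(batches), 1) + 1).astype(np.int64)
    iterator = range(len(edges) - 1)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="transport", unit="batch")
    t0 = time.perf_counter()
    for b in iterator:
        n_b = int(edges[b + 1] - edges[b])
        if n_b == 0:
            continue
        _run_batch(kind, par, dens, box_half, rho_max, float(source.energy),
                   params.em_estepe, params.estepe, params.ecut,
                   params.boundary_nudge, params.stopping_scale,
                   bx, by, bz, params.multiple_scattering,
                   params.first_order_field, params.max_steps, smin_eff,
                   ms_grid,
                   int(seed), int(history_offset + edges[b]), n_b,
                   n_emit, dep_sum, dep_sq, limiter_counts, counters)
    elapsed = time.perf_counter() - t0
    if counters[_CTR_STEPCAP] > 0:
        raise RuntimeError(
            f"{int(counters[_CTR_STEPCAP])} histories exceeded the step "
            "circuit breaker; stepping bug suspected")
    return RawRun(int(n_histories), float(source.energy), n_emit, dep_sum,
                  dep_sq, limiter_counts, int(counters[_CTR_STEPS]),
                  int(counters[_CTR_ESCAPES]), elapsed, int(seed))
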
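"""Condensed-history stepping: limits, energy bookkeeping, helix, equivalence."""

import numpy as np
import pytest

from fanomc import (Box, ElectronState, FanoSourceConfig, Geometry, Limiter,
                    RandomStream, TransportParams, collision_stopping_power,
                    do_step, gyroradius, propose_step, run_history,
                    run_transport, transport_history)
from fanomc.physics import _momentum_c
from fanomc.source import Emission


@pytest.fixture(scope="module")
def big_water_box():
    return Geometry(Box(center=(0, 0, 0), half=(50.0, 50.0, 50.0)), 1.0)


@pytest.fixture(scope="module")
def big_air_box():
    return Geometry(Box(center=(0, 0, 0), half=(200.0, 200.0, 200.0)), 0.0012048)


def _state(geometry, position, direction, energy):
    p = np.asarray(position, float)
    u = np.asarray(direction, float)
    return ElectronState(p, u / np.linalg.norm(u), energy,
                         geometry.locate(p))


class TestProposeStep:
    def test_energy_limited_in_water(self, big_water_box):
        st = _state(big_water_box, (0, 0, 0), (0, 0, 1), 1.0)
        s, lim = propose_step(st, big_water_box, TransportParams())
        assert lim == Limiter.ENERGY
        assert s == pytest.approx(0.25 / collision_stopping_power(1.0),
                                  rel=1e-12)
        assert s == pytest.approx(0.1335, rel=1e-3)

    def test_field_limited_in_air(self, big_air_box):
        st = _state(big_air_box, (0, 0, 0), (0, 1, 0), 1.0)
        par = TransportParams(b_field=(1.5, 0, 0), em_estepe=0.01)
        s, lim = propose_step(st, big_air_box, par)
        assert lim == Limiter.FIELD
        assert s == pytest.approx(3.1621e-3, rel=1e-4)

    def test_geometry_limited_near_wall(self, big_water_box):
        st = _state(big_water_box, (0, 0, 49.999), (0, 0, 1), 1.0)
        s, lim = propose_step(st, big_water_box, TransportParams())
        assert lim == Limiter.GEOMETRY
        assert s == pytest.approx(1e-3, rel=1e-9)

    def test_field_limit_independent_of_density(self, big_water_box,
                                                big_air_box):
        # the gyroradius knows nothing about the medium
        par = TransportParams(b_field=(1.5, 0, 0), em_estepe=0.005)
        expected = 0.005 * gyroradius(1.0, 1.5, 1.0)
        for geom in (big_water_box, big_air_box):
            st = _state(geom, (0, 0, 0), (0, 0, 1), 1.0)
            s_field = min(propose_step(st, geom, par)[0], expected * 2)
            assert s_field == pytest.approx(expected, rel=1e-12)


class TestCsdaPath:
    @pytest.mark.parametrize("estepe, tol", [(0.25, 1e-2), (0.005, 1e-4)])
    def test_total_path_matches_quadrature(self, big_water_box, estepe, tol):
        from scipy.integrate import quad
        par = TransportParams(estepe=estepe, multiple_scattering=False,
                              range_shortcut=False)
        emission = Emission(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0, 1.0)
        log = []
        transport_history(emission, big_water_box, par, RandomStream(1),
                          step_log=log)
        path = sum(rec.length for rec in log)
        oracle, _ = quad(lambda t: 1.0 / collision_stopping_power(t),
                         par.ecut, 1.0, limit=200)
        assert path == pytest.approx(oracle, rel=tol)


class TestEnergyBookkeeping:
    def test_per_history_conservation_is_exact(self, slab_geometry):
        src = FanoSourceConfig(energy=1.0, box_size=(2.5, 2.5, 2.5))
        par = TransportParams(b_field=(1.5, 0, 0), em_estepe=0.05)
        for h in range(30):
            _, deposits = run_history(slab_geometry, src, par, seed=9,
                                      history=h)
            assert sum(deposits.values()) == pytest.approx(1.0, rel=1e-12)

    def test_immediate_absorption_below_cutoff_margin(self, big_water_box):
        par = TransportParams()
        emission = Emission(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0,
                            par.ecut * 1.01)
        deposits = transport_history(emission, big_water_box, par,
                                     RandomStream(2))
        assert set(deposits) == {0}
        assert deposits[0] == pytest.approx(par.ecut * 1.01, rel=1e-12)

    def test_all_energy_stays_in_huge_homogeneous_phantom(self, big_water_box):
        par = TransportParams()
        emission = Emission(np.zeros(3), np.array([0.0, 0.0, 1.0]), 0, 1.0)
        deposits = transport_history(emission, big_water_box, par,
                                     RandomStream(3))
        assert set(deposits) == {0}


class TestHelixLimit:
    def test_low_density_trajectory_approaches_analytic_helix(self):
        # in a near-vacuum medium with scattering off, the chordwise polygon
        # converges to the gyration circle: after a path of pi r_G the
        # transverse displacement is the diameter 2 r_G
        geom = Geometry(Box(center=(0, 0, 0), half=(50.0, 50.0, 50.0)), 1e-9)
        par = TransportParams(b_field=(1.5, 0, 0), em_estepe=0.005,
                              multiple_scattering=False, range_shortcut=False)
        st = _state(geom, (0, 0, 0), (0, 1, 0), 1.0)
        r_g = gyroradius(1.0, 1.5, 1.0)
        stream = RandomStream(0)
        path = 0.0
        target = np.pi * r_g
        while path < target:
            s, _ = propose_step(st, geom, par)
            do_step(st, geom, par, stream)
            path += s  # the final step overshoots by < 0.005 r_G (2nd order)
        displacement = np.linalg.norm(st.position)
        assert displacement == pytest.approx(2.0 * r_g, rel=2e-3)

    def test_step_lengths_never_exceed_field_limit(self, slab_geometry):
        src = FanoSourceConfig(energy=1.0, box_size=(2.5, 2.5, 2.5))
        par = TransportParams(b_field=(1.5, 0, 0), em_estepe=0.01)
        b_hat = np.array([1.0, 0.0, 0.0])
        for h in range(5):
            stream = RandomStream(33, h)
            from fanomc.source import sample_emission
            em = sample_emission(slab_geometry, src, stream)
            st = ElectronState(np.array(em.position), np.array(em.direction),
                               em.energy, em.region_id)
            steps = 0
            while st.alive and steps < 5000:
                steps += 1
                sina = np.linalg.norm(np.cross(st.direction, b_hat))
                s, _ = propose_step(st, slab_geometry, par)
                if sina > 0:
                    r_g = gyroradius(st.kinetic_energy, 1.5, sina)
                    assert s <= 0.01 * r_g * (1 + 1e-12)
                do_step(st, slab_geometry, par, stream)


class TestEngineEquivalence:
    @pytest.mark.parametrize("kw", [
        dict(b_field=(1.5, 0.0, 0.0), em_estepe=0.05),
        dict(b_field=(1.5, 0.0, 0.0), em_estepe=0.01,
             multiple_scattering=False),
        dict(),
        dict(stopping_scale=2.0),
    ])
    def test_reference_and_vectorized_paths_agree(self, slab_geometry, kw):
        src = FanoSourceConfig(energy=1.0, box_size=(2.5, 2.5, 2.5))
        par = TransportParams(**kw)
        n = 150
        raw = run_transport(slab_geometry, src, par, n, seed=21)
        dep_py = np.zeros(slab_geometry.n_regions)
        for h in range(n):
            _, deposits = run_history(slab_geometry, src, par, seed=21,
                                      history=h)
            for rid, de in deposits.items():
                dep_py[rid] += de
        assert np.allclose(dep_py, raw.dep_sum, rtol=1e-12, atol=1e-14)

    def test_batching_does_not_change_results(self, slab_geometry):
        src = FanoSourceConfig(energy=1.0, box_size=(2.5, 2.5, 2.5))
        par = TransportParams(b_field=(1.5, 0, 0), em_estepe=0.05)
        a = run_transport(slab_geometry, src, par, 2000, seed=4, batches=1)
        b = run_transport(slab_geometry, src, par, 2000, seed=4, batches=7)
        assert np.array_equal(a.dep_sum, b.dep_sum)
        assert np.array_equal(a.n_emitted, b.n_emitted)

    @pytest.mark.parametrize("b_field", [(1.5, 0.0, 0.0), (0.0, 0.0, 0.0)])
    def test_range_shortcut_is_exact(self, chamber_geometry, b_field):
        src = FanoSourceConfig(energy=1.0, box_size=(5.0, 5.0, 7.0))
        par_on = TransportParams(b_field=b_field, em_estepe=0.05)
        par_off = TransportParams(b_field=b_field, em_estepe=0.05,
                                  range_shortcut=False)
        a = run_transport(chamber_geometry, src, par_on, 20_000, seed=8)
        b = run_transport(chamber_geometry, src, par_off, 20_000, seed=8)
        # identical up to summation order (E0 lands in one term instead of
        # hundreds of partial deposits)
        assert np.allclose(a.dep_sum, b.dep_sum, rtol=1e-12, atol=0.0)
        assert a.n_steps < 0.2 * b.n_steps  # and it is much cheaper

    def test_escapes_are_counted_when_margin_is_too_small(self):
        geom = Geometry(Box(center=(0, 0, 0), half=(0.7, 0.7, 0.7)), 1.0)
        src = FanoSourceConfig(energy=1.0, box_size=(1.2, 1.2, 1.2))
        raw = run_transport(geom, src, TransportParams(), 2000, seed=1)
        assert raw.n_escapes > 0
        assert raw.conservation_error < 1e-9  # energy still conserved

    def test_run_conservation_and_no_escapes_on_fixture(self, slab_geometry):
        src = FanoSourceConfig(energy=1.0, box_size=(2.5, 2.5, 2.5))
        par = TransportParams(b_field=(1.5, 0, 0), em_estepe=0.05)
        raw = run_transport(slab_geometry, src, par, 50_000, seed=12)
        assert raw.n_escapes == 0
        assert raw.conservation_error < 1e-9


class TestParamValidation:
    @pytest.mark.parametrize("kw", [
        dict(em_estepe=0.0), dict(em_estepe=1.5), dict(estepe=1.0),
        dict(ecut=0.0), dict(boundary_nudge=0.0), dict(stopping_scale=-1.0),
        dict(b_field=(1.0, 0.0)),
    ])
    def test_bad_knobs_rejected(self, kw):
        with pytest.raises(ValueError):
            TransportParams(**kw)
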
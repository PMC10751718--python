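"""Shipped study geometries: chamber-like, diode-like and slab fixtures.

The fixtures are deliberately simplified analogues of a vented thimble
ionization chamber and a silicon diode detector, preserving the printed
characteristic dimensions (0.07 cm^3 air cavity, 0.04 cm radius aluminium
electrode, 3.4e-4 cm^3 silicon volume) while replacing the proprietary
many-region CAD models with ~5-10 analytic regions.  Every material is
water-equivalent: regions differ only in mass density, which is exactly the
Fano substitution the consistency test requires.

Densities are fixture parameters in g/cm^3 (air 0.0012048, PMMA 1.19,
graphite 1.70, aluminium 2.70, epoxy 1.20, silicon 2.33).  The detector axis
is z, the origin sits at the sensitive-volume center, and the study field
points along x.
"""

from __future__ import annotations

import numpy as np

from .geometry import Box, Geometry, ZCylinder

RHO_AIR = 0.0012048
RHO_PMMA = 1.19
RHO_GRAPHITE = 1.70
RHO_ALUMINIUM = 2.70
RHO_EPOXY = 1.20
RHO_SILICON = 2.33

#: sensitive air volume of the chamber-like fixture [cm^3]
CAVITY_VOLUME = 0.07
#: central electrode radius [cm]
ELECTRODE_RADIUS = 0.04
#: sensitive silicon volume of the diode-like fixture [cm^3]
CHIP_VOLUME = 3.4e-4

_ELECTRODE_Z = (-0.38, -0.18)
_CAVITY_Z = (-0.40, -0.15)


def _cavity_radius() -> float:
    """Radius making the net air volume (cylinder minus electrode) 0.07 cm^3."""
    h = _CAVITY_Z[1] - _CAVITY_Z[0]
    v_electrode = np.pi * ELECTRODE_RADIUS ** 2 * (_ELECTRODE_Z[1] - _ELECTRODE_Z[0])
    return float(np.sqrt((CAVITY_VOLUME + v_electrode) / (np.pi * h)))


def chamber_like(phantom_size=(10.0, 10.0, 12.0)) -> Geometry:
    """Vented-chamber analogue: air cavity + electrode + wall + stem air gaps.

    Eight regions: water phantom, PMMA wall cylinder, graphite liner, the
    0.07 cm^3 air cavity with a 0.04 cm radius aluminium electrode, and three
    small air gaps buried in the PMMA stem (the low-density stem volumes that
    make the field step restriction bite hardest).
    """
    phantom = Box(center=(0.0, 0.0, 0.0),
                  half=tuple(np.asarray(phantom_size, float) / 2.0))
    r_cav = _cavity_radius()
    regions = [
        ("wall_pmma", ZCylinder(0.0, 0.0, 0.40, -0.50, 2.50), RHO_PMMA),
        ("liner_graphite", ZCylinder(0.0, 0.0, 0.33, -0.43, 0.30), RHO_GRAPHITE),
        ("cavity_air", ZCylinder(0.0, 0.0, r_cav, *_CAVITY_Z), RHO_AIR),
        ("electrode_al", ZCylinder(0.0, 0.0, ELECTRODE_RADIUS, *_ELECTRODE_Z),
         RHO_ALUMINIUM),
        ("stem_gap_1", ZCylinder(0.0, 0.0, 0.25, 0.60, 0.64), RHO_AIR),
        ("stem_gap_2", ZCylinder(0.0, 0.0, 0.25, 1.20, 1.24), RHO_AIR),
        ("stem_gap_3", ZCylinder(0.0, 0.0, 0.25, 1.80, 1.84), RHO_AIR),
    ]
    return Geometry(phantom, 1.0, regions, phantom_name="phantom_water")


def diode_like(phantom_size=(10.0, 10.0, 12.0)) -> Geometry:
    """Diode analogue: 3.4e-4 cm^3 silicon chip in epoxy with one air gap."""
    phantom = Box(center=(0.0, 0.0, 0.0),
                  half=tuple(np.asarray(phantom_size, float) / 2.0))
    chip_half_height = 0.005
    r_chip = float(np.sqrt(CHIP_VOLUME / (np.pi * 2.0 * chip_half_height)))
    regions = [
        ("housing_pmma", ZCylinder(0.0, 0.0, 0.35, -0.80, 0.80), RHO_PMMA),
        ("epoxy", ZCylinder(0.0, 0.0, 0.25, -0.50, 0.50), RHO_EPOXY),
        ("air_gap", ZCylinder(0.0, 0.0, 0.20, 0.10, 0.16), RHO_AIR),
        ("chip_si", ZCylinder(0.0, 0.0, r_chip, -chip_half_height, chip_half_height),
         RHO_SILICON),
    ]
    return Geometry(phantom, 1.0, regions, phantom_name="phantom_water")


def slab(gap_density: float = RHO_AIR, phantom_size=(4.0, 4.0, 4.0)) -> Geometry:
    """Three-layer sandwich (water / low-density gap / water) for oracle tests.

    The layered stack sits entirely inside the source box so every layer is a
    charged-particle-equilibrium region; the gap spans the full stack cross
    section, which gives it far better crossing statistics than a thimble
    cavity.
    """
    phantom = Box(center=(0.0, 0.0, 0.0),
                  half=tuple(np.asarray(phantom_size, float) / 2.0))
    half_xy = (0.6, 0.6)
    regions = [
        ("water_upstream", Box(center=(0.0, 0.0, -0.30), half=(*half_xy, 0.20)), 1.0),
        ("gap", Box(center=(0.0, 0.0, 0.0), half=(*half_xy, 0.10)), gap_density),
        ("water_downstream", Box(center=(0.0, 0.0, 0.30), half=(*half_xy, 0.20)), 1.0),
    ]
    return Geometry(phantom, 1.0, regions, phantom_name="phantom_water")


_BUILDERS = {"chamber_like": chamber_like, "diode_like": diode_like, "slab": slab}


def get_fixture(name: str, **kwargs) -> Geometry:
    """Build a shipped fixture by name (chamber_like, diode_like, slab)."""
    try:
        return _BUILDERS[name](**kwargs)
    except KeyError:
        raise KeyError(
            f"unknown fixture '{name}'; available: {sorted(_BUILDERS)}") from None


def study_conditions(energy: float):
    """Phantom and source-box sizes used in the Fano studies for an energy.

    (12 x 10 x 10) cm^3 phantom with a (7 x 5 x 5) cm^3 source box for
    electrons up to 1 MeV, (20 x 20 x 20) with (10 x 9 x 9) for 6 MeV; the
    long axis is the detector/stem axis z.
    """
    if energy <= 1.0:
        return (10.0, 10.0, 12.0), (5.0, 5.0, 7.0)
    return (20.0, 20.0, 20.0), (9.0, 9.0, 10.0)


def source_box_margin(geometry: Geometry, box_size) -> float:
    """Smallest phantom margin around a centered source box (cm)."""
    half = np.asarray(box_size, float) / 2.0
    return float(np.min(np.asarray(geometry.phantom.half) - half))
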
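"""High-level facade: configure a Fano cavity test, run it, get a result.

    >>> from fanomc import FanoSimulation
    >>> sim = FanoSimulation.from_fixture("slab", energy=1.0, b_field=(1.5, 0, 0),
    ...                                   em_estepe=0.01)
    >>> result = sim.run(n_histories=100_000, seed=42)
    >>> print(result.summary())

``FanoSimulation`` bundles the geometry, the Fano source and the transport
parameters; :meth:`run` executes the vectorized engine and returns a
:class:`~fanomc.analysis.FanoResult` with per-region doses, deviations,
uncertainties and a ``summary()``.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import yaml

from . import fixtures
from .analysis import PASS_K_SIGMA, PASS_TOLERANCE, FanoResult, build_result
from .engine import run_transport
from .geometry import Geometry, load_geometry
from .source import FanoSourceConfig
from .transport import TransportParams


class FanoSimulation:
    """A configured Fano cavity test: geometry + source + transport knobs."""

    def __init__(self, geometry: Geometry, source: FanoSourceConfig,
                 params: TransportParams | None = None):
        self.geometry = geometry
        self.source = source
        self.params = params if params is not None else TransportParams()
        source.validate_inside(geometry)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_fixture(cls, name: str, energy: float = 1.0,
                     source_box=None, phantom_size=None,
                     **param_kwargs) -> "FanoSimulation":
        """Build from a shipped fixture with study-standard phantom/source sizes."""
        default_phantom, default_box = fixtures.study_conditions(energy)
        if name == "slab":
            geometry = fixtures.slab() if phantom_size is None \
                else fixtures.slab(phantom_size=phantom_size)
            box = source_box if source_box is not None else (2.5, 2.5, 2.5)
        else:
            geometry = fixtures.get_fixture(
                name, phantom_size=phantom_size or default_phantom)
            box = source_box if source_box is not None else default_box
        source = FanoSourceConfig(energy=energy, box_size=tuple(box))
        return cls(geometry, source, TransportParams(**param_kwargs))

    @classmethod
    def from_config(cls, path) -> "FanoSimulation":
        """Build from a YAML run configuration (see docs/run_config_schema.md)."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "fixture" in doc:
            geometry = fixtures.get_fixture(
                doc["fixture"],
                **({"phantom_size": tuple(doc["phantom_size"])}
                   if "phantom_size" in doc else {}))
        else:
            geometry = load_geometry(doc["geometry"])
        source = FanoSourceConfig(energy=float(doc["energy"]),
                                  box_size=tuple(doc["source_box"]))
        keys = ("em_estepe", "estepe", "ecut", "boundary_nudge",
                "stopping_scale", "multiple_scattering", "first_order_field")
        params = TransportParams(
            b_field=tuple(doc.get("b_field", (0.0, 0.0, 0.0))),
            **{k: doc[k] for k in keys if k in doc})
        sim = cls(geometry, source, params)
        sim.default_histories = int(doc.get("histories", 100_000))
        sim.default_seed = int(doc.get("seed", 0))
        return sim

    def with_params(self, **changes) -> "FanoSimulation":
        """A copy of this simulation with transport knobs replaced."""
        return FanoSimulation(self.geometry, self.source,
                              replace(self.params, **changes))

    # -- execution ---------------------------------------------------------

    def run(self, n_histories: int | None = None, seed: int | None = None,
            history_offset: int = 0, batches: int = 1, progress: bool = False,
            tolerance: float = PASS_TOLERANCE,
            k_sigma: float = PASS_K_SIGMA,
            expectation: str = "expected") -> FanoResult:
        n = int(n_histories if n_histories is not None
                else getattr(self, "default_histories", 100_000))
        s = int(seed if seed is not None else getattr(self, "default_seed", 0))
        raw = run_transport(self.geometry, self.source, self.params, n, s,
                            history_offset=history_offset, batches=batches,
                            progress=progress)
        result = build_result(self.geometry, raw, self.params, seed=s,
                              tolerance=tolerance, k_sigma=k_sigma,
                              source_box=self.source.box_size,
                              expectation=expectation)
        if raw.n_escapes > 0:
            import warnings
            warnings.warn(
                f"{raw.n_escapes} histories escaped the phantom; the source "
                "box margin is smaller than the electron range and the Fano "
                "expectation is biased", stacklevel=2)
        return result

    def __repr__(self):
        return (f"FanoSimulation({self.geometry!r}, E0={self.source.energy} MeV, "
                f"B={tuple(self.params.b_field)} T, "
                f"em_estepe={self.params.em_estepe})")
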
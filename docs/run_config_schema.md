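# Run configuration files

`FanoSimulation.from_config(path)` and `fanomc run --config path` accept a
YAML run description.  Command-line options override config values; config
values override package defaults.

```yaml
# geometry: either a shipped fixture ...
fixture: chamber_like          # chamber_like | diode_like | slab
phantom_size: [10.0, 10.0, 12.0]   # optional fixture override
# ... or an external geometry file:
# geometry: path/to/geometry.yaml

# Fano source
energy: 1.0                    # MeV, monoenergetic
source_box: [5.0, 5.0, 7.0]    # cm, centered on the origin

# transport knobs (defaults shown)
b_field: [1.5, 0.0, 0.0]       # tesla; x is perpendicular to the detector axis
em_estepe: 0.25                # magnetic step cap, fraction of the gyroradius
estepe: 0.25                   # max fractional energy loss per step
ecut: 0.001                    # kinetic cutoff, MeV
multiple_scattering: true
stopping_scale: 1.0            # global stopping-power multiplier (diagnostics)
first_order_field: false       # first-order deflection instead of exact rotation
ms_grid: null                  # scattering mass-depth quantum, g/cm^2 (null: auto)

# run size
histories: 1000000
seed: 42
```
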
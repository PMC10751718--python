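# Geometry description files

A geometry is a YAML document: a rectangular water-equivalent phantom plus an
ordered list of shaped regions.  Later entries carve out earlier ones
(last-listed wins), so nested detector parts are described outside-in.
Lengths are cm, densities g/cm^3.  The detector symmetry axis is z.

```yaml
phantom:
  name: phantom_water        # optional, default "phantom"
  center: [0.0, 0.0, 0.0]    # optional, default origin
  size: [10.0, 10.0, 12.0]   # full edge lengths (x, y, z)
  density: 1.0
regions:
  - name: wall_pmma
    shape: cylinder          # finite cylinder along z
    center: [0.0, 0.0]       # axis position (x, y)
    radius: 0.40
    z: [-0.50, 2.50]
    density: 1.19
  - name: cavity_air
    shape: cylinder
    center: [0.0, 0.0]
    radius: 0.3007
    z: [-0.40, -0.15]
    density: 0.0012048
  - name: some_annulus
    shape: shell             # annular cylinder along z
    center: [0.0, 0.0]
    radius: [0.20, 0.30]     # [inner, outer]
    z: [0.0, 1.0]
    density: 1.7
  - name: some_box
    shape: box
    center: [0.0, 0.0, 0.0]  # box center (x, y, z)
    size: [1.2, 1.2, 0.2]    # full edge lengths
    density: 1.0
```

The loader validates on load and rejects files whose regions

* are not provably inside the phantom,
* overlap without provable nesting (every pair of shapes must be provably
  nested or provably disjoint),
* would completely swallow an earlier region, or
* leave an earlier region with no remaining volume.

Region volumes and masses follow in closed form from the containment tree;
the net volumes always tile the phantom exactly.  `fanomc validate-geometry
FILE` runs these checks and prints the per-region mass table.

The shipped fixtures live in `src/fanomc/fixtures/*.yaml` and reproduce the
builders in `fanomc.fixtures` exactly (a test asserts it).
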
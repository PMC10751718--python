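# Methods

## The consistency test

`fanomc` simulates electron transport through water-equivalent multi-region
detector geometries and checks the simulated absorbed dose of every region
against the analytic expectation of the Fano theorem.  Under charged-particle
equilibrium and interaction cross sections that are uniform per unit mass,
the charged-particle fluence is independent of the density distribution.  A
*Fano source* — monoenergetic electrons emitted isotropically with a position
density proportional to the local mass density — realizes these conditions
even in a uniform external magnetic field, because the Lorentz force is the
only term of the equation of motion that does not scale with density and an
isotropic, spatially uniform (per mass) source makes the equilibrium argument
field-independent.  The expected dose of region *i* is then

    D_i = n_i E0 / m_i

with `n_i` the number of source electrons emitted in the region, `E0` the
initial kinetic energy and `m_i` the region mass.  For a region lying fully
inside the source box this is the uniform `N E0 / M_box`.  Any statistically
resolved deviation of the Monte Carlo dose from `D_i` is a transport-algorithm
artifact, not physics — which is what makes the test useful for validating
condensed-history (CH) stepping in magnetic fields, where steps must resolve
the gyration of the trajectory (radius `r_G[cm] = pc[MeV]/(2.99792 |B|[T]
sin angle)`).

The central knob is the magnetic step-size restriction **EM ESTEPE**: the CH
step length in a field is capped at `em_estepe * r_G`.  The package
reproduces the central phenomenology: with the cap loose (0.25) the dose in
low-density regions — above all the chamber's air cavity — deviates by
percent; tightening it to 0.01 (1 MeV) or 0.005 (0.1 MeV) restores
sub-tolerance agreement in every region.

## Expected emission counts

`n_i` can be the *realized* (sampled) count or the analytic *expected* count
`N * m_i(in box) / M_box`.  The default is the expected count: for a
0.07 cm^3 air cavity the realized count at desk-scale history numbers is
O(1)–O(100) and its Poisson noise would dominate the deviation, defeating the
purpose of the comparison.  The expected count is the classic
uniform-dose-per-mass form of the test; the realized-count convention remains
available (`expectation="realized"`) and is recorded in the run metadata.
The closed-form region masses inside the source box require each non-phantom
region to lie provably inside (or outside) the box, which the shipped
fixtures guarantee.

## The stepping engine

One CH step, in order:

1. **Step length** `s = min(geometry chord, estepe*T/(S rho),
   em_estepe*r_G)`, recording which bound was active.  The chord query
   treats every shape surface as a stopping plane, so a step never spans two
   regions.
2. **Energy loss** `dE = S(E_mid) rho s` with the one-term midpoint energy
   `E_mid = T - S(T) rho s / 2`, deposited in the current region.  `S` is the
   Moller/ICRU-form collision stopping power of water without the density
   effect (water `Z/A = 0.55509`, `I = 75 eV`); its absolute accuracy is a
   sanity band (within ~3 % of published tables below ~2 MeV), not a
   contract — the Fano expectation is independent of the cross-section model,
   and a dedicated test re-runs the slab with the stopping power doubled.
3. **Field deflection**: exact rotation of the direction about B-hat by the
   pitch-independent gyration angle `alpha = s * 2.99792 |B| / pc`, with the
   sense of `du/ds ~ +u x B`.  A first-order single-term update is available
   behind a flag for step-size comparison studies.  The position advances
   along straight chords (the CH approximation); under-resolved curvature is
   exactly the artifact the test quantifies, and `em_estepe` controls it.
4. **Multiple scattering** (see below).
5. **Boundary handling**: after every step the endpoint is nudged 1e-8 cm
   along the outgoing direction and relocated.  Region membership uses exact
   closed boundaries (an exactly-on-surface point belongs to the innermost
   shape); the unconditional nudge guarantees the region tag always matches
   the side of a surface the electron is entering.  This combination was
   chosen after an earlier tolerance-based tie-break (assigning points within
   1e-10 cm of a surface to the inner region) produced stale tags for
   grazing trajectories — an electron parked on a face with an outward
   velocity would take one enormous wrong-density step.
6. **Termination**: when the remaining energy falls to the cutoff (1 keV
   kinetic) it is deposited at the endpoint and the history ends.  There are
   no secondary particles: continuous slowing-down with local absorption
   keeps the analytic expectation exactly applicable.

### Multiple scattering on a mass-depth grid

Angular deflections do *not* happen once per CH step.  Each electron carries
an accumulated mass depth (g/cm^2 along its track) and receives one Gaussian
kick — polar angle Rayleigh-distributed with variance `K(T) * dq`, uniform
azimuth — every time the depth crosses a multiple of the grid quantum `dq`,
applied exactly at the crossing position.  `K(T) = (13.6 MeV /(beta pc))^2 /
X0` is the Rossi–Greisen angular diffusion rate of water (`X0 = 36.08
g/cm^2`), evaluated at the energy interpolated to the kick position; kicks
are clamped at pi.  Sub-segments that follow a kick are chord-capped along
their own direction, and a boundary-truncated step recomputes its midpoint
energy loss for the path actually travelled.

This design is deliberate and load-bearing.  The obvious alternative — one
Highland-width kick per CH step — makes the *discrete* angular process depend
on how steps are subdivided, and steps are subdivided precisely at region
interfaces (chords) and wherever the field cap bites.  Because the Highland
width is not exactly proportional to the square root of the step's mass
thickness (logarithmic thickness correction, clamps), truncated near-boundary
steps carry a different scattering power per unit mass than bulk steps: a
scattering-anomalous skin forms on each side of every interface and the slab
test fails at the percent level *even without a field* (measured -1.5 % to
-6 % gap bias at ESTEPE = 0.25 depending on the kick-placement variant).
With kicks tied to mass depth alone, no step subdivision can move, resize or
split a deflection, so the angular process is identical per unit mass in
every region — the uniformity premise of the theorem holds for the discrete
algorithm itself — and the field-free slab and diode baselines pass the
resolved-deviation test at ESTEPE = 0.25.  One granularity artifact
remains: pooled multi-seed measurements resolve a small positive dose excess
in the slab's air gap at B = 0 (+0.34 +- 0.09 % at ESTEPE = 0.25, +0.20 +-
0.11 % at ESTEPE = 0.01, decreasing only weakly with the grid quantum
between 0.005 and 0.08 g/cm^2) — a floor of roughly +0.25 % that single
desk-scale runs (gap sigma >= 0.2 %) are only marginally sensitive to.  The
in-volume wiggle missing from a node-free crossing is provably negligible
(the gap's full-thickness scattering variance is 8e-4 rad^2, a 2e-4 path
effect), so the likely mechanism is the granularity of the nodal angular
walk distorting the near-grazing entrance flux, to which a thin volume's
mean chord — and hence its dose — is logarithmically sensitive; consistent
with the observed slow decrease with the quantum.  The public
`multiple_scattering_sigma` (Highland form with the conventional 0.25 bracket
clamp and 0.5 rad cap) is kept as the per-thickness width formula for
analysis use; the transport engine does not sample from it, for the reason
above.

The default quantum is `dq = min(0.02 g/cm^2, R_CSDA(E0)/20)`: about 22
kicks along a 1 MeV track, about 20 along a 0.1 MeV track.  In air a track
segment shorter than `dq/rho` (17 cm at `dq = 0.02`) usually contains no
threshold, so in-cavity scattering becomes shot noise — uniform per mass and
therefore harmless to the test, but not a faithful small-angle model of a
single crossing.

### Exact local absorption

An electron of energy `T` in a region of density `rho` can travel at most
`T/(rho S_min)` (no secondaries, strictly positive stopping power), so if no
shape surface lies within that distance its entire remaining energy provably
lands in the current region.  The engine deposits it and ends the history —
checked at emission, after every region change and every 16th step.  This is
an algebraic shortcut, not a variance-reduction scheme: per-region doses are
bit-identical with the shortcut on or off (a test asserts this), only the
step count changes.  It is what makes desk-scale history counts feasible: at
0.1 MeV ~99.9 % of histories never approach a surface, at 1 MeV ~96 %.

## Statistics

Per-region uncertainties are history-by-history: the accumulation unit is
the per-history deposit, `sigma_rel = sqrt((sum d^2 - (sum d)^2/N)/(N(N-1)))
/ mean`.  A region passes individually when `|delta| <= max(0.1 %,
2 sigma)` — 0.1 % is the conventional consistency bar, the 2-sigma guard is
this package's explicit rule for folding noise into it.

The whole-geometry verdict needs care: with ~8 regions tested
simultaneously, a per-region 2-sigma guard false-alarms on `1 - 0.9545^8 ~
31 %` of runs even for a perfect engine.  The headline quantity is therefore
the **resolved deviation**: `max_i max(|delta_i| - k_n sigma_i, 0)` with
`k_n` the Sidak-corrected two-sided normal quantile at family-wise level 1 %
(k = 3.23 for 8 regions, 2.58 for one).  Zero means every region is
consistent with the Fano dose at that sample size; a positive value is the
deviation the data actually establishes.  Per-region tables keep the plain
2-sigma flags.

Efficiency uses the standard figure of merit `1/(T sigma^2)` with `T` in
hours and `sigma` in percent.

## Random numbers

xorshift128+ streams, one per history, with both state words derived from
`(seed, history_index)` by splitmix64.  Results are therefore independent of
batching, and the pure-python reference transport consumes bit-identical
streams to the vectorized engine — an equivalence test pins the two paths to
identical per-region deposits.  A hand-rolled generator is used because the
jitted kernel needs a cheaply re-seedable counter-based stream inside the
compiled loop.

## Fixtures and study conditions

All media are water-equivalent: regions differ only in mass density (air
0.0012048, PMMA 1.19, graphite 1.70, aluminium 2.70, epoxy 1.20, silicon
2.33 g/cm^3).

* **chamber_like** (8 regions): water phantom, PMMA wall cylinder (r 0.40 cm,
  3 cm long), graphite liner, a 0.07 cm^3 air cavity (cylinder r ~ 0.30 cm,
  height 0.25 cm) holding a 0.04 cm radius aluminium electrode, and three
  0.04 cm thick air disks buried in the PMMA stem — the small stem air
  volumes where the field step restriction bites hardest.
* **diode_like** (5 regions): 3.4e-4 cm^3 silicon chip (r ~ 0.104 cm, 0.01 cm
  thick) in epoxy with a PMMA housing and one air gap.
* **slab** (4 regions): water / air-gap / water sandwich, the gap spanning
  the full 1.2 x 1.2 cm^2 stack cross-section, inside a 4 cm water cube —
  the oracle geometry, with far better cavity-crossing statistics than a
  thimble cavity.

Study conditions: monoenergetic electrons at 0.1, 1 or 6 MeV; phantom
(10 x 10 x 12) cm^3 with a (5 x 5 x 7) cm^3 source box up to 1 MeV and
(20 x 20 x 20) / (9 x 9 x 10) cm^3 at 6 MeV (source-box-to-wall margins
exceed the CSDA range, so the escape counter must stay zero — it is asserted);
B = 1.5 T along x, perpendicular to the detector axis z; ESTEPE = 0.25;
EM ESTEPE swept from 0.25 down to 0.005; cutoff 1 keV.

## Problem sizes

The shipped analyses are desk-scale by design: 2e5–2e7 histories per cell
(seconds to ~2 minutes on one CPU), 1e8 for the 0.1 MeV chamber cell.  At
these sizes the per-region sigma is ~2e-5 for the phantom, ~0.1–0.3 % for
slab layers and the chamber wall, ~1.5 % for the 0.07 cm^3 cavity at 1 MeV,
and tens of percent for air regions at 0.1 MeV, where the cavity dose is
carried by a handful of magnetically trapped electrons (gyroradius 0.07 cm at
1.5 T, smaller than the cavity: an electron born in air can spiral until it
drifts along the field out of the volume, so single histories carry large
deposits).  Air-region consistency at the 0.03 % level, as quoted for
cluster-scale runs of the same test, would require ~1e11 histories and is
out of desk scope; the resolved-deviation metric reports exactly what the
shipped sample sizes do establish.

## What the generator does and does not emulate

The source and transport emulate the consistency-test conditions, not a
clinical beam: monoenergetic electrons, no photons, no bremsstrahlung, no
delta rays, one common water medium.  Passing the test demonstrates that the
CH stepping, boundary crossing and field deflection are self-consistent
under density heterogeneity — it does not validate dose accuracy in real
materials, real spectra, or detector response factors.

## Known limitations

* Interface self-consistency carries a residual ~+0.25 % dose excess in
  thin low-density volumes (the shot-noise straight-crossing artifact above,
  resolved only by pooling ~1e8 histories); all other regions are consistent
  at the 0.1 % level or better.
* With the loose field cap (EM ESTEPE = 0.25) this engine's worst region is
  the air cavity (positive deviation, several percent at 1 MeV), but the
  detailed magnitude pattern across thin air gaps differs from
  production-code results — chord stepping that stops at every surface
  cannot "skip" regions, so part of the published artifact mechanism is
  structurally absent here.
* The scattering model is Gaussian small-angle theory on a fixed mass grid;
  it has no single-scattering tail and degenerates to shot noise in thin
  low-density volumes.
* Electric fields, spin, and density-effect corrections are out of scope.
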
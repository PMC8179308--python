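# Methods

`hingeflow` analyses how water crosses a water/octanol liquid–liquid
interface.  In molecular-dynamics studies of that interface, octanol forms a
bilayer-like structure: a monolayer whose hydroxyls face the water
(Layer-1), and a second, patchy layer whose hydroxyls face the organic
phase (Layer-2, organised into "bilayer islands").  Water moves between
the layers by three mechanisms — bare diffusion, riding on a single
stochastically flipping octanol, or carried inside an intact hydrogen-bonded
(oct)<sub>n</sub>(H₂O)<sub>m</sub> cluster that swings between the layers
like a door hinge.  This package implements the full analysis chain on
typed molecular configurations, plus a reduced Langevin model of the hinge
step.  All internal units are Å, ps, kcal/mol, and Kelvin.

## Hydrogen-bond network

A hydrogen bond between any two molecules (water–water, water–octanol,
octanol–octanol) is geometric: donor–acceptor O⋯O distance strictly below
3.5 Å and H–O(donor)⋯O(acceptor) angle at the donor oxygen of at most 30°.
The angle vertex is the donor oxygen, with minimum-image vectors — the
standard network-analysis convention.  The distance bound is strict and the
angle bound inclusive; the choice only matters on a measure-zero boundary.
Candidate pairs come from a periodic KD-tree, but the accepted edge set is
identical to an all-pairs scan (this is asserted, not assumed: every
geometric primitive in the package is tested against an independent
brute-force oracle).

Molecule clusters — used for carrier identification and bilayer islands —
are connected components of the O–O proximity graph at the same 3.5 Å
cutoff.

## Instantaneous interfaces

**ITIM.**  Probe spheres of radius 1.5 Å descend along a grid of test
lines (0.2 Å spacing) normal to the interface; a molecule is truly
interfacial iff a probe touches one of its atoms first (touch distance =
vdW radius + probe radius).  Van der Waals radii default to Bondi-type
values O 1.52, H 1.10, C 1.70 Å (configurable).  Before the probes are
dropped, a DBSCAN pass (eps 3.5 Å, min_samples 3, minimum-image metric) on
the water oxygens separates waters that penetrated the organic phase from
the aqueous network; DBSCAN clusters hydrogen-bonded to the main aqueous
cluster are pulled back in.  Octanols count as interfacial (Layer-1) when
their hydroxyl is hydrogen-bonded to a truly interfacial water, in either
donor/acceptor direction.

**Willard–Chandler.**  The water-oxygen density is coarse-grained with
Gaussians of width 2.5 Å on a 1.0 Å voxel grid (truncated at 4σ, periodic
in x,y); the instantaneous surface is the marching-cubes isosurface at 90%
of the bulk density, where bulk density is measured over the central 20%
of the aqueous slab.  The area is the summed triangle area.  A finite slab
also exposes an artificial bottom sheet (or a second interface in a doubly
periodic cell); an optional z-window selects which sheet is measured.
Convergence to the projected area for a flat slab and to the analytic
surface integral for a sinusoidal corrugation is a test, not an assumption.

## Layer assignment

Each frame is partitioned into five regions:

1. penetrated/aqueous split (DBSCAN, above);
2. ITIM over aqueous waters → `water_surface`;
3. octanols H-bonded to a surface water → `layer1`;
4. a second ITIM pass over the remaining octanols, approached from the
   water side, proposes `layer2` candidates, kept when the end-to-end
   vector (hydroxyl H → terminal C) points toward the water, i.e. the
   hydroxyl faces the organic phase, and the head group lies within a
   configurable depth bound (default 28 Å) of the mean surface-water
   height.  A fixed depth bound was chosen over locating a density-profile
   minimum per frame because the latter is not deterministic on sparse or
   synthetic frames; the bound is exposed as a parameter for real
   trajectories where the hydroxyl-density minimum is resolvable;
5. waters H-bonded to layer octanols inherit the layer label (majority
   over HB partners, ties to Layer-1); everything else is bulk by species.

Bilayer islands are Layer-2 clusters with ≥ 2 octanols.  Structural
observables: orientation profiles use cos θ of the end-to-end vector
against +z binned by hydroxyl-O height; 2D radial distribution functions
use xy-projected minimum-image distances with the (N−1) ideal-gas
normalisation so g → 1 for homogeneous layers (bin width 0.1 Å, range
min(Lx,Ly)/2); the excess coordination number is the 2D specialisation
N<sub>excess</sub>(r) = ρ ∫₀^r (g−1) 2πr′ dr′ by trapezoidal quadrature;
packing densities are per-frame count/area averages converted to nm⁻².

## Transport events

Region labels per frame give per-molecule label sequences; a transition is
a label change whose new label persists for at least `persistence` frames
(default 1 at 10 ps sampling, i.e. the sampling itself debounces).  For a
water crossing Layer-1 ⇔ Layer-2 the classifier inspects a window of ±1
frame around the crossing and finds the carrier: the O–O proximity cluster
containing the water, over all octanols plus any co-migrating waters (the
bulk water network is deliberately excluded so a surface departure is not
glued to the whole aqueous phase).  The maximal carrier composition over
the window is recorded.  Mechanism:

* **hinge** — carrier holds ≥ 2 octanols;
* **flip** — exactly 1 octanol, and that octanol itself changes layer in
  the window;
* **diffusion** — otherwise (no octanol contact).

Co-transferred waters sharing a carrier and window merge into one event.
Transfer statistics aggregate per direction: event counts, waters moved,
mean octanols/waters per HB-mediated event, mechanism fractions both by
events and by waters, and the per-water stoichiometry (mean octanols ÷
mean waters).  Uncertainties use three-block averaging over the
time-ordered event list throughout.

Activation energies use the Arrhenius relation E_a = R·T·ln(A/k) with
R = 1.98720425864083×10⁻³ kcal mol⁻¹ K⁻¹; negative results (A < k) are
flagged, never clipped.  For the per-water hinge reaction
H₂O + s·oct ⇔ H₂O + s·oct (default s = 1.63) the rate constant is the
water-transfer rate normalised by [H₂O]·[oct]^s of the source layer; the
prefactor convention (water–octanol HB-formation rate, or
surface-adsorption-plus-HB rate) is supplied by the caller and recorded
with the estimate, since two conventions differ exactly by R·T·ln(A₁/A₂).

## Langevin double-well model

The hinge step is reduced to one particle of water mass (18.015 amu) on a
1D double well along z.  Minima sit at −0.868 and +0.854 nm (the mean
octanol lengths of the two layers), the barrier at z = 0, and the two
barrier heights are the forward/reverse activation energies (defaults
6.00 and 5.60 kcal/mol).  On each side the potential is the constrained
quartic U(z) = −E_a + E_a(2s² − s⁴) with s the scaled distance from the
minimum, which satisfies every stated constraint (well positions, barrier
position, both depths, U′ = 0 at all three stationary points) with no free
shape parameters; harmonic continuations match the curvature beyond the
minima.  This shape choice is the one genuinely open design decision of
the model: only the constraints above are published, and any smooth
interpolant satisfying them differs in wall stiffness, which directly
scales the Kramers prefactor and hence the absolute crossing rate.

Dynamics are underdamped Langevin, discretised with BAOAB at an inner step
of 0.02 ps (the well period is ≈ 2.3 ps, so ω·dt ≈ 0.05; halving the step
changes crossing statistics only within noise).  Positions are sampled
every 1 ps for 100 000 samples per replicate; 1000 replicates all start at
the left minimum with Maxwell–Boltzmann velocities.  A well transition is
counted when the particle, last assigned to one minimum, reaches the other
minimum's position (hysteresis at the minima, evaluated at sample points),
so per-replicate forward/backward counts differ by at most one.  The
transport ratio is Σ forward / Σ backward over replicates with a
three-block SEM.  Friction is not published for this system; the default
is 0.5 ps⁻¹, the value (within the physically sensible 0.5–5 ps⁻¹ window)
that maximises the crossing rate, and it is recorded in every output.

A known limitation follows from the shape sensitivity: with this
constrained quartic the barrier curvature gives ≈ 2 well-to-well crossings
per 100 ns replicate, and because crossings alternate from the left-well
start the ratio lands near 1.3–1.4; a stiffer fitted well (≈ 3× the
crossing rate) would drive the same statistic toward ≈ 1.16.  The
integrator itself is validated independently: sampled velocities match
Maxwell–Boltzmann (KS test) and basin occupancies match basin-integrated
Boltzmann weights.

## Interfacial tension and solubility

The planar Kirkwood–Buff estimator γ = (L_z/(2N_int))·⟨P_zz −
(P_xx+P_yy)/2⟩ is applied to pressure-tensor time series with the exact
conversion 1 bar·Å = 10⁻² mN/m and three-block SEMs.  The mole-fraction
solubility of water in the octanol-rich phase is x_w = ρ_w/(ρ_w + ρ_oct).
These estimators are validated on synthetic series with planted
anisotropy; producing the real MD values would require the original 250 ns
trajectories, which are out of scope here.

## Synthetic data

The generators replace MD output and define the study conditions:

* **Slab** (`gen_slab`): a jittered water lattice (3.1 Å spacing) below a
  flat or sinusoidal boundary in a 40×40×80 Å cell periodic in x,y;
  Layer-1 octanols stand on every second surface site at exactly 45°
  end-to-end tilt (matching the observed interfacial orientation),
  hydrogen-bonded to their surface water; Layer-2 islands (default sizes
  4, 4, 5 with waters growing linearly with size) hang 26 Å above the
  water top with hydroxyls up and tails meeting the Layer-1 tails
  end-to-end; a penetrated water sits ≥ 15 Å past the boundary; bulk
  octanols lie flat higher up.  Chains within a group are parallel by
  construction so the scene is packed without steric clashes (heavy-atom
  contacts < 2 Å raise an error).  Every planted feature's ground-truth
  label is returned.
* **Scripted events** (`gen_event_trajectory`): each planted event lives
  in its own 16 Å xy cell.  Hinge carriers rotate rigidly about a pivot in
  the layer boundary plane (the door-hinge swing); flips rotate one
  elongated octanol about its centre; diffusing waters translate across
  the boundary with no octanol within HB reach; everything else jitters at
  0.05 Å, far below the HB-breaking scale.  Region labels for these scenes
  come from fixed z bands, which in this controlled geometry coincide with
  the layer definitions.  Event timing is quantised to the 10 ps sampling.
* **Pressure series / rate streams**: Gaussian series with prescribed mean
  anisotropy; Poisson event streams at planted Arrhenius rates (shared
  prefactor, chosen barrier gap) for recovery tests.

What passing tests on these fixtures do *not* show: the generators have no
thermodynamics — no capillary-wave spectrum, no realistic octanol
conformational ensemble, no genuine HB kinetics — so agreement here
validates the analysis operators and their definitions, not force-field
physics.  Scale is also reduced: fixtures use ~10³ molecules and tens of
frames where the original analyses used 10⁵ atoms over 30 ns.

## Numerical choices

* Neighbour searches: periodic cKD-trees with exact minimum-image
  post-filtering; results bit-identical to brute force.
* Degenerate inputs: zero-length end-to-end vectors are skipped with a
  warning in orientation profiles; empty phases, missing isosurfaces
  (reported with the attainable density range), single-frame turnover
  requests, zero concentrations and non-positive Arrhenius inputs raise
  errors.
* Ties in water layer inheritance resolve to Layer-1; cluster ordering is
  by smallest member id; all stochastic components take explicit seeds and
  are bit-reproducible under them.
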
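# Methods

This note documents the models, conventions, numerical choices and
known limitations of the package, in the order the pipeline uses them.

## Coordinate and symmetry conventions

Coordinates are in Å in a right-handed frame; the baseplate plane is
xy and the baseplate normal is +z.  The symmetry group is a C2 rotation
about +z through the origin composed with a 2D translation lattice.
Gauge freedom (global rotation/translation of the whole assembly) is
removed by fixing lattice vector **a** along +x, confining **b** to the
xy plane, and putting the C2 axis at the cell origin — any offset of
the physical dimer axis is absorbed into the monomer translation **t**.
An image `(s, m, n)` places the rigid monomer at
`x → C2^s (R x + t) + m a + n b`; the reference chain is `(0, (0,0))`.

The optimizer genome is the 9-vector
`[r_x, r_y, r_z, t_x, t_y, t_z, a, b_x, b_y]` with the orientation as a
rotation vector (axis × angle, radians).  A rotation vector rather than
a raw quaternion keeps the genome free of the unit-norm constraint and
collapses the quaternion double cover (q and −q) onto one genome point;
`SymmetryParams` itself stores a unit quaternion (w, x, y, z).

The angle between **a** and **b** is restricted to (30°, 150°) to
exclude degenerate (near-collinear) lattices.  The two lattice
directions are *not* forced to be perpendicular: the idealized
description of the lattice uses perpendicular translations, but
measured repeat directions in such layers deviate from 90° (≈81°), so
the angle is left free within the non-degenerate band.

## Ambiguous distance restraints

A cross peak in a long-mixing ¹³C–¹³C correlation spectrum is matched
against the assigned shift table: every atom whose shift lies within
half of the matching window (default window 1.35 p.p.m., so a maximum
deviation of 0.675 p.p.m., comparable to the observed linewidths) of a
peak coordinate is a candidate, and the restraint's option set is the
product of the two candidate lists.  The default atom filter keeps C′
and Cα of all residues plus Cβ of Ser/Thr, the carbons that resolve
from the carotenoid/lipid spectral ranges.  Peaks with no candidate
pair are reported unmatched.  A restraint is *trivial* — satisfied by
covalent geometry alone — when every option is an intra-residue pair or
a sequential (|i−j| = 1) backbone pair; trivial restraints are dropped
and counted (the filter can be disabled).

Ambiguity is resolved by r⁻⁶ sum averaging:

    d_eff = ( Σ_k d_k⁻⁶ )^(−1/6)

over all option instances k — the intra-chain pairing plus both
orientations of each option against every symmetry image.  This mirrors
how every candidate pair contributes to the observed cross-peak
intensity, and has the property that adding an instance never increases
d_eff, so ambiguity cannot create spurious violations.  The restraint
energy is a flat-bottom quadratic, `Σ w·max(0, d_eff − U)²`.  The upper
bound U defaults to 7.0 Å for 200 ms mixing, a common calibration for
this experiment class; it is configurable per restraint because no
single published calibration applies universally.

For speed the production evaluator prunes symmetry images whose
bounding sphere lies farther than a fixed cutoff (default bound + 2 Å)
from the reference chain; pruned images would contribute r⁻⁶ terms
below float noise.  The cutoff is a constant rather than a function of
the bounds so that bounds calibrated against the evaluator reproduce
exactly.

## Pigment geometry terms

From each pigment: the Mg position; the ring normal as the unit normal
of the least-squares plane through the four ring nitrogens, with the
sign taken from the ring-atom ordering cross product (NB−NA)×(ND−NA) —
this makes the normal transform as a proper pseudovector under
coordinate mirrors, which the spectroscopy invariants require; and the
Qy transition dipole direction along the NA→NC nitrogen axis (the axis
pair is configurable because ring-nitrogen nomenclature varies between
PDB dialects), projected exactly into the ring plane.

The pigment energy is
`w₁·max(0, d_min − 15 Å)² + w₂·Σ (n̂·ẑ)²`, where d_min is the minimum
over the reference-cell pigments of their nearest-neighbour Mg
distance, and the ring-normal sum runs over the reference-cell sites
only — every lattice image shares those orientations up to the C2
rotation, which preserves (n̂·ẑ)², so including all images would only
rescale the term with assembly size.

## Clash term

Soft-sphere repulsion `Σ max(0, r_min − d)²` over heavy-atom pairs of
*different* chains (the monomer is rigid input, so intra-chain geometry
is not scored), r_min = 2.8 Å.  Implemented with a k-d tree
(`scipy.spatial.cKDTree`); because only pairs below r_min contribute,
the binned result equals the all-pairs double loop to machine
precision (asserted in the tests).

Component weights default to restraint : pigment : clash = 1 : 1 : 0.1.
The clash weight is deliberately small: the term is a regularizer that
rules out overlapping packings, not a force field.

## Global search

A genetic algorithm over the 9-gene genome: tournament selection
(size 3), BLX-α blend crossover (rate 0.7, α 0.5), per-gene Gaussian
mutation (defaults 0.05 rad on rotation genes, 1 Å on translation and
lattice genes — scales matched to ~30 Å lattices), elitism (2), and
basin hopping applied to offspring: Gaussian perturbation, bounded
Nelder–Mead local minimization (derivative-free because the flat-bottom
terms kink the objective), Metropolis acceptance at dimensionless
temperature T.  Elitism makes the per-generation best energy
non-increasing; all randomness flows through one seeded generator, so a
run is bit-reproducible.  `run_ga` returns the K lowest-energy
*distinct* individuals (genome distance > 0.5) seen anywhere in the
run.  The production-scale defaults (population 64, 200 generations,
20 hops × 200 evaluations) are expensive; every test and the bundled
pipeline presets use smaller, explicitly stated budgets.

Search bounds encode prior knowledge, as they would in a real
determination: lattice ranges from the repeat distances seen in EM
power spectra, translations within half a cell, and the out-of-plane
rotation components limited to ±0.5 rad because the layer is a thin 2D
crystal of in-plane amphipathic helices.  The last prior also excludes
the global up/down flip of the layer, which short-range distance data
genuinely cannot distinguish (only the chiroptical data can, which is
why the flip ambiguity is otherwise resolved in the CD filtering
phase).

## What identifies which parameter

Worth stating explicitly, because it drives the pipeline design:

* Upper-bound distance restraints bound the lattice constants only
  from *above* (shrinking a lattice can never violate an upper bound);
  the lower side is held by the clash term, leaving a flat interval of
  a few tenths of an Å.  The density map pins the lattice constant —
  the refinement phase scans the lattice gene against the map
  cross-correlation (the computational analogue of reading the repeat
  distance from a power spectrum) before polishing the other genes.
* The monomer orientation and translation are two-sidedly constrained
  by the restraints and recover from the search alone.
* The layer flip and the enantiomer are constrained only by CD/ACD.

## Exciton spectroscopy

Each pigment carries one Qy transition with site energy 12500 cm⁻¹
(the 800 nm absorption region) and dipole strength 37 D² — literature
values for BChl *a*, configurable and not fitted.  Couplings use the
point-dipole formula `V = f · 5.04 · κ · √(D_i D_j) / r_nm³` cm⁻¹ with
orientation factor κ and an empirical screening factor f (default 1);
a warning is issued below 10 Å separation where the approximation
degrades, and below 2 Å it is refused.

Rotational strengths use the exciton chirality expression
`R_k = π ν₀ Σ_{i<j} c_ki c_kj r_ij·(μ_i×μ_j)` (Å→cm conversion folded
in) with ν₀ the *mean* site wavenumber: a constant prefactor makes the
point-dipole sum rule Σ_k R_k = 0 exact (the neglected state-energy
variation is of order V/ν₀ < 1%).  Oriented (ACD) rotational strength
is the quadratic form of a symmetric tensor normalized so its uniform
sphere average reproduces the isotropic value — the normalization is
pinned by that invariant.  LD weights are `D_k·S·(3cos²θ_k−1)/2` about
the orientation axis; S defaults to 1 (perfect uniaxial order), because
the actual order parameter of gel-compressed samples is unknown — S is
a configuration knob, and a green LD test establishes the geometry
only up to that assumption.

Band shapes are Gaussians (default FWHM 250 cm⁻¹) in wavenumber; band
areas on a wavenumber axis equal the corresponding strengths (verified
by quadrature in the tests).  Vibronic progressions are out of scope.

Shape comparison resamples both spectra onto a common wavelength grid,
normalizes to unit maximum magnitude, compares the lobe sign sequence
(lobes below 5% of the maximum are ignored as noise), and locates the
principal sign-inversion point — the zero crossing between the global
maximum and global minimum — by linear interpolation.  The candidate
filter requires matching lobe signs and a crossing within 10 nm
(configurable).

## Density

Maps are MRC2014 mode 2; reading normalizes any axis order to
x-fastest and honours the ORIGIN header (falling back to
NXSTART·voxel).  Model maps rasterize each heavy atom as an isotropic
Gaussian with FWHM equal to the nominal resolution and integral equal
to its atomic number.  Agreement is the Pearson correlation over
voxels (optionally above a mask threshold; default none) — scale- and
offset-free, which is all a low-resolution envelope can support.
Resampling between grids is trilinear; no Fourier-space interpolation
at these resolutions.  `downsample` provides block-averaged maps for
cheap scoring during refinement.

## Synthetic world

The fixture generator states one world per preset and the tests hold
it fixed:

* **small** — a 12-residue ideal α-helix (φ = −57°, ψ = −47°, giving
  CA–CA 3.80 Å) with a pseudo-pigment (Mg, four ring N at 2.05 Å, two
  dipole-marker carbons), on a 20 Å × 29 Å lattice (b_x = 4 Å shear),
  helix criss-cross half-angle 15° about z plus an 8° out-of-plane
  pitch, dimer Mg centres 9 Å apart.  The pitch exists because a
  perfectly planar arrangement has an accidental near-degeneracy under
  the layer flip that real (slightly pitched) helical layers do not
  have.  Map: 10 Å resolution, 2.5 Å voxels.
* **paperlike** — a 20-residue helix on a 33 Å × 33 Å lattice at 81°,
  criss-cross half-angle 12.5°, dimer Mg centres 15.0 Å apart along
  the rod axis, map resolution 19.1 Å.  This preset mirrors the
  published baseplate geometry for spectroscopy-scale tests; it is not
  used for recovery benchmarks.

Restraints are derived from the truth: every protein carbon pair
(intra-chain non-sequential, plus all inter-image pairs) below 7 Å
becomes a restraint; each carbon receives a synthetic chemical shift
(residue-type-typical ¹³C value + 0.4 p.p.m. Gaussian jitter) and the
option set is the product of the two shift-matching classes within the
0.675 p.p.m. half window — ambiguity arises the same way it does in a
real spectrum, from shift overlap.  This yields ≈4–5 options per
restraint on the small preset.  Upper bounds are the effective
distances evaluated at the truth (by the same evaluator the optimizer
uses, so the truth scores exactly zero) plus |Gaussian noise| when a
noise level is requested.  Restraint lists are capped (140 small / 200
paperlike) by seeded subsampling to keep objective evaluations fast.

What the generator does *not* emulate: real linewidth variation and
peak overlap handling, spectral regions obscured by carotenoids and
lipids, monomer flexibility (the monomer here is exactly rigid),
vibronic structure, and curvature of the native organelle (only the
flat infinite lattice is modelled).  A green recovery test therefore
establishes that the engine inverts its own forward model under
realistic ambiguity and noise — not that it would reach the same
precision on the native data.

## Pipeline

Phase 2: global GA search, keep K₁ distinct candidates (production
default 128); `ga_restarts` pools candidates from several independent
seeded runs, because a single small search can return only the
criss-cross hand the CD data reject.  Phase 3: rank by hybrid energy
(K₂ = 32), filter by CD shape against the observed spectrum, rank
survivors by map cross-correlation (K₃ = 7).  Phase 4: density-restrained rigid
refinement (basin hop on energy + w_cc·(1 − CC)), re-rank by the
combined objective with ties broken by CD rms — the final model is the
best refined candidate.  Every report carries the seed and a SHA-256
hash of the configuration; a fixed seed reproduces the report bytes.

The test and acceptance configurations scale population, generations
and hop budgets down by one to two orders of magnitude so the entire
suite fits in CI-scale time; the scaled budgets are stated next to
each run.

The acceptance-scale recovery benchmark composes the same phases in an
explicitly staged form suited to tiny budgets: GA search (restarted
when no candidate matches the observed CD band signs), deterministic
registration of each CD-consistent candidate against the map —
coordinate scans over row placement (t_y, b_y) and rod spacing/phase
(a, t_x), the computational analogue of reading repeat distances off a
power spectrum — followed by alternating subspace polish
(rotation-only on the restraint energy, translation/lattice on the
density-weighted target) and a final density-weighted refinement.  A
block-averaged map and a CA/Mg-only model speed up the inner scans;
the final scoring always uses the full map and all heavy atoms.

## Known limitations

* Rigid-monomer approximation throughout: no torsion-angle or
  all-atom refinement stage (the corresponding published stage used a
  simulated-annealing force-field refinement that is out of scope
  here).
* Point-dipole couplings and empirical Gaussian lineshapes; no
  quantum-chemical site energies or Franck–Condon structure.
* Upper-bound-only distance restraints leave the lattice constants
  one-sidedly constrained without a density map (see above).
* The MRC reader supports mode 2 only, and the NMR-STAR reader only
  the `_Atom_chem_shift` loop subset.
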
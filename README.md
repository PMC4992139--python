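# baseplate

Symmetry-constrained hybrid structure determination for two-dimensional
crystalline pigment–protein layers — the kind of assembly formed by the
chlorosome baseplate, where a small amphipathic helix (CsmA) binds one
bacteriochlorophyll *a* and the protein–pigment unit repeats as a C2
dimer on a 2D lattice.

Such assemblies cannot be solved by any single technique: solid-state
NMR cross peaks give short-range, *ambiguous* carbon–carbon distances;
cryo-EM gives only a low-resolution density envelope; and circular /
linear dichroism constrains the mutual orientation of the pigment
transition dipoles.  This package searches the symmetry parameter space
of the assembly directly — rather than sampling thousands of explicit
chains — and scores each candidate against all of those data at once.

## Model

A rigid monomer (one protein chain + one pigment) is placed by

* a rotation **R** and translation **t** (the pose in the dimer frame),
* a two-fold axis along the layer normal **z** (the C2 dimer),
* two in-plane lattice vectors **a** (fixed along +x) and **b**,

giving chain images  `x → C2^s (R x + t) + m a + n b`.  The nine free
parameters (rotation vector, translation, `a`, `b`) form the genome of
a genetic algorithm whose offspring are basin-hopped (perturb → bounded
Nelder–Mead → Metropolis).  The hybrid energy combines:

* **Ambiguous distance restraints** with r⁻⁶ sum averaging:
  `d_eff = (Σ_k d_k⁻⁶)^(−1/6)` over every candidate atom pair, intra-
  chain and against every symmetry image, with a flat-bottom quadratic
  penalty above the upper bound.
* **Pigment geometry**: nearest Mg–Mg distance kept below a cutoff
  (default 15 Å) and ring normals kept in the layer plane.
* **Steric clashes**: soft-sphere repulsion between heavy atoms of
  different chains.

Candidates are then filtered by exciton-theory band shapes (point-dipole
couplings `V = 5.04 κ √(D_i D_j)/r³` cm⁻¹; isotropic and oriented
rotational strengths; CD lobe signs and the sign-inversion point) and by
Pearson cross-correlation to a density map, and finally refined with the
density included in the objective.

## Worked example

Everything below runs offline on a synthetic fixture with a known
ground truth:

```bash
baseplate fixture --preset small --seed 1 --out fix
baseplate measure --structure fix/monomer.pdb --dihedrals | head -3
```

```
residue    1  phi    None  psi   -47.0
residue    2  phi   -57.0  psi   -47.0
residue    3  phi   -57.0  psi   -47.0
```

The fixture monomer is an ideal α-helix (φ = −57°, ψ = −47°), so the
measured backbone torsions reproduce the generator's set values; the
first φ is undefined (no preceding carbonyl) and reported as missing
rather than fabricated.

```python
from baseplate import EnergyModel, Weights, make_fixture_bundle

bundle = make_fixture_bundle("small", seed=1)
model = EnergyModel(bundle.monomer, bundle.restraints, Weights(), bundle.extent)
breakdown = model.evaluate(bundle.true_params)
print(breakdown.restraint_energy, breakdown.clash_energy)
# 0.0 0.0
```

Zero restraint and clash energy at the true parameters is the fixture's
defining invariant: noiseless restraints are calibrated so the truth
satisfies them exactly, which is what makes full parameter-recovery
experiments meaningful.  A full run (search → filter → refine) is:

```bash
baseplate run --monomer fix/monomer.pdb --restraints fix/restraints.json \
    --map fix/map.mrc --seed 1 --out report
```

The report directory contains the final model (PDB), the refined
candidate ensemble, per-candidate score tables (TSV), the forward
calculated spectra, and a provenance record with the seed and a config
hash — rerunning with the same seed reproduces the report bit for bit.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the small fixture from scratch and runs the complete
four-phase determination against it (global search, energy ranking,
CD-shape + density filtering, density-restrained refinement), writing
the target JSON to `--out`.

Two checks in `tests/test_acceptance.py` validate geometry measurements
against the deposited baseplate ensemble (PDB 5LCB); they need
`data/5LCB.pdb` to be present (or downloadable) and fail with an
explanatory message in offline environments without it.
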
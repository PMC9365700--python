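# shell-lattice

Geometric analysis of self-assembling protein-shell lattices imaged by
cryo-electron tomography, built around the square-tiled protein shell that
jumbo bacteriophages assemble to enclose their replicating genome (the
"phage nucleus"). The shell is a single layer of one protein, chimallin,
whose C4-symmetric tetramer forms an 11.5 × 11.5 nm square tile; tiles join
into a *p*442 wallpaper lattice on curved, micrometre-scale surfaces, and
purified protein closes into minimal cubes of 6 tiles (24 protomers) and
prisms of 10 tiles (40 protomers).

The package covers the geometry half of such a study end to end, with a
synthetic-data module supplying every input with known ground truth:

- **io_formats** — STAR particle tables (positions + ZYZ Euler orientations),
  PDB/mmCIF structures (Cα or all-atom bead models), ASCII PLY/OBJ meshes.
  All lengths are Å internally.
- **synthetic** — decorated surfaces (plane, sphere, ellipsoid, perturbed
  sphere, box) carrying p4/p2 quasi-lattices with a ground-truth neighbour
  graph; corruption (jitter, false positives/negatives, flips); bead-lined
  channels with analytic radius profiles; tetramer-sheet bead models; 1-D
  compartment line profiles.
- **seeding** — Poisson-disk oversampling of a traced surface at a 4 nm step
  with outward-normal orientations, and repair of inverted particles.
- **curation** — score-ranked duplicate removal at 9 nm, the
  ≥ 3-neighbours-in-10–13 nm filter, neighbour plots in each particle's
  local frame, and lattice-parameter estimation (a, b, γ, p4/p2/disordered).
- **curvature** — per-vertex principal curvatures by local quadric fitting;
  the bend-angle map θ = 2·arctan(s/2r) with s = 5.75 nm; signed
  inter-particle bend angles; spherical-compartment morphometrics and
  diameter-from-line-profile measurement.
- **builder** — ideal p442 sheets, the O-symmetric cube, the D4 prism; exact
  symmetry checking; cube→sheet unfolding with hinge accounting; linker
  spans; point-group symmetry expansion with coset-exact record counts.
- **enm** — Gaussian (10 Å cutoff) and anisotropic (15 Å) elastic network
  models, inverse-eigenvalue variance fractions, fixed-RMSD ensembles.
- **pore** — channel free-radius profiles R(z), restrictive diameters and
  solid-of-revolution pore volumes, with optional probe-centre relaxation.
- **pipeline / cli** — YAML-driven end-to-end runs (`shell-lattice run …`)
  plus thin subcommands (`simulate`, `seed`, `clean`, `bend`, `curvature`,
  `lattice`, `expand`, `enm`, `pore`, `usb`).

## Worked example

`examples/assembly_models.py` builds the ideal assemblies and measures their
geometry:

```text
cube : 6 tiles, 24 protomers, 1.67 MDa, O-symmetric: True
prism: 10 tiles, 40 protomers, 2.78 MDa, D4-symmetric: True
prism envelope: 22 x 22 x 33.5 nm
sheet: 9 tiles, 2502 kDa

edge-sharing cube tiles bend by 90.0 degrees (12 pairs)

unfolded net: 6 tiles, 5 hinges of 90 degrees each
implied C-terminal segment rotation: 54.7 degrees
```

The masses follow from the 69.5 kDa protomer (6 × 4 × 69.5 kDa = 1.67 MDa);
the 90° bend between edge-sharing tiles is the maximum hinge angle the
closed cube forces on the lattice; and unfolding the cube's three-fold
corner into the sheet's four-fold corner rotates the corner-crossing
C-terminal segment by arccos(1/√3) ≈ 55°. The other scripts in `examples/`
exercise the curation pipeline on a synthetic shell, the elastic-network
models, pore profiling and compartment morphometrics, each printing the
numbers it computes and what they mean.

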
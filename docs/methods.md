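# Methods

This note records the models, conventions and numerical choices behind
`shell_lattice`, and what the synthetic benchmarks do and do not establish
about real tomography data.

## Coordinate and orientation conventions

All internal lengths are Å; report writers that print nm say so per column.
Orientations are ZYZ intrinsic Euler triples (rot, tilt, psi) in degrees
with R = Rz(rot)·Ry(tilt)·Rz(psi) mapping the particle frame into the
tomogram frame; the particle's +Z axis is R[:, 2] and by convention points
outward (toward the cytosol for a shell). `tilt` lies in [0°, 180°]; at the
gimbal-locked poles the convention is rot := 0 with the in-plane angle
carried by psi. Rotation matrices are the only internal rotation
representation; Euler triples exist only at the I/O boundary. Mesh faces
wind counter-clockwise seen from outside.

## Surface seeding

"Sample every 4 nm over the surface" is implemented as dart-throwing
Poisson-disk sampling with minimum spacing 0.9 × step (ε = 0.1 of the
step·(1−ε) tolerance): curved triangulated surfaces admit no exact grid,
and the aim is oversampling relative to the 11.5 nm lattice, not a grid.
Candidates are drawn area-weighted per face and accepted greedily to
saturation (at most 60 batches, stopping after two empty batches). The
realized density is the random-sequential-packing value, ~0.8 points per
step² of area, within the [0.5, 1.0] band asserted in tests. Outward
direction comes from consistent mesh winding, or from sign against a
user-supplied interior point for unorientable input. In-plane angles are
randomized by default because the lattice register is unknown before
alignment.

## Lattice decoration (synthetic ground truth)

`decorate_lattice` wraps a 2-D Bravais basis (p4: a = b, γ = 90°; p2
general) over a mesh by breadth-first tangent stepping: from each accepted
particle, candidates at ±a·u and ±b·(cos γ·u + sin γ·v) are projected back
onto the mesh, the local frame is parallel-transported through the minimal
rotation between normals, and a candidate merges with an existing node when
it lands within 0.8·min(a, b) (0.9 recommended on spheres). Wallpaper
perfection is impossible on a closed curved surface, so the ground truth is
the realized neighbour graph, not an ideal lattice; the realized spacing on
a sphere is compressed by roughly the chord-to-arc factor (~1–3% at shell
radii of 80–150 nm). On a plane the construction is exact.

Corruption mirrors real picking pathologies: isotropic Gaussian positional
jitter; orientation noise as rotations with angle |N(0, σ)| about uniform
axes; binomial deletion; 180°-about-+X flips; and false positives placed
uniformly in tangent patches around existing particles (re-projected to the
mesh when given). False-positive scores are drawn uniform on [0, 0.9]
against 1.0 for generator truth — spurious picks cross-correlate worse
than real subunits, which is the premise of score-ranked duplicate removal.
All generators are pure functions of spec + seed.

## Curation rules

Duplicate removal is a single greedy pass in descending score order
(deterministic id tie-break): accept a particle iff no accepted particle
lies within 90 Å (9 nm) centre-to-centre. The output provably has pairwise
separation ≥ the cutoff, and on crowded random boxes it equals a brute-force
oracle. The neighbour-count filter is a single pass with counts computed on
the input set — the cleaning is one step, not an iteration to a fixed point
— removing particles with fewer than 3 neighbours at 100–130 Å. Distances
are 3-D Euclidean, not geodesic.

Lattice estimation works from positions alone: a pair-distance histogram
(4 Å bins, 3-bin smoothing) is shell-area corrected (density = count/r²);
a structure is "ordered" when a peak carrying ≥ 2% of all pairs exceeds
3× the median density. The first shell is refined by mean-shift (windowed
mean, iterated), which removes the leftward bias the 1/r² correction puts
on the peak bin. A second peak at √2·a with a ~90° modal neighbour angle is
recognized as the square lattice's diagonal shell (call: p4); otherwise the
second peak is the b shell and γ is the modal acute angle between a- and
b-shell neighbour vectors (call: p2 when the p4 bounds |a−b|/a < 0.1,
|γ−90°| < 8° fail). At 8 Å jitter the 115/135 Å shells of the test oblique
lattice are separated by less than 2σ of the pair-distance noise and merge;
the group call remains correct there, and spacing recovery is asserted at
4 Å jitter where the shells are resolvable.

## Curvature and bend angles

Per-vertex principal curvature uses local quadric fitting: neighbours
within radius_hint (default 3× the mean edge length, the analogue of a
3-pixel hit radius at typical segmentation sampling) are expressed in the
tangent frame of the area-weighted vertex normal and h = ax² + bxy + cy²
(+ linear terms, which absorb normal-estimate tilt and are discarded) is
fitted by least squares; κ₁ ≥ κ₂ are the eigenvalues of −[[2a, b], [b, 2c]],
so convex-toward-outside is positive. Vertices with fewer than 6 usable
neighbours are reported as missing rather than extrapolated. This is a
deliberate substitution for tensor-voting curvature: quadric fitting is
well-posed and testable against closed forms (sphere 1/R within 10%,
cylinder (1/R, 0), plane 0, rotation equivariance to 10⁻⁶).

Curvature converts to an inter-unit bend angle via θ = 2·arctan(s/(2r)),
r = 1/κ, with s = 57.5 Å — half the 11.5 nm repeat, i.e. the side of the
polygon the curved surface circumscribes. θ is odd and monotone in κ,
θ(0) = 0, θ → 180° as r → 0, and θ = 90° exactly at r = s/2 = 28.75 Å.

Between oriented particles the unsigned bend is arccos(n_i·n_j); the sign
is sign((p_j − p_i)·(n_j − n_i)), positive when normals diverge (convex
outward). This reproduces +90° on edge-sharing cube tiles, 0° on flat
sheets, and all-positive signs on spheres with outward normals (there
p = R·n makes Δp·Δn > 0 identically).

Compartment morphometrics treat bodies as spheres: V = (π/6)d³, reported
in μm³ to 3 significant figures; ratios are taken between the rounded
volumes and printed at 2 decimals. Apparent diameters come from line
intensity profiles as the distance between the outermost crossings of the
half level between background and interior plateaus, linearly interpolated
— exact for symmetric edges, accurate to ~1 pixel on hard edges.

## Ideal assemblies and symmetry bookkeeping

The tetramer unit is a square tile (side 115 Å, thickness 60 Å, four
69.5 kDa protomers, internal C4). Sheets place n × m tiles at spacing a
with identity rotations (p442: 4-folds at tile centres and corners, 2-folds
at edge midpoints, verified by an image-matching checker modulo internal
C4). The cube places 6 tiles on the faces of a cube of edge 115 Å, +Z
outward — 24 protomers, 1.67 MDa, invariant under the 24 rotations of O.
The prism is two square caps plus two rings of four side tiles (10 tiles,
40 protomers, 2.78 MDa) with tile footprints spanning 220 × 220 × 335 Å
and exact D4 invariance.

Unfolding fixes the cross-shaped net (the +z face keeps the four side faces
as children and the −z face rides on +x): five hinges of 90° each, applied
child-first so ancestors carry descendants, giving a planar 6-tile net whose
refold is the exact inverse. The net choice is arbitrary and documented
here. The ~55° rotation the corner-crossing C-terminal segment must absorb
is computed as the angle between the cube corner's three-fold axis (body
diagonal) and the sheet corner's four-fold axis: arccos(1/√3) = 54.74°.
Linker spans are Euclidean distances between user-supplied anchor points
per protomer; the builder ships synthetic defaults placed so both linkers
stay below their contour-length bounds (3.5 Å/residue × 8 or 10 residues).

Symmetry expansion replicates each record once per right coset of the
target group in the source group (|O|/|C4| = 6, |C4|/|C1| = 4), composing
each orientation with the coset representative in the particle frame
(R' = R·g). Coset representatives are found by explicit enumeration of the
group matrices (O generated by closure from the 4-fold z rotation and a
3-fold body-diagonal rotation; C4 about +z). Replicates of one particle
whose (tilt, psi) agree within 10⁻⁴ degrees differ only by an in-plane
symmetry rotation and are removed; for generic orientations nothing is
removed and the output count is exactly input × coset count, reproducing
128,798 → 772,788 (O→C4) and 664,363 → 2,657,452 (C4→C1).

## Elastic network models

GNM builds the N × N Kirchhoff matrix (Γij = −γ for contacts within 10 Å,
diagonal minus row sum); ANM the 3N × 3N Hessian with super-elements
−γ·(r rᵀ)/|r|² at a 15 Å cutoff; γ = 1.0. Dense symmetric
eigendecomposition is the default (scipy/LAPACK); zero modes are counted at
10⁻⁸ relative to the largest eigenvalue — one for a connected GNM graph,
six for a connected non-collinear ANM network. Beads with a single contact
carry genuine mechanism zero modes, so the synthetic sheet uses a regular
per-block bead grid (60 beads per 0.9a × 0.9a × 60 Å block, 5% pitch
jitter) dense enough that, at a coarse-bead cutoff of 40–50 Å, only the six
rigid-body modes are soft-zero. On that sheet the lowest GNM mode varies
smoothly across blocks, so block-edge beads fluctuate more than block
interiors (asserted directionally).

Variance fractions use the pseudo-inverse covariance convention (mode
variance ∝ 1/λ over non-zero modes, softest first); whether a published
"k lowest modes carry X%" figure uses all modes or a truncated subspace in
the denominator is generally ambiguous, and this convention is the one
documented here. The published 76%-in-five-modes figure itself is not a
benchmark because it requires the authors' 20,412-node atomic sheet model,
which is not redistributable; the convention is instead pinned by the
closed-form 3-bead chain (spectrum {0, 1, 3}, first-mode fraction 0.75).
Ensembles displace along one unit-norm ANM mode by α = RMSD_target·√N, so
the no-superposition RMSD equals the target exactly (default 25 Å).

## Pore profiling

At each station z along the axis, R(z) = max_u min_i (|x_i − u| − r_i) with
the probe centre u fixed to the axis (relax off) or maximized from the axis
seed by deterministic in-plane coordinate ascent with step halving from 2 Å
to 10⁻³ Å (relax on); clearances clamp at 0 ("closed"). Stations with no
bead within a 15 Å axial slab are unbounded: reported, excluded from the
restrictive diameter (2·min R, in nm), and fatal inside a volume
integration range. Volumes are π∫R²dz by the trapezoid rule. Bead radii
default to per-bead values on the model or 1.7 Å (carbon-like van der
Waals). The published MD pore statistics (≈1.4 nm mean restrictive
diameter; 798/1,429 nm³ volumes) require 1.5 μs of trajectories and are not
benchmarks; the same code paths are pinned by analytic channel fixtures
(cylinder and hourglass built from bead rings, compared at ring-plane
stations where the analytic profile is exact) and a brute-force oracle at
10⁻¹⁰ Å.

## Pipeline and determinism

Both pipeline entry points consume one YAML config with a global seed,
embed the resolved config and package version in their JSON reports, write
no timestamps, and sort report keys, so identical configs give
byte-identical reports. Every stochastic stage takes its own seed with the
global seed as fallback.

## Problem sizes in the default test run

The suite exercises spheres of radius 80–120 nm (≈600–1,300 lattice
particles), 29 × 29 plane lattices (841 particles) for the
recovery-under-corruption benchmark, 540–900-bead elastic networks and
published-scale symmetry expansion (128,798 and 664,363 records). These
sizes keep the full suite under a minute while leaving every algorithmic
path at realistic density.

## What the synthetic benchmarks do not show

The generators emulate geometry, not imaging: no missing wedge, no CTF, no
density, no alignment errors correlated with curvature, and false-positive
scores cleanly separated from true scores. Passing the curation benchmarks
therefore demonstrates the correctness of the geometric rules, not their
sufficiency on real tomograms, where score distributions overlap and
annotation noise on traced surfaces (which no published value quantifies;
defaults live in the config) adds structured error. Likewise the
quasi-lattice ground truth on spheres has its seams placed by the BFS
order, which is deterministic but not a physical nucleation model.
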
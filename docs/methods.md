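# Methods

## Lattice model

Capsomer centers of an ideal *(h, k)* capsid are the vertices of the
*(h, k)* geodesic subdivision of the icosahedron. Each icosahedral face is
tiled with the triangular-lattice points of the Caspar–Klug triangle whose
corners are lattice points (0,0), (h,k) and the +60° rotation of (h,k);
face tilings are merged at shared edges and vertices, giving exactly
10*T* + 2 unique points with *T* = *h*² + *hk* + *k*². Faces are oriented
consistently (counter-clockwise from outside), which is what keeps skew
(class III, *h* ≠ *k*, both > 0) tilings continuous across edges; (h, k)
and (k, h) therefore produce genuine mirror-image lattices. By default the
points are projected radially onto the sphere of the requested radius
(particles are quasi-spherical); `projection="facet"` keeps the facetted
polyhedron. Inter-capsomer distances differ by ~10% between the two
conventions, which is why the choice is explicit.

Prolate shells use the phage-style elongated icosahedron: two *(h, 0)*
icosahedral caps about a fivefold axis joined by `q_rings` hexagonal rings
of 5*h* capsomers rolled on a cylinder whose circumference equals the
seam-ring perimeter. The caps are cut from the sphere-projected *(h, 0)*
lattice at the pentamer-ring plane; successive tube rings advance by the
hexagonal row pitch (√3/2 × spacing) with a half-step azimuthal offset, and
the bottom cap is phase-rotated to continue the lattice. The construction
is exact combinatorially (capsomer count 10*h*² + 2 + 5*h*·q, always 12
pentamers, closed); metrically it is an idealisation — real irregular
particles need not be bodies of revolution, and the prolate family is one
representative of mixed-T geometry, not a claim about how any particular
virus deviates from sphericity.

Perturbation displaces each capsomer by an isotropic Gaussian (σ per axis,
nm) and removes a uniformly random subset (`round(drop_fraction·N)`), with
a single integer seed feeding one `numpy` Generator; provenance (source
expression and seed) is carried on the `CapsomerSet`.

## Neighbor graph and classification

Adjacency comes from a distance cutoff at `cutoff_factor` (default 1.4) ×
the median nearest-neighbor distance, chosen to sit between the first
lattice shell (~1.0 spacings) and the second (~√3). On ideal lattices the
margin is comfortable (longest true edge ≤ 0.93 × cutoff, shortest
non-edge ≥ 1.07 × cutoff across the (h ≤ 4) grid). Under heavier
positional noise the tails of the two shells meet and the cutoff graph can
break single first-shell edges, which is fatal to per-particle verdicts:
one broken edge creates two spurious "pentamers". The package therefore
also provides a spherical-Delaunay mode (convex hull of the radial
direction vectors, edges pruned at 1.8 × median NN distance to avoid
spanning the openings of partial shells), and an `auto` mode used by the
analysis pipeline: build the cutoff graph; only if it fails fullerene
closure while the Delaunay graph passes, switch to the latter — with a
logged warning and the chosen mode recorded in the graph and in reports.
At σ = 5% of the lattice spacing this recovers the correct icosahedral
verdict in 700/700 seeded trials across the (h ≤ 4) grid, where the plain
cutoff graph fails tens of percent of trials on skew lattices.

Classification is purely combinatorial: degree 5 → fivefold; degree 6 →
pseudothreefold if any neighbor is fivefold, else threefold; any other
degree → `edge`. Boundary capsomers of incomplete shells and 7+-coordinated
noise artifacts are thus excluded from class statistics rather than being
forced into one of the three symmetry classes; reports carry the excluded
count. Closure requires every degree in {5, 6} and disclination sum
Σ(6 − degree) = 12.

## T-number walks

A two-axis integer frame is transported from one pentamer across the
hexamer sublattice by breadth-first search. At every node the neighbors
are ordered counter-clockwise about the outward normal (position minus
particle centroid); a hexamer's six cyclic neighbors realise the six axial
unit steps, and the frame is carried across each edge by matching the
back-edge to the opposite direction. Pentamers are never transported
through: a pentagonal disclination removes a 60° wedge and makes transport
path-dependent, so walks are restricted to hexamer-only corridors. All
coordinates reaching the target pentamer are collected and the minimal-T
one is reported ("shortest route" semantics); directly adjacent pentamers
give (1,0). The five possible seed orientations at the start pentamer are
related by 60° lattice rotations and leave T unchanged. Results are
canonicalised to h ≥ k ≥ 0 under the 12-element hexagonal point group,
merging enantiomers; T is chirality-blind.

Per-particle verdicts: neighboring pentamer pairs are the convex-hull
edges of the 12 pentamer direction vectors (exactly 30 for icosahedral
particles) or, for incomplete shells, mutually-nearest pentamer pairs.
`icosahedral(T)` requires every pair resolved, all local T equal, and
agreement with the capsomer-count T = (N − 2)/10; closed shells with
heterogeneous local T are `mixed`; open shells are `incomplete` and never
receive a global T — their resolvable local values are listed. The ASU
decomposition divides each class's subunit contribution by 60 (fivefold
5·n₅/60, hexamer classes 6·n/60) and is defined only for icosahedral
particles; multiplicities always sum to T.

## Density maps and profiles

Rendering places unit-amplitude Gaussian blobs at capsomer centers in an
auto-sized box (3σ padding; maps with fewer than 8 voxels across the
particle are rejected). Interior morphologies emulate thin-section
appearance of immature vs mature particles: `thick_shell` adds a broad
band (center 0.75 R, width 0.12 R) under the capsomer layer;
`condensed_core` a central ball (σ = 0.25 R). Their amplitudes are set
relative to the rendered capsid layer's rotational-average density (0.75×
and 0.8×) so that the radial-profile peak remains the capsid shell for
both types — matching the observation that immature and mature particles
are assigned the same radius from their profile peaks. The generator makes
no attempt to model tomographic artifacts (missing wedge, CTF), membrane
layers, or intensity scales of real data; passing tests demonstrate the
analysis logic, not detector physics.

Radial profiles use one bin per voxel width with no smoothing. Center
estimation segments a Gaussian-smoothed copy of the map (escalating
smoothing scales 2, 4, ~min(shape)/8 voxels until the component picture
stabilises), takes the center of mass of the dominant component, and
refines by voxel-step hill climbing on profile sharpness (peak height /
half-max width). Two comparable, well-separated components raise an
explicit ambiguity error rather than returning a midpoint; flat maps raise
a no-particle error.

Morphology typing scores each profile by the ratio of mean density inside
0.6 × shell radius to the shell-peak density, with the shell radius taken
from a 3-bin-smoothed profile (the first two bins are skipped — their
voxel counts are too small to average noise). The two-group threshold
maximises between-class variance (Otsu on the 1-D statistic); the split is
declared degenerate — one label plus a warning — when the group means are
closer than the summed within-group spreads. A genuinely single-group
cohort whose statistic variance mimics two clusters can evade this check;
with the generator's two morphologies at signal-to-noise 1 the typing is
>99% accurate over 50 seeded 40-particle mixtures.

Cyclic-symmetry spectra resample the map on a cylindrical grid (1°
azimuthal step, linear interpolation) about a user-supplied axis and
center, and score order n as the Pearson correlation between the grid and
the map resampled 360°/n further. Note that smooth objects correlate well
under small rotations regardless of symmetry, so large n are mildly
favored on near-uniform objects; a flat spectrum (range < 0.05 for n ≥ 2)
is flagged ambiguous instead of trusting the argmax.

Align-and-average is translational only (integer-voxel circular shifts at
the FFT cross-correlation peak), mirroring simple in-cell particle
averaging; rotational alignment is out of scope. FSC uses shells one
frequency-voxel wide, normalised cross-correlation per shell, and
threshold crossings (0.5, 0.143 conventions) by linear interpolation; no
masking or phase-randomisation corrections are applied. The shrinkage
correction is the plain linear rescaling length × factor used to convert
measurements in embedded material to pre-embedding dimensions (e.g. factor
25/21 maps a 21 nm measured radius to 25 nm).

## Packaging arithmetic

bases/Gag = 1000·kb·copies / subunits and nm³/base = volume / (1000·kb·
copies), with the exact identity bases/Gag × subunits × nm³/base = volume.
The interior volume is a user input, not derived from a radius — which
surface bounds the interior is a modelling choice the caller must make (a
labelled (4/3)πr³ helper is provided). One-significant-figure roundings
accompany the raw values, matching how such estimates are usually quoted.

## File formats and reproducibility

Capsomer tables are plain CSV (UTF-8, dot decimal, mandatory header,
multiple particles keyed by `particle_id`); coordinates are written
particle-centered and read back at full precision (`float_precision=
"round_trip"`). Density maps are MRC2014 via gemmi, mode 2 only, with the
header voxel size and ORIGIN in Å converted to nm in memory; start-index
records are ignored (dialects disagree) with a logged note. Lattice maps
export as Chimera CMM marker XML, pentamers blue / threefold yellow /
pseudothreefold green / boundary gray, with links for lattice edges. Every
CLI report embeds a provenance block (package version, seed, options); a
fixed configuration reproduces byte-identical reports.

## Problem sizes and determinism in the test suite

Statistical checks use 50 seeds throughout: T-recovery runs the full
pipeline on all fourteen (h ≤ 4) lattices (12–482 capsomers) at σ = 5% of
spacing; morphology mixtures use 40 particles per seed rendered at 2 nm
voxels from a 92-capsomer shell at r = 24 nm. Hypothesis-based property
tests run derandomised. All randomness flows through explicit integer
seeds.

## Known limitations

- Frame transport assumes an outward normal from the particle centroid;
  strongly non-convex or tubular fragments can defeat the cyclic neighbor
  ordering.
- The spherical-Delaunay fallback assumes a star-convex shell; it is never
  applied silently.
- Walks on heavily damaged lattices report only what hexamer corridors
  survive; pairs blocked by adjacent pentamers or holes are listed as
  unresolved, not guessed.
- The synthetic prolate family is one mixed-T geometry among many; mixed-T
  verdicts on real particles do not imply this construction.
- FSC is unmasked; values from tightly boxed particles include solvent
  correlation.
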
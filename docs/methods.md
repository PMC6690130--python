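# Methods

This note records the model behind each processing stage, the defaults
that matter, and the choices made where the design was genuinely open.

## Geometry and conventions

Pixel coordinates have their origin at the centre of the top-left pixel,
*x* rightward, *y* downward, 0-based. Reciprocal space is in Å⁻¹. The
goniometer axis lies in the detector plane at azimuth φ from the pattern
*y*-axis; its unit vector is **u** = (sin φ, cos φ, 0) and the tilt is a
right-handed rotation about **u**. A diffraction frame records the
intersection of the reciprocal lattice with the Ewald sphere of radius
1/λ tangent to the detector plane at the pattern centre; back-projection
therefore assigns a detector position at planar radius r the out-of-plane
component

    g_z = 1/λ − √(1/λ² − r²),

positive toward the electron source, before rotating by the frame's tilt
angle about **u**. For r → 0 this approaches the planar approximation
λr²/2; the exact curvature factor 2/(1 + √(1 − (λr)²)) stays within 1% of
it for r ≤ 0.195/λ. Positions with r ≥ 1/λ are geometrically impossible
and rejected.

Electron wavelengths come from the relativistic de Broglie relation with
CODATA constants; 300 kV gives λ = 0.019687 Å. The diffraction-limited
probe FWHM uses the Airy prefactor 0.51·λ/α (≈ 2.0 nm at 300 kV and
0.5 mrad). Equal-dose exposure scales as the illuminated area,
t₂ = t₁ (d₂/d₁)².

## The simulator (ground truth for every solver)

The generator is a purely geometric forward model. For each frame at tilt
η every lattice node **g** = B·hkl with d ≥ d_min is rotated into the lab
frame, and the extra tilt Δη that would carry it exactly onto the Ewald
sphere is solved in closed form (A cos θ + B sin θ = C with A = v_z,
B = (u×v)_z, C = λ|v|²/2). A node is rendered when |Δη| ≤ the rocking
half-width, at the detector position of the sphere crossing, as a
normalized Gaussian spot whose total counts are the node amplitude times
a triangular falloff 1 − |Δη|/rocking. The rocking width stands in for
precession/fine-step integration of the excitation error; the hollow-cone
path itself is not modelled. Consequences used by the tests:

* rotations about one axis commute, so back-projecting a rendered spot
  recovers R(Δη)·g — the position error of the whole method is bounded by
  the rocking arc;
* with rocking width = tilt step, the triangular samples on consecutive
  frames form a linear partition of unity: summed over frames, an
  interior node integrates to exactly its amplitude.

Node amplitudes are drawn log-uniformly from (300, 6000) counts, keyed by
the canonical (sign-normalized) hkl so Friedel mates are exactly equal,
as kinematical intensities are; there are no structure factors, since the
processing chain only needs geometrically exact, stable intensities.
Poisson noise (optional, on by default) and an optional central beam
(2×10⁵ counts, σ = 2.5 px) complete the frame. All randomness flows from
one integer seed through named SeedSequence channels, so identical seeds
give bit-identical frames. Defaults emulate the acquisitions the package
targets: 0.2–1° tilt steps over a ±45° wedge, 1° rocking, 256² detector,
spot σ ≈ 1.2 px.

Diffuse rods (the signature of planar disorder: continuous lines along
one lattice direction) are added by sampling the rod finely in its
parameter t and rendering every sample whose sphere-crossing tilt lies
inside the rocking width — each frame thus shows the short segment of rod
it actually cuts, and the number of rendered samples scales inversely
with the tilt step. The rod profile along t is flat with amplitude in
counts per pixel of rod length; no quantitative disorder model is
implied.

What the simulator deliberately omits — detector PSF/MTF, inelastic
background, dynamical diffraction, goniometer drift — means that passing
recovery tests demonstrates the correctness of the geometry and
bookkeeping, not robustness to every instrumental artefact of real data.

## Centring and peak search

The direct-beam centre is the intensity-weighted centroid of the
connected region above the 99.9th percentile that maximizes
(peak intensity × extent); ties go to larger extent, then lower y, then
lower x. The Friedel route votes over all peak-pair midpoints (tolerance
2 px) and refines the winner as the mean of accepted midpoints. Per-frame
manual overrides in the metadata sidecar always win.

Peak search thresholds at median + k·1.4826·MAD (k = 5) unless an
explicit threshold is given, labels 8-connected components, and keeps
clusters of ≥ 4 px. Each peak carries the centre of gravity, summed
counts, the intensity density over the bounding rectangle and the
rectangle aspect; elongated clusters (aspect > 5 by default) are split
off into a shape-flagged list rather than silently dropped. The density
filter exists but is off by default — no principled cutoff is known.

## Tilt-axis search

For a candidate φ all peaks are back-projected, pairwise difference
vectors (magnitude ≤ 1 Å⁻¹, at most 2×10⁵ nearest pairs, selected once at
a reference φ since pair *selection* barely depends on φ) are normalized
to the unit sphere, folded to the z ≥ 0 hemisphere (difference vectors
are sign-ambiguous), projected stereographically from the south pole and
accumulated on a 512×512 histogram. The score is the sum of squared bin
counts — a peakiness functional; its absolute value is meaningless, only
the recovery and invariance behaviour is contracted. A 1° coarse scan
over [−90°, 90°) is refined by golden section to 0.01°. Solutions from
fewer than 10 peaks or 5 frames, or with a flat score curve
(max/median < 1.05), are flagged unreliable. Noiseless recovery across 12
ground-truth azimuths is better than 0.05°, well inside the contracted
0.5°. The axis is assumed constant over the measurement; no drift model.

## 3-D peaks and merging

A node sampled on consecutive frames while traversing the rocking width
must become one 3-D peak. Merging links back-projected peaks on adjacent
frames closer than a radius, takes intensity-weighted positions and sums
counts. The default radius is the smaller of two scales: 0.75× the
expected node spacing (estimated before any cell is known as the median
nearest-neighbour 2-D peak distance, so distinct nodes never merge) and
the physical frame-to-frame travel of a node, 1.5·g_max·sin(Δη) plus a
3-px centroid-noise floor. The second bound matters: at typical spot
densities the nearest-neighbour estimate alone is of the order of a
reciprocal axis and would fuse the lattice. Union-find components are
restricted to frame gaps ≤ 1; merging is idempotent on its output.

## Cell determination

Difference vectors of the (strongest 400) 3-D peaks, capped at 0.35 Å⁻¹
from the origin and sign-normalized to a canonical hemisphere, are
clustered density-based (DBSCAN) honouring the three user parameters
eps = max intra-cluster distance (default 0.01 Å⁻¹), minPts (default 4)
and max origin distance. Cluster centres approximate the translation
lattice. Basis search scores triples of the 30 shortest centres by the
weighted fraction of all centres within 0.25 (fractional) of integers;
ties break toward the smaller direct cell volume, then lexicographic
parameters. The winner is least-squares refined over its indexed centres
(two passes) and Niggli-reduced (Krivy–Gruber, with the change of basis
applied to the orientation matrix, so B stays consistent with the
reduced scalars). A best indexed fraction below 0.5 raises a no-lattice
error, as does a cluster set that does not span 3-D. Indexing is
hkl = round(B⁻¹g) with the largest fractional residual below 0.25.

## Intensities and statistics

Per-observation intensity is the sum over the source-frame contributions
merged into one 3-D peak (maximum-projection across frames is available
as an option in the reconstruction but summation is the integration
default); σ = √I floored at 1 count. Merging supports the 11 Laue classes
(2/m unique axis b; trigonal/hexagonal on hexagonal axes), always merges
Friedel pairs, canonicalizes each orbit to its lexicographically greatest
member, and reports

    R_int = Σ_hkl Σ_i |I_i − ⟨I⟩| / Σ_hkl Σ_i I_i

over groups with ≥ 2 observations, with merged σ = √(Σσᵢ²)/n.
Completeness is purely observational: 100 × observed unique / all
symmetry-unique nodes with d ≥ d_min, the denominator enumerated by brute
force over the hkl box bounding the resolution sphere. Nothing is
imputed. On synthetic data the R_int of a noisy run reflects partial
rocking integration (samples lost below the detection threshold at the
rocking tails) exactly as it does in measurements without frame scaling.

## Voxel volume and diffuse extraction

Reconstruction deposits every detector pixel at its Ewald-corrected 3-D
position by nearest-voxel assignment, accumulating by maximum (default —
robust against the uneven sampling density of a tilt series) or by sum
(which conserves the total in-bounds intensity exactly and is used as a
bookkeeping check). Grids are cubic, centred on the origin, sized to
cover the corner radius of every frame; a configurable voxel cap
(default 320³) raises a resource error with a suggested voxel size
instead of exhausting memory.

Zone projections take the direct-lattice zone vector, project the slab
|g·n̂| ≤ thickness/2 through the origin onto the plane, and label the
axes with the two shortest reciprocal lattice vectors in the zone.
Profiles along a pathway B·(anchor + t·direction) are sampled on a grid
of `samples_per_unit` points per direction unit; the value at each sample
is the mean over an integration-tube stencil (centre plus two rings of 8
points at radius/2 and radius) built in the plane perpendicular to the
path, evaluated by trilinear interpolation (nearest-voxel mode exists for
exactness tests). The perpendicular stencil makes profiles
rotation-covariant: rotating volume and orientation matrix together
changes profiles only by interpolation error (< 2% for features resolved
by ≥ 3 voxels). The tube mean (not sum) keeps profiles invariant under
thickness changes; the default radius is 1.5 voxels. Samples outside the
reconstructed wedge are flagged, not zero-filled; below 80% coverage the
extraction refuses and reports the missing t-range. Profiles are reported
raw — the inelastic halo under diffuse features is left to the user, as
no defensible automatic background model exists without an energy filter.

## Problem sizes in the shipped tests

The test suite and the acceptance script run tilt series of 97–181 frames
at 160–256 px and d_min 1.3–1.8 Å. These sizes put every stage through
realistic spot densities (≈ 20 peaks/frame, ≈ 1000–2000 peaks/series)
while keeping a full chain run around 20 s; the recovered-parameter
tolerances quoted in the tests (0.5° axis, 2% / 1° cell) are unchanged
from the larger acquisitions the defaults emulate, because the governing
scales (rocking width vs step, spot σ vs spacing) are preserved.

## Known limitations

Goniometer wobble and tilt-axis drift are not modelled or corrected; no
frame-to-frame scaling; no absorption or dynamical-intensity correction;
no automatic space-group determination from systematic absences; vendor
microscope formats are not read (TIFF/MRC + JSON/YAML sidecar only);
near-degenerate basis triples are resolved by the deterministic
tie-break, with manual cell override available rather than guessed.
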
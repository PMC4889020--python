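# Methods

## Grid conventions and units

Volumes are arrays indexed `(z, y, x)` with z the section/depth axis; voxel
spacing is isotropic in micrometres (default 8 µm, the working resolution of
micro-CT protocols for paraffin-embedded lung blocks, at which slice index k
sits at depth 8k µm and 125 slices span the conventional 1 mm annotation
depth). A voxel is the closed cube `[i·s, (i+1)·s]` per axis. Focus volumes
are reported in µm³, tissue volumes in mm³, number densities per mm³, and
section profusion per cm² — the units the field prints. Metadata (spacing,
origin, kind) lives in a JSON sidecar next to each multi-page TIFF;
TIFF resolution tags are deliberately ignored so there is exactly one source
of grid truth.

## Connectivity and the Euler–Poincaré characteristic

Foreground connectivity is 26-adjacency (shared face, edge or corner joins
voxels); the complementary background is read with 6-adjacency, the standard
pairing that makes cavity semantics consistent. χ is computed on the *closed
cubical complex*: χ = V − E + F − C over the distinct vertices, edges, faces
and cubes of the union of closed voxel cubes. Under this convention a solid
blob scores 1, a solid torus 0, a hollow shell 2, and χ is additive over
components. The implementation counts each cell class with vectorized
logical ORs of shifted occupancy arrays (a d-cell is present iff any of its
2^(3−d) incident voxels is foreground); its correctness is defined — and
tested — against a brute-force enumeration of the explicit cell sets, not
against the method itself. An alternative estimator family computes χ from
2×2×2 octant counts; exact enumeration was chosen because it admits a
transparent oracle.

The quantity reported for the discreteness question is
`loops_estimate = n_components − χ_total`, which counts independent loops
*provided no component encloses a cavity*. Since a cavity-free component has
χ ≤ 1, any per-component χ > 1 raises `cavity_warning` and the loop estimate
should then not be read as network redundancy. "No interconnectivity" is the
observation χ_total = n_components.

## Phantom generator

The generator emulates a paraffin-embedded fibrotic lung sample: a paraffin
bath (gray mean 80 on an 8-bit-like scale), a tissue block (160) with
spherical airspaces (75, alveolus-scale radii 32–80 µm), and fibroblast foci
(120) — darker than surrounding tissue, brighter than paraffin, which is the
contrast that makes larger foci visible in real scans. Gaussian noise
(σ = 5 by default) is added to every voxel. All randomness flows from one
seeded generator per call; identical configurations are bit-identical.

**Focus shapes** are unions of `complexity` overlapping random ellipsoids
chained so each lobe's center lies inside an earlier lobe, then rescaled
until the voxelized volume is within ±10 % of the requested target (exact
convergence for multi-hundred-voxel targets; a 1-voxel target is honored
exactly). Each shape is verified to be a single 26-connected component with
χ = 1 (cavities filled, pathological draws re-sampled, with a digital ball
as final fallback). Real foci have no published per-lesion shape statistics,
so lobed blobs are a heuristic that reproduces the qualitative "multiform"
appearance; shape descriptors measured on them validate bookkeeping, not
biology.

**Placement** draws the focus count from Poisson(density × tissue volume),
floored at one focus (two in reticulum mode), samples per-focus volumes
log-uniformly, and rejection-samples positions inside the tissue block with
a minimum pairwise Chebyshev separation (default 24 µm = 3 voxels), so
discrete-mode truth is unambiguously disconnected. Large foci are placed
first. The default volume range is 1.6 × 10⁴ – 5 × 10⁶ µm³: the lower end is
the smallest lesion scale of interest, and the upper end is set so that the
largest focus still fits inside the default 2 × 2 × 1 mm phantom with the
separation constraint — observed lesions in large-field scans reach
~10⁸ µm³, and the range is configurable up to that scale for larger
phantoms. Airspaces are stamped last, avoiding foci, and are cosmetic: they
threshold out with the background.

**Reticulum mode** merges all foci into one network: a Euclidean minimum
spanning tree over per-focus interior points contributes F−1 cylindrical
bridges (radius 16 µm by default), then each of `n_extra_edges` additional
bridges adds exactly one independent loop. Every tube is accepted only if it
changes (components, χ) by exactly the intended delta — (−1, −1) for tree
edges, (0, −1) for loop edges — recomputed on the trial volume; rejected
tubes are re-routed through jittered waypoints. The final volume is verified
to have one component and χ = 1 − n_extra_edges, so the truth the phantom
advertises is checked, not assumed.

What the phantom does *not* emulate: X-ray acquisition physics (beam
hardening, ring artefacts, reconstruction filtering), histological texture,
intensity gradients within lesions, and anisotropic section distortion.
Passing recovery tests on phantoms therefore demonstrates that the pipeline
measures what is in a volume correctly; it does not certify segmentation
performance on real scanner data.

## Tissue segmentation

The global threshold is the arithmetic mean gray value of a known paraffin
region (nominally 1 mm³ ≈ 1.95 × 10⁶ voxels at 8 µm, giving a standard error
of ~0.004 gray levels at σ = 5; smaller regions are accepted with a
warning). Classification is strict: tissue ⇔ gray > threshold + margin, so
ties go to paraffin, conservative for tissue volume. The `margin` exists
because thresholding a noisy image *at* the paraffin mean sends half the
paraffin voxels over the line; the pipeline default of 20 gray levels places
the cut midway between the default paraffin (80) and focus (120) means,
≥ 4σ from both, so misclassification is at the 10⁻⁵ level before smoothing.
With the default intensities this reproduces analytic tissue volumes to
≪ 1 %; for other contrast settings the margin is a free parameter.

Mask smoothing is a majority vote over the face-connected cross neighborhood
(the 6r+1 voxels on the axis segments through each voxel; default r = 1,
one pass). The cross neighborhood — rather than the full (2r+1)³ cube — is a
deliberate choice: cube-neighborhood majority erodes the corners and edges
of solid blocks, whereas the cross vote leaves solid blocks exactly fixed
while still deleting isolated speckle and filling pinholes. The neighborhood
is odd-sized, so ties cannot arise; the tie-keeps-input rule is retained for
safety. The commercial label-smoothing functions used in practice are
unpublished, so this filter is defined by its stated properties.

## Slice assembly and shape-based interpolation

Manual lesion annotation arrives as sparse 2D label images at known depths,
with gaps where sections are lost (ribbon breaks). Present slices are copied
verbatim. A missing slice inside a gap of at most `max_gap` slices (default
3 ≈ 24 µm) is reconstructed per label by linearly blending the signed
Euclidean distance maps of the two bounding slices at the slice's fractional
position and thresholding at zero. This shape-based rule restores constant
cross-sections exactly, interpolates disc radii linearly (radii 4 and 8
bounding a gap give 6 ± voxelization), and degrades gracefully for cones.
A label absent from either bounding slice does not enter the gap — extending
a lesion into a gap it may not cross would fabricate connectivity, the exact
quantity under study; for the same reason gaps wider than `max_gap` are left
empty with a warning rather than bridged.

## Morphometry

Per-focus: voxel count, volume (count × spacing³), centroid, bounding box,
axis extents, per-component χ, sphericity π^(1/3)(6V)^(2/3)/A, and
elongation. The surface area A is the exposed-voxel-face count times the
face area, which overestimates the area of smooth bodies by up to ~1.5×
(faces are axis-aligned), so sphericity is biased low for round objects and
can slightly exceed 1 for perfect cubes; the descriptors are reproducible
and comparable within the package but are not certified surface metrology.
Elongation is the square root of the ratio of extreme eigenvalues of the
voxel-cloud covariance, regularized by the single-voxel moment (1/12 per
axis) so lines and plates stay finite and a single voxel scores exactly 1.
Foci touching the volume boundary are included but flagged as censored.
No minimum-size filter is applied by default; an optional volume floor
exists because lesions under ~200 µm are typically not resolvable in the
gray data when labels come from intensity rather than histology.

Case summaries report n, tissue volume, density n/V, the volume extremes and
their fold range. With zero foci the volume fields are absent (`None`),
never NaN, and density is 0.

## Profusion

Sections are sampled every 24 µm by default (inside the conventional
20–30 µm stereological band, snapped to a multiple of the voxel spacing).
In-plane islands are counted with 8-connectivity — the 2D analogue of the
3D faces/edges/corners rule — and divided by the tissue area of the same
slice (per cm² *of tissue*, not of field). The 0–6 semiquantitative scale
has no published bin edges; the defaults are log-spaced over 1–1000 foci/cm²
with 0 reserved for exactly zero and saturation at 6, and every conclusion
drawn from the score relies only on monotonicity and the 0 ↔ 0 anchor.
Intratissue variability is the max/min ratio of nonzero per-section
profusion; an all-zero stack has no defined ratio and is reported as such.

## Registration and association

Histology-to-CT registration fits a planar transform to ≥ 2 (similarity) or
≥ 3 non-collinear (affine) manually matched landmark pairs by closed-form
least squares — Umeyama's method for similarity (scale > 0, rotation,
translation; degenerate configurations rejected by name), normal equations
for affine. Similarity is the default model: sectioning geometry is rigid up
to uniform shrinkage, with affine available for shear. Landmark sets are
small and curated, so no robust reweighting is applied. Resampling is
bilinear with a declared fill value; whole-pixel translations are exact.

The density–FVC association is a single exploratory OLS (p from t with
n − 2 df, via `scipy.stats.linregress`); a constant response is reported as
slope 0 with r² = 0 and p = 1. No multiple-testing correction is applied to
the single test. Cohorts at this imaging depth are tiny, so n < 10 raises a
wide-uncertainty flag and p < 0.05 is attached as a label, never used as a
filter.

## Problem sizes and numerical choices

Validation runs use discrete phantoms at the full default scale
(250 × 250 × 125 voxels = 2 × 2 × 1 mm, 5 foci/mm³, σ = 5) and reticulum
phantoms at 120 × 120 × 80 voxels with 0, 1 or 3 extra loop edges — sizes
chosen so a complete study (20 seeds per mode) completes in well under a
minute per mode on one core while keeping per-phantom expected focus counts
high enough that the at-least-one-focus floor does not bias density
estimates. Oracle suites enumerate all 512 single-slice configurations and
100+ random volumes. Determinism is end-to-end: identical run configs
produce byte-identical CSV/JSON reports.

## Known limitations

- The loop estimate is only valid for cavity-free components; cavities are
  flagged, not resolved into separate Betti numbers.
- Focus labels are inputs; the package does not detect foci from gray
  values, matching the histology-driven identification workflow.
- Phantom realism is geometric, not radiological; see the generator section
  for what recovery tests do and do not show.
- Sphericity inherits the face-count area bias; compare values only within
  this package.
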
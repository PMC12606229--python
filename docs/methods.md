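# Methods

`ctfiber` characterises collagenous connective tissue in 3D colour volumes:
it segments collagen-rich voxels by colour, converts anisotropic stacks to
cubic voxels, measures a directional minimum-thickness field, computes local
orientation tensors with a Westin fibrous/planar/spherical classification,
and aggregates both over anatomical label maps. This note records the model
choices, the parameters that matter, the numerical conventions, and what the
synthetic phantoms do and do not establish.

## Colour segmentation

Collagen-containing connective tissue occupies a narrow, near-white band of
RGB space in cryo-section photographs; peri-organ tissue and the tissue
embedded in subcutaneous fat differ slightly in hue, motivating two colour
classes. The classifier is deliberately simple and fully configurable: a
3×3 linear transform of the (r, g, b) triple followed by nearest-reference
assignment, with a per-class acceptance radius (`max_distance`, in
transformed-space units) beyond which a voxel is background. Ties go to the
lowest class id, so segmentation is deterministic. The shipped default model
(identity transform; references (235, 230, 220) and (205, 190, 165); radius
60) separates whitish tissue classes from reddish muscle/fat backgrounds and
is intended for phantom work — real stacks need a model fitted to their own
staining, and no published constants exist for the classic cryo-section
datasets, so their deposited segmentations cannot be regenerated bit-exactly.

Artefact removal deletes 26-connected components below a voxel-count
threshold, computed on the union of all classes so a small class-2 fragment
attached to a large class-1 body survives. Missing cross-sections (the
quarter-block gaps of cryo-sectioned bodies) are filled by shape
interpolation: the signed Euclidean distance fields of the bounding valid
slices are interpolated linearly at the missing slice's fractional position
and re-thresholded at zero. This preserves topology (a disc shrinking from
radius 10 to 6 passes through radius ≈ 8) where per-voxel intensity
interpolation would blur the boundary; a missing slice with only one valid
neighbour copies it.

## Isometric binning

Direction-unbiased ray casting requires cubic voxels. Binning produces
*count* volumes: each target voxel counts the source voxels inside it, so
the conserved quantity is the count sum (physical tissue volume = counts ×
source-voxel volume). Integer spacing ratios use exact non-overlapping
block summation. Non-integer ratios distribute each source voxel over the
target voxels it geometrically overlaps (separable per-axis overlap
weights), then round to integers with a deterministic cumulative-sum carry:
every voxel is within one count of its exact overlap value and the total is
conserved to within half a count. Plain per-voxel rounding was rejected
because it biases a uniform fractional density (e.g. a 1.5× ratio gives
3.375 everywhere, which would round to 3 and lose 11 % of the mass).
Counts are stored 16-bit unsigned; overflow raises. Upsampling is refused.

## Ray casting and the boundary convention

All directional measurements step by integer lattice generators, landing
exactly on voxel centres — deterministic and checkable against a naive
per-voxel oracle, at the cost of a documented undercount of diagonal chords
through curved surfaces (the centre of a radius-10 ball measures
11√3 ≈ 19.05 voxel edges rather than 21, because the (1,1,1) chord
undercuts the axis chord). Direction sets are all primitive integer vectors
with components in [−n, n]; n = 1 gives 13 axes (26 signed directions),
n = 2 — the default — 49 axes (98 directions), bracketing the minimum chord
within ~13° of angular resolution.

A ray stops at the first background voxel. Samples that fall outside the
grid replicate the nearest in-grid voxel (edge padding): the volume crop is
not a tissue boundary, so a slab spanning the grid measures its true
thickness even at the lateral crop edges, while background stays background
beyond the crop. Blanket alternatives fail in opposite directions —
treating out-of-grid as background truncates in-plane diagonal chords at
crop corners (a grid-spanning slab of thickness 3 would read √2 at its
corners), while treating it as foreground inflates oblique rays that leave
through a lateral face (slab border voxels would read partly spherical).

## Thickness field

For each tissue voxel, the chord along an axis is
(r₊ + r₋ + 1)·‖g‖·s, with r± the capped run lengths along ±g and s the
voxel edge; the voxel's thickness is the minimum chord over the axis set.
The centre voxel counts once, so the smallest possible thickness is one
voxel edge — consistent with whole-body minima equal to the voxel size.
The default per-ray cap of 64 steps matches the working scale of
whole-body data at 0.5/0.33 mm voxels; values therefore lie in
[s, 129·maxnorm·s], and interiors deeper than the cap saturate at 129·s on
the axis chord.

Generators with a component of magnitude 2 (present from n = 2 up) step
two voxels at a time and can skip entirely over structures up to two
voxels thin: a 3-voxel slab measured from its mid-plane along (1, 0, 2)
collapses to a single-voxel chord of √5·s ≈ 2.24·s, undercutting the true
3·s. The denser axis set buys angular resolution on thick structures at
the price of this thin-structure artefact; for structures near the voxel
scale, measure with the n = 1 axes (which step one voxel on every
component and cannot skip). Background voxels carry 0 rather than a missing value so
fields store directly as NIFTI; consumers mask by the segmentation.

## Orientation tensors and Westin classification

At each tissue voxel, every direction of an *unreduced* set (both signs of
every axis, so each voxel sees the same number of orientations) yields a
scan vector xᵢ = rᵢ·d̂ᵢ with rᵢ = 1 + capped run length. The local
second-moment tensor is the dyadic sum A = Σᵢ xᵢ⊗xᵢ = Σᵢ rᵢ² d̂ᵢd̂ᵢᵀ — the
r² weighting is not a tunable knob but the consequence of the dyadic
product. The scan cap of 16 voxels sets the scale of the measurement:
structures larger than the scan window read as spherical even if they are
planar at a larger scale. An alternative neighbourhood-aggregation mode
(`mode="neighborhood"`, following fascicle-tracing work) is available:
each voxel contributes one vector along its longest bidirectional chord,
and tensors sum those vectors over a box window. It is not the default —
the ray-vector reading keeps each voxel's sample count identical by
construction, while the best-direction estimate is unstable in near-
isotropic tissue (ties break to the first axis in lattice order).

Eigenvalues are sorted descending and clamped at −10⁻⁹·λ₁ (dyadic sums are
PSD up to round-off). Eigenvector signs: largest-magnitude component
positive for e₁ and e₂, then e₃ = e₁ × e₂ — the two conventions
(per-vector sign and right-handedness) can conflict, and right-handedness
wins for e₃. The sum-normalised Westin measures

    c_l = (λ₁−λ₂)/S,  c_p = 2(λ₂−λ₃)/S,  c_s = 3λ₃/S,  S = λ₁+λ₂+λ₃

form a partition of unity mapping directly to RGB; the λ₁-normalised
variant does not and was not chosen. Classification is argmax with an
optional dominance threshold θ (default 0; published regional proportions
not summing to 100 % imply some exclusion rule, so θ is exposed for users
who want to emulate one). Ties break fibrous > planar > spherical; a
zero-trace tensor is unclassified. Tensor grids are optionally
block-averaged (mean over member tissue tensors; default output bin 2,
matching deposited tensor files at doubled spacing).

## Regional statistics

Anatomical label maps, drawn at coarse resolution, are upsampled
nearest-neighbour to the analysis grid. Per region: tissue volume in dm³
(count × s³/10⁶), thickness mean and *population* SD in mm over tissue
voxels (the choice between population and sample SD is undocumented in the
source datasets; population SD is used and trivially switchable), and class
percentages of tissue voxels (the remainder unclassified). Region label 0
is excluded. CSV output is rounded to two decimals, labels ascending.

## Phantoms: what passing tests show

The phantom generator rasterises slabs, cylinders, balls and cuboids by the
voxel-centre rule (no partial-volume antialiasing), so foreground counts
are integer-exact against enumeration oracles. Noise is limited to
independent Bernoulli voxel flips and Gaussian per-channel colour noise,
both seeded; there is no global random state. Phantoms establish that the
implementation computes its definitions correctly (exact tensors on
hand-derivable geometry, exact chords, conserved counts, closed
segmentation loops). They do not emulate real histology: no texture, no
staining gradients, no curved fascicles, no partial-volume mixing at tissue
interfaces, no registration error between sections. Recovery rates on
phantoms are therefore upper bounds on real-data performance, not estimates
of it.

## Problem sizes and determinism

The validation suite runs on 64³-and-smaller phantom grids (with one 131³
solid cube for cap saturation and 16³ random masks for oracle equality) —
large enough that every regime of the method (cap saturation, boundary
replication, block averaging) is exercised, while whole-body grids differ
only in extent, not in code path. All stochastic steps take explicit seeds;
pipeline re-runs with identical configuration produce bit-identical
artefacts (gzip payloads compared after decompression, since gzip headers
embed timestamps).

## Known limitations

- The colour transform for the classic cryo-section datasets is
  unpublished; the default model is a phantom-scale stand-in.
- Integer-generator rays undercut chords through curved boundaries
  (ball example above); thickness on strongly curved structures is a lower
  bound within the axis-set resolution.
- NIFTI orientation matrices are not interpreted beyond spacing; volumes
  are assumed axis-aligned. NIFTI-2 is rejected.
- The 64-voxel thickness range means structures thicker than
  129 voxel edges saturate; values beyond that range are not measured.
- Tensor e1/e2 colour maps are unweighted direction colours; no
  anisotropy-strength modulation is applied.
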
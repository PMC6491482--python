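# Methods

This note records the model behind `spherostack`, the parameters that
matter, the design choices made where the method description left the
design open, and what the synthetic benchmark does and does not show.

## Image model and conventions

A stack is an ordered list of multi-channel 2D slices with voxel size
metadata (defaults 0.345 × 0.345 × 0.432 µm). Channels are picked, not
luminance-mixed: the membrane role maps to the red (phalloidin) layer
and the nuclei role to the blue (DAPI) layer. The canonical working
intensity scale is 0–255 — all histogramming uses 256 classes — with a
[0, 1] normalized view used by the darkness rules; the conversion
factor is exactly 255. Inputs deeper than 8 bits are linearly rescaled
by their dtype range (65535 → 255). Slice 0 is the first acquired
frame, i.e. the top of the spheroid dome away from the culture
surface; a `reverse` flag accommodates bottom-up acquisitions.
Coordinates are row-major, 0-based; areas convert to µm² as pixel
count × pixel_size².

## Threshold selection

The progressive weighted mean (PWM) of the histogram assigns to each
class P the weighted mean of all bins up to P; it is monotone
non-decreasing and bounded by 0 ≤ PWM(P) ≤ P, with classes before the
first occupied bin defined as 0. A degree-10 least-squares polynomial
is fitted over all 256 classes with the abscissa mapped to [-1, 1] — a
raw degree-10 Vandermonde on 0..255 is numerically singular; the
mapping changes nothing in exact arithmetic. Inflections are located
by a dense sign-change scan of the fitted second derivative (2551
grid points, refined by bisection); a sign change is required, so
even-multiplicity touches never become candidates, and numerically
flat stretches (below 1e-9 of the curve's second-derivative scale) are
treated as zero so fit noise on featureless curves cannot fabricate
inflections. Candidates are rounded to integer classes and
deduplicated.

Each candidate is scored by binarizing at `intensity > t` (strict, per
the definition of objects as brighter than the threshold), labelling
8-connected components, and pooling the intensities of all object
pixels into one sample standard deviation (n−1). Pooling, rather than
averaging per-object deviations, matches the selection goal — one
scalar measuring how homogeneous the detected material is — and is
fixed here as the convention; the per-object alternative changes the
argmin only in contrived cases. The candidate with the lowest spread
wins; ties go to the lower threshold (the more inclusive
segmentation).

### What counts as a detection

Unconstrained, the minimum-spread rule degenerates: the upper tail of
any unimodal intensity distribution is always more homogeneous than
the distribution itself, so the argmin drifts to a handful of bright
specks; symmetrically, on background-dominated images the background
is the largest homogeneous region. Four validity rules, all phrased in
terms of what an *object* is, keep the competition meaningful:

1. components smaller than a minimum object area are not objects
   (membrane: the 1200 µm² spheroid rule; nuclei: 25 µm², the
   cross-section of the smallest plausible nucleus, ≈5.6 µm diameter);
2. a candidate whose objects cover more than 95% of the field has
   swallowed the background;
3. a candidate below the histogram's dominant mode cannot separate
   objects from background;
4. objects with mean normalized intensity below 0.10 are background
   glow, not stained structures (deliberately below the 0.20 cut-off
   rule so genuinely dim surface-contact frames still reach the
   cut-off scan).

When no candidate survives — a featureless slice — the selector falls
back to Otsu's threshold and logs a warning; downstream filters then
usually empty the mask, which is the correct outcome for a slice with
no object.

## Membrane segmentation

Per slice: threshold, flood-fill hole filling (the spheroid region is
the filled border; internal cavities belong to it), deletion of
components strictly below `min_area_um2` (default 1200 µm²), and
deletion of components darker than the 0.10 floor. Across slices, the
iterative refinement walks forward: frame i's retained objects form
the reference; every object O of frame i+1 with
|O ∩ R| / |O| < 0.75 is deleted, and the refined frame becomes the
next reference. The overlap denominator is the object's own area —
the rule description names no denominator, and the object-relative
form makes the rule scale-free per object. The first frame is never
modified, the output is pixelwise a subset of the input, and the
operation is idempotent. Leading empty frames pass through and the
first non-empty frame starts the chain; a strict reading (overlap
with an empty reference is zero) would erase every stack whose top
slice is below the area filter.

In the assembled pipeline, frames before the first *bright* frame
(mean in-mask intensity ≥ 0.20) are additionally cleared: the stack by
construction starts above the dome, so a detection there is
autofluorescent background, and — being dark — it would otherwise
trigger the cut-off scan at the top of the stack.

**Touching-spheroid separation.** The Euclidean distance transform of
the mask is computed per connected component; its regional maxima are
reduced by a minimum-separation rule — peaks closer than N px
(default 20, ≈6.9 µm) to a deeper accepted peak are merged, with
deterministic ordering by (depth, row, column) — and the surviving
peaks seed a watershed on the negated distance transform, constrained
to the foreground, with 1-px watershed lines assigned to background.
The neighborhood-size parameterization of regional-maxima extraction
is implemented as this minimum-separation rule; the textbook h-maxima
operator (whose natural parameter is a height, not a length) is
available as an alternative marker strategy. A component with a single
marker is returned unchanged (no-split guarantee), and markers are
extracted per component, so disconnected objects are never merged.

## Nuclei

The same threshold selection runs on the whole DAPI slice (scored
with the nucleus-scale validity area); the binary result is
intersected with the membrane mask of the same slice — objects outside
the spheroid are not analyzed — then cleaned by a speck filter
(default 7 µm², ≈3 µm diameter disc; 0 disables it) and the darkness
floor, and separated by the watershed with a 10 px (≈3.5 µm) marker
separation. The speck filter and the nucleus-scale marker separation
are extensions where the original description is silent; both are
configurable. Counts are per-slice 2D detections; nuclei are not
linked across slices. Every reported nucleus pixel lies inside the
membrane mask, which is asserted in the tests.

## Cut-off frame and 3D assembly

Scanning slices in order and skipping empty masks, the first slice
satisfying any of the following is the cut-off frame, with the
lowest-numbered satisfied rule reported:

1. **intensity** — mean normalized membrane-channel intensity inside
   the mask < 0.20 (the frame is too dark for reconstruction);
2. **shape difference** — |area_i − area_prev| / area_prev > 0.30,
   where `prev` is the previous non-empty mask (skipped for the first
   one); absolute change by default, growth-only behind a flag;
3. **solidity** — area / convex-hull area of the largest component
   < 0.60 (too irregular to be a single spheroid). The largest
   component is used because after separation a slice may hold several
   spheroids and a slice-global solidity would trigger spuriously.

The scan runs on the pre-refinement masks. This is a deliberate
ordering decision: an area jump above 30% implies an overlap below
75%, so the refinement deletes precisely the frames the
shape-difference rule exists to catch; on refined masks that rule is
unsatisfiable for growth. Volumes stack slices 0..cutoff−1 (all slices
when no rule fires) into 3D membrane and nuclei label arrays carrying
the voxel size; the cut-off frame itself, being defective by
definition, is excluded.

The scan is order-dependent by design: reversing a stack does not
mirror the trigger slice (the area rule compares each frame to its
predecessor), which the tests demonstrate on a fixture.

## Evaluation metrics

TP/FP/FN are exact pixel-set counts between aligned masks;
recall = TP/(TP+FN), precision = TP/(TP+FP), F1 their harmonic mean,
Jaccard = TP/(TP+FP+FN). Degenerate denominators (a blank slice on
either side) yield 0 with an explicit flag instead of raising, which
batch evaluation requires. The shell stratification splits the
membrane into an outer band — pixels within `shell_width_um` (default
20 µm, configurable; the split radius is not prescribed anywhere) of
the border, via the distance transform — and the inner remainder, and
scores each restriction separately; inner TP + outer TP equals the
membrane-restricted TP for any width. Comparing score distributions
between operators is a standard rank test (e.g. Kruskal–Wallis,
`scipy.stats.kruskal`) applied to the per-image score columns of the
evaluation CSV; it is not reimplemented here.

## Synthetic stacks: what they emulate, and what they do not

The generator builds a hemisphere of radius R (default 30 µm) sitting
on the culture surface, imaged top-down: slice z covers a disc of
radius r(z) = √(R² − (R − z·Δz)²), clipped at the equator. The
membrane channel is a textured actin interior (multiplicative smooth
field plus fine granularity) with a brighter cortical rim; the nuclei
channel renders ellipses (semi-axes 3.2–4.0 µm) with graded DNA
density — brightest at the centre, ~74% of peak at the rim — near-
uniform staining across nuclei (±2%), and fine chromatin texture.
Both channels get a smooth autofluorescent background, a mild optical
blur (σ = 1 px) and Gaussian read noise (σ = 8). Nuclei are placed by
dart throwing with a hard separation so they never fuse by accident;
a configurable fraction (default 10%) is placed as touching pairs to
exercise the watershed, and when a disc cannot host the requested
number the truth records what was actually placed. All randomness
comes from one seeded generator; stacks are bit-reproducible.

`spread_slice` emulates first surface contact: from that slice on the
disc flattens into a 1.10 × 1.20 ellipse (area jump ≈ 1.33×) and the
membrane signal dims to 30% (spreading actin thins out), so the
pipeline flags the engineered frame through the intensity rule. The
solidity rule is exercised separately by `engineered_cutoff_stack`,
which builds three mask/image stacks tripping exactly one rule each
(an intensity dip to 0.15; a 45% area jump; a thin cross of solidity
≈ 0.40 at matched area).

The rendering choices are not arbitrary: flat, equally bright
structures make the minimum-spread selector behave pathologically
(any threshold inside a sharp mode halves every object), which
real, textured fluorescence data does not exhibit. The graded and
textured rendering reproduces the operating regime in which the
method demonstrably works. Passing on these stacks therefore shows
the pipeline's logic is correct under realistic degradations — uneven
background, intensity variation, touching objects, laser-intensity
changes — but not robustness to effects the generator omits: axial
PSF anisotropy and bleed-through between z-planes, photobleaching,
mitotic figures and apoptotic debris, chromatic shift between
channels, and truly saturated staining.

## Problem sizes and numerical choices

The test suite and the acceptance script use 256×256 slices with
32–64 slices per stack and 6–10 stacks per experiment — the geometry
(spheroid-to-field ratio, nucleus diameters in pixels) matches the
full-scale acquisition, only the field of view is cropped. Hole
filling uses 4-connected background flood fill
(`scipy.ndimage.binary_fill_holes`); component labelling is
8-connected throughout, the common default of the reference
implementations in this field. The watershed is per-slice 2D; no
anisotropy-aware 3D flooding. Evaluation of synthetic runs excludes
slices whose true cross-section is below the 1200 µm² rule: the
method defines such sections as undetectable, so scoring them would
measure the generator, not the segmentation.

## Known limitations

- Thresholds are global per slice; strong lateral illumination
  gradients within one slice can bias a single threshold.
- The refinement is forward-only; an object absent from the first
  frames but genuine deeper in the stack is unrecoverable once its
  first appearance overlaps nothing.
- The cut-off scan reports the first triggering slice only; stacks
  containing several spheroids contacting the surface at different
  depths get a single, earliest cut-off.
- Nucleus counts are per-slice 2D objects; a 3D count would require
  linking across slices, which is out of scope.
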
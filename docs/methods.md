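# Methods

This note records the models, conventions, and numerical choices behind
`metaspread`, in the spirit of a methods section: what each stage
computes, which knobs matter, and what the synthetic benchmark does and
does not establish about real data.

## Conventions

All rasters use 0-based `(row, col)` indexing with pixel centers at
integer coordinates; distances are Euclidean in pixel units. Label masks
are 2D integer images with background 0 and one positive label per
chromosome instance. Channel files are matched by case-sensitive
substring tokens on the basename (one single-plane TIFF per channel per
field); multi-plane files are rejected. Label masks are written at the
smallest unsigned integer width that holds the maximum label, so
round-trips are bit-exact. CSV outputs are comma-separated UTF-8 with a
fixed header, no index column, and period decimal separators; floats are
written at full round-trip precision.

## Watershed segmentation baseline

The classical baseline is fixed so comparisons are reproducible:

1. Gaussian smoothing (`smoothing_sigma`, default 1 px).
2. Foreground by Otsu threshold (or an absolute value), followed by
   hole filling — DNA-stain texture otherwise leaves pinholes that
   destabilize IoU.
3. Euclidean distance transform of the foreground.
4. Seeds: within each 8-connected foreground component, local maxima of
   the distance transform, thinned greedily (strongest first, ties broken
   by raster order) to pairwise separation ≥ `seed_min_distance`. Seeds
   are selected per component so that a dim object near a bright one
   cannot lose its only seed, and every component keeps at least one seed
   (its distance argmax).
5. Marker-controlled watershed on the negated distance map restricted to
   the foreground.
6. Removal of objects smaller than `min_object_area` (default 50 px — a
   debris filter, exposed as a flag) and sequential relabeling from 1.

`seed_min_distance` is the over/under-segmentation dial: for rod-shaped
objects the distance ridge is elongated, so the spacing must exceed the
longest object extent for one seed per rod (we use 60 px against the
synthetic rods of 30–60 px length; the parameter default is 35 px).
This baseline counts well-separated objects correctly but, by
construction, cannot split touching chromosomes that share one distance
ridge — the known failure mode that motivates learned backends.

Learned models enter through an adapter contract: any callable mapping a
2D raster to an equal-shape non-negative integer instance map. The
package validates the contract, filters small objects, and relabels; it
ships no weights and performs no training.

## Mask curation

Merge assigns all listed instances the smallest listed label (pixel
count conserved). Split rasterizes a polyline at `split_width` (default
1 px, minimal material loss), clears instance pixels under the cut, and
gives each remaining 8-connected fragment a fresh label above the current
maximum (unambiguous lineage; a cut crossing a bent instance twice may
legitimately yield more than two fragments). 8-connectivity prevents
single-pixel diagonal bridges from defeating a cut. A cut that misses or
fails to bisect the instance is a warning no-op. Delete clears the
instance. All edits are pure functions; a JSON-lines log of actions
replays to a bit-identical mask.

## Spot detection and quantification

"Local contrast" is realized as a white top-hat with a disk of radius
`tophat_radius` (default 5 px, the expected spot scale at 60×/1024²
sampling of ~2 px-sigma spots). Detections are local maxima of the
enhanced image separated by ≥ `min_peak_distance` (default 5 px) whose
enhanced value strictly exceeds the threshold — absolute, or
`threshold_value ×` the global enhanced maximum (default relative 0.1;
noisy data warrants a higher user threshold, e.g. 0.5 at 10:1
signal-to-noise). The threshold applies to enhanced values, not raw ones.

Sub-pixel refinement is an intensity-weighted centroid in the 3×3 window
around the peak, computed on enhanced values after subtracting the window
minimum; without that subtraction the pedestal under the peak shrinks the
estimated offset severely (mean 2D error ~0.3 px for 2 px-sigma spots
versus <0.1 px with it). The offset is clamped to ±0.5 px per axis.

Intensities are always measured on the raw channel: `peak` is the value
at the rounded position, `aperture` the mean over pixels within
`aperture_radius` (default 3 px) of the sub-pixel position, clipped to
the image. No local background subtraction is applied; experiments are
expected to normalize to a control condition instead.

Assignment takes the mask label under the rounded position; background
hits snap to the nearest instance pixel within `snap_radius` (default
3 px), ties resolved by distance then smaller label. Spots-only mode runs
the identical detect/pair/measure path with no mask, leaving all labels 0.

## Colocalization and aggregation

Pairing is greedy one-to-one: candidate FISH–IF pairs at Euclidean
distance **strictly less than** `max_distance` (default 12 px) are
accepted in ascending distance order, ties broken by index; each spot
pairs at most once, so one bright blob cannot colocalize several partners.
A chromosome is colocalized iff an accepted pair's FISH spot is assigned
to it. The ratio is `100 · n_coloc / n_FISH-bearing` by default — a
locus-specific probe marks only a few chromosomes per spread, so the
all-chromosome denominator (also available) mostly measures probe
coverage. A zero denominator yields a missing value, not 0.

Fold-change normalization divides by the mean of the control condition
(control mean maps to 1 by construction; a zero control mean is an
error). Timepoint comparisons use the two-sided independent-samples
t-test, pooled-variance by default with Welch behind a flag, with an
optional prior log2 transform for intensity data. Consolidation
concatenates per-image tables after attaching condition/timepoint/
replicate columns and enforces a common schema.

## Segmentation evaluation

IoU is pure pixel counting via a joint label histogram. Matching at a
threshold is the assignment-problem optimum (`scipy`
`linear_sum_assignment` on IoU plus a large eligibility bonus): maximum
match count first, then maximum total IoU — greedy matching can undercount
true positives, and the optimum is implementation-independent and
verified against exhaustive enumeration in the tests. TP = matches,
FP = predicted − TP, FN = truth − TP; precision = TP/(TP+FP), recall =
TP/(TP+FN), F1 their harmonic mean; zero-denominator metrics are missing
rather than 0. The default threshold sweep is {0.5, …, 0.9}. The XOR
overlay classifies pixels as correct / false-positive / false-negative /
instance-mismatch (codes 0–4 with 0 background).

## Synthetic spreads

Chromosomes are thickened quadratic Bézier ribbons: length 30–60 px,
width 8–14 px, bend 0–0.9 rad (sagitta = length·bend/8), placed by
rejection sampling with a 6 px clearance (1 px in the `allow_touching`
stress mode) inside a 1024×1024 (default) frame — the morphology that
makes ridge-based watershed brittle, without chromatin texture. The DNA
channel is a two-level image (background 100, foreground 3000 by
default); spots are isotropic Gaussians (sigma 2 px, amplitude 2000)
added to the background; Gaussian read noise (default sd 20) is added
last and clipped at zero. Fractional object counts round half away from
zero so planted counts are exact integers.

FISH spots land at interior points (≥ 2 px from the boundary) of a
`fish_spot_fraction` of chromosomes, mutually ≥ 15 px apart. For a
`coloc_fraction` of those, an IF spot is placed at exactly
`offset_coloc` (default 6 px); the rest receive one at `offset_noncoloc`
(default 30 px) or none. Placement enforces a 13 px clearance between
every spot pair that must not count as colocalized, so the planted
colocalization fraction is recovered exactly at the 12 px criterion by
construction. Controlled mask corruptions (drop, merge, centroid-
perpendicular split, per-instance erosion) provide error masks with
hand-derivable TP/FP/FN.

What the synthetic benchmark does **not** emulate: chromatin banding and
sister-chromatid substructure, intensity gradients and uneven
illumination, true shot (Poisson) noise, overlapping chromosome clusters,
and out-of-focus blur. Passing tests therefore establish the *logic* of
the pipeline — counting, pairing, accounting, determinism — not
segmentation accuracy on real spreads, which depends on the chosen
backend and data quality.

## Problem sizes and determinism

The test suite and the acceptance script run on scaled-down fields
(256²–512² with 6–20 chromosomes for most properties; 20 fields of 46
chromosomes at 1024² for the counting check), chosen to exercise every
code path at interactive runtimes. Everything is deterministic given the
seed: the generator threads one `numpy` Generator, the watershed breaks
seed ties by raster order, matching ties are fixed by ascending label,
and batch outputs are byte-identical across reruns (fields processed in
sorted order, no timestamps in tables).
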
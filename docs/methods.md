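# Methods

## Problem and model

A single axial brain-MRI slice, min–max normalized to [0, 1], contains a
dark background, a bright skull, a mid-intensity cerebrum, and possibly
several bright lesions of widely varying size (radius ~2 px up to ~25 px)
and brightness. The detector assumes exactly this ordering of tissue
intensities — it is an intensity-based method with no shape or texture
model — and makes two anatomical assumptions: the skull is the largest
closed bright/medium structure in the slice, and genuine tumors arise in
the cerebral tissue, away from the skull. Everything else follows from
those assumptions.

### Stage 1 — intensity clustering

Lloyd's k-means on the scalar intensities with k = 3 yields dark, medium
(cerebrum), and bright (skull + candidate lesions) clusters. Centroids are
seeded deterministically at the (2j−1)/2k intensity quantiles, so the whole
pipeline is RNG-free; an emptied cluster is re-seeded at the worst-fit
pixel. Convergence is declared when the largest centroid shift drops below
`tol = 1e-4` (normalized intensity) or after `max_iter = 100` iterations —
generous for 1-D data, which typically converges in well under 20. The
within/between sums of squares

    SSW = Σᵢ (xᵢ − c_{k(i)})²,   SSB = Σⱼ nⱼ (cⱼ − x̄)²

are exposed for diagnostics; SSW is non-increasing across iterations and
SSW + SSB equals the total sum of squares (both are asserted in tests).
Note that with a bright skull present, a lesion only slightly brighter than
the cerebrum falls in the *medium* cluster (the medium/bright boundary sits
near the midpoint of cerebrum and skull intensities); such lesions are
recovered downstream by the mid-intensity gate, not by the bright cluster.

### Stage 2 — skull edge, brain size, distance threshold

The union of the bright and medium masks is outlined by removing interior
pixels (a pixel is interior when all four edge-neighbors are set — erosion
by the 3×3 cross kernel [[0,1,0],[1,1,1],[0,1,0]]); the largest 8-connected
outline component is the skull edge. Outlining uses 4-connectivity and
labeling 8-connectivity, the conventional foreground/background duality.
Filling the edge's holes (border-connected 4-connected background flood)
gives the brain support; its pixel count maps to the false-tumor rejection
threshold through a piecewise-linear curve through (5000, 5), (8000, 6),
(100000, 25), extrapolated with the nearest segment's slope and floored at
3 px. The curve between the three quoted anchor points is a declared
modeling choice — only the anchors themselves are given; monotone
increase in brain size is the property that matters. An open (C-shaped)
edge lets the flood fill leak, in which case the filled mask degenerates to
the edge itself; this is documented behavior, and the pipeline then reports
a correspondingly small brain and threshold rather than guessing.

A band of width `edge_expand_iterations = 10` px (cross-kernel erosion of
the filled support, differenced) marks the tissue immediately inside the
skull. 10 px removes skull-attached bright rims on ~512² slices; it scales
with image resolution and is exposed in the config.

### Stage 3 — detection image

Two images are multiplied:

* the **cerebral mask**: medium cluster minus the inward band, reduced to
  its largest 8-connected component, holes filled (component first, fill
  second — a lesion fully inside the cerebrum is a hole in the medium
  cluster and must be brought back);
* the **focus image**: 3×3 box mean of the slice × a 49.99–50.01 %
  intensity window of the unsmoothed slice (in effect a binarization at
  mid-intensity), the product re-windowed to 10–90 %. Intensity windows
  are linear clip maps `clip((x − lo)/(hi − lo), 0, 1)`.

The product suppresses background, skull, and rim while keeping every
above-mid-intensity interior structure at near-full contrast.

### Stage 4 — patch scan with shift voting

The detection image is tiled into 200×200 patches, each bilinearly
upscaled 3×. Every upscaled patch is scanned twice (as-is, and after a
30–70 % stretch that lifts low-contrast lesions); each scan smooths with a
3×3 mean, zeroes pixels below 0.05, thresholds at {0.1, 0.3, 0.5, 0.7,
0.9} plus the patch's 256-bin Otsu value (skipped for constant patches),
drops components smaller than `min_object_area`, fills holes, and sums the
layers into an accumulation image. Candidates are peeled iteratively: the
component carrying the maximum accumulated value (ties: larger area, then
topmost-leftmost centroid) is eroded by Euclidean disks of growing radius
until one object survives — implemented as a single distance transform of
the zero-padded mask, since erosion by the radius-r disk equals
EDT(mask) > r — and a region is grown from the survivor's center over
8-connected pixels within `grow_delta = 0.2` below the seed intensity
(never below the 0.05 floor, which would otherwise let a dim seed flood the
background). The grown region and its source component are cleared and the
loop repeats, up to `max_candidates = 20` per patch.

The full tiling is repeated at grid shifts (0, 0), (0, 50), (0, 100),
(0, 150); each shift contributes one vote per pixel. A second set of four
passes runs on the *unmasked* focus image so lesions clipped by the
cerebral mask still vote (`original_pass="focus"`; the skull structures
this re-admits are eliminated by the distance rule). Running these passes
on the raw normalized slice instead (`original_pass="raw"`) is supported
but not the default: the mid-gray cerebrum passes the 0.1/0.3 thresholds,
the peel loop then grows a whole-head candidate in every patch, and after
voting that component absorbs every lesion and is rejected wholesale at
the distance stage — the setting is provided for experimentation only.
Pixels with ≥ `min_votes = 2` votes become candidates, which suppresses
patch-boundary artifacts (a lesion cut by one grid is intact under the
50-px shifts).

**`min_object_area = 80`** (pixels at working scale) is the calibration
that gives the patch magnification its meaning: a single-pixel noise spike
covers ~25–30 px after 3× bilinear upscaling, an *unmagnified* radius-3
lesion with its smoothing halo covers ≤ ~60 px, while a magnified radius-2
lesion covers ≥ ~100 px. 80 therefore rejects noise and unmagnified small
blobs but keeps every magnified lesion down to radius 2 — small-lesion
detection genuinely requires the 3× scale, which is the method's central
claim.

### Stage 5 — candidate evaluation

Each 8-connected candidate's minimum Euclidean distance from any of its
pixels to the skull edge (one distance transform of the edge complement)
is compared with the brain-size threshold; closer candidates are flagged
as false tumors. Distance is measured from the nearest pixel, not the
centroid, so a large lesion leaning against the skull is judged by its
closest point. Candidates are flagged, never deleted: the report carries
every region with centroid, half-open bounding box, area, skull distance,
and the accepted flag, and the acceptance decision is re-checkable from
the report alone.

### Scoring

Pixel-level confusion counts give precision TP/(TP+FP), recall TP/(TP+FN),
specificity TN/(TN+FP), Dice 2TP/(2TP+FP+FN), accuracy
(TP+TN)/(TP+FP+FN+TN). A zero denominator yields an undefined (None)
score, never a silent 0 or 1. Reports round to 4 decimals; full precision
is kept internally.

## Phantom generator

`make_phantom` renders, deterministically per seed (numpy PCG64): a
background at 0.02, an elliptical skull annulus (semi-axes 210×180 px,
6 px thick, intensity 0.90) enclosing a cerebrum at 0.40 with additive
Gaussian noise σ = 0.03 (clipped to [0, 1]), plus anti-aliased tumor disks
and optional skull-adjacent decoy disks. Ground truth is the ≥ 50 %
coverage set of the tumor disks only. The defaults mimic a T2-style slice
at ~512² resolution; the noise level is typical of a visually clean
clinical slice. The 8-phantom `default_suite` covers: one large tumor; one
tiny (r = 3) tumor; eight mixed-size tumors (r = 3…25, intensities
0.80–0.95); tumors near but beyond the distance threshold; decoys only; an
empty brain; low-contrast tumors (0.55 on 0.40); and a tumor straddling a
patch boundary.

What the phantoms do **not** emulate: bias fields, Rician noise, partial
volume beyond a 1-px rim, anatomical texture (ventricles, sulci), irregular
tumor shapes, or edema. Passing the suite therefore demonstrates the
pipeline's geometric and intensity logic — magnification, voting, decoy
rejection — not clinical performance; on real slices the intensity
assumptions (bright skull, darker cerebrum, bright lesions) must hold after
normalization for the method to transfer.

## Numerical and degenerate-case choices

* Min–max normalization; a constant image maps to all zeros and is
  reported as "no brain found" (the pipeline warns instead of crashing).
* All coordinates 0-based (row, col); bounding boxes half-open.
* Mask→float multiplication uses exact {0.0, 1.0}; box filters use reflect
  padding; bilinear upscaling uses edge padding and preserves constants.
* Vote-mask downscaling is a ≥ ½ majority over each scale×scale block.
* If disk erosion jumps from ≥ 2 components straight to zero, the largest
  component of the last nonzero erosion is used (ties: topmost-leftmost).
* Degenerate region growth (seed below the intensity floor) returns the
  seed pixel alone.
* The candidate cap (`max_candidates = 20` per patch) guarantees
  termination of the peel loop.

## Problem sizes

The test suite and the acceptance script run the full pipeline on 512²
phantoms (each run ≈ 10–15 s on one core: 8 shift passes × up to 12
patches × two scans). Shared session fixtures keep the suite to a handful
of full-pipeline runs; unit and property tests use 20²–140² arrays.

## Known limitations

* Single-slice, single-channel only; no 3-D context, no DICOM.
* Detection of non-bright (hypointense) lesions is out of scope by design.
* The brain-size → threshold curve is anchored at three points; behavior
  far outside 5 000–100 000 brain pixels relies on linear extrapolation.
* On uniform structureless data, single-start Lloyd can stop in a local
  SSW minimum; with the quantile seeding this does not occur on data with
  actual cluster structure, which is the operating regime.
* The vote threshold assumes a lesion is detectable under at least two of
  the four grid shifts; a lesion that only ever appears cut by every grid
  (possible only if it is comparable in size to a patch) would be
  attenuated, not helped, by voting.
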
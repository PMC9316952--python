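# Methods

`halocell` detects, filters, measures and cross-references
immunoreactive cells — "halo cells", cells with a brown perinuclear
ring of DAB chromogen — in whole-slide immunohistochemistry (IHC)
image tiles, and fuses the resulting cell heatmaps with H&E
morphological feature maps from adjacent sections. This note records
the model, the parameter choices that matter, and the design decisions
taken where more than one reasonable option existed.

## Bifocal patch classification

Every candidate location is represented by two co-centred RGB crops: a
narrow 32x32 patch focused on the cell body and a wide 64x64 patch
carrying the tissue context, mirroring how a microscopist inspects both
a structure and its surroundings. Crops use half-open
`[c - s/2, c + s/2)` windows so even-sized patches have an unambiguous
centre; marks closer than 32 px to a tile border are skipped (and
counted), never padded — padding would fabricate tissue context that
the two-scale design exists to exploit.

The classifier is a two-branch convolutional network: per branch, three
3x3 convolution blocks (16 -> 32 -> 64 channels, each followed by ReLU
and 2x2 max-pooling), the final feature map flattened, both branch
vectors concatenated and passed through a 128-unit hidden layer to a
2-way softmax. Two choices deserve comment:

* **Flatten, not global average pooling.** Spatially pooled branch
  features are translation-invariant, which is fatal for sliding-window
  localisation: the score then saturates over a ~30 px neighbourhood of
  every cell and neighbouring cells merge into one detection blob. The
  flattened head keeps feature position and, together with the
  near-miss negatives below, concentrates the response on well-centred
  windows.
* **Channel widths.** 16/32/64 channels train in minutes on one CPU
  core with the pure-numpy engine (`minicnn.py`: im2col + GEMM
  convolutions, float32 throughout, bit-reproducible on a single
  thread); the widths are configurable.

Training uses SGD with momentum 0.9, weight decay 0.005, batch size 32
and a learning rate of 0.0005 decaying gradually — implemented as a
cosine schedule down to 0.00005 — with 70 epochs as the configurable
default regime. Batches are class-balanced by oversampling the minority
class. Augmentation applies right-angle rotations plus contrast and
sharpness scaling drawn from [0.8, 1.2]; magnitudes are deliberately
mild so stain intensity (which later stages measure) is not distorted.
`build_training_set` can additionally emit *near-miss hard negatives*:
for each positive mark, pairs centred 22–40 px away labelled negative.
These teach the network that an off-centre cell is not a hit,
keeping adjacent cells' detection blobs separate; the recovery the
benchmark reports depends on them.

## Sliding-window inference and detection merging

At inference, windows are evaluated on a stride-10 lattice from the
upper left to the bottom right of a tile; a tile of shape (H, W) yields
`floor((H-64)/10)+1 x floor((W-64)/10)+1` scores, rendered as a
pseudo-colour heatmap (red = cell, turquoise = background; palette
configurable, rendering invertible at the binary-mask level).

A cell tens of pixels across lights up several stride-10 windows, so
supra-threshold lattice cells are merged into discrete detections by
8-connected component analysis, one record per component at the
score-weighted centroid (snapped to the nearest pixel), with the
component's maximum score. The decision threshold defaults to 0.5 (the
softmax argmax). Known property: component counts are *not* globally
monotone in the threshold — raising it can split a component into two
before both vanish; the tests assert the true invariant (component
count never exceeds the supra-threshold cell count).

## Discriminability filtering

Each detected cell's 64x64 crop is reduced to a single-channel stain
signal in [0, 1]. The default channel is the DAB optical density from
Ruifrok–Johnston colour deconvolution (`skimage.color.rgb2hed`, scaled
by 0.2 OD and clipped): with a hemalum counterstain present, a plain
inverted grayscale makes nuclei at least as dark as a weakly stained
ring, and any statistic computed from it stops tracking stain strength.
An inverted-luminance channel remains available for stains without a
deconvolution basis. The signal is denoised with a Gaussian
(sigma = 1 px by default; 0 disables) and may be contrast-enhanced with
a local max–min range filter (CLAHE optional).

The per-patch statistic sigma is the Otsu threshold of the signal
histogram: 256 equal bins on [0, 1], between-class variance maximised,
the value reported as a bin centre. When the variance curve has a flat
maximal plateau (two modes separated by empty bins) the plateau
midpoint is returned, so a symmetric bimodal signal splits halfway
between its modes; on generic signals this coincides with the first
argmax. A constant patch has no bimodal split: the operation raises,
and the detection pipeline records sigma = 0 (trivially
less-discriminable). Two measurement choices:

* sigma is computed on the *un-enhanced* denoised signal. A
  local-contrast image no longer carries absolute intensity, which
  inflates the sigma spread within a stain stratum and erodes the
  separation the acceptance threshold relies on.
* the histogram is restricted to a 24 px-radius disc around the
  detection centre (configurable), so a neighbouring cell intruding
  into a crop corner cannot skew the statistic.

Per case (whole slide) — antibody labelling intensity varies from slide
to slide — the acceptance threshold is

    T = (sum of sigma) / N - min(sigma),

the mean Otsu statistic minus the lowest one, and a detection is
discriminable iff `sigma > T` (strict; `>=` configurable). T is
permutation-invariant, non-negative, and scales linearly with the
sigma values. Note the structural consequence: the weakest detection is
retained only when `2*min > mean`, i.e. the filter always discards the
bottom of the distribution unless the sigmas are tightly clustered.

## Morphometry

Discriminable crops are binarised at their own sigma (cell white on
black), the largest 8-connected foreground component is selected, its
holes filled, and the closed outer contour traced by Moore boundary
following (counter-clockwise in Cartesian orientation). Measures:

* **area** — pixels on or inside the contour, counted by filling the
  traced boundary (identical to the component's pixel count by
  construction);
* **perimeter** — boundary chain length with axial steps counting 1 and
  diagonal steps sqrt(2); a raw boundary-pixel count would undercount
  diagonal travel and make compactness orientation-dependent;
* **compactness** — `perimeter^2 / (4 pi area)`; 1 for an ideal disc
  (isoperimetric lower bound), ~1.05–1.10 for rasterised discs under
  the chain convention, larger for irregular outlines;
* **minimum pixel intensity** — reported as the patch's Otsu value
  sigma, which estimates the lowest intensity of the cell's own pixels.

Case-level features are arithmetic means over the case's cells plus a
density in cells/mm^2, with tissue area defaulting to tile pixel count
x (microns-per-pixel)^2.

## Wavelet fusion and cross-modal densities

The cell heatmap is thresholded to keep only positive-colour pixels,
registered onto the H&E feature heatmap by a least-squares affine (or
similarity) transform fitted to >= 3 non-collinear control-point pairs
(residual reported; nearest-neighbour resampling preserves the
palette), and fused per RGB channel by single-level 2-D discrete
wavelet decomposition, element-wise averaging of the approximation,
horizontal, vertical and diagonal bands, and inverse transform. Haar is
the default wavelet; odd dimensions use symmetric extension with a crop
back to the input size. For any orthogonal wavelet band-averaging
equals plain pixel averaging `(A + B) / 2` to numerical precision — the
wavelet path is kept because band-wise fusion generalises to
non-linear rules and makes the frequency split explicit.

Each retained cell is then labelled with the morphological feature
class (tumour, necrosis, vessels, ...) of the nearest raster pixel at
its registered location; cells mapping off the raster are counted as
unassigned and excluded from densities. Densities divide by the *region*
area (raster pixel count x physical pixel area), not the slide area.

## Synthetic data

The generator emulates what the downstream stages need from a
40x-magnification DAB/hemalum slide and nothing more: a pale
eosinophilic background with coarse texture and luminance noise
(sd 0.01), scattered blue-grey counterstained nuclei, and brown
perinuclear rings at known centres with per-cell radius (8–14 px),
ring width 5 px and stain intensity recorded as ground truth.

Stain intensity is *defined* as 1 − relative luminance of the ring
pixels; ring colours interpolate white -> DAB brown (0.36, 0.22, 0.08)
whose luminance is 0.24, so intensities up to 0.75 are renderable and
the config validates the requested range against [0, 0.75]. A
read-back helper recovers the mean rendered intensity, and the tests
hold it to the ±0.05 fidelity contract. Cell centres keep a
32 px border margin (both focal crops fit) and pairwise separation of
twice the maximum outer radius (no overlap); exported negative marks
stay >= 64 px from every positive centre and sample both plain
background and nuclei clusters. All randomness flows from a single
integer seed through one generator instance per call; identical
configs produce bit-identical tiles and marks. Infeasible packing
raises an explicit error naming the violated constraint.

Cases are rows of tiles sharing one case id. A categorical feature
raster (one H&E morphology class per stride-sized cell, injective
palette) can drive placement: per-class counts are Poisson with mean
density x region area, positions uniform within the class region.

The end-to-end benchmark (`halocell.validation`) plants two intensity
strata — weak rings at 0.05–0.12 and strong rings at 0.45–0.70 —
mirroring the distinction between faint, less-discriminable positivity
and clear immunoreactivity; trains on ~2,100 pairs (10 tiles of 25
cells; originals + 3 augmented variants + 2 near-miss negatives per
positive) for 15 epochs; and tests on a held-out case of four 512x512
tiles whose cells follow a 3:1:2 density ratio across three vertical
feature bands. These sizes are chosen so the whole cycle runs in
minutes on a single CPU core.

**What the generator does not model** — and hence what passing tests do
not establish about real slides: scanner artefacts, defocus and tissue
folds; touching or overlapping cells; chromatic variation of the
chromogen and counterstain between laboratories; non-ring CD276
morphologies; tissue-level context (the background is texture, not
histology). The benchmark demonstrates that the machinery is correct
and self-consistent, not that the classifier's accuracy transfers to
clinical material.

## Numerical choices and degenerate inputs

* The CNN engine is float32, single-threaded numpy; identical seeds
  give identical weights, training trajectories and scores. Batch size
  does not change predictions beyond 1e-6.
* Otsu bins: 256; ties: plateau midpoint (above); constant image:
  error, mapped to sigma = 0 by the detection pipeline.
* Contours: the largest component wins (detection crops are
  cell-centred, so the detected cell dominates); components below 5 px
  are rejected as unsegmentable.
* Transform estimation fails loudly on < 3 or collinear control
  points.
* Empty cases are defined: a case with no cells yields a summary with
  absent means and density 0.

## Known limitations

* The component-merging rule can still fuse two cells whose detection
  blobs touch; the hard-negative training keeps blobs tight, but
  densely packed tissue would need a local-maxima or watershed split.
* Eq-style `T = mean - min` filtering is sensitive to the sigma
  distribution's shape: a single very weak outlier drags `min` down
  and thus T up.
* The engine implements exactly the operators this architecture needs
  (3x3/pad-1 convolutions, 2x2 pooling); it is not a general deep
  learning framework.
* Registration is control-point-based; automatic feature matching
  between adjacent sections is out of scope.
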
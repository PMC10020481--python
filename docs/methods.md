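# Methods

## Model

`fibroquant` performs per-pixel, color-only tissue classification. The
model is a set of fixed cluster centers ("sub-clusters") in HSV color
space, each carrying one of three parent class labels — background (code
0), healthy tissue (1), fibrotic tissue (2). Segmentation is a single
nearest-center assignment pass followed by a union of each class's
sub-cluster assignments; centers are never recomputed from the data. This
is equivalent to a nearest-centroid classifier whose class regions are
unions of Voronoi cells, one cell per user sample. The classifier core
accepts any label set of two or more classes; the quantification layer
(cell area, fibrosis percentage, CSV schema) hard-wires the three-class
workflow.

Assumptions: stain identity is carried by per-pixel color alone (no
texture or spatial features), illumination is roughly uniform across a
slide, and the user's sample points cover every color mode of each class.
A class whose color range is multimodal — pale and saturated collagen,
say — should receive one sample per mode; keeping each sample as its own
center rather than averaging is exactly what makes this work.

## Color metric

Pixels are converted from 8-bit RGB by the standard hexcone transform
(scikit-image / colorsys). The distance between colors a and b is

    d(a, b) = sqrt(w_h · Δh² + w_s · Δs² + w_v · Δv²)

with hue rescaled to [0, 1) and its difference taken around the circle,
Δh = min(|h_a − h_b|, 1 − |h_a − h_b|). Achromatic colors (saturation 0)
are canonicalized to hue 0, so distances involving white or gray
backgrounds are well defined; with that canonicalization the metric is
symmetric and satisfies the triangle inequality (property-tested).
Default weights are (1, 1, 1); they are exposed everywhere a model is
built because background/tissue separation leans on value while
tissue/tissue separation leans on hue, and an unusual stain may benefit
from reweighting. 16-bit images are rescaled to 8-bit (divide by 257,
round) before conversion so a single conversion path exists.

Ties at exactly equal distance go to the earliest sub-cluster in insertion
order. Ties have measure zero for generic centers but are reachable with
hand-picked ones, and a deterministic rule keeps every run reproducible.

## Iterative baseline

`standard_kmeans` is conventional Lloyd k-means over the same HSV
features (scikit-learn, k-means++ initialization, explicit seed, default
max 100 iterations, tolerance 1e-4). It returns unsupervised cluster
indices; for scoring, clusters are matched to classes post hoc by
maximizing pixel agreement with the ground truth (Hungarian assignment),
which is the most generous possible reading of the baseline. On charts
whose class color distributions are multimodal, three moving centers must
either split a bimodal class or merge it with a neighbor, so the baseline
misclassifies large regions while the fixed-center classifier does not;
the test suite demonstrates this on a seeded chart.

## Synthetic reference charts

Accuracy is evaluated against generated charts: non-overlapping
rectangles, each assigned a tissue class, filled per pixel with colors
drawn uniformly (seeded) from the class palette; pixels outside every
rectangle are background. Ground-truth areas follow exactly from
rectangle arithmetic. Noise is i.i.d. Gaussian per RGB channel, clipped
to [0, 255] — a sensor-style model applied before HSV conversion; its
sigma is in 8-bit intensity units.

The standard benchmark layout (`default_table3_spec`) is a 590×254 canvas
tiled by a 422×254 healthy band (107,188 px²) and 168×127 fibrotic and
background blocks (21,336 px² each), yielding a defined fibrosis-to-cell
ratio of 100·21,336/128,524 = 16.60%. Only the areas matter to a
per-pixel classifier; the rectangle arrangement is arbitrary. The shipped
preset palettes double as the chart palettes, so an "exact-palette" model
(centers equal to the palette colors) reproduces a noise-free chart pixel
for pixel — the end-to-end identity the test suite asserts.

What the charts deliberately do not model: tissue morphology (fibril
texture, vessels, staining gradients), chromatic illumination drift, and
compression artifacts. A per-pixel color classifier is blind to the
first; the others would degrade any color-based method and are better
probed with real slides via the pass-through palette (charts built from
cropped regions of user images). Passing chart tests therefore
demonstrates correctness of the algorithmic pipeline and its noise
robustness, not performance on arbitrary real-world staining variation.

## Presets

Preset center colors for Masson's Trichrome (collagen/ECM blue, muscle
red, near-white background) and Picosirius Red (collagen red, cytoplasm
yellow, near-white background) ship with two sub-clusters per class, a
lighter and a darker variant of each stain. They encode the conventional
appearance of well-calibrated stains — Masson fibrotic hues fall in
180–280°, Picosirius fibrotic hues in the red band around 0°/360° — and
are intended as starting points; differently calibrated protocols should
use a sample-point or colors file instead.

## Quantification and evaluation

The reference ("cell") area is the section with background removed:
healthy + fibrotic pixels. The fibrosis percentage is
100·fibrotic/(fibrotic + healthy); background never enters the
denominator, which is why background must be segmented as its own class.
An empty cell area raises an error rather than returning 0 or NaN. CSV
export writes counts and the full-precision ratio (rounding is display
only), with the model fingerprint in a leading comment line.

Per-class accuracy against a reference mask is reported as defined
(truth) and analyzed (predicted) pixel counts plus the Dice coefficient;
a class absent from both masks scores 1.0 (perfect-agreement convention
for empty sets). Dice of the full pipeline is non-increasing in chart
noise (tested over sigma ∈ {0, 4, 8, 16, 32}, five seeds each).

## Batch processing

All images of a folder are segmented with the same model — the guarantee
that makes percentages comparable across slices of one experiment. Files
are processed in natural-sort filename order (filesystem enumeration is
nondeterministic); unreadable files become failure records without
aborting the batch. The CSV dialect is fixed (comma, dot decimal, UTF-8,
newline-terminated) with a `--delimiter` escape hatch.

## Numerical and design choices

- Sub-cluster centers come from single pixels by default, matching the
  sample-point workflow; an odd-sized median patch (`patch=3, 5, …`) is
  available to damp speckle noise, off by default.
- Nearest-center search compares squared distances; argmin over the
  insertion-ordered center list implements the tie-break for free.
- The benchmark protocol in `scripts/acceptance.py` uses five charts of
  149,860 px each at noise sigma 8 — ample for a per-pixel method, and
  small enough that a full run takes seconds; all chart seeds derive from
  the single `--seed` argument.
- Degenerate inputs: identical sample colors under different classes
  build successfully with a warning (tie-break decides); empty images,
  empty folders, empty batches, and empty cell areas raise.

## Limitations

Purely per-pixel: no spatial regularization, so isolated misclassified
pixels are kept (no morphological cleanup, by design — counts stay
faithful to the classifier). Colors outside every sampled mode are
assigned to whichever center happens to be nearest, however far; there is
no rejection class. Whole-slide pyramidal formats are out of scope; inputs
are plain TIFF/PNG.
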
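# Methods

`scmbench` implements a family of *stochastic context models* (SCMs):
procedurally defined image distributions whose contextual rules — feature
prevalence, relative positions, intensity–size relationships, texture laws
— are exactly known and recoverable from the pixels alone. Because the
ground truth is known, the package can (a) generate constraint-exact
training ensembles, (b) re-derive the context from images post hoc, and
(c) verify that every analyzer actually detects the error modes it claims
to detect, by injecting those errors at controlled rates.

## Alphabet model (single class)

A realization is an 8×8 grid of 32×32-pixel letter tiles over the alphabet
{H, K, L, V, W, X, Y, Z}. Two rules hold in every image:

* the tile letters form the exact multiset
  {24 H, 2 K, 16 L, 1 V, 1 W, 8 X, 8 Y, 4 Z};
* ordered pairs: every X has Y immediately to its right and every K, V, W
  has Z immediately above, giving pair counts X-Y = 8, Z-K = 2, Z-V = 1,
  Z-W = 1. The paired letters never occur outside these pairings.

**Sampling.** The 12 pair dominoes are placed in random order at uniformly
random admissible positions (restarting a pass on a dead end, which is
rare on an 8×8 board); the remaining 40 cells receive a random permutation
of 24 H + 16 L. Both rules therefore hold by construction; an independent
brute-force validator that scans all 64 cells and all adjacencies is used
in the tests rather than trusting the sampler.

**Glyphs and recovery.** The letter bitmaps are a deterministic, versioned
fixture drawn as thick line strokes. Recovery is per-tile template
matching with zero-mean normalized cross-correlation; the maximal
correlation between two distinct glyphs is 0.60, so the argmax assignment
is unambiguous, and a clean tile scores exactly 1.0 against its own glyph.
The recognizability threshold defaults to 0.9: it only matters for
degraded images, and 0.9 sits far above the worst inter-glyph correlation
while tolerating mild noise.

**Statistics.** Letter prevalence is tested with a chi-squared
goodness-of-fit statistic against the prescribed multiset (8 categories,
df = 7, 95% critical value). Pair prevalence is a full adjacency scan that
also flags *orphans* — paired letters outside their prescribed pairing.

## Voronoi model (four classes)

A realization is a 256×256 nearest-center (Euclidean) partition with
c ∈ {16, 32, 48, 64} regions; c is the class label. Prescribed context:
inter-region edges at intensity 0; each region a constant gray from a
128-value palette (evenly spaced integers in [1, 254]); and gray assigned
by area rank, so Spearman ρ(area, gray) = 1 exactly in every image.

**Centers.** Spatially random with a minimum separation d_min = 8 px,
placed by dart-throwing (sequential rejection). The separation prevents
sub-resolution regions that a one-pixel edge could not delimit. Joint
rejection of all c draws at once is infeasible at c = 64 (acceptance
probability ≈ 0.2%), so the sequential sampler is used; it remains
uniform up to the separation constraint.

**Rasterization.** Pixels are labeled by nearest center (pixel centers at
half-integer coordinates); a pixel is an edge pixel when its label differs
from its right or lower neighbor, giving a ~1-px boundary. Areas are
pixel counts after edge removal. If two regions tie in area (rare after
rasterization), centers are resampled — ties would make an exact rank
correlation of 1 unattainable.

**Recovery.** Candidate edge pixels must fall below a Sauvola local
threshold (window 15, k = 0.2) *and* at or below the prescribed edge
intensity 0. The absolute cap is necessary: the palette spans [1, 254], so
contrast between adjacent regions can exceed the region-to-edge contrast
and a local threshold alone absorbs dark regions bordering bright ones
(observed count errors of −7 to −26 without the cap). The candidate mask
is padded with a true frame before morphological thinning so that edge
branches terminating at the image border are not retracted as topological
spurs (without the frame, border regions merge); the frame's own skeleton
lies outside the image and is cropped away. Regions are the 4-connected
components of the skeleton complement, with modal non-zero gray and
pixel-count area; components under 10 px (isolated one-pixel holes left by
thinning) are dropped. On clean images this recovers the exact region
count and ρ > 0.95.

**Implicit context.** Seven emergent statistics are computed from the
skeletonized edge graph and the label map: region count, junction count
(skeleton pixels with ≥3 neighbors, adjacent junction pixels merged),
junction density (junctions per pixel of image area), mean/std edge-segment
length (8-connected components after junction removal, lengths in pixels),
and mean/std region area. Region counts classify as in-class,
interpolated (strictly between 16 and 64) or extrapolated; equidistant
counts resolve to the lower class.

## Flag model (eight classes)

A realization is a 16×16 grid of 16×16-pixel tiles. A binary template
matrix A (256 tile indices × 8 classes) fixes which tiles are foreground:
80 foreground and 176 background tiles per class, 24 indices foreground in
no class, columns pairwise distinct. Since every class has 80 foreground
tiles, all images share the same foreground pixel budget (80 × 256),
removing zero-order variance across classes. Tile intensities are iid
scaled Beta draws placed at random pixel positions:
foreground 152·X + 96 with X ~ Beta(4, 2); background 192·X + 8 with
X ~ Beta(2, 4); rounded to the nearest integer (supports [96, 248] and
[8, 200] without clipping).

**Templates.** The per-class patterns are a deterministic
constrained-random fixture. Naive independent sampling of 80 indices per
class leaves ≈8 additional never-chosen indices by chance; a repair sweep
swaps each uncovered allowed index into some class (displacing an index
covered at least twice), so exactly the 24 designated indices are
never-foreground. Users may supply their own 256×8 plain-text matrix.

**Recovery and classification.** A tile is foreground iff its pixel mean
exceeds the midpoint of the theoretical tile means,
(197.33 + 72)/2 ≈ 134.67; the tile-mean distributions are separated by
≈ 16 standard errors, so the per-tile error probability is far below
10⁻⁶. Class identity is the argmin over template columns of the mean
absolute error between the recovered pattern and the column (reported
relative to the 80-tile foreground count); ties resolve to the lower
class id. Any recovered foreground at a never-foreground index raises a
forbidden-pattern flag.

**Texture.** Moran's I per tile with raw binary rook-adjacency weights.
For randomly placed variates E[I] = −1/(n−1) = −1/255 (the arrangement
within a tile is a uniform permutation of the draws, so the permutation
null applies exactly); a tile is "random texture" when its I falls in the
central 99% band of a 10⁴-tile simulation null. An image passes the
texture check when at most 8 of its 256 tiles fall outside the band
(≈3× the expected number of null exceedances). Constant tiles have
undefined I and are flagged, not scored.

**Intensity.** Pooled foreground and background pixels are tested by
chi-squared against the theoretical Beta bin probabilities on 16
equal-width bins per support. Acceptability cutoffs are the 99.5th
percentiles of the per-image statistics over a reference generated
ensemble (theoretical-CDF binning rather than empirical training
histograms; recorded in report metadata).

## Phantom fixture (four density classes)

A deliberately simplified, fully synthetic breast-slice stand-in: it
reproduces only the properties the evaluation pipeline needs — zero
background, a compact ellipse-like region, two disjoint tissue intensity
bands (glandular [60, 120], fatty [150, 200]) plus a bright ligament band
([230, 255]) so that global thresholding is exact, a thin ligament web
(Voronoi ridges of 20–34 random interior points), and a fat-to-glandular
pixel ratio that determines the class. Class F/G intervals — fatty [3, 5),
scattered [1.5, 3), heterogeneous [0.5, 1.5), dense [0.1, 0.5) — are
disjoint and ordered; class prevalence is 1:4:4:1 by largest-remainder
allocation. The target ratio is drawn from the class interval (5% inset
from each boundary) and realized by thresholding a Gaussian-smoothed
random field at the exact pixel quantile, so the measured ratio matches
the target to well under 1%. No anatomical realism is claimed: attenuation
physics, 3D anatomy, slice extraction and clinical BI-RADS fidelity are
out of scope, so passing tests demonstrate the *evaluators*, not anatomy.

## Corruption injection and detector calibration

Each corruption affects exactly round(rate·n) images and introduces exactly
one violation of the named kind, so detector recall and false-positive
rates are unambiguous; rate 0 is the identity transform.

* Alphabet: reverse one X-Y pair; add one extra Z-K pair on filler cells;
  drop one orphaned paired letter on a filler cell (safe by construction —
  existing pair partners are never adjacent to filler); replace one H with
  L (breaks the multiset only). Matched detectors: the pair-prevalence
  scan, or exact letter prevalence for the multiset mode. All are
  deterministic with total recall.
* Voronoi: permute region grays (destroys ρ = 1; flagged when recovered
  ρ < 0.9); erase the edge between two regions, filling with the adjacent
  gray (flagged when a recovered region holds two substantial gray
  populations); regenerate with an off-class count from {8, 24, 40, 56, 80}
  (flagged when the recovered count is more than 3 away from every class —
  the band absorbs residual recovery noise while off-class counts are at
  least 8 away).
* Flags: swap one foreground tile with an allowed background tile; move
  one foreground tile onto a forbidden index (conserving the 80-count);
  draw foreground tiles with the background Beta(2, 4) shape rescaled to
  the foreground support (so position recovery still succeeds while the
  intensity law is wrong). The calibration detector for the last mode uses
  a 2× margin on the 99.5th-percentile chi-squared null, keeping the clean
  false-positive rate negligible while corrupted statistics exceed the
  cutoff by orders of magnitude.
* Phantom: erase a disk of ligament pixels (radius 8), filling with the
  nearest tissue value; detected by a paired skeleton comparison
  (endpoint-count increase or total-length drop).

A separate graded corruption, `shift_tissue_intensities`, promotes each
glandular pixel to the fatty band with probability equal to the corruption
strength; the measured F/G ratio then grows monotonically with strength.
It is used to probe the monotone sensitivity of the ensemble framework,
because rare-but-severe per-image errors barely move a pairwise
cosine-similarity distribution, whereas a graded population-level shift
moves it smoothly.

## Ensemble evaluation framework

Per-image features in four families: GLCM texture summaries (contrast,
homogeneity, energy, correlation at offsets {1, 2, 4} × {0°, 90°},
averaged); morphology (mean area, perimeter, eccentricity, solidity over
labeled regions of the tissue mask); skeleton statistics (branch count,
junction count, mean/std branch length, total length of the thinned
ligament mask); and the F/G ratio. Images where a family is uncomputable
(e.g., an empty skeleton) are flagged and excluded per family.

Features are z-scored by training statistics and projected on principal
components fit on the training rows only (generated-set pathologies must
not distort the reference axes). Cosine similarity is computed for 10,000
randomly selected training-training pairs (self-pairs excluded; sampling
with replacement across pairs) and the same number of training-generated
pairs; the two distributions are summarized by the two-sample
Kolmogorov-Smirnov statistic, per family and over all features (10
components). Coverage and density use the top-2 component space with
k = 5 nearest neighbors: each real sample owns a ball with radius equal
to the distance to its k-th nearest other real sample; density is the
mean number of balls containing a generated sample divided by k, coverage
the fraction of balls containing at least one generated sample. Class
prevalence is reported as percentages.

## Problem sizes and numerical conventions

The test suite validates detector calibration on 200-image ensembles per
corruption mode and rate (rates 0, 0.1, 0.25), roundtrip identities on 100
clean images per model, and the coverage/density identity benchmark on
two independent 250-phantom ensembles (512×512); the monotone-sensitivity
experiment uses 100 phantoms at 256×256 with 5,000 similarity pairs.
These sizes give binomial intervals tight enough to be informative while
keeping the default suite fast. All randomness flows from explicit
integer seeds; ensembles derive per-image seeds as seed + index.

## Known limitations

* The phantom fixture's band structure makes segmentation lossless by
  construction; results on it say nothing about threshold-based
  segmentation of realistic attenuation images.
* Voronoi edge recovery relies on the prescribed zero edge intensity via
  the darkness cap; heavily blurred or noise-contaminated edges (as a
  generative model might produce) would need the cap relaxed and would
  reintroduce recovery error.
* The Moran's I image-level pass rule (≤8 outlier tiles of 256) and the
  chi-squared calibration margin are conventions chosen for near-zero
  false-positive rates on clean data; they are configurable, and other
  choices trade recall against false alarms.
* Coverage/density estimates in 2-D embedding space carry sampling error
  of a few percent at the 250-image scale; the identity benchmark is
  expected near (1, 1), not exactly at it.
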
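# Methods

## Model and assumptions

The core assumption is that *very similar* endoscopic frames are related by a
single planar affine transform: the stomach wall deforms, but between frames
with high feature-match similarity the motion of the imaged patch is well
approximated by 6 degrees of freedom. Large deformations are then reached by
chaining local affine maps along a graph pathway, so the global registration
is piecewise-affine rather than truly nonrigid. Consequences:

- accuracy degrades with pathway length (affine estimation errors compose
  multiplicatively), which is why edges are restricted to high-similarity
  pairs and validated by warped normalized cross correlation;
- a query frame showing content the graph has never observed cannot be
  registered at all — it is rejected (`NoMatchError`) rather than
  extrapolated.

Coordinates are 0-based pixel centers, x = column, y = row; all transforms
are 3×3 homogeneous matrices acting on column vectors, where "transform from
frame a to frame b" means the point map taking a-coordinates to
b-coordinates. That same matrix is the pull-back used to warp image b onto
frame a, so warping never inverts a matrix internally. `compose([f, g])`
applies f then g; composing a pathway's hops in travel order therefore yields
the end-to-end point map.

## Feature detection

The detector is a single-octave difference-of-Gaussians pyramid with levels
σᵢ = 0.8·2^(i/3), i = 0…7. Extrema are accepted only on interior DoG layers
whose σ lies in [1, 3]: endoscope optics have fixed focal length and bounded
working distance, so usable features concentrate in that scale band and the
remaining pyramid is dead weight. "Scale" of a keypoint is the σ of its
detection layer. Candidates pass an absolute-contrast test (|DoG| > 0.004 on
[0, 1] intensities), an edge-response test (principal-curvature ratio < 10),
and one clamped Newton step of in-plane subpixel refinement. Keypoints are
ranked by |DoG| response with (y, x) tie-break, so truncation to the feature
budget (default 200) is deterministic.

Descriptors use the SIFT histogram-of-gradients layout reduced to a 2×2
spatial grid × 8 orientation bins = 32 dimensions, sampled in a rotated
window of 6σ per cell with soft trilinear binning and Gaussian radial
weighting. After unit-L2 normalisation, entries strictly greater than 0.4
are set to 1 with *no* re-normalisation: the clamp suppresses illumination
effects without redistributing mass across the vector.

Matching is mutual-nearest-neighbour in Euclidean descriptor space plus a
strict ratio test (default 0.8); distance ties resolve to the lower index.
These matching rules are package conventions chosen for determinism — they
are the de-facto standard for SIFT-family descriptors.

## Registration scores

The printed form of cross-correlation validation is realised as
zero-normalised cross correlation over the valid-overlap mask (mean-centred,
bounded in [−1, 1], offset-invariant), since validation must compare "close
to 1" meaningfully across exposure changes. The decision thresholds are kept
at accept > 0.8 (edge validation) and reject < 0.2 (subgraph rejection).
Pairs whose warped overlap is below `min_overlap` (default 0.25 of frame
area) cannot be validated at all: below that, interpolation boundary effects
dominate the statistic.

SSD edge weights are *mean* squared difference over the joint validity mask,
not a raw sum — edges with different overlap areas must be comparable inside
one Dijkstra run.

RANSAC draws 3-point minimal samples from a seeded generator, rejects
collinear samples, scores by reprojection error (default tolerance 3 px,
2000 iterations, confidence-based early exit at 0.995) and re-fits by least
squares on the consensus set. Every seed in the package threads down from a
single run seed, so all estimates are reproducible.

## Threshold search and graph scale

The connection threshold h is searched once over a pooled pair sample
(default 200 pairs), not per subgraph. Each iteration can only raise h
(B_low ← h), and the bracket gap shrinks by the factor λ = 0.1 per
iteration; in floating point the proposal reaches B_high after ~16
iterations, at which point no pair satisfies the strict S > h condition and
the search exits vacuously with a warning. A genuine non-convergence (some
high-similarity pair never validating) therefore surfaces only with small
iteration budgets, and the error carries the final bracket state.

At production scale (tens of thousands of frames) near-duplicate video
frames push B_high ≈ 1 and the top similarity band is exactly the set of
near-duplicate pairs, so the found h yields a connected chain. At the
desk scale this package targets (tens of frames, widely spaced), the found
h is honest but sparse; the worked examples and the acceptance pipeline
build the graph at a fixed desk-scale threshold h = 0.3, which connects a
12-frame synthetic sequence into one component while still pruning
low-overlap pairs. `build-graph` exposes both modes.

## Pathway weights for arbitrary edges

The SSD edge weight is defined against the moving image warped into the
tail node's frame. The direct transform from an arbitrary tail node u to
the moving image is obtained by composing the moving image's query-side
RANSAC transform with the stored edge transforms along the minimum-hop
graph path from the moving image's node to u; weights are computed lazily
and memoized per query, so the graph itself stores no weights. The moving
image itself (not its matched node's image) is what gets warped, keeping
the weight sensitive to genuine query content.

The full retargeting map for one query is
(reference → its node) ∘ (pathway composition) ∘ (node → moving image),
where the two outer terms are the query-side RANSAC transforms. Dijkstra
ties break deterministically: fewest hops, then lexicographically smallest
node-id sequence. Marker radii transform by √|det| of the linear block —
circles stay circles; anisotropy is a display-level approximation.

## Evaluation

Forward–backward error is the origin-to-return distance after tracking to
the last frame and back; lost points are flagged and excluded from the
statistics but counted. The trajectory criterion bins each marker's forward
and backward positions on a fixed spatial grid (square 8 px cells over the
frame, chosen so that a one-cell systematic shift is clearly separable),
smooths both histograms additively (ε = 1e-6) and renormalises before
computing both directed KL divergences in natural log; acceptance requires
both below 0.1. With short trajectories (~12 positions) the histogram is
sparse, so a position falling within a fraction of a pixel of a cell
boundary can flip one bin between passes and reject an otherwise sub-pixel
trajectory — the criterion is conservative at small sample sizes.

The dispersion column of the accuracy report is exposed both as a standard
deviation in mm and a variance in mm², under unambiguous names. Pixel→mm
conversion divides the 8 mm biopsy-forceps diameter by its apparent size in
pixels; the synthetic pipeline uses a nominal 40 px forceps.

## Synthetic data

The generator renders a multi-octave value-noise texture (band-limited,
gradient-rich at all detector scales) through a chain of bounded random
affine steps. Defaults: 280×240 frames (half the 560×480 endoscope capture,
preserving aspect ratio), per-step rotation ≤ 0.05 rad, jitter translation
≤ 5 px, scale ∈ [0.98, 1.02], additive Gaussian noise with clipping, and a
deterministic camera pan of (20, 5) px/step across the surface. The pan is
the key realism ingredient: it makes frame overlap — and with it
feature-match similarity — decay with frame separation, reproducing the
distance-dependent similarity structure that real endoscopic corpora show
and that the graph method relies on. Site labels are assigned in contiguous
blocks to emulate anatomic subgraphs. Ground-truth step transforms and
landmark positions are stored exactly.

What the generator does *not* emulate: specular highlights, mucosal fold
occlusion, illumination drift, lens distortion, and genuinely nonrigid
tissue deformation (each frame is an exact affine view of one surface).
Passing tests on this data demonstrate the correctness of the graph
machinery — similarity, validation, pathway search, composition,
retargeting — not robustness to the photometric pathologies of clinical
video.

## Problem sizes and numerical choices

The test suite and acceptance pipeline run 12-frame, 280×240 sequences with
6 markers and 200 features per frame — small enough for interactive runs
while exercising multi-hop pathways (typical pathways span 2–4 edges at
h = 0.3). Tolerances: transform algebra identities hold to 1e-9; stored
edge inverses to 1e-6; serialization round-trips transforms to 1e-12 and
edge similarities as 12-significant-digit decimal strings. Degenerate
inputs are first-class: constant images yield empty feature sets, collinear
correspondences raise a geometry error, empty warp overlaps raise an
overlap error, and unreachable pathway destinations raise a pathway error.

## Known limitations

- Piecewise-affine composition accumulates error on long pathways; no
  global bundle refinement is attempted.
- The greedy, direction-guided node walk is not guaranteed to find the
  globally best node in arbitrary graphs; subgraph rejection plus the
  acceptance threshold make it reliable on graphs whose subgraphs contain
  genuinely distinct content.
- Graphs are static: frames observed after construction extend nothing
  (no incremental update scheme).
- Desk-scale focus: the implementation is correct for hundreds of nodes
  but makes no attempt at the indexing or caching needed for
  tens-of-thousands-of-frame corpora.
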
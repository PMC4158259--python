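# endograph

Noninvasive multitarget lesion retargeting for endoscopic image sequences.

During gastroscopy, an endoscopist marks suspicious lesions on screen with
virtual circles instead of tattooing them with ink or argon plasma
coagulation. The problem is then to *re-find* those marked regions in later
frames — after the scope has moved, the stomach wall has deformed, and the
lesion may even have left the field of view. `endograph` solves this by
organising a corpus of pre-observed frames into an **image graph** and
turning deformable registration between any two frames into a shortest-path
search.

It is aimed at researchers in endoscopic image analysis and computer-assisted
intervention who need a transparent, fully seeded reference implementation of
graph-based retargeting, complete with a synthetic ground-truth generator for
quantitative evaluation.

## Method

**Nodes and edges.** Every pre-observed frame is a node. Frames are
described by scale-restricted SIFT-style keypoints (detected only at image
scales σ ∈ [1, 3], reflecting the fixed focal length and confined motion of
an endoscope) with simplified 32-dimensional descriptors (2×2 spatial grid ×
8 orientation bins); after unit normalisation, descriptor entries above 0.4
are clamped to 1 to suppress illumination effects. The similarity of frames
*i* and *j* is

&nbsp;&nbsp;&nbsp;&nbsp;S<sub>ij</sub> = M<sub>p</sub> / max(Fp<sub>i</sub>, Fp<sub>j</sub>),

the number of one-to-one descriptor matches over the larger feature count.
Two nodes are connected directly when S<sub>ij</sub> > h. The threshold h is
found iteratively: starting from the sampled similarity range
[B<sub>low</sub>, B<sub>high</sub>], propose
h = B<sub>high</sub> − λ(B<sub>high</sub> − B<sub>low</sub>) with λ = 0.1,
fit a RANSAC affine transform H<sub>ij</sub> to every connected pair, warp
one frame onto the other and validate with zero-normalised cross correlation
(Dif<sub>H</sub>); any pair with Dif<sub>H</sub> ≤ 0.8 raises the floor
(B<sub>low</sub> ← h) and the search repeats. Each stored edge carries
H<sub>ij</sub>, with H<sub>ji</sub> = H<sub>ij</sub><sup>−1</sup>.

**Query matching.** The graph is partitioned into anatomic subgraphs
(angularis, antrum, body, …). A query image starts at a seeded random node:
if Dif<sub>H</sub> < 0.2 the whole subgraph is abandoned; otherwise the walk
steps to the neighbour whose stored edge transform is most consistent (in
Frobenius distance) with the query's current affine estimate, until no
neighbour improves the score.

**Pathway registration.** Between the reference image's node and the moving
image's node, each candidate edge is weighted by the mean squared difference
(SSD) of two warps into the tail node's frame — the head node's image through
the stored transform against the moving image through its query-derived
transform. Dijkstra's algorithm finds the minimum-weight pathway
[n<sub>i</sub>, n<sub>1</sub>, …, n<sub>j</sub>], and the deformation is the
composition of its edge transforms,
H<sub>ij</sub> = H<sub>n<sub>j−1</sub>n<sub>j</sub></sub> ∘ … ∘ H<sub>n<sub>i</sub>n<sub>1</sub></sub>,
which carries the marked circles onto the moving image (radius scaled by
√|det| of the linear block).

**Evaluation.** Tracking quality is judged without physical ground truth by
forward–backward (FB) symmetry: markers are tracked to the end of a sequence
and back, the FB error being the origin-to-return distance. A trajectory is
accepted only when both directed Kullback–Leibler divergences between the
forward and backward spatial histograms fall below 0.1. Pixel distances
convert to millimetres against the 8 mm biopsy-forceps diameter seen in
frame.

## Worked example

No clinical data ships with the package; the `simulate` command generates a
textured surface imaged through a smooth affine camera walk with known
ground truth:

```bash
endograph simulate demo --n-frames 12 --seed 1
endograph build-graph demo/frames demo/graph.json --h 0.3 --sites demo/sites.json --seed 1
endograph track demo/graph.json demo/frames/frame0000.png demo/markers.json \
    demo/frames demo/tracking.jsonl --stride 1 --seed 1
endograph evaluate --tracking demo/tracking.jsonl --ground-truth demo/ground_truth.json
```

which prints

```
wrote 12 frames, markers and ground truth to demo
graph: 12 nodes, 52 edges, 1 component(s) -> demo/graph.json
tracked 6 markers over 12 frames -> demo/tracking.jsonl
{
  "fraction_within_3px": 1.0,
  "fraction_within_5px": 1.0,
  "max_error_px": 0.2145976532268007,
  "mean_error_mm": 0.005703813307287842,
  "mean_error_px": 0.028519066536439208,
  "mode": "ground-truth",
  "n_frames": 12,
  "n_markers": 6,
  "package_version": "0.1.0"
}
```

All 12 frames connect into a single graph component, and the six marked
circles are retargeted onto every frame with a mean error of 0.03 px
(maximum 0.21 px) against the generator's exact transforms — every
retargeted center lands within the 3 px acceptance radius. Passing
`--overlay-dir` to `track` additionally writes the frames with numbered
green circles drawn at the retargeted positions.

Omitting `--h` makes `build-graph` run the iterative threshold search
instead of using a fixed connection threshold.

## Layout

- `src/endograph/features.py` — scale-restricted detector, 32-D descriptors, matching, similarity
- `src/endograph/transforms.py` — affine estimation (RANSAC), algebra, warping, NCC/SSD scores
- `src/endograph/graph.py` — threshold search and graph construction
- `src/endograph/matching.py` — query-to-node matching with subgraph rejection
- `src/endograph/pathway.py` — edge weights, Dijkstra pathway, retargeting, tracking
- `src/endograph/evaluation.py` — forward–backward framework, KL criterion, reports
- `src/endograph/synthetic.py` — seeded ground-truth sequence generator
- `src/endograph/io.py`, `src/endograph/cli.py` — file formats and the `endograph` command

See `docs/methods.md` for modelling assumptions, parameter defaults and known
limitations.
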
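# Methods

## The model

A mosaic is a set of tiles `i` with constrained affine poses mapping
tile-frame pixels to global coordinates,

    g = s·R(θ)·p + (a, b),

in one of three modes: `T` (translation only, the default — microscope
stages translate), `TR` (adds rotation), `TRS` (adds isotropic scale). The
tile frame has its origin at the top-left pixel center, x rightward, y
downward; pixel centers sit at integer coordinates. The first registered
tile is the anchor and is pinned to the identity, which removes the global
gauge freedom; all reported pose errors are therefore relative to the
anchor frame.

Lens distortion is modeled once per session (not per tile — the optical
train does not change between fields of view) with the Brown–Conrady
radial–tangential model on normalized coordinates `x' = (u−cx)/fx`:

    r² = x'² + y'²
    rad = (1 + k1 r² + k2 r⁴ + k3 r⁶) / (1 + k4 r² + k5 r⁴ + k6 r⁶)
    x'' = x'·rad + 2 p1 x'y' + p2 (r² + 2x'²)
    y'' = y'·rad + p1 (r² + 2y'²) + 2 p2 x'y'
    u = fx x'' + cx,  v = fy y'' + cy

The principal point is fixed at the image center and `fx = fy` at the
tile's larger side: a planar mosaic cannot identify focal length separately
from scale, so optimizing it would only add a degenerate direction. The
model has no closed-form inverse; undistortion solves the 2-D system per
point by Newton iteration (forward-difference Jacobian, pinhole starting
point, tolerance 1e-8 px, 50 iterations max). Points that fail to converge
(fold-over regimes of extreme distortion) are flagged and excluded.

## Registration stage

Per tile: SIFT features (scikit-image implementation; ORB available for
binary descriptors) on the full-resolution luma image; Lowe ratio matching
at 0.75 (L2 for float descriptors, Hamming for binary); robust constrained
fit of the relative pose. For translation-only fits every match offset is
tried as a candidate and scored by consensus (inlier tolerance 3 px) —
deterministic and exhaustive; `TR`/`TRS` use a seeded 2-point RANSAC
(confidence 0.995, ≤2000 iterations) around the closed-form 2-D Procrustes
solution, refit on inliers. A match succeeds with ≥8 inliers and ≥20 %
inlier ratio; below that, homogeneous-tissue estimates are unreliable and
the attempt is treated as failed.

Sequential matching against the previous tile comes first; on failure the
tile is matched against all earlier tiles in descending recency (the
operator usually resumes near a recent position). A tile that matches
nothing is held *pending* and retried after each later success — a
discontinuous acquisition loses no data. Additional matching then runs
against every registered tile whose projected bounding box overlaps the new
tile by ≥5 % of its area (filtering candidates by pose is what keeps the
attempt count near-constant as the mosaic grows); each success adds an edge
to the bundle problem. Every 10th registration, one LM iteration over all
poses runs (`ba_interval=10`, one iteration per trigger; both
configurable). In `sequential_only` mode neither fallback nor additional
matching nor the brief adjustment runs — exactly one attempt per
registration, the baseline the growth-rate measurements compare against.
`brute_force` mode matches against all previous tiles every time, the
worst-case reference.

## Bundle adjustment

Parameters are the non-anchor pose blocks (2/3/4 values by mode), plus —
during composition — one shared distortion block, by default (k1, k2, p1,
p2); k3–k6 stay at zero unless enabled. Four coefficients are stable at
bench scale, and the rational tail is unidentifiable from typical
microscope fields. Residuals are `T_i(U(q_i)) − T_j(U(q_j))` over all
inlier pairs, two components each, in deterministic edge/pair order. The LM
update uses analytic Jacobians for pose blocks and forward differences
(step 1e-6) for the distortion block, damping λ starting at 1e-3, ÷10 on
accepted steps, ×10 with parameter revert on rejected ones. The brief
(registration-stage) adjustment runs a fixed number of iterations with the
distortion block disabled; the composition run iterates until the relative
RMS change drops below 1e-6 (or 100 iterations, or eight consecutive
rejections — λ has then grown eight decades without progress).

## Composition

The canvas is the tight integer bounding box of all projected (undistorted)
tile corners. Warping is inverse mapping with bilinear sampling: canvas
pixel → pose⁻¹ → forward distortion → source pixel; integer translations
therefore reproduce source values exactly. Seams are a Voronoi partition:
every covered pixel belongs to the tile with the nearest projected center
(ties to the lower id) — deterministic, chunk-independent, and with
exposure correction and blending off (evaluation mode) every output pixel
is exactly one tile's resampled value, so residual misalignment stays
visible. Optional per-tile exposure gains minimize squared differences of
overlap-mean intensities (regularized toward 1); optional multi-band
blending (5 bands) merges Laplacian bands weighted by smoothed seam masks.
Rendering proceeds in `chunk_px` square blocks (≥256); every per-pixel
decision depends only on global quantities, so the output is bit-identical
for any chunk size. Output is a tiled TIFF (BigTIFF over 4 GiB) with
subsampled pyramid levels, plus an optional PNG overview; 16-bit input is
preserved end-to-end.

## Acquisition coupling

The stitcher is one-way coupled to the acquisition software through the
file system: a polling watcher detects new files, and a file is ingested
only when its size has been stable across a 200 ms window *and* it decodes
as an image (creation events routinely fire before writes finish). Live
sessions process files in event order, batch runs in lexicographic order;
the two yield identical graphs on the same file sequence. The session state
(poses, inlier pairs, logs) is checkpointed to a JSON project file after
every registration; a killed session resumes from the checkpoint with
bit-identical RMS. Multi-channel fluorescence is handled by filename
patterns: one configured reference channel drives registration, other
channels attach to the reference tile and inherit its pose.

## Synthetic acquisitions

The simulator draws a ground-truth specimen plane in three regimes:
`tissue_blobs` (≈800 anisotropic Gaussian blobs per megapixel plus
band-limited noise — dense multi-scale structure, SIFT finds hundreds of
keypoints per 160 px tile), `homogeneous` (dense low-contrast cellular
texture with sparse vessel-scale landmarks — the liver-like regime where
matching is weakest; feature counts fall clearly below `tissue_blobs`), and
`sparse` (isolated structures over near-empty background). Trajectories
are serpentine, center-out clockwise spiral, discontinuous (a mid-sequence
tile is deferred to the end, so the final capture has no overlap with its
predecessor but overlaps earlier tiles — exercising the fallback path), and
random walk. `jitter_frac` adds hand-placement wobble per step while
re-sampling to preserve the consecutive-overlap contract. The camera
renders each tile by inverting the distortion map on the pixel grid
(cached per camera), sampling the plane bilinearly, then applying one
multiplicative exposure factor per tile (default ±5 % when enabled) and
additive Gaussian sensor noise. Everything is deterministic per seed, and
the ground-truth sidecar (true poses + true distortion) suffices to score a
stitcher without touching its internals.

What the simulator does not emulate: optical point-spread/defocus blur,
stage drift dynamics, staining variability, JPEG artifacts, and the gross
repetitive-pattern ambiguity of real parenchyma. Synthetic matches are
therefore substantially cleaner than real-tissue matches: passing tests
show the machinery is correct and self-consistent, not that real liver
sections will match as reliably.

## Benchmark conditions

The standard benchmark (`slidestitch.benchmarks`) fixes these problem
sizes, chosen to keep a full run on one CPU core in minutes while leaving
each effect clearly measurable:

- Trial accounting: 30-tile noiseless serpentine, 160 px tiles, 20 %
  overlap. Brute-force matching must show an attempt-growth slope of
  exactly 1 per registration; the default schedule must fire the brief
  adjustment at registrations 10, 20, 30.
- Additional matching: 100-tile spiral, 160 px tiles, 25 % overlap, barrel
  distortion k1=−0.05, k2=0.01 (fx = tile width), sensor noise σ=3 gray
  levels, ±5 % exposure jitter, 5 % hand wobble. Both runs reuse one
  feature detection; RMS is evaluated over a common edge set rebuilt from
  every overlapping tile pair under each run's frozen poses (a chain-only
  graph has no loop-closure edges of its own, so scoring only its own edges
  would hide the drift).
- Distortion correction: 30-tile serpentine at 256 px tiles (corner
  displacement ≈4 px, comfortably above the ≈0.5 px feature-localization
  jitter), same camera/noise; composition runs once with the shared
  distortion block and once without, from the same registered poses.
- Ground-truth recovery: the noiseless 9-tile serpentine must recover all
  poses to <0.1 px after anchor alignment; the 10-tile discontinuous
  sequence must register every tile through the fallback path.

## Known limitations

- Pose modes cover rigid/similarity stage motion only; shear or
  non-uniform scale would demand a full affine mode.
- The LM solver builds dense normal equations — fine to ~1000 tiles,
  wasteful beyond.
- No robust loss in the bundle objective: a grossly wrong edge (possible on
  strongly repetitive tissue) is averaged in, not down-weighted.
- Voronoi seams ignore image content; a graph-cut seam would hide moving
  debris or stitching artifacts better.
- AKAZE/BRISK/KAZE are accepted in configuration as names but have no
  backing implementation here; requesting them raises a configuration
  error.
- At bench-scale tile counts the simulator cannot reproduce the error
  magnitudes of 300–900-image real acquisitions: per-step registration
  error shrinks with the square root of the per-edge inlier count, so a
  100-tile mosaic built from clean synthetic matches drifts far less,
  relative to its jitter floor, than the long weak-texture sequences the
  two-stage design targets (see the benchmark discussion above).
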
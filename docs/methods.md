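# Methods

`cellvfa` quantifies the temporal dynamics of a single tracked cell in a
live-cell video and classifies its activation state.  The model has three
layers: frame-pair dynamic features, video-wide aggregation by compact
encoding, and a linear-SVM evaluation protocol.  This note records the model
assumptions, the parameters that matter, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Frame-pair dynamic features

For a frame pair (i, i+Δ) the package computes a feature vector
F = (F_DCS, F_MDF, F_ACF) of length L + 2R.

**Contour deformation (F_DCS).**  Both cell contours are resampled to n
points equally spaced by arc length (canonical start: the vertex nearest
angle 0 from the centroid).  Each point receives a shape context — a
log-polar histogram (5 radial × 12 angular bins; radial edges log-spaced in
[1/8, 2] × the mean pairwise distance, so the descriptor is translation- and
scale-invariant; rotation is deliberately not normalized because tracked,
stabilized cells have a meaningful absolute orientation).  Points are put in
correspondence by the Hungarian algorithm on the χ² histogram cost
(zero-denominator terms contribute 0, the only finite reading), and a
regularized thin-plate spline warps one contour onto the other.  The
symmetric shape-context distance

D_SC = (1/n) Σ_p min_q C(p, T(q)) + (1/m) Σ_q min_p C(p, T(q))

is recorded at each of L matching rounds, always under the transform
accumulated in the *previous* rounds (identity at round 1, so D_SC¹ is the
raw distance of the unregistered contours).  Recording before rather than
after each warp keeps the first entry a pure deformation magnitude; with
exact interpolation after a bijective matching the post-warp distance is
identically zero and the feature would be degenerate.  When a round reaches
distance exactly 0 the contours are registered and the remaining entries
stay 0.

TPS fits after round 1 use regularization λ = 10⁻³·(mean pairwise
distance)², which scales correctly under similarity transforms and avoids
the singular refits exact interpolation produces on registered contours.
`fit_tps` itself supports λ = 0 and then interpolates controls exactly
(machine precision); collinear controls raise `LinAlgError`.

Defaults: n = 100, L = 10 in the combined feature (L = 30 when the contour
feature is used standalone).

**Cytoplasmic streaming (F_MDF, F_ACF).**  Dense per-pixel SIFT descriptors
(16×16 support, 4×4 cells × 8 orientation bins, ℓ2-normalized to [0, 255],
mirror-padded borders) are matched between the frames by minimizing the
truncated SIFT-flow energy

E(w) = Σ_p min(‖s¹_p − s²_{p+w_p}‖₁, t) + Σ_p η(|u_p|+|v_p|)
     + Σ_{(p,q)} [min(α|u_p−u_q|, d) + min(α|v_p−v_q|, d)]

over integer displacement fields (4-neighbor smoothness, decoupled per
component).  Optimization is coarse-to-fine (descriptor images average-pooled
until the short side is < 16): at every level, checkerboard ICM sweeps move
each pixel to its locally optimal displacement inside a ±2 search window;
candidate starts are the upsampled coarse field and an exhaustive
best-data-match field centered at the median upsampled displacement, and the
lower-energy result wins.  Each sweep can only lower the energy, the
reported energy always equals an independent re-evaluation of E(w), and
displacements are capped (default 8 px at full resolution in the pipeline).
The optimizer contract is near-optimality against an ICM oracle restarted
from exhaustive best matches on small instances, not global optimality.

Energy weights: η = 0.005·255 and t = 40·255 follow common SIFT-flow
practice; the smoothness pair is set to α = 0.5·255, d = 10·255 — one
quarter of the weights used for richly textured natural scenes, at the same
α:d ratio.  Microscopy frames carry gradients only at the cell boundary and
on intracellular granules; under the natural-scene weights the ground-truth
streaming field of a synthetic cell has *higher* energy than the zero field,
so every estimate collapses to zero motion.  The scaled default makes true
motion optimal while leaving flat background still.

The appearance change field is ‖s¹_p − s²_{p+w_p}‖₂ — descriptor discrepancy
along the estimated correspondence (the natural reading of "corresponding
points"; with w = 0 it reduces to the same-position difference).  It is zero
where the matched descriptors agree, so coherent motion scores low while
split / merge / disappearance events of cargo score high.

Both fields are summarized as orientation histograms over R equal sectors of
[0, 2π): each pixel with nonzero displacement contributes its flow magnitude
(movement histogram) or its appearance discrepancy (appearance histogram) to
the sector containing its flow angle.  Zero-displacement pixels have no
angle and are skipped; histograms are restricted to the cell mask dilated by
2 px; no frame-level normalization is applied (the encoding normalizations
handle scale).  R = 10 in the combined feature, 36 standalone.  Flow is
computed on the union bounding box of the two contours padded by 16 px
(full-frame mode available).

## Video-wide aggregation

A video's frame-pair features X = (x₁ … x_N) are pooled into one vector:

* **Fisher vector (FV)** under a diagonal-covariance GMM with K components:
  per component the soft-assignment-weighted first- and second-order
  residuals u_k, v_k; size 2D′K; signed-square-root (SSR) then global ℓ2
  normalization.
* **VLAD-k**: sum of residuals of each descriptor to its k (default 5)
  nearest k-means centers; intra (per-block ℓ2) → SSR → global ℓ2; size D′K.
* **H-VLAD**: first/second/third-order residuals between the assigned
  descriptors' statistics and each word's training statistics; empty words
  encode as zero blocks and the skewness residual is zeroed when undefined
  (N_k ≤ 2 or zero spread); intra → SSR → global ℓ2; size 3D′K.
* **Temporal pyramid pooling (TPP)**: the encodings of the whole sequence,
  its halves and its thirds (contiguous near-equal windows, earlier windows
  take the remainder) are concatenated and ℓ2-normalized again — ×6 the
  size, restoring coarse temporal order that the pooled encodings discard.

Numerical choices that matter at desk scale:

* Frame-pair descriptors are z-scored on training statistics before
  codebook learning and encoding — the 30 dimensions span four orders of
  magnitude (χ² distances vs magnitude-weighted histograms) and would
  otherwise be represented only by their largest dimensions.
* PCA to D′ = 3 before the codebook.  On idealized two-state descriptor
  clouds (a shared rest mode plus a class-specific active mode, the regime
  these encodings target) small D′ maximized FV accuracy, and it keeps the
  FV+TPP dimension (2·3·8·6 = 288) commensurate with ~40-video training
  sets; with identity PCA the many noise dimensions dominate the SSR+ℓ2
  geometry.  Configurable, and disabled for the pooling baseline.
* GMM variance floor 0.1 × the mean global variance.  With a few hundred
  training descriptors EM produces near-singleton components whose σ → 0;
  the FV residuals divided by that σ explode and one block absorbs the whole
  ℓ2 norm.  The floor keeps component scales commensurate (measured on the
  binary benchmark: 0.68 accuracy with a 10⁻⁶ floor vs 0.98 with 0.1, same
  data and splits; VLAD, which divides by no σ, is unaffected).
* The `avgpool` scheme is the reference baseline: the plain temporal mean of
  the *raw* frame-pair features fed directly to the SVM, with none of the
  above preprocessing.

## Evaluation protocol

Per random split (default 30 splits, 20 training videos per class; the desk
benchmarks use 5 splits with 10 per class), the codebook, PCA and
standardization are fitted on training videos only; every video is encoded;
a linear SVM (penalty selected from 2⁻⁵…2¹⁵ in powers of 4 by stratified
fivefold cross-validation on the training encodings) is scored on the
held-out videos.  Metrics: accuracy, macro one-vs-rest precision / recall /
F-score, per-class accuracy and its mean (mAP), all as mean ± sd over
splits.  The binary score-overlap diagnostic histograms the SVM decision
values of the two classes on shared bins (each normalized to unit mass) and
reports Σ min(h⁺, h⁻).

All randomness (splits, k-means/GMM/SVM-CV seeds, generators) flows from
explicit integer seeds; rerunning any stage reproduces it bit-exactly.

## Synthetic benchmark

The generator emulates one tracked cell per field: a star-shaped contour
r(θ, t) = R₀(1 + Σ_m a_m(t) cos(mθ + φ_m + s_m ω_m t)) whose Fourier bump
pattern travels around the membrane at a near-constant rate (the cell
elongates from a slowly rotating angle), a speckled cytoplasm of bright and
dark Gaussian granules advected by a smoothed random velocity field of
controlled mean speed (with optional uniform drift), per-particle
split / merge / disappear events, distractor blobs strictly outside the
contour, and additive Gaussian frame noise.  Ground truth (contours and
per-pixel displacement fields) is returned alongside the frames; an optional
`observe_contour` step can degrade contours with segmentation-like wobble
and glitches (off by default).

Two canonical studies define the benchmarks:

* **Binary (normal vs abnormal)** — sustained dynamics; deformation
  amplitude 0.05 vs 0.30, streaming speed 0.5 vs 3.0 px/frame; 20 videos per
  class, 24 frames of 64×64 px, frame interval Δ = 4.
* **Graded activation (4 classes)** — normal / slight / moderate / drastic
  with amplitudes {0.02, 0.1, 0.2, 0.35} and speeds {0.5, 1, 2, 3};
  36-frame videos.  Cells are active only in intermittent bouts: a smooth
  periodic envelope (period 16 frames) gates both deformation and streaming
  between a quiescent floor (amplitude 0.02, speed 0.3) and the class level.
  The fraction of time spent active varies per video (duty ∈ [0.25, 0.75])
  while the *intensity* of active episodes is the class signature (±5%
  per-video jitter).  This is the regime in which temporal aggregation
  matters: the time-averaged feature confounds "how often" with "how
  strongly", whereas the encodings retain where in descriptor space the
  active episodes sit.

What passing benchmarks show — and what they do not: the synthetic cells
exercise contour deformation measurement, dense-correspondence estimation,
appearance events, class-dependent dynamics and the whole evaluation
protocol, with known ground truth.  They do not reproduce phase-contrast
optics, imaging artifacts, segmentation error (unless enabled), cell
division or migration, multi-cell occlusion, or 3-D streaming projected to
2-D; absolute accuracies on them say nothing quantitative about real
recordings.

## Degenerate inputs and edge rules

Orientation-bin boundaries use floor with a 10⁻⁹ bin-fraction epsilon and a
wrap of the 2π boundary onto bin 0, so proportional point sets bin
identically (exact scale invariance).  Flow targets outside the image are
charged the data truncation t and masked invalid; appearance values there
are 0.  All-zero encodings (every descriptor exactly on its center) are
returned unnormalized with a warning.  TPP requires N ≥ 3 frame-pair
features.  Classes with fewer than n_train_per_class + 1 videos are rejected
by name.

## Known limitations

Integer displacements only (no sub-pixel flow or variational refinement);
ICM with restarts is a heuristic minimizer and can keep collective local
minima on adversarial inputs; the shape-context stage assumes a single
simple closed contour (no occlusion or outlier points); runtime is
dominated by the flow estimator (~0.5 s per 64×64 frame pair on one core).
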
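# Methods

## Problem and model

A bulk image of milled rice on a dark belt is reduced to a binary mask;
each connected component is either a free kernel or a chain of touching
kernels. The method rests on three observations: (i) two convex kernels
in shallow contact create exactly two reflex (concave) boundary points at
their neck; (ii) a reflex point is detectable locally, because a square
window centered on it is mostly foreground; (iii) the segment joining the
two neck points separates the kernels with a one-pixel cut. Lengths of
the separated kernels against a ¾-of-intact-length rule then give the
head rice rate as an area ratio.

## Concavity score and threshold

The ECMP of boundary pixel `t` is the foreground fraction of an odd
square template centered on it. Template side ≈ `max_dim / 300`, rounded
down to odd and clamped to ≥ 3 (9×9 at a 3000×2500 frame); windows
overhanging the frame are padded with background, biasing frame-edge
pixels toward "convex" so no false cuts appear at the frame. The profile
is sampled clockwise from the lexicographically smallest edge pixel via
Moore-neighbor tracing (holes ignored).

The detection threshold is `λ = E(k) + a·σ(k)` per component, clipped to
at most 1, with `σ` the sample standard deviation over the N boundary
samples. On the synthetic suites this lands at λ ≈ 0.65-0.72 — straight
edges score 45/81 ≈ 0.56 and necks 0.78-0.92 — so detection has a wide
margin on both sides. `a` is a variety coefficient: japonica ≈ 3,
indica ≈ 2. Slender kernels produce flatter profiles (long straight
flanks, milder tip curvature), so a smaller multiple reaches the same
absolute threshold; both defaults follow the variety presets.

Two numerical guards:

* **Reflex floor.** A run of `k(t) ≥ λ` only counts if it also reaches
  k ≥ 2/3 (a 240° interior angle). Rasterized convex outlines have
  staircase jaggies that peak at 49/81 ≈ 0.605 under the 9×9 template;
  true necks score ≥ 0.78. Without the floor, a low-variance convex
  profile can put λ under its own jaggies and emit spurious points.
* **Circular runs.** Runs of `k ≥ λ` wrap around the profile start; each
  maximal run contributes its peak index (ties to the smallest index).

## Matching and cutting

Walking the boundary both ways from a concave point A until it leaves the
template window gives the crossover points M and N. The admissible region
is the closed cone with apex A bounded by the rays *opposite* AM and AN:
of the two cones the template geometry defines, this is the one that
points across the neck into the other kernel, and on symmetric two-kernel
fixtures it is the only orientation under which the opposing neck point
is admissible. Collinear M, A, N degenerate to the half-plane on the
local-foreground-centroid side.

Basic points are visited in boundary order (a deterministic stand-in for
an arbitrary starting point); each unmatched point takes its nearest
unmatched admissible candidate, and every point joins at most one pair —
one cut per neck follows from two points per pairwise contact. Cuts are
rasterized 4-connected (a Bresenham line plus one pixel at each diagonal
step) so an 8-connected mask always disconnects across the cut; fragments
below 25% of the variety's minimum kernel area are merged back into their
largest neighbor, and a cut that fails to split its component leaves it
whole with a warning. Matching is single-pass; detection is not re-run on
the cut pieces.

## Lengths, the ¾ rule, and yield

`mer_length` rotates the outline about its centroid over {0°, 3°, …,
87°}, takes the axis-aligned extent (max − min + 1, the pixel-extent
convention) at each step, and returns the longer side of the
smallest-area box, ties to the smaller angle. At a 3° grid the worst
misalignment is 1.5°, bounding the overestimate by a factor 1/cos 1.5°;
tests verify agreement with an exact rotating-calipers oracle within one
pixel plus that bound. `med_length` (maximum pairwise distance, computed
on the convex hull and verified against the O(n²) scan) and `cr_length`
(maximum extent under centroid rotation) are comparators only: both
return the outline diagonal — the *theoretical* length, slightly longer
than the kernel — which is why MER is the primary estimator.

The head call is boundary-inclusive: length ≥ 0.75 × reference, so an
exactly-¾ kernel is head. The reference is the mean measured length of
ten intact kernels, taken with the same length method as the
measurements so systematic rasterization bias cancels. One sub-pixel
correction matters here: a pixel extent measures a true length L as
≈ L + 1 px, and scaling a raw extent by ¾ shrinks that offset to 0.75 px,
handing every kernel a +0.25 px advantage exactly at the boundary. The
calibration therefore returns the reference for which ¾ of it equals the
extent of a true ¾-length kernel (`ref + 1/3`). Head rice yield is the
exact ratio `S_hr / S_total` of summed pixel areas, the standard
area-for-mass proxy for a single variety.

## Synthetic scenes

Kernels are superellipses (exponent 2.5 — blunter-ended than an ellipse,
matching milled-kernel silhouettes), truncated by a chord perpendicular
to the major axis for broken kernels; a kernel is "broken" exactly when
its length fraction is below 0.75. Two variety regimes: japonica-like
(length 92-112 px, aspect 1.8-2.2) and indica-like (112-136 px, 2.8-3.4).
The pixel scale matches the acquisition geometry the template rule is
calibrated for: a ~3000×2500 px frame holding 100-200 kernels at
~15 px/mm, so a 6-7 mm kernel spans ~100 px. Intensities: belt ≈ 10/255,
kernels ≈ 200/255, Gaussian noise σ = 3, plus bright specks (area
3-30 px, well below the ~100 px noise cutoff at full-frame scale).

Chains of 2-5 kernels are built by sliding each new kernel along a
random direction until first pixel contact, then pushing in by a random
1-4 px overlap depth (the contact geometry is a modeling choice — no
measured value exists for it); contacts deeper than ~60 px² or touching
non-consecutive members are rejected, so every pairwise contact is a
clean two-concave-point neck. Truth labels assign contact pixels to the
earlier kernel. Clusters are placed with ≥ 24 px clearance (about two
template widths) so one cluster's concavity windows never see another;
benchmark scenes use a fixed 2500×3000 canvas so a 100/150/200
kernels-per-frame sweep changes true density. Scenes are pure functions
of their arguments including the seed.

What the generator does *not* emulate: photometric texture, shadows,
lens distortion, motion blur, heavy occlusion (kernels on top of each
other), and clumps of more than five. Passing benchmarks therefore show
the geometric separation logic is sound under realistic contact
geometry, not that the thresholding survives difficult illumination.

## Benchmark protocol

Separation accuracy is detected-count / true-count per scene, averaged —
over-segmentation can push a scene above 1 and is reported raw. Head-call
omission (true head called broken) and false detection (true broken
called head) are computed by matching each detected kernel to the truth
kernel of maximal pixel overlap. The boundary-straddling suite draws
length fractions uniformly on [0.55, 1.0] with all intact kernels at one
fixed full length: with within-variety length variation there is no
single reference length consistent with the per-kernel fractional truth,
so a fixed intact length is the only setting in which the ¾ rule against
the shared reference coincides with the per-kernel ground truth.

Default suite sizes (6 scenes × ~150 kernels; 500 kernels for the
straddle suite) keep a full benchmark run within a few minutes on one
CPU while holding the binomial noise on the reported rates near or below
a percentage point.

## Known limitations

* One concave point can be missed on shallow necks in dense japonica
  chains (λ rises with every neck the component carries, since each neck
  inflates σ); its partner then stays unmatched and the pair of kernels
  is counted as one. This is the dominant residual error (~2-4% of
  kernels at default conditions).
* Under-segmented blobs measure long and are usually called head, so
  separation misses bias the head rice rate slightly upward.
* The head call is sharp at the ¾ boundary; kernels within ~0.3% of it
  can flip either way from sub-pixel measurement noise.
* The automatic template and noise-cutoff rules assume full-frame
  images; small crops of the same kernel geometry need
  `template_size`/`min_component_area` set explicitly.
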
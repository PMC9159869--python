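# Methods

## Model

`ovaseg` segments a 2-D grayscale image by joint spatial–gray mean
shift.  Every pixel is a sample x_i = (r_i, c_i, g_i); mode seeking from
a start pixel iterates the Gaussian-kernel weighted mean

    y ← Σ_i w_i x_i / Σ_i w_i,
    w_i = exp(−‖y_s − x_{s,i}‖²/2h_s²) · exp(−(y_g − g_i)²/2h_g²).

Each such step is a mean shift step on the joint kernel density
estimate at the bandwidths used for that step, so the KDE value cannot
decrease along the trajectory (checked as a property test).  Iteration
stops when the *gray* component of the shift drops below `tol`.  The
gray component is the quantity segmentation consumes; a joint
(spatial+gray) stopping rule would keep border pixels of flat regions
iterating indefinitely on a pure spatial drift toward the grid
centroid, with no effect on the output gray.

The traditional algorithm fixes h_g = f_max.  The improved variant
re-evaluates, at every iteration, the bandwidth law

    h_g(t) = f_max · (1 − z_t · exp(−(t − t_ROI)²/2σ_ROI²)),

at the current iterate's gray t, contracting the bandwidth near the
gray level of the region of interest and relaxing it to f_max far away.
As printed in its source, the law has no gray scale in the exponent
(exp(−(t−t_ROI)²) is ≈ 0 for any |t−t_ROI| > 3 gray levels, leaving the
adaptation inert on 8-bit data); σ_ROI supplies that scale while
preserving the law's shape.

### Texture weighting

z_t = Q_max / Σ Q_i is computed from four directional texture-energy
maps.  The filter bank holds oriented first-derivative kernels at
0°/45°/90°/135° (Sobel operator and its 45° rotation), gain-normalized
so that a gray step of height h produces a peak response of h; energy
is the local mean of |response| over a square window.  Laws' classical
separable bank was considered and rejected for the directional role:
it has no true 45° member (its E5ᵀE5 "ripple" kernel responds to both
diagonals identically), whereas the Sobel pair is exactly closed under
90° rotation, which gives the bank a clean invariance: rotating the
image permutes the four energies.  For isotropic speckle the four Q_i
are nearly equal and z_t ≈ 1/4; z_t grows toward 1 only when one
orientation dominates.  A textureless (constant) image has Σ Q_i = 0;
the pipeline then falls back to z_t = 0, i.e. fixed-bandwidth behavior.

### Post-processing

1. **Mode labelling** — neighbouring pixels (4-connectivity by
   default) sharing a label iff their converged grays differ by at most
   `gray_tol` (1.0); connected components become regions.
2. **Threshold merging** — adjacent regions whose mean grays *in the
   filtered image* differ by ≤ H merge, globally smallest difference
   first, means recomputed after every merge; ties break on the label
   pair, making the result order-independent and deterministic.  H is
   automatic: the mean of the direction texture-energy map (pixel-wise
   maximum over the four directional maps, native gray units) of the
   *filtered* image, clamped to [h_min, h_max] = [2, 64].  Computing H
   on the raw input would measure speckle amplitude rather than
   residual structure: on 4-look phantoms it saturates the clamp at 64,
   which exceeds the 60-gray tissue contrast and collapses the
   partition.  The filtered image is the one the merge operates on, so
   its residual texture is the right yardstick.  `merge.threshold_override`
   bypasses the automatic value.
3. **Non-protruding-mode absorption** — each region's mode height is
   the maximum joint-KDE value over its pixels' converged points (the
   maximum, not the density at an averaged point: regions need not be
   convex, and the mean converged point of a ring-shaped background
   region lies inside the structure it surrounds).  A region whose
   height is below `prominence` (0.3) times the height of its
   strongest neighbour is absorbed into that neighbour, weakest first,
   to a fixpoint.
4. **Fragment removal** — regions smaller than `min_size` (20 px at
   128×128) join the adjacent region with the closest filtered mean
   gray, smallest fragment first.

Every stage maps a partition to a coarser or equal partition.

## Evaluation metrics

For a segmented target mask U₁ and truth mask U₂:
RDD = ||U₂|−|U₁||/|U₂|·100 (area agreement; the printed source formula
is ambiguous between area difference and set difference, so the
set-difference reading |U₂∖U₁|/|U₂| ships as `rdd_setdiff`),
ROD = min(|U₁∩U₂|/|U₂|, |U₁∩U₂|/|U₁|)·100 (the weaker directional
overlap), Dice = 2|U₁∩U₂|/(|U₁|+|U₂|).

The target mask is extracted from a label map by a greedy union:
regions ordered by the fraction of their pixels inside the truth mask
are added while the Dice of the running union improves.  With one
dominant region this reduces to picking the single best region; on a
perfect segmentation of a multi-structure target (several follicles,
one region each) it returns exactly the truth pixels, which a
single-region rule cannot.

## Phantom generator

The generator emulates the gross radiometry of a transvaginal B-mode
view: background tissue at gray 150, an elliptical ovary (semi-axes
44×32 px at 128×128) at gray 90, and dark follicles (radius 8–12 px,
gray 30) rejection-sampled strictly inside the ovary without overlap.
The clean scene receives a Gaussian point-spread blur (σ = 1 px) and
then per-pixel multiplicative unit-mean Gamma speckle with shape
parameter `looks` (default 4, a heavily speckled B-mode regime:
intensity SD is mean/2); ground truth is emitted before degradation and
is bit-independent of the noise settings.  Per-pixel Gamma noise is
harsher than real envelope speckle, whose grains are correlated at the
resolution-cell scale, and the phantom omits attenuation, shadowing and
refraction; phantom results therefore bound the method's behavior under
idealized speckle, not under every clinical artefact.  All randomness
flows from a single integer seed through independent sub-streams
(geometry vs noise), so outputs are bit-reproducible.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `bandwidth.f_max` | 24 | gray | maximum (and fixed-mode) gray bandwidth |
| `bandwidth.h_s` | 8 | px | spatial bandwidth |
| `bandwidth.sigma_roi` | image gray SD | gray | scale of the ROI Gaussian in h_g(t) |
| `roi.seed` | none | (row, col) | ROI pixel; t_ROI is its 5×5 median, else the Otsu-foreground mean |
| `meanshift.tol` | 0.1 | gray | gray-shift convergence tolerance |
| `meanshift.max_iter` | 100 | — | per-pixel iteration cap |
| `texture.window` | 15 | px | energy-averaging window |
| `merge.h_min`, `merge.h_max` | 2, 64 | gray | clamp band for the automatic H |
| `merge.gray_tol` | 1.0 | gray | mode-labelling tolerance |
| `merge.prominence` | 0.3 | — | non-protruding absorption ratio |
| `merge.min_size` | 20 | px | fragment floor (scaled for 128×128) |

f_max was chosen on phantoms as the smallest bandwidth that flattens
4-look speckle plateaus without absorbing the 60-gray follicle–ovary
contrast; it is applied identically to both algorithm variants in every
comparison, so the improved-vs-traditional ordering does not hinge on
it.  σ_ROI defaulting to the image gray SD ties the width of the
bandwidth dip to the image's own contrast range.

## Numerical choices

- Working gray range is [0, 255] held as float64.  Inside the filter,
  *sample* grays are snapped to the integer 8-bit grid (ultrasound
  exports are 8-bit), which lets the gray kernel be evaluated through a
  256-entry table per iteration instead of one exp per neighbour
  (≈3× faster); iterate grays stay continuous.  On integer-valued
  images the snap is the identity, and the compiled kernel agrees with
  a brute-force O(N²) reference to better than 1e-9.
- The spatial kernel is truncated at 3 h_s around the current iterate;
  the gray kernel is never truncated, so on images smaller than the
  truncation radius results are identical to the untruncated
  computation (this is what the brute-force equivalence tests rely on).
- h_g is floored at 0.01 gray inside the filter so the degenerate
  z_t = 1, t = t_ROI corner cannot divide by zero; if every kernel
  weight underflows, the iterate simply stops.
- Gray-inversion symmetry (inverting the image and t_ROI negates the
  mode grays) holds to ~1e-9, limited by floating-point reassociation
  in the compiled kernels.
- Mean shift filtering is *not* idempotent on noisy images:
  re-filtering a filtered image merges shallow plateaus further.  On
  piecewise-flat images (its own fixed points) a second pass changes
  grays by less than `tol`, and that is the scope of the idempotence
  test.

## Problem sizes

The shipped benchmark segments 20 phantoms at 128×128 with both
variants (≈10 s per segmentation end to end on one core), and the
noiseless check uses 5 phantoms; these sizes make the full comparison
reproducible on a laptop in a few minutes while leaving the median
ordering of the two variants stable across seed bases.

## Known limitations

- The adaptive advantage is modest by construction: for isotropic
  speckle z_t ≈ 0.25, so the bandwidth contracts by at most a quarter
  at t_ROI.  Median follicle Dice over 20 phantoms is ≈ 0.45 vs ≈ 0.40
  for the fixed baseline at 4 looks — heavy speckle, where absolute
  accuracy is limited for both.
- t_ROI from the Otsu-foreground mean is a crude fallback; seeding the
  ROI explicitly is recommended whenever the target is known.
- The phantom's iid Gamma speckle is pessimistic (see above); no
  attempt is made to simulate scanner post-processing such as log
  compression or persistence.
- The pipeline is single-channel and 2-D; Doppler/color channels and
  3-D volumes are out of scope.
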
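# ovaseg

Mean shift segmentation with an adaptive gray bandwidth for
speckle-corrupted B-mode ultrasound images, built around the use case of
delineating dark follicles inside the ovary on transvaginal scans.

## The problem and the method

Classical mean shift filtering treats every pixel as a sample
x_i = (r_i, c_i, g_i) in the joint spatial–gray domain and moves each
point uphill on the Gaussian kernel density estimate

    y ← Σ_i w_i x_i / Σ_i w_i,
    w_i = exp(−‖y_s − x_{s,i}‖² / 2h_s²) · exp(−(y_g − g_i)² / 2h_g²),

until it reaches a mode; pixels whose modes agree form regions.  With a
*fixed* gray bandwidth h_g the method must compromise: a bandwidth large
enough to flatten speckle in bright tissue destroys the low-contrast
structures of interest, while a small bandwidth leaves speckle
over-segmented.

`ovaseg` makes the gray bandwidth a function of the current iterate's
gray level t:

    h_g(t) = f_max · (1 − z_t · exp(−(t − t_ROI)² / 2σ_ROI²)),

so the bandwidth contracts to f_max·(1 − z_t) at the gray level of the
region of interest t_ROI (preserving target detail) and relaxes to f_max
elsewhere (suppressing speckle).  The weight

    z_t = Q_max / Σ_i Q_i

comes from four directional texture-energy maps (mean absolute oriented
derivative over a local window): Q_i is the mean of map i and Q_max the
largest of them, so strongly oriented texture increases the contraction.

Filtering is followed by mode labelling, threshold merging of adjacent
regions whose filtered mean grays differ by at most an automatically
derived threshold H (the clamped mean of the direction texture-energy
map of the filtered image), absorption of non-protruding modes (regions
whose kernel-density peak is weak relative to an adjacent mode), and
removal of small fragments.

Segmentations are scored against ground truth with the relative
difference degree RDD = ||U₂|−|U₁||/|U₂|·100, the relative overlap
degree ROD = min(|U₁∩U₂|/|U₂|, |U₁∩U₂|/|U₁|)·100 and the Dice
coefficient 2|U₁∩U₂|/(|U₁|+|U₂|).

Because no clinical images ship with the package, a seeded phantom
generator emulates the B-mode scene (bright background, mid-gray
elliptical ovary, dark circular follicles, point-spread blur,
multiplicative unit-mean Gamma speckle) and emits the matching
ground-truth label map.

## Worked example

```python
import ovaseg

# a 128x128 4-look speckle phantom and its ground truth
img, truth = ovaseg.make_phantom(ovaseg.PhantomConfig(seed=5))

# segment, seeding the region of interest at a follicle centre
res = ovaseg.segment_image(img, {"roi.seed": ovaseg.follicle_roi_seed(truth)})
print(res.labels.n_regions)
print(round(res.manifest["resolved"]["z_t"], 4))
print(round(res.manifest["resolved"]["merge_threshold_H"], 2))
print(ovaseg.score_follicles(res.labels, truth))
```

prints

```
51
0.2511
18.04
MetricsReport(rdd=259.53051643192487, rod=27.709584747975974, dice=0.43359215365753984)
```

51 regions survive post-processing; the texture weighting coefficient
z_t ≈ 0.25 (speckle is nearly isotropic, so each direction carries about
a quarter of the energy); the automatic merge threshold is ≈ 18 gray
levels; and the follicle class is recovered with Dice 0.43 under heavy
4-look speckle — the fixed-bandwidth baseline on the same phantom
reaches 0.38.  In the noiseless limit
(`speckle_looks=math.inf, blur_sigma=0`) the same pipeline returns the
ground-truth partition exactly (Dice 1.0).

The same pipeline is available from the shell:

```sh
ovaseg phantom --out ph --n 20 --seed 7 --looks 4
ovaseg segment ph/phantom_0007.png -o seg --roi 64,64
ovaseg evaluate seg ph -o metrics.csv
ovaseg stats detection-rate --detected 132 --not-detected 28
```

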
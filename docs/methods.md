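# Methods

This note records the modelling assumptions, parameter choices and known
limitations of the package. It documents *how* quantities are computed;
every number quoted elsewhere is produced by the examples, tests or
acceptance script at run time.

## Zone geometry

A binary lung-field mask is split into its two largest 4-connected
components (smaller components are discarded with a warning; fewer than
two components, or two components whose column ranges overlap by more
than half, are errors). The component with the smaller column centroid —
the image left — is the patient's anatomical **right** lung, the standard
posteroanterior-film convention.

Per lung, the apex row is the topmost foreground row and the dome row the
bottommost. With span = dome − apex, the third boundaries are
b₁ = apex + ⌊span/3⌋ and b₂ = apex + ⌊2·span/3⌋, and the zone row
intervals are [apex, b₁), [b₁, b₂), [b₂, dome] — half-open except the
last, so the three intervals tile [apex, dome] exactly and the remainder
rows are absorbed by the lower zones. Lungs shorter than four rows cannot
be partitioned and raise a geometry error. Crops span the lung's column
bounding box; pixels outside that lung are zeroed, so non-lung anatomy
cannot leak signal and the six crop masks conserve the lung-field pixel
count exactly (a property the tests check on generated masks).

## Intensity harmonisation and resizing

Histogram matching is the exact empirical quantile map: each pixel value
is replaced by the reference-image quantile at its source CDF position,
computed with integer arithmetic so matching an image to itself is the
identity and the output takes only reference values. A constant reference
has no spread to match against and is rejected. (The interpolating
variant in scikit-image agrees with this map on continuous images and is
used as an independent cross-check in the tests.)

Zone crops are resized to a fixed height (default 256; the desk-scale
examples use 48) with a per-zone width of round(height × r_w), where the
aspect 1:r_w is the ratio of the mean width to the mean height of the
zone's *training-split* crops — computed per cross-validation fold and
frozen into a policy file, so no test-set statistics leak into
preprocessing. Rounding is half-away-from-zero; interpolation is bilinear
(nearest-neighbour selectable). Optional augmentation (rotations ≤ 7°,
translations ≤ 5 %, brightness ± 10 %) is off by default; horizontal
flips are disabled because they would swap anatomical laterality.

## Attention module

Channel attention is a squeeze-and-excitation gate: global average
pooling, a bottleneck MLP of width max(1, ⌊C/r⌋) (so small test backbones
with C < r remain valid), and a sigmoid. An inner rectifier is applied
between the two linear maps — without it the two maps collapse to one
linear map — and the MLP carries bias vectors initialised (and defaulting)
to zero, so the zero-parameter gate is exactly ½ everywhere. Channel
attention pools by average only, not an average/max pair.

Spatial attention stacks the per-position channel mean and channel max of
the (channel-refined) map into a 2-channel descriptor and applies a
single 7×7 convolution with SAME zero padding and a scalar bias
(initialised 0), followed by a sigmoid, giving an H×W gate.

Compositions: `none`, `ca`, `sa`, `sequential` (the default: the spatial
gate is computed from the channel-refined map) and `parallel`. The
parallel fusion rule is this package's convention: both gates are
computed from the raw input map and applied as a joint broadcast product
A_c[c]·A_s[h,w]·F[h,w,c]. Every gate value lies strictly in (0, 1), so
refinement never amplifies a feature. The vectorised implementation is
tested to 1e-6 against a loop-based scalar reference on small tensors,
and all layer gradients are verified against central finite differences.

## Classifier and training protocol

Architecture: backbone → deepest feature map → attention → global average
pooling → fully connected → softmax. Global average pooling is the
package's choice of head; argmax ties break toward the lower category.
Two backbones are provided, both hand-written NumPy CNNs sized for CPU
training: `tiny` (three stride-2 3×3 blocks, C = 32 — the default for
every desk-scale experiment) and `deep` (five blocks, C = 64). No
pretrained weights ship with the package; weights can be loaded from file
after construction. Six independent models are trained, one per zone.

Optimisation: Adam on categorical cross-entropy; learning rate reduced by
factor 0.2 when validation loss fails to improve for 10 epochs ("weight
decay factor 0.2, patience 10" is read as a reduce-on-plateau schedule —
an Adam weight decay of 0.2 would be implausibly large); early stopping
after 10 non-improving epochs; the best-validation-loss weights are
restored. Defaults (learning rate 1e-4, batch 4, ≤ 100 epochs, 5 folds)
mirror the full-scale protocol; the from-scratch tiny backbone in the
examples and tests uses 1e-3, the standard rate for a small CNN trained
from random initialisation. Reducing the plateau patience below the
protocol's 10 proved counter-productive at desk scale: the schedule can
collapse the learning rate before training escapes its initial plateau.

Cross-validation folds are assigned at image level, stratified on the
image label, so the six zone samples of an image always share a fold and
train/validation image ids are disjoint across all zones simultaneously.
Optional inverse-frequency class weighting of the loss is off by default.

## Evaluation

From the K×K confusion matrix (rows true, columns predicted), one-vs-rest
counts per class k are TP = cm[k,k], FN = row − TP, FP = col − TP,
TN = N − TP − FN − FP, and

ACC_k = (TP+TN)/N, SEN_k = TP/(TP+FN), SPE_k = TN/(TN+FP),
F1_k = 2TP/(2TP+FP+FN).

Reported values are support-weighted means. Two conventions follow from
this: support-weighted SEN equals the plain multiclass accuracy trace/N
(an algebraic identity, property-tested on random matrices), and for
binary problems the one-vs-rest accuracies of both classes coincide, so
binary ACC and SEN columns are identical while multiclass reported ACC —
the weighted mean of one-vs-rest accuracies — exceeds SEN. 0/0 ratios are
defined as 0 and zero-support classes get weight 0, both logged. AUC is
the support-weighted mean of one-vs-rest areas computed by the tie-aware
rank (Mann–Whitney) statistic, equivalent to a threshold sweep over all
distinct scores (cross-checked against scikit-learn).

Image level: the predicted image category is the maximum of the six
predicted zone categories; binary detection is category ≥ 1 ⇒ positive,
derived from the multiclass label. The image-level probability vector
used only for AUC is the per-class maximum over the six zone probability
vectors renormalised to the simplex — a convention mirroring the label
rule, since no aggregation of probabilities is otherwise defined. Fold
dispersion is reported as mean ± standard deviation expressed in percent.

## Synthetic data

The generator emulates exactly the structure the classifier assumes. A
two-lobed mask is drawn with a smooth per-lobe width profile (narrow
apex, wide mid-lung), jittered apex/dome rows, centres and widths; lobes
never cross the mid-line, so the mask always has two 4-connected
components with a ≥ 4-column gap. The background is low-amplitude
smoothed noise; the aerated lung interior is slightly darker. Each zone
draws a category from `category_weights` and receives a uniform count of
isotropic Gaussian bright blobs from the category's range — defaults
cat-0 [0,0], cat-1 [3,6], cat-2 [9,15], cat-3 [20,35], disjoint and
increasing so the Bayes accuracy of the task is high and a working
classifier is clearly distinguishable from a broken one. Blob centres
fall only on lung pixels of that zone and the bumps are masked to the
lung. The image label is the maximum zone label by construction. Output
is 8-bit PNG by default (16-bit selectable). One master seed drives a
per-image substream (`SeedSequence((seed, index))`), so datasets are
byte-identical across runs and any subset is reproducible.

Default conditions: 128×128 images, 200 images, balanced per-zone
category weights (0.25 each) — the four-category zone task then has a
0.25 chance floor. A consequence of per-zone sampling is that the
image-level label, a maximum of six draws, concentrates at category 3
under balanced zone weights; the pipeline demos therefore use zone
weights skewed toward category 0 (0.80/0.10/0.06/0.04), which yields an
approximately balanced image-label mix and makes image-level stratified
folds feasible at small n. The learning-signal checks use a fixed
image-level 75/25 split on the balanced-zone dataset instead of
stratified image-level folds. The ILO standard defines category
boundaries against reference images, not blob counts; the synthetic
ranges are a controllable stand-in, not a calibration claim.

What passing on synthetic data shows — and what it does not: the
geometry, preprocessing, training loop, aggregation and metrics are
exercised end-to-end, and the planted profusion signal is recoverable far
above chance. The generator has no ribs, heart shadow, clavicles,
exposure artifacts, co-morbid opacities or inter-observer label noise, so
results here say nothing about accuracy on real radiographs, and the
published full-scale accuracies (obtained with GPU-scale pretrained
backbones on private data) are deliberately out of scope.

## Problem sizes

Desk-scale defaults keep every check on one CPU: 96–128 px images, zone
crops resized to height 32–48, the tiny backbone (≈ 6.6 k parameters with
sequential attention), batches of 4, and ≤ 40 epochs. The learning-signal
check trains 6 zones × 3 seeds × 2 variants on the 200-image dataset;
the pipeline smoke runs 20–24 images with 2 folds.

## Known limitations

- The backbone is deliberately small; no pretrained ImageNet backbone is
  bundled, so absolute synthetic-task accuracy is not comparable to
  published full-scale numbers.
- The parallel attention fusion and the image-level probability
  aggregation are package conventions (documented above), not uniquely
  determined by the zone-classification design.
- Histogram matching assumes single-channel grayscale inputs.
- The augmentation recipe is a placeholder and off by default.
- AUC confidence intervals (DeLong, bootstrap) and calibration analysis
  are not provided.
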
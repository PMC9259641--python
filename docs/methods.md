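# Methods

## Scope and design

`weakseg` studies how well a convolutional segmentation network trained on
*weak* (systematically erroneous) labels recovers the true event structure of
two-channel HTS autophagy imagery. Because pixel-perfect ground truth cannot
be obtained for real screens, every quantitative claim in this package is
made on a synthetic benchmark with known truth; the components are, in data
flow order: simulator → weak labeler / corruption model → U-net trainer →
evaluation suite → experiment orchestration.

## Synthetic image model

Each field is rendered at a configurable size (the desk default is 256×256;
a `full_scale_config()` preset reproduces the 680×512 geometry of real
plates). Per image the two vesicle classes are drawn with Poisson counts and
Gaussian radii:

| parameter | phagophore | autolysosome | unit |
|---|---|---|---|
| expected count (256×256) | 39 | 16.5 | events/image |
| radius | 3.5 ± 0.7 | 5.5 ± 1.0 | px |
| red peak intensity | 0.70 | 0.85 | fraction of full scale |
| green peak intensity | 0.80 | 0.10 | fraction of full scale |

The colour logic encodes the dual-fluorophore biosensor: the green
(pH-sensitive) fluorophore is quenched in acidic autolysosomes, so they are
red-only, while neutral phagophores are bright in both channels; config
validation enforces `green ≥ 0.8·red` for phagophores and `green ≤ 0.2·red`
for autolysosomes. Autolysosomes are larger on average, and the constructor
rejects configurations that violate that ordering.

Vesicles are uniform disks composited by maximum intensity; the clean label
mask is painted in a seeded random draw order, later disks overwriting
earlier ones where they overlap. The optical chain is a Gaussian PSF
(σ = 1 px), Poisson shot noise (scale 400 photons per full-scale intensity)
and Gaussian read noise (σ = 0.01). Faint unlabelled clutter blobs
(2×10⁻⁴ per pixel) emulate out-of-focus debris that a labeler must reject.

The count/radius defaults were calibrated once so that the pooled pixel
frequencies of a 50-image desk dataset match the strong class imbalance of
real screens — background/phagophore/autolysosome ≈ 0.95/0.023/0.024; with
seed 1 the generator measures 0.954/0.0234/0.0227 (each within 6% relative
of its target). Counts scale with pixel area in the presets so the
frequencies are size-invariant. Event *size and count distributions are
modelling choices*, not measured properties: only the frequency targets, the
colour logic and the size ordering are constrained by the screen being
emulated.

Reproducibility: every image gets an independent child generator spawned
from the dataset seed, so datasets are bit-identical across runs and
individual fields do not depend on how many precede them.

### What the simulator does not model

No optics-accurate PSF, no flat-field or vignetting artefacts, no cell
context (vesicles are not clustered inside cell boundaries), no chromatic
offset between channels, and none of the two rare intermediate vesicle
classes (below 0.1% pixel frequency in real screens, and discarded there
too). Passing results on this benchmark therefore demonstrate the *logic*
of the bootstrapping workflow — detectability of events by colour and
scale, and robustness of training to controlled label corruption — not
performance on any particular microscope's data.

## Weak labeler (CIP)

The conventional-image-processing labeler is a standard spot-segmentation
chain: difference of Gaussians (σ 1 and 6 px, negative response clipped) →
white top-hat (radius 8 px) → threshold (Otsu by default; a near-constant
response short-circuits to "no events") → discard components under
6 px² → optional watershed split on the distance transform → per-component
classification by the ratio of mean green to mean red intensity with cutoff
`ratio_tau = 0.5`, the midpoint between the two simulated colour regimes.
Detection runs on the pixelwise maximum of the two channels so red-only
autolysosomes are found. Components use 8-connectivity throughout the
package.

This labeler is a re-engineering from the standard operator vocabulary of
such pipelines; it deliberately omits deconvolution, Butterworth and
flat-field steps, which correct optical artefacts the simulator does not
produce. On clean synthetic fields it is consequently *more* accurate than a
production pipeline on real data. The controlled corruption model exists for
exactly this reason: experiments about label noise inject the three
systematic error types directly —

- **missed detection**: with probability `p_miss` an event is deleted;
- **misclassification**: otherwise, with probability `p_swap` its class is
  flipped;
- **incomplete segmentation**: otherwise `erosion_fraction` of its area is
  peeled from the boundary inward (distance-transform ranked, never below
  1 px).

The three are mutually exclusive per event so each error's effect stays
attributable. Corruption never invents events. Each mask in a list gets an
independent child seed.

## Network and training

The segmenter is a symmetric encoder–decoder with 3 pooling stages and one
skip connection per stage. Each stage is two (3×3 conv → batch norm → ReLU)
blocks; widths start at `base_filters` and double per stage; the decoder
upsamples by nearest-neighbour and concatenates the matching encoder map; a
1×1 convolution and per-pixel softmax give class probabilities. The exact
channel widths of such networks are a free choice; the full-scale default is
`base_filters = 16`, and the desk preset (`desk_unet_spec()`) halves it to 8,
which one CPU trains on 128×128 crops in minutes. The implementation is a
self-contained NumPy core (im2col convolutions over BLAS matmul, explicit
backprop); its gradients are verified against finite differences in the
test suite.

The loss is the generalized dice loss with squared inverse class-volume
weights, `w_l = 1/(Σ_n r_ln + ε)²`, ε = 1e-7 in both the weights and the
denominator so batches with an absent class stay finite. Weights are
computed per mini-batch. Loss is 0 for a perfect one-hot prediction and 1
when all probability mass is on wrong classes.

Optimisation is SGD with momentum 0.9, L2 regularisation 0.001 on
convolution weights (not biases or batch-norm parameters), initial learning
rate 0.002 for the weak-label (CDL) regime and 0.001 for the curated (MDL)
regime, dropped by a factor 0.8 every 3 epochs, mini-batches of 4, 15
epochs from scratch — the schedule appropriate for full-scale runs of order
10⁵ updates. Desk-scale runs of a few hundred updates sit in a different
step-size regime; `desk_train_config()` keeps the relative schedule and
raises the initial rate to 0.2 with 10 epochs, where the desk-scale training
loss plateaus. Early stopping is not implemented; the per-epoch training and
validation losses are logged instead.

Preprocessing is per-image, per-channel min–max normalisation to [0, 1]
(a constant channel maps to zero). Augmentation applies an identical random
reflection (each axis with probability ½) and rotation to image and mask;
rotations are restricted to multiples of 90° so label masks never need
interpolation. The train/validation/test split shuffles ids with a seed and
floors the validation and test sizes, assigning the remainder to training
(4000 ids at 0.85/0.10/0.05 → 3400/400/200); the CDL regime splits
0.85/0.10/0.05, the MDL regime 0.80/0.10/0.10.

Inference pads inputs by reflection to a multiple of 2^depth and crops the
output back, so any image size is accepted.

## Evaluation

**Pixel metrics.** Confusion matrices count pixels with rows = predicted
class, columns = actual class; the row-normalised variant leaves all-zero
rows at zero. One-vs-rest per class: precision TP/(TP+FP), recall
TP/(TP+FN), specificity TN/(TN+FP), IoU TP/(TP+FP+FN). Per-class
*accuracy* is TP/(TP+FN) — the per-class segmentation-accuracy convention,
equal to the diagonal of the column-normalised confusion matrix. An
alternative formula TP/(TP+TN) that circulates in some metric tables is
exposed as `accuracy_as_printed` for transparency but is neither standard
accuracy nor recall and is never aggregated. 0/0 ratios are NaN and are
excluded from Mean aggregation rather than zero-filled.

Aggregations: *Global* accuracy pools all pixels; *Mean* scores pool pixels
per class across images first, then average over classes (the
per-image-then-class alternative is available via `per_image_mean=True`);
*Weighted* IoU weights each class's pooled IoU by its share of actual
pixels. Under strong class imbalance the Mean and per-class numbers are the
informative ones; Global accuracy is dominated by background.

**Boundary F1.** Class-region boundaries (inner boundary pixels); a
boundary pixel matches if a boundary pixel of the other mask lies within a
Euclidean tolerance, default ceil(0.75% of the image diagonal); BFS is the
harmonic mean of boundary precision and recall. Empty vs empty boundaries
score 1, empty vs non-empty 0.

**Detection surrogate.** Tight axis-aligned boxes (0-based, half-open) are
extracted per 8-connected component per class. Matching is one-to-one
greedy by descending IoU with candidate threshold 0.1 (removing chance
overlap); greedy prevents one box from being counted against several
references, and ties break deterministically by index. The report gives,
per class: false-positive ratio (unmatched method boxes / method boxes),
false-negative ratio (unmatched reference boxes / reference boxes), match
counts in a lower [0.1, 0.5) and higher [0.5, 1.0] IoU bin (an exactly-0.49
overlap falls in the lower bin, 0.50 in the higher), and the detection
overlap percentage (matched reference boxes / reference boxes × 100). Zero
denominators report ratio 0 with an explicit `undefined` flag.

**Rating statistics.** The two-sample Kolmogorov–Smirnov statistic
D = sup|ECDF_a − ECDF_b| is computed exactly over the pooled sample points;
the p-value uses the asymptotic Kolmogorov distribution at
√(mn/(m+n))·D. The exact small-sample p-value is not implemented; for the
score-list sizes this analysis targets the asymptotic value is adequate,
and the D statistic itself is the reported effect size.

## Experiments

`run_cdl` chains simulate → weak labels → split → train → predict →
evaluate, reporting both the network's test-set metrics and the weak
labels' own metrics against clean truth on the same images. Weak labels
come either from the CIP labeler (realistic route) or from the corruption
model applied to ground truth (controlled route). The controlled route is
the default for quantitative noise experiments, because the re-engineered
CIP lacks its real-world failure modes on synthetic data and would make the
"weak" labels nearly perfect; the corruption model reproduces the error
*types* at measured, dialled rates. For the three-method comparison the
corrupted labels likewise stand in for the weak labeler's output, so "CIP"
in that ordering means "the weak labelling the network was bootstrapped
from".

`run_mdl` trains on a small curated subset of the training pool (clean
ground-truth masks standing in for expert-corrected annotations; PNGs in a
`corrected/` directory override them by filename, replacing an interactive
correction GUI with a scriptable file convention). All stage seeds derive
from one master seed by fixed offsets, so the non-training stages are
bit-reproducible and every report carries the config hash and seeds as
provenance.

## Problem sizes used by the shipped analyses

The acceptance script's generalisation experiment uses 240 fields of
128×128 at the calibrated event density (expected counts scale with area),
corruption rates p_miss = 0.3, p_swap = 0.15, erosion = 0.3, a 200/40
sequential train/test split, and the desk U-net (base 8) for 10 epochs.
With seed 1 this measures weak-label mean IoU ≈ 0.58 against clean truth
and network mean IoU ≈ 0.73, a relative improvement of ≈ +26%. The test
suite runs a smaller replica (100 fields at 96×96, 6 epochs) plus a curated
(MDL) run on the same split to check the method ordering weak-labels <
{CDL, MDL}.

## Known limitations

- The NumPy core is single-threaded except for BLAS matmul; it is a desk
  instrument, not a production trainer, and supports only the layers the
  architecture needs.
- Batch normalisation uses running statistics at inference; two training
  runs are bit-identical under a fixed seed, but loss curves are sensitive
  to BLAS library versions at the last few ulps.
- The greedy box matching is a ½-approximation of the optimal one-to-one
  assignment in total IoU; the test suite checks it exactly against a
  step-wise exhaustive oracle and against the optimal assignment's bound.
- Watershed splitting of touching vesicles uses a fixed minimum peak
  distance (3 px); heavily overlapping events of the same class may remain
  merged, which is visible in the detection FP/FN ratios on dense fields.
- The KS p-value is asymptotic (see above).
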
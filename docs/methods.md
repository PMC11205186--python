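# Methods

`cellstates` classifies the state of individual adherent cells — mitosis,
apoptosis, interphase, necrosis, senescence, or a discarded multiplet —
directly from grayscale phase-contrast (or bright-field) micrographs, with no
stains or fluorescence channels. It has three parts: a classical
image-processing pipeline that finds cells and cuts standardized 100×100
single-cell crops; a small convolutional network that classifies each crop;
and a phantom generator that produces labeled synthetic fields and crops so
the whole system can be built, trained, and scored without microscopy data.

## Segmentation and cropping

Input frames are 16-bit grayscale at a nominal 20× magnification; 10× frames
are first upscaled 2× (bilinear) to the reference scale. The pipeline is:

1. **Contrast stretch.** Linear rescale mapping the 1st/99th intensity
   percentiles onto the full 16-bit range (clip percentage configurable).
   Constant frames pass through with a warning.
2. **Adaptive filter.** A 5×5 local Wiener filter (`scipy.signal.wiener`),
   with the noise power estimated as the mean of the local variances. This
   suppresses the noise amplified by the contrast stretch while preserving
   cell boundaries.
3. **Dilation + binarization + hole fill.** The threshold is computed by Otsu
   on the *absolute deviation from the median background*, after a grayscale
   dilation with a radius-2 disk. Cells in phase contrast deviate from the
   mid-gray background in both directions — bright rims and halos, dark
   flattened bodies — so thresholding the deviation image is stable where a
   raw-intensity Otsu is bistable (with dark and bright cells in one frame
   the raw histogram is trimodal, and the two candidate splits have nearly
   equal between-class variance; the chosen one flips with the noise
   realization). The dilation closes 1–2 px gaps in cell rims so the fill
   produces one solid component per cell. A noise-floor guard declares the
   frame empty when the Otsu threshold does not clear 4 robust standard
   deviations (1.4826·MAD) of the background, which keeps pure-noise frames
   from binarizing into speckle.
4. **Debris cuts and erosion.** Components smaller than 30×30 px (900 px²)
   are removed as debris before erosion. A radius-3 disk erosion then
   separates touching objects and shrinks rims; components below 2000 px²
   after erosion are likewise removed. Both thresholds are configurable; the
   pre-/post-erosion split reflects that the two cuts target different
   artifacts (speckle debris vs. thin bridges and rim remnants).
5. **Duplicate suppression.** Among detections whose centroids lie within 30
   px, only the largest-area one is kept (ties broken by (row, col) order);
   the others are marked `duplicate_merged`.
6. **Centroid cropping.** A half-open `crop_size`×`crop_size` window (default
   100×100) is cut from the *original* pixels around the rounded centroid
   (round-half-up). Windows that would leave the frame mark the detection
   `edge_rejected`; no partial crops are emitted.

Every detected object ends in exactly one terminal status — `kept`,
`edge_rejected`, `duplicate_merged`, or `debris_removed` — so detection
counts are conserved across the pipeline and sample-loss accounting is exact.

Structuring-element radii (2 for dilation, 3 for erosion) were chosen so that
a 1–2 px broken rim closes while a 1 px bridge between touching cells opens;
both are parameters of `SegmentationParams`.

## Classifier

The network is seven convolution–batch-norm–ReLU blocks with 3×3 same-padded
kernels: three blocks of 64 filters, then four of 128, with 2×2/stride-2
max-pooling after blocks 1–4 (100 → 50 → 25 → 12 → 6), one fully connected
layer to 6 logits, and a softmax. Pooling early keeps the wide 64-channel
convolutions on small maps, which makes single-CPU training practical without
changing the final 6×6×128 feature map; the pool positions are configurable.
Inputs are divided by 65535 into [0, 1] so training is camera-bit-scale
invariant. Argmax ties break toward the lowest class index, for determinism.

The engine (`cellstates.nn`) is a compact numpy implementation: convolutions
are evaluated as one im2col GEMM per pass, elementwise stages run in place,
and each layer owns persistent workspace buffers backed by growable flat
arrays (first-touch page faults on fresh multi-hundred-MB temporaries
otherwise dominate single-CPU step time). Max-pool backward routes gradients
to every window entry equal to the maximum; exact float ties after batch
normalization are vanishingly rare, and tied zeros are masked by the
preceding ReLU's backward pass.

## Training recipe

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at an initial learning rate of 0.01,
dropping by a factor of 0.1 every 10 epochs; at most 20 epochs; mini-batches
of 128 with the final partial batch kept; shuffling every epoch; L2 penalty
0.005·Σw² on convolution and dense weights (gradient 2·0.005·w); an 80/20
stratified train/validation split; validation every 50 mini-batches and at
every epoch end; early stopping when the epoch-end validation loss has not
improved for 5 consecutive epochs. Weights use seeded He (variance-scaling)
initialisation. Cross-entropy is the data loss (implied by the softmax
output).

Two choices deserve comment, both driven by the small number of mini-batches
per epoch (about 8 at 200 crops per class):

* **Batch-norm statistics.** Running averages with conventional momentum
  would stay stale for many epochs, so inference statistics are *population*
  statistics: at each epoch end (and for the final model) the training set is
  passed through once more, in class-interleaved batches, and per-channel
  means/variances are pooled by the law of total variance. Monitored
  validation metrics, the early-stopping decision, and final inference
  therefore share identical semantics. Mid-epoch validations use the cheaper
  running statistics (momentum 0.6) and are logged but not used for patience.
* **Returned model.** At learning rate 0.01 the optimization oscillates;
  training returns the weights of the best-validation-loss epoch rather than
  the last epoch, snapshotted together with that epoch's population
  statistics.

## Metrics

Accuracy = correctly categorized images / all scored images; sensitivity =
the same restricted to one true category. True multiplets ("discarded") and
edge-rejected detections are excluded from numerators and denominators
alike; excluding the discarded class removes both its row and its column of
the confusion matrix. When nothing is excluded, accuracy equals the
class-size-weighted mean of sensitivities (tested as an identity).

Segmentation is scored against phantom ground truth by greedy one-to-one
centroid matching within 25 px (half the default crop radius; configurable),
reporting recall, precision, and a Wilson 95% interval on the recall.

The crop-size sweep re-runs detection and cropping at several window sizes
and reports, per size, classification accuracy over ground-truth-matched
kept crops (crops are bilinearly rescaled to the network input size when
they differ) and

    sample_loss = (edge_rejected + duplicate_merged + predicted_discarded)
                  / total detections,

the fraction of detected objects that never reach a scored classification.
Because a larger window centered on the same centroid can only hit the frame
border more often, the geometric part of the loss is monotone in crop size.

## Phantom generator

The generator emulates sparse adherent cells on a mid-gray phase-contrast
background (level 28000 of 65535, additive Gaussian noise σ = 350). Every
cell is an ellipse with a bright rim — the optical boundary of an adherent
cell reads brighter than the background in phase contrast — plus
class-specific morphology:

| class      | major axis (px) | axis ratio  | rim      | interior | extras |
|------------|-----------------|-------------|----------|----------|--------|
| mitosis    | 60–70           | 0.88–1.0    | +14000   | +3500    | strong rim, near-circular |
| apoptosis  | 58–66           | 0.85–1.0    | +8000    | −2000    | 3–6 bright peripheral blebs |
| interphase | 80–92           | 0.5–0.7     | +9000    | −3500    | oblong, clear boundary |
| necrosis   | 96–112          | 0.75–0.95   | +5500    | −1500    | swollen, faint rim |
| senescence | 120–140         | 0.7–0.9     | +5000    | −6500    | very large, flat and dark |

"Discarded" training examples are two touching interphase-like cells whose
centroid distance is below the sum of their semi-minor axes. Mean mask areas
order senescence > necrosis > interphase > apoptosis (a tested property).

The pixel scale is anchored to the segmentation stage's own thresholds: the
smallest class (apoptosis) must still exceed the 2000 px² post-erosion
minimum object area, which puts apoptotic bodies near 60 px across and the
other classes proportionally larger at the simulated 20×; senescent cells
deliberately overflow the 100×100 crop, as very large flattened cells do at
this magnification. Field placement keeps non-multiplet cells separated far
enough that the dilation stage cannot bridge their rims, and keeps centroids
at least `margin` (default 65) px from the border, emulating the
low-confluence culture condition the method expects. All sizes, intensities,
noise, density and margins are configurable; every stochastic choice draws
from a single seeded generator, and the seed is recorded in the ground-truth
manifest.

**What the phantoms do not model:** halo/shade-off optics, uneven
illumination, focus drift, texture inside cells, debris with cell-like
sizes, and the continuum of intermediate morphologies (e.g. early
senescence resembling interphase) that makes real data hard. Passing the
phantom-based checks demonstrates that the pipeline and training recipe are
implemented correctly and can learn genuinely class-separable morphology; it
does not certify accuracy on real micrographs.

## Numerical and design notes

* All image intensities are processed in float64 inside the segmentation
  stages and rounded back to uint16 only for stored crops and fields; the
  network trains in float32.
* Coordinates are 0-based (row, col) with the origin at the top-left; crop
  windows are half-open.
* The duplicate-suppression radius (30 px) equals the debris cut side; the
  largest-area detection wins deterministically.
* The label-permutation control re-trains the network on a corpus whose
  labels were randomly permuted; its held-out accuracy estimates the chance
  level (1/6). The control uses a 50/50 split: with the corpus sizes used
  here the wider held-out set roughly halves the binomial noise of that
  estimate, and the training half remains large enough to overfit if any
  leakage existed. It is capped at 10 epochs — with random labels the
  validation loss is a random walk, so patience rarely fires, and any
  genuine leakage would surface well before then.
* Per-stage seeds are forked from one master seed through
  `RunConfig.child_seed` (CRC-32 of the stage name as a spawn key), so the
  order in which stages execute cannot perturb one another's streams.
* Default problem sizes in tests and the acceptance script — 50 fields of
  ~20 cells for segmentation scoring, 200 crops per class for training, 6
  fields for the crop-size sweep — were chosen as the smallest sizes at
  which the measured quantities are stable; all are parameters.

## Known limitations

* The classifier is only as good as the morphology contrast in the training
  corpus; phantoms are strongly separable by construction.
* A single global threshold cannot rescue frames with strong illumination
  gradients; no background-field correction is implemented.
* Time-lapse tracking, watershed splitting of dense clumps, and color
  bright-field handling are out of scope.
* At learning rate 0.01 individual epochs can transiently diverge; the
  best-epoch snapshot makes the returned model robust to this, but training
  curves are not monotone.
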
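# Methods

## The problem and the model

Segmenting the knee bones (femur, tibia, patella) is the anchoring step
for downstream analysis of osteoarthritis MRI: cartilage, bone marrow
lesions and menisci are delineated relative to the bone surfaces. A 3D
knee scan arrives as an ordered stack of 2D slices (160 per scan at
384×384 px for the DESS sequences this package targets); each bone
appears only on a contiguous sub-interval of the stack, and those
intervals differ between compartments and between knees.

The pipeline is two networks in sequence:

1. **Slice-presence detection.** A U-net variant maps each slice
   (downsampled to 128×128) to a per-pixel bone probability map. A
   slice counts as bone-bearing when at least `min_area` pixels
   (default 1) reach `prob_threshold` (default 0.5); an all-black
   output map means "no bone". This per-pixel reading, rather than a
   scalar classification head, is what makes a true negative
   well-defined as "both ground truth and output are pure black", and
   it lets detection and segmentation share one architecture.
2. **Segmentation.** The same architecture at full cropped resolution
   (352×352) segments the slices that survive detection; rejected
   slices carry empty masks by construction (pipeline causality).
   Either one whole-knee model or three per-compartment models can be
   used; per-compartment predictions combine into a whole-knee mask by
   voxelwise union, with an optional label map resolving overlaps by
   model probability (ties broken femur > tibia > patella, a fixed
   arbitrary order).

**Architecture.** Depth-5 encoder/decoder. Encoder level ℓ ∈ {0..3}:
two same-padded 3×3 convolutions + ReLU at width 64·2^ℓ, then 2×2
max-pool. Bottleneck: two 3×3 convolutions at width 1024. Decoder
level: 2×2 stride-2 transposed convolution halving the width,
concatenation with the encoder skip (skip first, upsampled second —
either order carries the same parameter count; one is fixed for
determinism), two 3×3 convolutions. Head: 1×1 convolution to one
channel, sigmoid. Same padding keeps output size equal to input size.
There is no batch normalization and no dropout, and upsampling is a
learned transposed convolution — both are forced by the parameter
accounting: with 3×3 conv = 9·Cin·Cout+Cout, transposed 2×2 conv =
4·Cin·Cout+Cout and 1×1 head = Cin·Cout+Cout, the 23 weight-bearing
layers sum to exactly 31,030,593 parameters at the reference
configuration, and `count_parameters` must (and does, by test) equal
enumeration over the instantiated network.

**Losses.** Detection: per-pixel binary cross-entropy with predictions
clipped to [1e-7, 1−1e-7]. Segmentation: soft Dice
L = −(2Σpg+ε)/(Σp+Σg+ε) with ε = 1 during training (the usual
smoothing; makes empty/empty perfect and the loss differentiable
everywhere). On binary predictions the loss converges to −Dice as
ε→0, which is property-tested against the metrics module.

**Optimization.** Adam (β₁ 0.9, β₂ 0.999, ε 1e-8 — the framework
defaults; the source of the method is silent on moments), learning
rate 1e-5, batch 16, at most 300 epochs, early stopping with patience
35 (midpoint of the stated 30–40 range) on the validation metric:
case-pooled Dice of thresholded predictions for segmentation,
per-slice presence accuracy for detection. On stop, the best epoch's
weights are restored (the standard Keras-style behaviour; keeping the
last weights is the other defensible reading). Weights initialize
He-uniform with zero biases, seeded. No data augmentation.

## Numpy network engine

No deep-learning framework is part of the dependency set; the
convolution/pooling/transposed-convolution layers, backpropagation and
Adam are implemented directly on numpy arrays (`kneeseg.nn`), float32
by default with a float64 mode for gradient checking. Convolutions run
as im2col windows contracted with `tensordot` (BLAS); the input
gradient of a same-padded correlation is computed as another
same-padded correlation with the flipped, channel-transposed kernel.
Analytic gradients are tested against central finite differences; the
test perturbs parameters off zero first because zero-initialized
biases put pre-activations exactly on the ReLU kink, where only a
subgradient exists and finite differences legitimately disagree (the
same applies to max-pool ties, hence the distributional tolerance in
that test).

## Evaluation

Segmentation is scored **per case, in 3D**: Sg and Sm are pooled over
all slices of the scan before any ratio is formed, so large and small
slices weigh by their pixel counts within a case, and cases average
unweighted across the test set. Dice and Jaccard obey D = 2J/(1+J)
exactly; FNR = 1−TPR exactly; both identities are property-tested
against brute-force voxel-set arithmetic. Degenerate denominators
yield `None` sentinels rather than exceptions; the empty-ground-truth /
empty-prediction case scores Dice = SI = 1 by convention and is
flagged — it never arises in the intended flow because detection
removes bone-free slices before segmentation is scored.

Bone volume is voxel count × voxel volume; voxel spacing is taken from
the input metadata and defaults to 1 mm³ (the DESS voxel size is not
hard-coded because it is not part of the package's inputs). Agreement
between manual and automatic volumes is an OLS fit of predicted on
true volume plus squared Pearson correlation. Pipeline variants
(automatic vs. manual slice selection; one whole-knee model vs. three
combined models) are compared with a **paired** two-tailed t-test on
per-case scores — paired because the same test cases are scored under
both conditions. Differences with zero variance (up to float rounding)
return a degenerate sentinel.

Preprocessing follows the data-preparation recipe: per-case min–max
normalization to [0,1] (per case, not per slice, to preserve
inter-slice intensity relations within a scan; constant cases map to
zero), 16-px border crop taking 384×384 to 352×352 (manual labels do
not reach the image border), bilinear resize for intensities /
nearest-neighbour for masks, and a case-level 70/15/15 split with
round-half-up sizes for validation and test (99 cases → 69/15/15,
i.e. 11,040/2,400/2,400 slices at 160 slices per case). Slice order is
DICOM InstanceNumber ascending, or the numeric part of the filename
for PNG stacks; slice indices are 0-based internally.

## The phantom generator

The phantom emulates exactly the structural assumptions the pipeline
exploits, and nothing else:

- each compartment occupies one contiguous slice interval whose
  endpoints are drawn per case from ranges centred on realistic
  anatomy (femur ≈ 22–134 of 160, tibia ≈ 30–136, patella ≈ 50–115,
  scaled proportionally for shorter stacks);
- per slice the compartment is a filled ellipse; its centre drifts
  sinusoidally inside a fixed, compartment-specific image region
  (femur upper half, tibia lower half, patella anterior strip), and
  its radii taper elliptically toward the interval ends with a floor
  of max(1.5 px, 3 % of image size) so every in-interval slice is
  non-empty — bones appear, swell and vanish like 3D bodies in
  cross-section;
- the fixed disjoint regions guarantee disjoint masks and
  whole = union exactly;
- intensity is bone 0.9 / background 0.2 with additive Gaussian noise
  (sd 0.05) clipped to [0,1]. The default contrast-to-noise ratio
  (0.7 vs. 3σ = 0.15) keeps the task threshold-separable: with zero
  noise a mid-intensity threshold reproduces the ground truth exactly,
  which provides an analytic oracle for every pipeline stage.

Randomness: one root seed; case i uses stream seed + i, so cases are
independent and individually reproducible.

What the phantom deliberately does **not** model: MRI physics (bias
fields, DESS contrast, partial volume), anatomical shape detail,
cartilage and soft tissue, inter-rater labelling noise. Passing the
phantom suite therefore demonstrates that the pipeline's machinery —
architecture, losses, training loop, gating, metrics — is correct and
recoverable end to end; it does not certify real-data accuracy, which
depends on data the package does not bundle.

## Desk-scale study conditions

The end-to-end acceptance experiment trains both networks from scratch
on one CPU: 30 phantom cases (20 train / 5 validation / 5 test) of 24
slices at 64×64, detection at 32×32, base width 8, depth 3, Adam at
1e-3, batch 16, ≤50 epochs with patience 8, seeds fixed. Base width 8
and the 20/5/5 split mirror the full method at 1/8 width; depth 3 and
24 slices keep a full run in minutes; the learning rate is the
standard Adam default because 1e-5 — tuned for an 11k-image, 300-epoch
budget — cannot move a small network within 50 epochs. Thresholds
(detection accuracy ≥ 0.95, mean case Dice ≥ 0.90, automatic-vs-manual
ablation gap < 0.05) sit deliberately below what the pipeline actually
achieves on phantoms (≈1.00 / ≈0.999) and qualitatively mirror the
finding that manual slice selection does not significantly beat the
automatic detector.

## Known limitations

- The numpy engine is single-threaded BLAS-bound; it trains the
  desk-scale models in minutes but is not meant for 31M-parameter
  full-scale training.
- The detection decision is purely areal (`min_area` pixels above
  threshold); no connected-component or morphology post-processing.
- The phantom's intensity model is two-level + Gaussian noise; methods
  that exploit texture would be untested by it.
- NIfTI axis conventions: volumes are stored (row, col, slice) with a
  diagonal affine built from the spacing; oblique affines are not
  interpreted.
- DICOM reading requires InstanceNumber; spatial sorting by position
  tags is not implemented.
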
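# Methods

## Model

`wsimil` classifies a slide from the bag of its patch embeddings with
gated-attention MIL. The shared backbone squeezes each embedding
z_k ∈ R^D to h_k = W₁z_k ∈ R^{H1}; two parallel layers V_a, U_a ∈
R^{H2×H1} feed a tanh/sigmoid gate whose element-wise product is scored by
one attention vector W_{a,i} ∈ R^{1×H2} per class. The default ("paper")
profile is D/H1/H2 = 1024/512/256; a proportional "small" profile
(16/8/4) mirrors every shape for fast CPU work. Attention weights are a
softmax over the patches of a slide, so the pooled representation
h_{slide,i} is a convex combination of the h_k and the architecture is
permutation-invariant at the slide level by construction.

Each class has its own slide classifier W_{c,i} ∈ R^{1×H1} acting on its
own pooled representation. (Some descriptions of this architecture print
the classifier as 1×256; that shape cannot multiply the 512-dimensional
pooled vector, so the classifier here is 1×H1.)

The instance-clustering heads W_{inst,i} ∈ R^{2×H1} act on the projected
instances. During training, the `k_sample` most-attended patches of the
**ground-truth** class get pseudo-label 1 and the `k_sample`
least-attended get pseudo-label 0 (ties break toward the lower index; the
two sets are forced disjoint; when a bag is smaller than `2·k_sample` the
count shrinks to ⌊K/2⌋ with a warning). Only the true class's head is
supervised per slide. The alternative — supervising all N heads, with
out-of-class bags contributing only negatives — is a legitimate reading of
the architecture; single-head supervision was chosen because it keeps the
auxiliary signal consistent with the attention that generated it.
Pseudo-label *selection* is treated as a constant during backpropagation;
gradients flow through the cluster scores (and hence W₁) but not through
the top-k choice itself.

## Losses

Slide-level: softmax cross-entropy. Instance-level: the smooth multi-class
SVM loss L_{1,τ}(s,y) = τ·logsumexp_j[(α·1[j≠y]+s_j−s_y)/τ], computed with
a shifted log-sum-exp so scores up to |s| ≈ 10⁴ cannot overflow. Its
gradient has the same softmax-minus-indicator form as cross-entropy. Three
identities anchor the implementation and are asserted in the tests: it
upper-bounds the hinge everywhere, converges to the hinge as τ→0, and
equals cross-entropy exactly at α=0, τ=1. The patch loss is the *mean*
over the 2·k_sample sampled instances so that changing `k_sample` does not
rescale the objective. Total: c₁·L_slide + c₂·L_patch.

Defaults α=1.0, τ=1.0, c₁=0.7, c₂=0.3, k_sample=8. The formulation does
not prescribe these; the chosen values follow common practice for
clustering-constrained attention MIL and are all exposed in `LossConfig`.

## Training protocol

One bag per optimization step; Adam with lr 2·10⁻⁴, weight decay 10⁻⁵
(classic L2, folded into the gradient), β₁=0.9, β₂=0.999, ε=10⁻⁸;
dropout p=0.25 after the backbone projection and after the gated product,
train mode only. Bags larger than 512 instances are randomly subsampled to
512 per training step — reconciling bag-at-a-time optimization with a
fixed patch batch size — while evaluation always uses every patch.
Early stopping monitors validation slide-level cross-entropy (the model
selection signal) while the optimizer minimizes the mixed objective; the
checkpoint with the smallest validation loss is kept, and training stops
after 20 validation epochs without improvement (`max_epochs` 200 as a
safety cap). Every source of randomness — shuffling, subsampling, dropout
— derives from per-epoch substreams of the config seed, so runs are
bit-reproducible and early stopping does not perturb the stream.

All forward/backward computation is NumPy; the backward pass is derived by
hand and checked against central finite differences (relative error
≤ 10⁻⁴ asserted; observed ~10⁻⁶ at ε=10⁻⁶, consistent with truncation
error of the central difference itself).

## Metrics

Accuracy, precision, sensitivity, specificity from the confusion matrix
with BRAF-positive as the positive class, plus mean SS = (sensitivity +
specificity)/2 — the balanced summary appropriate for an imbalanced cohort
(e.g. 82% positive slides, where an all-positive classifier scores
accuracy 0.82 but mean SS 0.50). A metric whose denominator is zero is
reported as NaN with a warning, never silently as 0.

## Slide pipeline

Foreground rule (unspecified by the formulation; standard practice for
Papanicolaou/H&E slides): HSV saturation channel, 5×5 median blur, Otsu
threshold, morphological closing (disk radius 2), hole filling, minimum
object area 64 px at the mask resolution. The mask is computed at an
integer downsample keeping it ≤ 4 Mpixels. A slide with near-constant
saturation (blank glass) yields an empty mask with a warning. Tiling is a
non-overlapping grid anchored at (0,0), patch size 256, keeping patches
with foreground fraction ≥ 0.5 by default; coordinates are 0-based,
level-0, half-open boxes, sorted row-major.

## Encoders

The encoder is a contract: any deterministic map from RGB patches to a
fixed-dimension float matrix. The bundled desk encoder (16×16 thumbnail →
seeded Gaussian projection → tanh, 1024-dim output, one matrix-vector
product per patch so results are bit-identical across batch sizes) exists
so the pipeline runs offline and deterministically; it is **not** a
trained feature extractor and its embeddings carry only coarse color/
intensity information. A pretrained deep trunk — e.g. a ResNet101 cut
after its 1024-channel stage, the only truncation consistent with a
1024-dimensional patch embedding — plugs into the same contract.

## Synthetic fixtures

`simulate_bags` draws instance embeddings from a two-component isotropic
Gaussian mixture: background ~ N(μ_bg·1, σ²I), signal ~ N(μ_sig·1, σ²I).
Exactly round(n_bags·prevalence) bags are positive (evenly spaced indices,
so truncating a split keeps both classes); a positive bag of size K holds
⌈witness_rate·K⌉ signal instances. Per-bag RNG substreams make datasets
grow without reshuffling earlier bags. Defaults: dim 1024 (matching the
encoder contract), bag sizes 30–120 for CPU-scale speed, prevalence 0.82
mirroring a strongly imbalanced clinical cohort.

This geometry is deliberately the simplest separable one — an isotropic
scalar mean shift — which makes attention recovery analytically
predictable. What passing tests show: the architecture, losses, gradients,
and protocol are implemented correctly and can localize minority signal
instances from bag labels alone. What they do not show: performance on
real cytology, where signal is a subtle morphological texture, the
encoder matters enormously, and witness instances are not i.i.d.

Toy slides paint saturated rectangles ("tissue", with an optional
redder "lesion" color in positive cohort slides) on bright gray
background with additive Gaussian noise; the ground-truth mask is exactly
the union of the rectangles.

## Study conditions and problem sizes

The parameter-recovery study uses witness rate 0.1, μ_sig−μ_bg = 3σ
(σ=1), dim 16 with the small model profile, 350 bags split 200 train /
50 validation / 100 test (prevalence 0.5), up to 60 epochs — sizes chosen
so a full recovery run completes in well under a minute on one CPU while
leaving the separation and witness rate firmly in the regime where
attention-based MIL should succeed. The end-to-end toy-cohort example
uses 40 slides of 512×512 px.

## Numerical choices and degenerate inputs

Softmaxes and log-sum-exps are max-shifted. Attention over a single-patch
bag is [1.0]; identical patches get uniform attention. Constant attention
rows normalize to 0.5 everywhere in heatmaps (with a warning) rather than
dividing by zero; min-max normalization is rank-preserving otherwise.
Features are stored float32; model arithmetic is float64. Checkpoints are
single `.npz` files with a JSON shape manifest and schema version.

## Known limitations

No pen-mark/artifact removal, stain normalization, or multi-scale tiling.
The desk encoder cannot express morphology, so real-slide performance is
bounded by whatever encoder is plugged in. Heads are supervised for the
true class only (see above). `stratified_split` rounds per class, so very
small cohorts can produce empty validation splits — the trainer rejects
these explicitly.
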
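# wsimil

Weakly supervised whole-slide-image (WSI) classification with
clustering-constrained attention multiple instance learning (MIL).

## The problem

Molecular markers such as the BRAF (V600E) mutation guide therapy in
papillary thyroid cancer, but confirming them requires immunohistochemistry
or sequencing. A classifier that predicts marker status directly from
routinely scanned cytology slides needs to learn from *slide-level* labels
only: a gigapixel slide is a bag of thousands of image patches, and no one
annotates which patches carry the signal. `wsimil` implements that
annotation-free pipeline end to end for researchers in computational
pathology: tissue segmentation and patch tiling, patch feature extraction
behind a pluggable encoder contract, a gated-attention MIL classifier with
an instance-clustering auxiliary objective, the training/evaluation
protocol, and attention heatmaps for interpretation — all exercisable on
synthetic fixtures with known ground truth.

## The model

Each patch embedding z_k ∈ R^1024 is projected to h_k = W_1 z_k ∈ R^512.
For class *i*, a gated attention branch scores every patch

    a_{i,k} = softmax_k [ W_{a,i} ( tanh(V_a h_k) ⊙ sigm(U_a h_k) ) ],

the slide representation is the attention-weighted pool
h_{slide,i} = Σ_k a_{i,k} h_k, and the slide score is
s_{slide,i} = W_{c,i} h_{slide,i}, softmaxed into class probabilities.
During training the most- and least-attended patches of the true class are
pseudo-labeled positive/negative and a per-class linear head
p_{i,k} = W_{inst,i} h_k is supervised with the smooth multi-class SVM loss

    L_{1,τ}(s, y) = τ log Σ_j exp[ (α·1[j≠y] + s_j − s_y)/τ ],

a temperature-smoothed hinge that upper-bounds the max-margin loss,
converges to it as τ→0, and reduces to cross-entropy at α=0, τ=1. The
total objective is L = c₁·L_slide + c₂·L_patch with cross-entropy slide
loss. Optimization is one bag per Adam step (lr 2·10⁻⁴, weight decay
10⁻⁵, dropout 0.25) with early stopping on validation loss (patience 20).

The model, its analytic gradients, and the optimizer are implemented in
NumPy; gradients are verified against central finite differences in the
test suite.

## Worked example

`examples/03_train_and_evaluate.py` trains on separable synthetic bags
(witness rate 0.1, 3σ mean separation, 200/50/100 split):

```
best epoch: 58  val loss: 0.0126
test accuracy: 1.000  mean SS: 1.000
confusion: tp=50 tn=50 fp=0 fn=0
attention-vs-signal AUROC (positive bags): 1.000
```

Accuracy 1.0 means every held-out slide label was recovered from bag-level
supervision alone; the attention AUROC of 1.0 means the attention ranks the
hidden signal patches above background in every positive test bag — the
model found the evidence without ever seeing an instance label. The other
examples cover bag simulation, segmentation/tiling (`mask IoU 1.0000`,
4/16 tiles kept for a centered 512×512 blob), and the full pipeline with a
heatmap overlay.

A thin CLI mirrors the stages:

```bash
wsimil simulate --n-bags 100 --out bags/
wsimil segment-tile --slide toy.tif --patch-size 256 --min-fg 0.5 --out tiles/
wsimil train --bags bags/ --profile small --out ckpt/
wsimil run --config run.yaml --out artifacts/
```

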
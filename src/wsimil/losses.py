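"""Classification losses: multi-class SVM hinge, its smooth variant, and the
combined slide/patch objective.

The instance-clustering heads are trained with a smoothed multi-class SVM
loss: the usual max-margin hinge

    l(s, y) = max{ max_{j != y} (s_j + alpha) - s_y, 0 }

is replaced by a temperature-scaled log-sum-exp

    L_{1,tau}(s, y) = tau * log sum_j exp[ (alpha * 1[j != y] + s_j - s_y) / tau ]

which is infinitely differentiable, upper-bounds the hinge, converges to it
as tau -> 0, and reduces exactly to cross-entropy at alpha = 0, tau = 1.
Slide-level classification uses plain softmax cross-entropy; the total
objective mixes the two with scalars c1 and c2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, softmax

__all__ = [
    "LossConfig",
    "svm_hinge",
    "svm_smooth",
    "svm_smooth_grad",
    "slide_loss",
    "slide_loss_grad",
    "patch_loss",
    "total_loss",
]


@dataclass
class LossConfig:
    """Margin, temperature, mixing weights and pseudo-label count.

    Defaults: alpha=1, tau=1, c1=0.7, c2=0.3, k_sample=8 — conventional
    values for clustering-constrained attention MIL; none is prescribed by
    the underlying formulation, and all are exposed here.
    """

    alpha: float = 1.0
    tau: float = 1.0
    c1: float = 0.7
    c2: float = 0.3
    k_sample: int = 8

    def validate(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("c1 and c2 must be non-negative")
        if self.k_sample < 1:
            raise ValueError("k_sample must be >= 1")


def _check_label(s: np.ndarray, y: int) -> np.ndarray:
    s = np.asarray(s, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("scores must cover at least 2 classes")
    if not 0 <= y < s.size:
        raise ValueError(f"label {y} out of range for {s.size} classes")
    return s


def svm_hinge(s, y: int, alpha: float = 1.0) -> float:
    """Multi-class SVM loss: hinge on the margin between y and the runner-up."""
    s = _check_label(s, y)
    others = np.delete(s, y)
    return float(max(np.max(others) + alpha - s[y], 0.0))


def svm_smooth(s, y: int, alpha: float = 1.0, tau: float = 1.0) -> float:
    """Smoothed multi-class SVM loss (stable log-sum-exp form).

    Strictly positive for finite tau: the j = y term contributes exp(0).
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    s = _check_label(s, y)
    m = s - s[y] + alpha * (np.arange(s.size) != y)
    return float(tau * logsumexp(m / tau))


def svm_smooth_grad(s, y: int, alpha: float = 1.0, tau: float = 1.0) -> np.ndarray:
    """Gradient of :func:`svm_smooth` w.r.t. the score vector.

    With q = softmax(m / tau) of the margin-augmented scores, the gradient
    is q except at the true class, where it is q_y - 1 — the same form as
    the cross-entropy gradient.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    s = _check_label(s, y)
    m = s - s[y] + alpha * (np.arange(s.size) != y)
    g = softmax(m / tau)
    g[y] -= 1.0
    return g


def slide_loss(s_slide, y: int) -> float:
    """Cross-entropy of softmax(s_slide) at the true slide label."""
    s = _check_label(s_slide, y)
    return float(logsumexp(s) - s[y])


def slide_loss_grad(s_slide, y: int) -> np.ndarray:
    s = _check_label(s_slide, y)
    g = softmax(s)
    g[y] -= 1.0
    return g


def patch_loss(p_rows, pseudo_labels, alpha: float = 1.0, tau: float = 1.0) -> float:
    """Mean binary smooth SVM loss over the sampled instances.

    ``p_rows`` holds one 2-class score row per sampled instance and
    ``pseudo_labels`` the matching 0/1 pseudo-cluster labels.  Averaging
    (rather than summing) keeps the objective scale independent of the
    pseudo-label count.
    """
    p_rows = np.atleast_2d(np.asarray(p_rows, dtype=float))
    labels = np.asarray(pseudo_labels, dtype=int).ravel()
    if p_rows.shape[0] == 0 or labels.size == 0:
        raise ValueError("patch_loss requires at least one sampled instance")
    if p_rows.shape[0] != labels.size:
        raise ValueError("score rows and pseudo labels must have equal counts")
    return float(np.mean([svm_smooth(r, int(t), alpha, tau) for r, t in zip(p_rows, labels)]))


def total_loss(slide_l: float, patch_l: float, c1: float = 0.7, c2: float = 0.3) -> float:
    """Weighted sum c1 * slide loss + c2 * patch loss."""
    if c1 < 0 or c2 < 0:
        raise ValueError("c1 and c2 must be non-negative")
    return float(c1 * slide_l + c2 * patch_l)
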
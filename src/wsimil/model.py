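"""Gated-attention MIL network with class-specific branches and
instance-clustering heads, in plain NumPy with analytic gradients.

Architecture, per bag of K patch embeddings z_k in R^D:

* shared backbone: h_k = W1 z_k  (D -> H1, default 1024 -> 512);
* gated attention: for class i, attention logit
  Wa_i ( tanh(Va h_k) ⊙ sigmoid(Ua h_k) ) with Ua, Va: H1 -> H2
  (default 512 -> 256); a_{i,·} = softmax over the K patches;
* attention pooling: h_slide,i = Σ_k a_{i,k} h_k;
* class-specific slide scores: s_slide,i = Wc_i · h_slide,i, softmaxed
  into class probabilities;
* instance clustering heads: p_{i,k} = Winst_i h_k in R^2, supervised by
  pseudo-cluster labels from the most- and least-attended patches.

Dropout (p = 0.25 by default) is applied after the shared backbone layer
and after the gated product during training only; evaluation is
deterministic.  :func:`bag_backward` returns the exact analytic gradient
of the mixed slide/patch objective, verified elsewhere against central
finite differences.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import softmax as _softmax

from .bags import FeatureBag
from .losses import LossConfig, patch_loss, slide_loss, slide_loss_grad, svm_smooth_grad, total_loss

__all__ = [
    "PROFILES",
    "ModelParams",
    "AttentionForward",
    "init_params",
    "project_instances",
    "attention_scores",
    "attention_pool",
    "slide_scores",
    "instance_cluster_scores",
    "assign_pseudo_labels",
    "forward",
    "bag_backward",
    "save_checkpoint",
    "load_checkpoint",
]

#: (input dim D, backbone dim H1, attention dim H2)
PROFILES: dict[str, tuple[int, int, int]] = {
    "paper": (1024, 512, 256),
    "small": (16, 8, 4),
}

CHECKPOINT_SCHEMA = 1


@dataclass
class ModelParams:
    """All learnable weights; shapes follow the profile (D, H1, H2)."""

    W1: np.ndarray  # (H1, D)
    Ua: np.ndarray  # (H2, H1)
    Va: np.ndarray  # (H2, H1)
    Wa: np.ndarray  # (N, H2) attention branches, one row per class
    Wc: np.ndarray  # (N, H1) class-specific slide classifiers
    Winst: np.ndarray  # (N, 2, H1) instance clustering heads
    dropout_p: float = 0.25

    @property
    def n_classes(self) -> int:
        return self.Wa.shape[0]

    @property
    def dims(self) -> tuple[int, int, int]:
        h1, d = self.W1.shape
        return (d, h1, self.Ua.shape[0])

    def arrays(self) -> dict[str, np.ndarray]:
        return {"W1": self.W1, "Ua": self.Ua, "Va": self.Va,
                "Wa": self.Wa, "Wc": self.Wc, "Winst": self.Winst}

    def copy(self) -> "ModelParams":
        return copy.deepcopy(self)

    def validate(self) -> None:
        d, h1, h2 = self.dims
        n = self.n_classes
        expected = {"W1": (h1, d), "Ua": (h2, h1), "Va": (h2, h1),
                    "Wa": (n, h2), "Wc": (n, h1), "Winst": (n, 2, h1)}
        for name, arr in self.arrays().items():
            if arr.shape != expected[name]:
                raise ValueError(f"{name} has shape {arr.shape}, expected {expected[name]}")
            if not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")


def init_params(profile: str | tuple[int, int, int] = "paper", n_classes: int = 2,
                seed: int = 0, dropout_p: float = 0.25) -> ModelParams:
    """Seeded small-random initialization (scaled by 1/sqrt(fan-in))."""
    d, h1, h2 = PROFILES[profile] if isinstance(profile, str) else profile
    rng = np.random.default_rng(seed)

    def w(rows, cols):
        return rng.normal(0.0, 1.0 / np.sqrt(cols), size=(rows, cols))

    return ModelParams(
        W1=w(h1, d), Ua=w(h2, h1), Va=w(h2, h1),
        Wa=w(n_classes, h2), Wc=w(n_classes, h1),
        Winst=np.stack([w(2, h1) for _ in range(n_classes)]),
        dropout_p=dropout_p,
    )


@dataclass
class AttentionForward:
    """Everything the forward pass produces for one bag."""

    h: np.ndarray  # (K, H1) projected instances
    a: np.ndarray  # (N, K) attention distributions, rows sum to 1
    h_slide: np.ndarray  # (N, H1) pooled slide representations
    s_slide: np.ndarray  # (N,) slide scores
    probs: np.ndarray  # (N,) softmax of s_slide
    p_inst: np.ndarray  # (N, K, 2) instance cluster scores
    cache: dict = field(default_factory=dict, repr=False)


def _check_features(Z: np.ndarray, params: ModelParams) -> np.ndarray:
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2:
        raise ValueError("features must be a K x D matrix")
    d = params.W1.shape[1]
    if Z.shape[1] != d:
        raise ValueError(f"feature dim {Z.shape[1]} != model input dim {d}")
    return Z


def project_instances(bag_or_features, params: ModelParams) -> np.ndarray:
    """Backbone projection h_k = W1 z_k, applied row-wise."""
    Z = bag_or_features.features if isinstance(bag_or_features, FeatureBag) else bag_or_features
    Z = _check_features(Z, params)
    return Z @ params.W1.T


def _gate(h: np.ndarray, params: ModelParams) -> tuple[np.ndarray, ...]:
    v = h @ params.Va.T
    u = h @ params.Ua.T
    t = np.tanh(v)
    sg = 1.0 / (1.0 + np.exp(-u))
    return t * sg, t, sg


def attention_scores(h: np.ndarray, params: ModelParams, class_i: int) -> np.ndarray:
    """Softmax-normalized gated attention over the K patches for one class."""
    if h.shape[0] < 1:
        raise ValueError("need at least one instance")
    g, _, _ = _gate(h, params)
    logits = g @ params.Wa[class_i]
    return _softmax(logits)


def attention_pool(h: np.ndarray, a_row: np.ndarray) -> np.ndarray:
    """Convex combination Σ_k a_k h_k."""
    a_row = np.asarray(a_row, dtype=float).ravel()
    if a_row.size != h.shape[0]:
        raise ValueError("attention length must match instance count")
    return a_row @ h


def slide_scores(h_slide: np.ndarray, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Per-class scores s_i = Wc_i · h_slide,i and their softmax."""
    h_slide = np.atleast_2d(h_slide)
    s = np.einsum("ij,ij->i", params.Wc, h_slide)
    return s, _softmax(s)


def instance_cluster_scores(h: np.ndarray, params: ModelParams, class_i: int) -> np.ndarray:
    """Linear binary cluster scores p_{i,k} = Winst_i h_k, shape (K, 2)."""
    return h @ params.Winst[class_i].T


def assign_pseudo_labels(a_row: np.ndarray, k_sample: int) -> tuple[np.ndarray, np.ndarray]:
    """Top/bottom attended instances as (positive, negative) pseudo-labels.

    Returns ``(top_idx, bottom_idx)``: the ``k_sample`` most-attended
    instances (pseudo-label 1) and the ``k_sample`` least-attended ones
    (pseudo-label 0).  Ties break toward the lower index; the two sets are
    always disjoint (bottom picks skip indices already taken by top).
    If ``2 * k_sample > K`` the count is reduced to ``floor(K / 2)`` with a
    warning.
    """
    a_row = np.asarray(a_row, dtype=float).ravel()
    k_avail = a_row.size
    if 2 * k_sample > k_avail:
        k_sample = k_avail // 2
        warnings.warn(f"k_sample reduced to {k_sample} for a bag of {k_avail} instances")
    if k_sample == 0:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    top = np.argsort(-a_row, kind="stable")[:k_sample]
    taken = set(top.tolist())
    bottom = [i for i in np.argsort(a_row, kind="stable") if i not in taken][:k_sample]
    return top.astype(int), np.asarray(bottom, dtype=int)


def forward(bag_or_features, params: ModelParams, train: bool = False,
            rng: np.random.Generator | None = None) -> AttentionForward:
    """Full forward pass over all classes for one bag.

    In eval mode (``train=False``) dropout is disabled and the output is a
    deterministic, permutation-equivariant function of the bag.  In train
    mode an RNG must be supplied for the dropout masks.
    """
    Z = bag_or_features.features if isinstance(bag_or_features, FeatureBag) else bag_or_features
    Z = _check_features(Z, params)
    K = Z.shape[0]
    d, h1, h2 = params.dims
    p = params.dropout_p
    h_raw = Z @ params.W1.T
    if train and p > 0:
        if rng is None:
            raise ValueError("train-mode forward requires an RNG for dropout")
        m1 = (rng.random((K, h1)) >= p) / (1.0 - p)
        m2 = (rng.random((K, h2)) >= p) / (1.0 - p)
    else:
        m1 = np.ones((1, 1))
        m2 = np.ones((1, 1))
    h = h_raw * m1
    g_raw, t, sg = _gate(h, params)
    g = g_raw * m2
    logits = g @ params.Wa.T  # (K, N)
    logits -= logits.max(axis=0, keepdims=True)
    e = np.exp(logits)
    a = (e / e.sum(axis=0, keepdims=True)).T  # (N, K)
    h_slide = a @ h  # (N, H1)
    s, probs = slide_scores(h_slide, params)
    p_inst = np.einsum("kj,ncj->nkc", h, params.Winst)  # (N, K, 2)
    cache = {"Z": Z, "h": h, "g": g, "t": t, "sg": sg, "m1": m1, "m2": m2, "a": a}
    return AttentionForward(h=h, a=a, h_slide=h_slide, s_slide=s, probs=probs,
                            p_inst=p_inst, cache=cache)


def bag_backward(bag_or_features, y: int, params: ModelParams, cfg: LossConfig,
                 train: bool = False, rng: np.random.Generator | None = None,
                 fwd: AttentionForward | None = None):
    """Loss and analytic gradients of the mixed objective for one bag.

    The slide term is cross-entropy on the class scores; the patch term is
    the mean binary smooth SVM loss of the ground-truth class's clustering
    head over pseudo-labeled instances picked from the current attention
    (selection treated as constant, scores differentiated).  Returns
    ``(total, slide_l, patch_l, grads)`` with ``grads`` keyed like
    :meth:`ModelParams.arrays`.
    """
    cfg.validate()
    if fwd is None:
        fwd = forward(bag_or_features, params, train=train, rng=rng)
    c = fwd.cache
    Z, h, g, t, sg, m1, m2, a = (c["Z"], c["h"], c["g"], c["t"], c["sg"],
                                 c["m1"], c["m2"], c["a"])
    K = Z.shape[0]
    N = params.n_classes
    if not 0 <= y < N:
        raise ValueError(f"label {y} out of range for {N} classes")

    slide_l = slide_loss(fwd.s_slide, y)
    ds = slide_loss_grad(fwd.s_slide, y)  # (N,)

    top, bottom = assign_pseudo_labels(a[y], cfg.k_sample)
    sampled = np.concatenate([top, bottom])
    pseudo = np.concatenate([np.ones_like(top), np.zeros_like(bottom)])
    dP = np.zeros((K, 2))  # grad of patch loss w.r.t. p_inst[y]
    if sampled.size:
        patch_l = patch_loss(fwd.p_inst[y][sampled], pseudo, cfg.alpha, cfg.tau)
        for idx, lab in zip(sampled, pseudo):
            dP[idx] = svm_smooth_grad(fwd.p_inst[y][idx], int(lab), cfg.alpha, cfg.tau) / sampled.size
    else:
        patch_l = 0.0
    total = total_loss(slide_l, patch_l, cfg.c1, cfg.c2)

    # ---- backward ----
    dH = np.zeros_like(h)
    dG = np.zeros_like(g)
    dWa = np.zeros_like(params.Wa)
    dWc = np.zeros_like(params.Wc)
    dWinst = np.zeros_like(params.Winst)

    for i in range(N):
        dsi = cfg.c1 * ds[i]
        dWc[i] = dsi * fwd.h_slide[i]
        dh_slide = dsi * params.Wc[i]  # (H1,)
        da = h @ dh_slide  # (K,)
        dH += np.outer(a[i], dh_slide)
        # softmax jacobian over the K patches
        dlog = a[i] * (da - float(a[i] @ da))
        dWa[i] = dlog @ g
        dG += np.outer(dlog, params.Wa[i])

    # patch term: only the ground-truth class's head
    dWinst[y] = cfg.c2 * dP.T @ h
    dH += cfg.c2 * dP @ params.Winst[y]

    # through the gate
    dg_raw = dG * m2
    dv = dg_raw * sg * (1.0 - t * t)
    du = dg_raw * t * sg * (1.0 - sg)
    dVa = dv.T @ h
    dUa = du.T @ h
    dH += dv @ params.Va + du @ params.Ua

    dW1 = (dH * m1).T @ Z
    grads = {"W1": dW1, "Ua": dUa, "Va": dVa, "Wa": dWa, "Wc": dWc, "Winst": dWinst}
    return total, slide_l, patch_l, grads


def save_checkpoint(params: ModelParams, path: str | Path, meta: dict | None = None) -> Path:
    """Serialize parameters to a single .npz with a shape manifest."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "schema": CHECKPOINT_SCHEMA,
        "dims": list(params.dims),
        "n_classes": params.n_classes,
        "dropout_p": params.dropout_p,
        "shapes": {k: list(v.shape) for k, v in params.arrays().items()},
        "meta": meta or {},
    }
    np.savez(path, manifest=np.frombuffer(json.dumps(manifest).encode(), dtype=np.uint8),
             **params.arrays())
    return path


def load_checkpoint(path: str | Path) -> tuple[ModelParams, dict]:
    with np.load(path) as data:
        manifest = json.loads(bytes(data["manifest"]).decode())
        if manifest.get("schema") != CHECKPOINT_SCHEMA:
            raise ValueError(f"unsupported checkpoint schema {manifest.get('schema')}")
        params = ModelParams(
            W1=data["W1"], Ua=data["Ua"], Va=data["Va"],
            Wa=data["Wa"], Wc=data["Wc"], Winst=data["Winst"],
            dropout_p=float(manifest["dropout_p"]),
        )
    params.validate()
    return params, manifest.get("meta", {})
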
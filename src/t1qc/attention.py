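"""Attention maps and the attention-supervision loss.

Two complementary visualisations of what the classifier attends to when it
scores segment ``s``:

* **saliency** — the gradient of the segmental score with respect to every
  input pixel, summed pixelwise over the T1, R² and IRW components (the IRW
  stack collapsed by sum of absolute per-frame gradients);
* **Grad-CAM** — channel-importance weights ``w_k`` obtained by global
  average pooling of the score gradient on the last convolutional layer's
  feature maps ``A_k``, combined as ``ReLU(Σ_k w_k A_k)`` and bilinearly
  upsampled to input resolution.

Attention supervision turns the Grad-CAM construction into a training
signal: each per-segment map is normalised to [0, 1] and penalised by
pixelwise binary cross-entropy against the segment mask, so attention mass
outside the scored segment costs loss.  The total objective is
``L = L_att + α · L_cl`` with the classification term ``L_cl`` the mean
binary cross-entropy of the six scores against the human labels.

The neuron-importance weights are treated as constants of the current
forward pass (the gradient flows into the feature maps, not through the
weight computation itself); this first-order construction is what the
engine differentiates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor, backward
from .network import ModelInput, MotionClassifier
from .phantom import N_SEGMENTS, SegmentMaskSet

__all__ = [
    "AttentionMap",
    "NeuronWeights",
    "LossValues",
    "saliency_map",
    "grad_cam",
    "grad_cam_map",
    "supervised_attention_maps",
    "attention_loss",
    "classification_loss",
    "combined_loss",
    "attention_mass_fraction",
]

EPS = 1e-6


@dataclass(frozen=True)
class AttentionMap:
    """Non-negative per-pixel importance map for one segment."""

    map: np.ndarray  # (H, W)
    segment_index: int  # 1..6
    method: str  # saliency | grad_cam | supervised


@dataclass(frozen=True)
class NeuronWeights:
    """Per-channel importance weights of the last-layer feature maps."""

    weights: np.ndarray  # (N,)
    segment_index: int


@dataclass(frozen=True)
class LossValues:
    l_att: float
    l_cl: float
    alpha: float
    total: float
    total_graph: Tensor | None = None


def _check_segment(segment_index: int) -> int:
    if not 1 <= segment_index <= N_SEGMENTS:
        raise ValueError(f"segment_index must be in 1..{N_SEGMENTS}")
    return segment_index - 1


def _select_scores(scores: Tensor, col: int) -> Tensor:
    """Sum of one score column over the batch (a scalar graph node)."""
    onehot = np.zeros(scores.shape[-1], dtype=np.float32)
    onehot[col] = 1.0
    return (scores * Tensor(onehot)).sum()


# ---------------------------------------------------------------------------
# Visualisation
# ---------------------------------------------------------------------------

def saliency_map(
    classifier: MotionClassifier, model_input: ModelInput, segment_index: int
) -> AttentionMap:
    """Input-gradient attention for one segment of one case."""
    col = _check_segment(segment_index)
    t1 = Tensor(model_input.t1_image[None, None, None], requires_grad=True)
    r2 = Tensor(model_input.r2_image[None, None, None], requires_grad=True)
    irw = Tensor(model_input.irw_stack[None, None], requires_grad=True)
    scores = classifier.forward_tensors(t1, r2, irw, training=False)
    backward(_select_scores(scores, col))
    sal = (
        np.abs(t1.grad[0, 0, 0])
        + np.abs(r2.grad[0, 0, 0])
        + np.abs(irw.grad[0, 0]).sum(axis=0)
    )
    classifier.zero_grad()
    return AttentionMap(map=sal.astype(np.float32), segment_index=segment_index, method="saliency")


def grad_cam_map(
    activations: np.ndarray, gradients: np.ndarray, out_size: int | None = None
) -> np.ndarray:
    """Pure Grad-CAM arithmetic: ``ReLU(Σ_k mean(g_k) · A_k)``, then upsample.

    ``activations`` and ``gradients`` are (C, h, w).
    """
    weights = gradients.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * activations).sum(axis=0), 0.0)
    if out_size is not None and cam.shape != (out_size, out_size):
        my = ad._interp_matrix(cam.shape[0], out_size)
        mx = ad._interp_matrix(cam.shape[1], out_size)
        cam = my @ cam @ mx.T
    return cam.astype(np.float32)


def grad_cam(
    classifier: MotionClassifier, model_input: ModelInput, segment_index: int
) -> tuple[AttentionMap, NeuronWeights]:
    """Grad-CAM attention for one segment, upsampled to input resolution."""
    col = _check_segment(segment_index)
    scores, features = classifier.forward(model_input, capture_features=True)
    backward(_select_scores(scores, col), stop=(features,))
    if features.grad is None:
        raise RuntimeError("no captured feature gradients")
    acts = features.data[0, :, 0]  # (C, h, w)
    grads = features.grad[0, :, 0]
    classifier.zero_grad()
    cam = grad_cam_map(acts, grads, out_size=model_input.crop_size)
    return (
        AttentionMap(map=cam, segment_index=segment_index, method="grad_cam"),
        NeuronWeights(weights=grads.mean(axis=(1, 2)), segment_index=segment_index),
    )


def attention_mass_fraction(attention: AttentionMap | np.ndarray, mask: np.ndarray) -> float:
    """Fraction of total attention mass falling inside a binary mask."""
    m = attention.map if isinstance(attention, AttentionMap) else attention
    total = float(m.sum())
    if total <= 0:
        return 0.0
    return float(m[mask.astype(bool)].sum() / total)


# ---------------------------------------------------------------------------
# Supervision
# ---------------------------------------------------------------------------

def supervised_attention_maps(
    scores: Tensor, features: Tensor, out_size: int | None
) -> list[Tensor]:
    """Differentiable per-segment attention maps from one forward pass.

    For each segment: one backward pass (stopped at the feature maps) gives
    the per-sample channel weights, which enter the weighted sum as
    constants; the resulting ``ReLU(Σ w_k A_k)`` stays differentiable with
    respect to the classifier parameters through the feature maps.  Maps are
    upsampled to ``out_size`` (input resolution) when given.

    The caller should ``classifier.zero_grad()`` afterwards: the weight
    extraction deposits gradients in the classification head.
    """
    b, c = features.shape[:2]
    h, w = features.shape[-2:]
    maps = []
    for s in range(N_SEGMENTS):
        features.grad = None
        backward(_select_scores(scores, s), stop=(features,))
        weights = features.grad.mean(axis=(2, 3, 4))  # (B, C), detached
        wt = Tensor(weights[:, :, None, None, None])
        cam = ad.relu((features * wt).sum(axis=1)).reshape(b, h, w)
        if out_size is not None and (h, w) != (out_size, out_size):
            cam = ad.upsample_bilinear(cam, (out_size, out_size))
        maps.append(cam)
    features.grad = None
    return maps


def _as_map_tensor(m) -> Tensor:
    if isinstance(m, Tensor):
        return m
    if isinstance(m, AttentionMap):
        m = m.map
    arr = np.asarray(m, dtype=np.float32)
    return Tensor(arr[None] if arr.ndim == 2 else arr)


def _as_mask_array(masks, n_batch: int, idx: int) -> np.ndarray:
    if isinstance(masks, SegmentMaskSet):
        m = masks.masks[idx].astype(np.float32)[None]
        return np.repeat(m, n_batch, axis=0) if n_batch > 1 else m
    arr = np.asarray(masks, dtype=np.float32)
    if arr.ndim == 3:  # (6, H, W)
        return arr[idx][None]
    return arr[:, idx]  # (B, 6, H, W)


def _bce_mean(p: Tensor, target: np.ndarray) -> Tensor:
    t = target.astype(np.float32)
    return -(
        Tensor(t) * ad.log(p) + Tensor(1.0 - t) * ad.log(1.0 - p)
    ).mean()


def attention_loss(attention_maps, masks, *, eps: float = EPS) -> Tensor:
    """Sum over segments of pixel-mean cross-entropy between each normalised
    attention map and its segment mask.

    Cross-entropy needs values in [0, 1] while Grad-CAM maps are unbounded
    above, so each map is divided by its per-sample maximum whenever that
    maximum exceeds 1 (maps already in [0, 1] pass through unchanged; the
    scale is treated as a constant of the forward pass), then clamped into
    ``[ε, 1 − ε]``.  Accepts graph Tensors (for training) or
    AttentionMap/ndarray (plain evaluation).
    """
    if len(attention_maps) != N_SEGMENTS:
        raise ValueError("expected 6 attention maps")
    total: Tensor | None = None
    for s, raw in enumerate(attention_maps):
        m = _as_map_tensor(raw)
        n_batch = m.shape[0]
        mask = _as_mask_array(masks, n_batch, s)
        if mask.shape[-2:] != m.shape[-2:]:
            raise ValueError(
                f"map shape {m.shape[-2:]} does not match mask shape {mask.shape[-2:]}"
            )
        peak = np.maximum(m.data.reshape(n_batch, -1).max(axis=1), 1.0)
        m = m * Tensor(1.0 / peak[:, None, None])
        m = ad.clamp(m, eps, 1.0 - eps)
        term = _bce_mean(m, mask)
        total = term if total is None else total + term
    return total


def classification_loss(scores: Tensor, labels: np.ndarray, *, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy of the six segmental scores against labels."""
    p = ad.clamp(scores, eps, 1.0 - eps)
    return _bce_mean(p, np.asarray(labels, dtype=np.float32).reshape(scores.shape))


def combined_loss(
    scores: Tensor,
    labels: np.ndarray,
    attention_maps,
    masks,
    alpha: float = 1.0,
) -> LossValues:
    """Total training objective ``L = L_att + α · L_cl``.

    The reported scalars satisfy the decomposition exactly; ``total_graph``
    is the differentiable node to backpropagate.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    l_att_t = attention_loss(attention_maps, masks)
    l_cl_t = classification_loss(scores, labels)
    total_graph = l_att_t + float(alpha) * l_cl_t
    l_att = float(l_att_t.data)
    l_cl = float(l_cl_t.data)
    return LossValues(
        l_att=l_att,
        l_cl=l_cl,
        alpha=float(alpha),
        total=l_att + float(alpha) * l_cl,
        total_graph=total_graph,
    )
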
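"""Training protocol: augmentation, 5-fold cross-validation, Adam with
plateau learning-rate drops and early stopping.

The protocol mirrors routine practice for this classifier: batches of 16,
initial learning rate 1e-3 lowered by a factor of 10 when the validation
loss plateaus (patience 30 epochs), training stopped once the validation
loss has not improved for 50 epochs, and on-the-fly augmentation with
rotations within ±5° and translations within ±10 px about the LV centre.
Each cross-validation repetition trains on three folds, validates on one
and tests on one; over the five rotations every case is scored exactly once
by a model that never saw it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import autodiff as ad
from .attention import (
    attention_loss,
    classification_loss,
    combined_loss,
    supervised_attention_maps,
)
from .network import (
    ModelInput,
    MotionClassifier,
    NetworkConfig,
    build_classifier,
    crop_and_stack,
    crop_array,
)
from .nn import Adam
from .phantom import N_SEGMENTS, SyntheticCase

__all__ = [
    "TrainConfig",
    "FoldSplit",
    "TrainingSample",
    "prepare_samples",
    "augment",
    "make_folds",
    "train_fold",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 16
    initial_lr: float = 1e-3
    lr_drop_factor: float = 10.0
    plateau_patience_epochs: int = 30
    early_stop_patience_epochs: int = 50
    max_epochs: int = 1000
    max_rotation_deg: float = 5.0
    max_translation_px: float = 10.0
    alpha: float = 1.0
    seed: int = 0
    min_delta: float = 1e-4  # improvement below this counts as a plateau
    augment: bool = True

    def __post_init__(self) -> None:
        for name in (
            "batch_size",
            "initial_lr",
            "lr_drop_factor",
            "plateau_patience_epochs",
            "early_stop_patience_epochs",
            "max_epochs",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")


@dataclass(frozen=True)
class FoldSplit:
    """Assignment of each case to one of k folds, plus the role rotation."""

    assignments: dict[str, int]
    k: int = 5

    def fold_ids(self, fold: int) -> list[str]:
        return [cid for cid, f in self.assignments.items() if f == fold]

    def roles(self, repetition: int) -> tuple[list[int], int, int]:
        """(train folds, validation fold, test fold) for one repetition."""
        test = repetition % self.k
        val = (repetition + 1) % self.k
        train = [f for f in range(self.k) if f not in (test, val)]
        return train, val, test


@dataclass
class TrainingSample:
    case_id: str
    model_input: ModelInput
    masks: np.ndarray  # (6, crop, crop) float32
    labels: np.ndarray  # (6,) int
    slice_tag: str = "mid"


def prepare_samples(cases: list[SyntheticCase], crop_size: int) -> list[TrainingSample]:
    """Crop, normalise and package simulated cases for training."""
    samples = []
    for case in cases:
        mi = crop_and_stack(case, crop_size=crop_size)
        masks = crop_array(
            case.segment_masks.masks.astype(np.float32), case.lv_centroid, crop_size
        )
        samples.append(
            TrainingSample(
                case_id=case.case_id,
                model_input=mi,
                masks=masks,
                labels=case.labels.copy(),
            )
        )
    return samples


def draw_augmentation(
    rng: np.random.Generator,
    max_rotation_deg: float = 5.0,
    max_translation_px: float = 10.0,
) -> tuple[float, np.ndarray]:
    """Draw one (angle°, (dy, dx)) rigid perturbation, uniform within bounds."""
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    shift = rng.uniform(-max_translation_px, max_translation_px, size=2)
    return float(angle), shift


def augment(
    model_input: ModelInput,
    masks: np.ndarray,
    rng: np.random.Generator,
    max_rotation_deg: float = 5.0,
    max_translation_px: float = 10.0,
) -> tuple[ModelInput, np.ndarray]:
    """One random rigid transform applied identically to all nine images and
    the segment masks.

    Rotation angle ~ U(−max°, +max°) about the crop centre (the LV centroid
    after cropping) and translation ~ U(−max, +max) px per axis; bilinear
    interpolation with zero fill; masks re-binarised at 0.5.
    """
    angle_deg, shift = draw_augmentation(rng, max_rotation_deg, max_translation_px)
    angle = np.deg2rad(angle_deg)
    size = model_input.crop_size
    c = np.array([(size - 1) / 2.0, (size - 1) / 2.0])
    cosa, sina = np.cos(angle), np.sin(angle)
    m = np.array([[cosa, -sina], [sina, cosa]])  # input = m @ (out - c - t) + c
    offset = c - m @ (c + shift)

    def warp(img, order=1):
        return ndimage.affine_transform(
            img, m, offset=offset, order=order, mode="constant", cval=0.0
        )

    t1 = warp(model_input.t1_image)
    r2 = warp(model_input.r2_image)
    irw = np.stack([warp(f) for f in model_input.irw_stack])
    out_masks = np.stack([(warp(mk) >= 0.5).astype(np.float32) for mk in masks])
    return (
        ModelInput(
            t1_image=t1.astype(np.float32),
            r2_image=r2.astype(np.float32),
            irw_stack=irw.astype(np.float32),
        ),
        out_masks,
    )


def make_folds(
    case_ids: list[str],
    k: int = 5,
    seed: int = 0,
    stratify_labels: np.ndarray | None = None,
) -> FoldSplit:
    """Seeded random partition into k near-equal folds.

    With ``stratify_labels`` (whole-image binary labels), positives and
    negatives are dealt separately so each fold sees a similar prevalence.
    """
    ids = list(case_ids)
    if k > len(ids):
        raise ValueError("more folds than cases")
    rng = np.random.default_rng(seed)
    if stratify_labels is not None:
        labels = np.asarray(stratify_labels)
        order = []
        for value in (1, 0):
            group = [cid for cid, l in zip(ids, labels) if l == value]
            rng.shuffle(group)
            order.extend(group)
    else:
        order = ids.copy()
        rng.shuffle(order)
    return FoldSplit(assignments={cid: i % k for i, cid in enumerate(order)}, k=k)


# ---------------------------------------------------------------------------
# Optimisation loop
# ---------------------------------------------------------------------------

def _batch_forward(model, samples, training, capture):
    return model.forward([s.model_input for s in samples], training=training,
                         capture_features=capture)


def _evaluate_loss(model, samples, batch_size, alpha, supervised):
    """Validation loss: the same objective as training, in evaluation mode."""
    totals = []
    for i in range(0, len(samples), batch_size):
        chunk = samples[i : i + batch_size]
        labels = np.stack([s.labels for s in chunk]).astype(np.float32)
        if supervised:
            scores, feats = _batch_forward(model, chunk, False, True)
            maps = supervised_attention_maps(scores, feats, out_size=chunk[0].model_input.crop_size)
            model.zero_grad()
            masks = np.stack([s.masks for s in chunk])
            lv = combined_loss(scores, labels, maps, masks, alpha=alpha)
            totals.append(lv.total * len(chunk))
        else:
            scores = _batch_forward(model, chunk, False, False)
            totals.append(float(classification_loss(scores, labels).data) * len(chunk))
    return sum(totals) / len(samples)


def train_fold(
    samples: list[TrainingSample],
    train_idx: list[int],
    val_idx: list[int],
    net_config: NetworkConfig,
    config: TrainConfig,
    supervised_attention: bool = True,
    seed: int | None = None,
) -> tuple[MotionClassifier, pd.DataFrame]:
    """Train one model on a train/validation split; returns the model at its
    best validation loss plus the per-epoch history."""
    if not train_idx or not val_idx:
        raise ValueError("empty train or validation set")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    model = build_classifier(net_config, seed=seed)
    opt = Adam(model.parameters(), lr=config.initial_lr)
    crop = net_config.crop_size

    best_val = np.inf
    best_state = model.state_dict()
    best_epoch = 0
    since_best = 0
    since_plateau = 0
    history = []

    for epoch in range(1, config.max_epochs + 1):
        order = np.array(train_idx)
        rng.shuffle(order)
        ep_att, ep_cl, ep_tot, n_seen = 0.0, 0.0, 0.0, 0
        for i in range(0, len(order), config.batch_size):
            chunk = [samples[j] for j in order[i : i + config.batch_size]]
            if config.augment:
                aug = [
                    augment(s.model_input, s.masks, rng,
                            config.max_rotation_deg, config.max_translation_px)
                    for s in chunk
                ]
                inputs = [
                    TrainingSample(s.case_id, mi, mk, s.labels)
                    for s, (mi, mk) in zip(chunk, aug)
                ]
            else:
                inputs = chunk
            labels = np.stack([s.labels for s in inputs]).astype(np.float32)
            if supervised_attention:
                scores, feats = _batch_forward(model, inputs, True, True)
                maps = supervised_attention_maps(scores, feats, out_size=crop)
                model.zero_grad()
                masks = np.stack([s.masks for s in inputs])
                lv = combined_loss(scores, labels, maps, masks, alpha=config.alpha)
                loss_graph, l_att, l_cl, total = lv.total_graph, lv.l_att, lv.l_cl, lv.total
            else:
                scores = _batch_forward(model, inputs, True, False)
                loss_graph = classification_loss(scores, labels)
                l_att, l_cl = 0.0, float(loss_graph.data)
                total = l_cl
            if not np.isfinite(total):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (l_att={l_att}, l_cl={l_cl})"
                )
            ad.backward(loss_graph)
            opt.step()
            opt.zero_grad()
            b = len(inputs)
            ep_att += l_att * b
            ep_cl += l_cl * b
            ep_tot += total * b
            n_seen += b

        val_loss = _evaluate_loss(
            model, [samples[j] for j in val_idx], config.batch_size,
            config.alpha, supervised_attention,
        )
        improved = val_loss < best_val - config.min_delta
        if improved:
            best_val = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
            since_best = 0
            since_plateau = 0
        else:
            since_best += 1
            since_plateau += 1
        if since_plateau >= config.plateau_patience_epochs:
            opt.lr /= config.lr_drop_factor
            since_plateau = 0
        history.append(
            {
                "epoch": epoch,
                "lr": opt.lr,
                "train_l_att": ep_att / n_seen,
                "train_l_cl": ep_cl / n_seen,
                "train_total": ep_tot / n_seen,
                "val_loss": val_loss,
                "best_val": best_val,
                "best_epoch": best_epoch,
            }
        )
        if since_best >= config.early_stop_patience_epochs:
            break

    model.load_state_dict(best_state)
    return model, pd.DataFrame(history)


def predict_scores(model: MotionClassifier, samples, batch_size: int = 16) -> np.ndarray:
    out = []
    for i in range(0, len(samples), batch_size):
        out.append(model.predict([s.model_input for s in samples[i : i + batch_size]]))
    return np.vstack(out)


def train(
    samples: list[TrainingSample],
    folds: FoldSplit,
    net_config: NetworkConfig,
    config: TrainConfig,
    supervised_attention: bool = True,
) -> dict:
    """Full k-fold protocol.

    Each repetition trains on three folds, validates on one and tests on one;
    test-fold predictions are concatenated so every case receives a machine
    score exactly once.  Returns models, histories and the whole-dataset
    score table (case_id, score1..6, label1..6).
    """
    by_id = {s.case_id: i for i, s in enumerate(samples)}
    rows = []
    models, histories = [], []
    for rep in range(folds.k):
        train_f, val_f, test_f = folds.roles(rep)
        train_idx = [by_id[c] for f in train_f for c in folds.fold_ids(f)]
        val_idx = [by_id[c] for c in folds.fold_ids(val_f)]
        test_idx = [by_id[c] for c in folds.fold_ids(test_f)]
        if not (train_idx and val_idx and test_idx):
            raise ValueError(f"repetition {rep}: empty fold")
        model, hist = train_fold(
            samples, train_idx, val_idx, net_config, config,
            supervised_attention=supervised_attention,
            seed=config.seed + 9973 * rep,
        )
        test_samples = [samples[i] for i in test_idx]
        scores = predict_scores(model, test_samples, config.batch_size)
        for s, sc in zip(test_samples, scores):
            row = {"case_id": s.case_id, "fold": rep}
            row.update({f"score{k + 1}": float(sc[k]) for k in range(N_SEGMENTS)})
            row.update({f"label{k + 1}": int(s.labels[k]) for k in range(N_SEGMENTS)})
            rows.append(row)
        models.append(model)
        histories.append(hist)
    table = pd.DataFrame(rows).sort_values("case_id").reset_index(drop=True)
    return {"models": models, "histories": histories, "score_table": table}
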
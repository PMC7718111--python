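"""Multi-stream 34-layer residual classifier for segmental motion scoring.

The model mirrors how a human reader works: it looks at the T1 map, the R²
quality map and the 7 raw inversion-recovery-weighted (IRW) frames at once.
Three convolutional stems (2D for the T1 and R² maps, 3D for the IRW stack)
produce feature slabs that are fused along the depth axis into a
``crop × crop × 9`` volume; a 34-layer residual trunk with stride-2
down-sampling then reduces it, switching from 3D to 2D convolutions once
the depth axis is exhausted (9 → 5 → 3 → 2 → 1), and a global-average-pool
plus fully connected layer with per-output sigmoids emits six segmental
motion scores in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import BatchNorm, Conv, Linear, Module
from .phantom import ConfigurationError, N_FRAMES, N_SEGMENTS, SyntheticCase

__all__ = [
    "NetworkConfig",
    "ModelInput",
    "MotionClassifier",
    "build_classifier",
    "crop_and_stack",
    "crop_array",
]

T1_NORMALISATION_MS = 3000.0  # fixed scale keeps T1 semantics across cases


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyper-parameters.

    Defaults give the full-size model: crop 160², canonical 34-layer block
    schedule [3, 4, 6, 3] with widths [64, 128, 256, 512].  ``tiny()`` is a
    quarter-width 64² variant for CPU-scale experiments.
    """

    crop_size: int = 160
    stem_kernel: tuple[int, int, int] = (3, 3, 3)
    stem_stride: int = 1
    stem_channels: int = 3
    fused_depth: int = N_FRAMES + 2
    block_counts: tuple[int, ...] = (3, 4, 6, 3)
    stage_channels: tuple[int, ...] = (64, 128, 256, 512)
    downsample_stride: int = 2
    n_outputs: int = N_SEGMENTS

    def __post_init__(self) -> None:
        if self.fused_depth != N_FRAMES + 2:
            raise ConfigurationError("fused_depth must equal n_frames + 2 == 9")
        if self.n_outputs != N_SEGMENTS:
            raise ConfigurationError("n_outputs must be 6")
        if len(self.block_counts) != len(self.stage_channels):
            raise ConfigurationError("block_counts and stage_channels must align")

    @classmethod
    def tiny(cls) -> "NetworkConfig":
        return cls(crop_size=64, stage_channels=(16, 32, 64, 128))

    @property
    def layer_count(self) -> int:
        # stem (three parallel streams at one depth level) + two convs per
        # residual block + the fully connected head; projection shortcuts are
        # not counted, per ResNet convention.
        return 1 + 2 * sum(self.block_counts) + 1

    @property
    def n_downsamples(self) -> int:
        """Stride-2 reductions: the post-stem pool plus every stage after the first."""
        return 1 + sum(1 for i in range(len(self.block_counts)) if i > 0)

    @property
    def feature_size(self) -> int:
        return self.crop_size // 2**self.n_downsamples


@dataclass(frozen=True)
class ModelInput:
    """The normalised (T1, R², IRW) triple fed to the classifier."""

    t1_image: np.ndarray  # (H, W)
    r2_image: np.ndarray  # (H, W)
    irw_stack: np.ndarray  # (7, H, W)

    def __post_init__(self) -> None:
        h, w = self.t1_image.shape
        if h != w:
            raise ConfigurationError("model input must be square")
        if self.r2_image.shape != (h, w) or self.irw_stack.shape != (N_FRAMES, h, w):
            raise ConfigurationError("t1, r2 and irw shapes must agree")

    @property
    def crop_size(self) -> int:
        return self.t1_image.shape[0]


def crop_array(arr: np.ndarray, centroid: tuple[float, float], crop_size: int) -> np.ndarray:
    """Crop the trailing two axes to ``crop_size``² with the centroid at the
    crop centre (even-size convention: centre pixel at index crop_size/2)."""
    h, w = arr.shape[-2:]
    cy, cx = int(round(centroid[0])), int(round(centroid[1]))
    if not (0 <= cy < h and 0 <= cx < w):
        raise ConfigurationError("centroid outside the image")
    half = crop_size // 2
    r0, c0 = cy - half, cx - half
    pad_top = max(0, -r0)
    pad_left = max(0, -c0)
    pad_bottom = max(0, r0 + crop_size - h)
    pad_right = max(0, c0 + crop_size - w)
    if max(pad_top, pad_bottom, pad_left, pad_right) > crop_size // 2:
        raise ConfigurationError("centroid too close to the border for this crop size")
    if any((pad_top, pad_bottom, pad_left, pad_right)):
        widths = [(0, 0)] * (arr.ndim - 2) + [(pad_top, pad_bottom), (pad_left, pad_right)]
        arr = np.pad(arr, widths)
        r0 += pad_top
        c0 += pad_left
    return np.ascontiguousarray(arr[..., r0 : r0 + crop_size, c0 : c0 + crop_size])


def crop_and_stack(
    case: SyntheticCase,
    lv_centroid: tuple[float, float] | None = None,
    crop_size: int = 160,
) -> ModelInput:
    """Crop all nine images around the LV centroid and normalise.

    Normalisation: T1 divided by 3000 ms (degenerate NaN pixels set to 0),
    R² used as-is (already in [0, 1]), IRW frames z-scored jointly per case.
    """
    centroid = lv_centroid if lv_centroid is not None else case.lv_centroid
    t1 = crop_array(np.nan_to_num(case.t1_map, nan=0.0), centroid, crop_size)
    r2 = crop_array(case.r2_map, centroid, crop_size)
    irw = crop_array(case.irw_stack, centroid, crop_size)
    mu = irw.mean()
    sd = irw.std()
    irw = (irw - mu) / (sd if sd > 1e-8 else 1.0)
    return ModelInput(
        t1_image=(t1 / T1_NORMALISATION_MS).astype(np.float32),
        r2_image=r2.astype(np.float32),
        irw_stack=irw.astype(np.float32),
    )


class ResidualBlock(Module):
    """Two 3×3(×3) convolutions with BN+ReLU and an identity/projection skip.

    The depth-kernel collapses to 1 (a 2D convolution) once the incoming
    depth axis is exhausted; stride-2 blocks down-sample depth as well while
    any depth remains.
    """

    def __init__(self, c_in, c_out, depth_in, spatial_stride, rng):
        kd1 = 3 if depth_in >= 2 else 1
        sd = spatial_stride if (spatial_stride > 1 and depth_in > 1) else 1
        self.conv1 = Conv(
            c_in, c_out, (kd1, 3, 3), stride=(sd, spatial_stride, spatial_stride), rng=rng
        )
        self.bn1 = BatchNorm(c_out)
        depth_mid = (depth_in - 1) // sd + 1
        kd2 = 3 if depth_mid >= 2 else 1
        self.conv2 = Conv(c_out, c_out, (kd2, 3, 3), rng=rng)
        self.bn2 = BatchNorm(c_out)
        if spatial_stride > 1 or c_in != c_out:
            self.proj = Conv(
                c_in, c_out, (1, 1, 1), stride=(sd, spatial_stride, spatial_stride), rng=rng
            )
            self.proj_bn = BatchNorm(c_out)
        else:
            self.proj = None
        self.depth_out = depth_mid

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        h = ad.relu(self.bn1(self.conv1(x), training))
        h = self.bn2(self.conv2(h), training)
        skip = self.proj_bn(self.proj(x), training) if self.proj is not None else x
        return ad.relu(h + skip)


class MotionClassifier(Module):
    """The multi-stream 34-layer residual network (see module docstring)."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        sc = config.stem_channels
        ss = config.stem_stride
        self.stem_t1 = Conv(1, sc, (1, 3, 3), stride=(1, ss, ss), rng=rng)
        self.stem_t1_bn = BatchNorm(sc)
        self.stem_r2 = Conv(1, sc, (1, 3, 3), stride=(1, ss, ss), rng=rng)
        self.stem_r2_bn = BatchNorm(sc)
        self.stem_irw = Conv(1, sc, config.stem_kernel, stride=(1, ss, ss), rng=rng)
        self.stem_irw_bn = BatchNorm(sc)

        depth = (config.fused_depth - 1) // 2 + 1  # post-stem max pool
        c_in = sc
        self.blocks: list[ResidualBlock] = []
        for si, (n_blocks, width) in enumerate(
            zip(config.block_counts, config.stage_channels)
        ):
            for b in range(n_blocks):
                stride = config.downsample_stride if (si > 0 and b == 0) else 1
                blk = ResidualBlock(c_in, width, depth, stride, rng)
                depth = blk.depth_out
                c_in = width
                self.blocks.append(blk)
        if depth != 1:
            raise ConfigurationError(
                f"depth schedule leaves {depth} depth planes; add down-sampling stages"
            )
        self.fc = Linear(c_in, config.n_outputs, rng=rng)

    # -- public API -------------------------------------------------------

    def layer_count(self) -> int:
        return self.config.layer_count

    def forward(
        self,
        batch: "ModelInput | list[ModelInput]",
        training: bool = False,
        capture_features: bool = False,
    ):
        """Score a ModelInput (or list of them).

        Returns a ``(B, 6)`` score Tensor; with ``capture_features`` also the
        last convolutional layer's feature maps ``A`` (``(B, C, 1, h, w)``)
        for attention analysis.
        """
        inputs = [batch] if isinstance(batch, ModelInput) else list(batch)
        size = self.config.crop_size
        for mi in inputs:
            if mi.crop_size != size:
                raise ConfigurationError(
                    f"input size {mi.crop_size} != configured crop {size}"
                )
        t1 = Tensor(np.stack([mi.t1_image for mi in inputs])[:, None, None])
        r2 = Tensor(np.stack([mi.r2_image for mi in inputs])[:, None, None])
        irw = Tensor(np.stack([mi.irw_stack for mi in inputs])[:, None])
        return self.forward_tensors(t1, r2, irw, training, capture_features)

    def forward_tensors(
        self,
        t1: Tensor,
        r2: Tensor,
        irw: Tensor,
        training: bool = False,
        capture_features: bool = False,
    ):
        """Graph-level forward on (B,1,1,H,W), (B,1,1,H,W), (B,1,7,H,W) tensors."""
        x1 = ad.relu(self.stem_t1_bn(self.stem_t1(t1), training))
        x2 = ad.relu(self.stem_r2_bn(self.stem_r2(r2), training))
        x3 = ad.relu(self.stem_irw_bn(self.stem_irw(irw), training))
        fused = ad.concat([x1, x2, x3], axis=2)  # depth: 1 + 1 + 7 = 9
        x = ad.maxpool3d(fused, k=3, s=2, p=1)
        for blk in self.blocks:
            x = blk(x, training)
        features = x
        pooled = features.mean(axis=(2, 3, 4))
        scores = ad.sigmoid(self.fc(pooled))
        if capture_features:
            return scores, features
        return scores

    def predict(self, batch) -> np.ndarray:
        """Evaluation-mode scores as a plain (B, 6) array."""
        single = isinstance(batch, ModelInput)
        scores = self.forward(batch, training=False).data
        return scores[0] if single else scores


def build_classifier(config: NetworkConfig, seed: int = 0) -> MotionClassifier:
    """Construct a seeded, deterministically initialised classifier."""
    return MotionClassifier(config, seed=seed)
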
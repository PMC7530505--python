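"""Shallow CNN for MGMT promoter-methylation status classification.

The classifier is deliberately small — two convolutional stages and two
fully connected layers — because the cohorts this pipeline targets are
small.  Each convolutional stage is 3x3 stride-1 convolution ->
LeakyReLU(0.3) -> batch normalization -> 4x4 max pooling; the head is
FC(hidden, ReLU) -> FC(2, softmax).  All weights are He-normal
initialized.

At the reference geometry (208x208 single-channel input, hidden width 4)
the network has exactly 3,498 trainable parameters:

    conv1 (3x3x1 -> 16):  16*9  + 16 =  160
    bn1   (16 channels):  2*16       =   32
    conv2 (3x3x16 -> 4):  4*144 + 4  =  580
    bn2   (4 channels):   2*4        =    8
    fc1   (13*13*4=676 -> 4): 676*4+4 = 2708
    fc2   (4 -> 2):       4*2 + 2    =   10
                                       ----
                                       3498

(208 -> pool4 -> 52 -> pool4 -> 13; batch-norm running statistics are
buffers, not trainable parameters.)  The geometry and hidden width are
configurable; only the total parameter count pins the reference values.

In the cascaded pipeline the classifier input is the normalized image
multiplied elementwise by the binarized predicted tumor mask, cropped to
the mask's bounding box, and resampled to the classifier geometry — the
shallow network then sees the tumor's internal morphology at a normalized
scale (see :func:`cascade_input`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "ClsConfig", "ClassProbability", "MethylationCNN", "build_classifier",
    "count_parameters", "classify", "cascade_input", "CLASS_ORDER",
]

# softmax output order: index 0 = methylated, 1 = unmethylated
CLASS_ORDER = ("methylated", "unmethylated")


@dataclass
class ClsConfig:
    input_height: int = 208
    input_width: int = 208
    in_channels: int = 1
    conv_filters: tuple[int, int] = (16, 4)
    kernel: int = 3
    stride: int = 1
    leaky_slope: float = 0.3
    pool_size: int = 4
    fc_hidden: int = 4
    n_classes: int = 2

    def __post_init__(self):
        if len(self.conv_filters) != 2:
            raise ValueError("exactly two convolutional stages")
        if self.n_classes != 2:
            raise ValueError("binary methylation status: n_classes must be 2")

    def feature_shape(self) -> tuple[int, int, int]:
        """(channels, height, width) after the two conv/pool stages.

        Pooling uses floor division when the pool size does not divide the
        spatial extent.
        """
        h, w = self.input_height, self.input_width
        for _ in range(2):
            h, w = h // self.pool_size, w // self.pool_size
        if h == 0 or w == 0:
            raise ValueError("input too small for two pooling stages")
        return self.conv_filters[1], h, w


@dataclass
class ClassProbability:
    """Softmax output (p_methylated, p_unmethylated)."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (2,) or abs(self.p.sum() - 1.0) > 1e-6:
            raise ValueError("p must be a length-2 vector summing to 1")

    @property
    def p_methylated(self) -> float:
        return float(self.p[0])

    @property
    def label(self) -> str:
        return CLASS_ORDER[int(np.argmax(self.p))]


class MethylationCNN(nn.Module):
    """conv-LeakyReLU-BN-pool x2, then FC(hidden, ReLU) -> FC(2, softmax)."""

    def __init__(self, config: ClsConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        pad = c.kernel // 2  # 'same' convolution
        self.conv1 = nn.Conv2d(c.in_channels, c.conv_filters[0], c.kernel,
                               stride=c.stride, padding=pad, rng=rng)
        self.bn1 = nn.BatchNorm2d(c.conv_filters[0])
        self.conv2 = nn.Conv2d(c.conv_filters[0], c.conv_filters[1], c.kernel,
                               stride=c.stride, padding=pad, rng=rng)
        self.bn2 = nn.BatchNorm2d(c.conv_filters[1])
        ch, fh, fw = c.feature_shape()
        self.fc1 = nn.Linear(ch * fh * fw, c.fc_hidden, rng=rng)
        self.fc2 = nn.Linear(c.fc_hidden, c.n_classes, rng=rng)

    def logits(self, x: Tensor) -> Tensor:
        c = self.config
        h = nn.max_pool2d(self.bn1(nn.leaky_relu(self.conv1(x), c.leaky_slope)),
                          c.pool_size)
        h = nn.max_pool2d(self.bn2(nn.leaky_relu(self.conv2(h), c.leaky_slope)),
                          c.pool_size)
        h = h.reshape(h.shape[0], -1)
        return self.fc2(nn.relu(self.fc1(h)))

    def forward(self, x: Tensor) -> Tensor:
        """Softmax class probabilities, shape (N, 2)."""
        z = self.logits(x)
        e = np.exp(z.data - z.data.max(axis=1, keepdims=True))
        return Tensor(e / e.sum(axis=1, keepdims=True))

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Class probabilities for a batch (or single) of 2D slices."""
        arr = np.asarray(images, dtype=np.float32)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        was_training = self.training
        self.eval()
        p = self.forward(Tensor(arr[:, None])).data
        if was_training:
            self.train()
        return p[0] if single else p


def build_classifier(config: ClsConfig | None = None, seed: int = 0) -> MethylationCNN:
    return MethylationCNN(config or ClsConfig(), seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Trainable parameter count (conv/FC weights and biases, batch-norm
    scale and shift; running statistics excluded)."""
    return model.n_parameters()


def cascade_input(image: np.ndarray, mask: np.ndarray, height: int,
                  width: int, margin: int = 4) -> np.ndarray:
    """Build the classifier input from a slice and its (predicted) tumor mask.

    The normalized image is multiplied elementwise by the binary mask,
    cropped to the mask's bounding box (with a small margin) and resampled
    to the classifier geometry.  The crop normalizes tumor scale so the
    shallow CNN sees the tumor's internal morphology rather than its size
    or position; an empty mask yields an all-zero input.
    """
    from skimage.transform import resize

    img = np.asarray(image, dtype=float)
    m = np.asarray(mask) > 0
    if img.shape != m.shape:
        raise ValueError("image and mask shapes differ")
    masked = img * m
    ys, xs = np.nonzero(m)
    if ys.size == 0:
        return np.zeros((height, width), dtype=np.float32)
    y0, y1 = max(0, ys.min() - margin), min(m.shape[0], ys.max() + 1 + margin)
    x0, x1 = max(0, xs.min() - margin), min(m.shape[1], xs.max() + 1 + margin)
    crop = masked[y0:y1, x0:x1]
    return resize(crop, (height, width), order=1, preserve_range=True,
                  anti_aliasing=False).astype(np.float32)


def classify(image: np.ndarray, model: MethylationCNN) -> ClassProbability:
    """Deterministic inference on a single slice at the model geometry."""
    img = np.asarray(image)
    c = model.config
    if img.shape != (c.input_height, c.input_width):
        raise ValueError(
            f"image shape {img.shape} does not match classifier geometry "
            f"({c.input_height}, {c.input_width}); resample first")
    return ClassProbability(model.predict_proba(img))
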
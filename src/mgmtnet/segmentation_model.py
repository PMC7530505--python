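"""VAE-regularized encoder-decoder network for whole-tumor segmentation.

The architecture follows the BraTS-style design of a fully convolutional
encoder-decoder with an auxiliary variational-autoencoder branch: the
encoder halves the spatial dimensions with stride-2 convolutions while
doubling channels; the decoder mirrors it with nearest-neighbour
upsampling, 1x1 channel-reduction convolutions and additive skip
connections, ending in a sigmoid probability map at input resolution.  The
VAE branch compresses the encoder endpoint to a diagonal Gaussian latent
(default 256 dimensions, N(0,1) prior), and reconstructs the input through
a decoder-like path without skip connections — a regularizer that is
especially useful on small cohorts.

Training loss (soft Dice + weighted reconstruction and KL terms):

    L = L_Dice + 0.1 * L_L2 + 0.1 * L_KL

with soft Dice 2*sum(p*q) / (sum(p^2) + sum(q^2) + eps), eps = 1e-8.
Both output heads are 3x3 convolutions with dropout 0.2 and an L2 weight
penalty of 1e-3.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import nn
from .nn import Tensor, autograd

__all__ = [
    "SegConfig", "SegOutput", "ResBlock", "SegmentationNet",
    "build_seg_model", "soft_dice", "dice_loss", "reconstruction_loss",
    "kl_loss", "total_loss", "seg_training_loss",
]


@dataclass
class SegConfig:
    input_height: int = 96
    input_width: int = 96
    in_channels: int = 1
    base_channels: int = 32
    depth: int = 4
    blocks_per_level: int = 1
    latent_dim: int = 256
    vae_reduce_channels: int = 16
    dropout_rate: float = 0.2
    l2_weight: float = 1e-3
    w_l2: float = 0.1
    w_kl: float = 0.1
    dice_epsilon: float = 1e-8

    def __post_init__(self):
        d = 2 ** self.depth
        if self.input_height % d or self.input_width % d:
            raise ValueError(
                f"input dims {self.input_height}x{self.input_width} must be "
                f"divisible by 2^depth = {d}")
        if self.latent_dim <= 0:
            raise ValueError("latent_dim must be positive")
        if min(self.w_l2, self.w_kl, self.l2_weight) < 0:
            raise ValueError("loss weights must be non-negative")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "SegConfig":
        return cls(**d)


@dataclass
class SegOutput:
    """Forward-pass bundle: tumor probabilities, VAE reconstruction and the
    latent Gaussian parameters."""

    probability_map: Tensor
    reconstruction: Tensor
    mu: Tensor
    logvar: Tensor


# ----------------------------------------------------------------------
# losses (accept numpy arrays or autograd Tensors; plain-array calls
# return python floats)

def _pair(pred, truth):
    tensor_in = isinstance(pred, Tensor) or isinstance(truth, Tensor)
    p = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=float))
    t = truth if isinstance(truth, Tensor) else Tensor(np.asarray(truth, dtype=float))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return p, t, tensor_in


def soft_dice(pred, truth, epsilon: float = 1e-8):
    """Soft Dice overlap 2*sum(p*q) / (sum(p^2)+sum(q^2)+eps) in [0, 1]."""
    p, t, tensor_in = _pair(pred, truth)
    num = (p * t).sum() * 2.0
    den = (p * p).sum() + (t * t).sum() + epsilon
    out = num / den
    return out if tensor_in else float(out)


def dice_loss(pred, truth, epsilon: float = 1e-8):
    """1 - soft Dice; the segmentation term of the composite loss."""
    out = 1.0 - soft_dice(pred, truth, epsilon)
    return out if isinstance(out, Tensor) else float(out)


def reconstruction_loss(reconstruction, input_image):
    """Mean squared difference between VAE output and the input image."""
    a, b, tensor_in = _pair(reconstruction, input_image)
    d = a - b
    out = (d * d).mean()
    return out if tensor_in else float(out)


def kl_loss(mu, logvar):
    """KL(N(mu, exp(logvar)) || N(0, 1)) for a diagonal Gaussian.

    0.5 * sum_j(mu_j^2 + exp(logvar_j) - logvar_j - 1); for batched (N, d)
    inputs the per-sample KL is averaged over the batch.
    """
    tensor_in = isinstance(mu, Tensor) or isinstance(logvar, Tensor)
    m = mu if isinstance(mu, Tensor) else Tensor(np.asarray(mu, dtype=float))
    lv = logvar if isinstance(logvar, Tensor) else Tensor(np.asarray(logvar, dtype=float))
    if m.shape != lv.shape:
        raise ValueError("mu and logvar shapes differ")
    if not (np.isfinite(m.data).all() and np.isfinite(lv.data).all()):
        raise ValueError("non-finite latent parameters")
    per = (m * m + nn.exp(lv) - lv - 1.0) * 0.5
    out = per.sum() if m.ndim == 1 else per.sum(axis=1).mean()
    return out if tensor_in else float(out)


def total_loss(dice_l, l2_l, kl_l, config: SegConfig | None = None,
               w_l2: float | None = None, w_kl: float | None = None):
    """Composite loss: Dice term + 0.1 * reconstruction + 0.1 * KL."""
    if config is not None:
        w_l2, w_kl = config.w_l2, config.w_kl
    w_l2 = 0.1 if w_l2 is None else w_l2
    w_kl = 0.1 if w_kl is None else w_kl
    for name, v in (("dice", dice_l), ("l2", l2_l), ("kl", kl_l)):
        val = float(v.data) if isinstance(v, Tensor) else float(v)
        if not np.isfinite(val) or val < 0:
            raise ValueError(f"{name} loss component must be finite and >= 0, got {val}")
    out = dice_l + w_l2 * l2_l + w_kl * kl_l
    return out if isinstance(out, Tensor) else float(out)


# ----------------------------------------------------------------------
# architecture

class ResBlock(nn.Module):
    """Pre-activation residual block: two 3x3 convolutions, each preceded
    by group normalization and ReLU, plus an additive skip connection."""

    def __init__(self, channels: int, rng: np.random.Generator, groups: int = 8):
        super().__init__()
        self.n1 = nn.GroupNorm(groups, channels)
        self.c1 = nn.Conv2d(channels, channels, 3, rng=rng)
        self.n2 = nn.GroupNorm(groups, channels)
        self.c2 = nn.Conv2d(channels, channels, 3, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.c1(nn.relu(self.n1(x)))
        h = self.c2(nn.relu(self.n2(h)))
        return x + h


class _UpStage(nn.Module):
    """Upsample x2 then 1x1 convolution halving the channel count."""

    def __init__(self, in_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, in_ch // 2, 1, padding=0, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(nn.upsample_nearest2d(x, 2))


class SegmentationNet(nn.Module):
    """Encoder-decoder with VAE branch; see module docstring.

    Training loops live in :mod:`mgmtnet.training`; this class is the bare
    network plus single-slice inference helpers (:meth:`predict_proba`,
    :meth:`predict_mask`).
    """

    def __init__(self, config: SegConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        chans = [c.base_channels * 2 ** i for i in range(c.depth + 1)]
        self.stem = nn.Conv2d(c.in_channels, chans[0], 3, rng=rng)
        self.enc_blocks = [
            nn.Sequential(*[ResBlock(ch, rng) for _ in range(c.blocks_per_level)])
            for ch in chans]
        self.down = [nn.Conv2d(chans[i], chans[i + 1], 3, stride=2, rng=rng)
                     for i in range(c.depth)]
        self.dec_up = [_UpStage(chans[i + 1], rng) for i in reversed(range(c.depth))]
        self.dec_blocks = [
            nn.Sequential(*[ResBlock(chans[i], rng) for _ in range(c.blocks_per_level)])
            for i in reversed(range(c.depth))]
        self.seg_dropout = nn.Dropout(c.dropout_rate)
        self.seg_head = nn.Conv2d(chans[0], 1, 3, rng=rng)

        # VAE branch geometry
        hb = c.input_height // 2 ** c.depth
        wb = c.input_width // 2 ** c.depth
        self._vd_stride = 2 if (hb % 2 == 0 and wb % 2 == 0) else 1
        hv, wv = hb // self._vd_stride, wb // self._vd_stride
        self._vae_shape = (c.vae_reduce_channels, hv, wv)
        flat = c.vae_reduce_channels * hv * wv
        self.vd_norm = nn.GroupNorm(8, chans[-1])
        self.vd_conv = nn.Conv2d(chans[-1], c.vae_reduce_channels, 3,
                                 stride=self._vd_stride, rng=rng)
        self.fc_latent = nn.Linear(flat, 2 * c.latent_dim, rng=rng)
        self.fc_up = nn.Linear(c.latent_dim, flat, rng=rng)
        self.vu_conv = nn.Conv2d(c.vae_reduce_channels, chans[-1], 1,
                                 padding=0, rng=rng)
        self.vae_up = [_UpStage(chans[i + 1], rng) for i in reversed(range(c.depth))]
        self.vae_blocks = [
            nn.Sequential(*[ResBlock(chans[i], rng) for _ in range(c.blocks_per_level)])
            for i in reversed(range(c.depth))]
        self.rec_dropout = nn.Dropout(c.dropout_rate)
        self.rec_head = nn.Conv2d(chans[0], c.in_channels, 3, rng=rng)

    # ------------------------------------------------------------------
    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> SegOutput:
        """Full forward pass.  ``rng`` drives dropout masks and the VAE
        reparameterization sample during training; in eval mode dropout is
        disabled and the latent mean is used."""
        rng = rng or np.random.default_rng(0)
        c = self.config
        h = self.stem(x)
        skips = []
        for i in range(c.depth):
            h = self.enc_blocks[i](h)
            skips.append(h)
            h = self.down[i](h)
        h = self.enc_blocks[c.depth](h)

        # segmentation decoder with additive skips
        s = h
        for i in range(c.depth):
            s = self.dec_up[i](s)
            s = s + skips[c.depth - 1 - i]
            s = self.dec_blocks[i](s)
        s = self.seg_dropout(s, rng=rng)
        # clamp away from exact 0/1: float32 sigmoid saturates for |logit|>~17
        prob = autograd.clip(nn.sigmoid(self.seg_head(s)), 1e-6, 1.0 - 1e-6)

        # VAE branch
        v = self.vd_conv(nn.relu(self.vd_norm(h)))
        n = v.shape[0]
        v = v.reshape(n, -1)
        lat = self.fc_latent(v)
        mu_t, lv_t = _split_halves(lat, c.latent_dim)
        if self.training:
            eps = Tensor(rng.standard_normal(mu_t.shape).astype(lat.data.dtype))
            z = mu_t + nn.exp(lv_t * 0.5) * eps
        else:
            z = mu_t
        u = nn.relu(self.fc_up(z))
        u = u.reshape(n, *self._vae_shape)
        u = self.vu_conv(nn.upsample_nearest2d(u, self._vd_stride)
                         if self._vd_stride > 1 else u)
        for i in range(c.depth):
            u = self.vae_up[i](u)
            u = self.vae_blocks[i](u)
        u = self.rec_dropout(u, rng=rng)
        recon = self.rec_head(u)
        return SegOutput(probability_map=prob, reconstruction=recon,
                         mu=mu_t, logvar=lv_t)

    # ------------------------------------------------------------------
    def head_l2_penalty(self) -> Tensor:
        """l2_weight * sum of squared weights of the two output heads."""
        w1, w2 = self.seg_head.weight, self.rec_head.weight
        return ((w1 * w1).sum() + (w2 * w2).sum()) * self.config.l2_weight

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        """Tumor probability map for a single 2D slice (inference mode)."""
        was_training = self.training
        self.eval()
        x = Tensor(np.asarray(image, dtype=np.float32)[None, None])
        out = self.forward(x)
        if was_training:
            self.train()
        return out.probability_map.data[0, 0]

    def predict_mask(self, image: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(image) >= threshold).astype(np.uint8)


def _split_halves(lat: Tensor, d: int):
    """Split a (N, 2d) tensor into two (N, d) halves with gradient flow."""
    mu = Tensor(lat.data[:, :d], requires_grad=lat.requires_grad)
    lv = Tensor(lat.data[:, d:], requires_grad=lat.requires_grad)
    if lat.requires_grad:
        def make_bwd(offset):
            def bwd(g):
                full = np.zeros_like(lat.data)
                full[:, offset:offset + d] = g
                lat._accumulate(full)
            return bwd

        mu._backward, mu._parents = make_bwd(0), (lat,)
        lv._backward, lv._parents = make_bwd(d), (lat,)
    return mu, lv


def build_seg_model(config: SegConfig, seed: int = 0) -> SegmentationNet:
    """Construct the segmentation network from a config."""
    return SegmentationNet(config, seed=seed)


def seg_training_loss(model: SegmentationNet, out: SegOutput, x: Tensor,
                      y: Tensor):
    """Composite training loss and its components.

    Returns (total, parts) where parts holds float values of the Dice,
    reconstruction and KL terms.
    """
    c = model.config
    d = dice_loss(out.probability_map, y, c.dice_epsilon)
    r = reconstruction_loss(out.reconstruction, x)
    k = kl_loss(out.mu, out.logvar)
    tot = total_loss(d, r, k, config=c) + model.head_l2_penalty()
    parts = {"dice_loss": float(d.data), "recon_loss": float(r.data),
             "kl_loss": float(k.data)}
    return tot, parts
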